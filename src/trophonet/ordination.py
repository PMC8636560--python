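"""Niche-segregation analysis: Bray-Curtis similarity, group-average
clustering with percent-similarity cuts, and nonmetric multidimensional
scaling (NMDS) minimizing Kruskal's stress-1.

Profiles are square-root transformed before the similarity computation to
damp the dominance of the most abundant prey. Similarities are reported on
the 0-100 percent scale, so "a 40% similarity cut" reads exactly as in the
community-ecology literature. NMDS is the nonmetric SMACOF scheme: Guttman
majorization steps alternating with an isotonic (pool-adjacent-violators)
fit of configuration distances to the dissimilarity rank order, with weak
("primary") tie handling — tied dissimilarities impose no order constraint.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import cdist, pdist, squareform

from .datamodel import (
    ClusterAssignment,
    NmdsResult,
    PreyProfile,
    SimilarityMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


def profiles_to_matrix(profiles: Iterable[PreyProfile]) -> pd.DataFrame:
    """Stack profiles into an items x prey-keys matrix (missing keys -> 0)."""
    profiles = list(profiles)
    keys = sorted({k for p in profiles for k in p.proportions})
    data = [[p.proportions.get(k, 0.0) for k in keys] for p in profiles]
    return pd.DataFrame(data, index=[p.sample_id for p in profiles], columns=keys)


def transform_profiles(
    profiles: Iterable[PreyProfile] | pd.DataFrame, transform: str = "sqrt"
) -> pd.DataFrame:
    """Element-wise square-root (or identity) transform of a profile matrix."""
    matrix = (
        profiles if isinstance(profiles, pd.DataFrame) else profiles_to_matrix(profiles)
    )
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("profile values must be nonnegative")
    if transform == "sqrt":
        values = np.sqrt(values)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def bray_curtis_similarity(matrix: pd.DataFrame) -> SimilarityMatrix:
    """Percent Bray-Curtis similarity between all rows.

    S(i,j) = 100 * (1 - sum|x_i - x_j| / sum(x_i + x_j)). Pairs where both
    rows are all-zero are undefined; they get similarity 0 and are flagged
    in ``zero_pairs``.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 items")
    if (x < 0).any():
        raise ValidationError("Bray-Curtis input must be nonnegative")
    num = cdist(x, x, metric="cityblock")
    rowsum = x.sum(axis=1)
    den = rowsum[:, None] + rowsum[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = 100.0 * (1.0 - np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0))
    ids = [str(i) for i in matrix.index]
    zero_pairs = []
    zero_rows = np.where(rowsum == 0)[0]
    for a_pos, i in enumerate(zero_rows):
        for j in zero_rows[a_pos + 1 :]:
            zero_pairs.append((ids[i], ids[j]))
            logger.warning("all-zero pair (%s, %s): similarity set to 0", ids[i], ids[j])
    np.fill_diagonal(sim, 100.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 100.0)  # symmetrize rounding noise
    return SimilarityMatrix(item_ids=ids, values=sim, zero_pairs=zero_pairs)


def average_linkage_clusters(
    sim: SimilarityMatrix, threshold: float
) -> ClusterAssignment:
    """Cut a group-average (UPGMA) dendrogram at a percent-similarity level.

    Clusters are the maximal groups whose members merge at similarity >=
    ``threshold`` (i.e. dissimilarity <= 100 - threshold). Items are fed to
    the linkage in lexicographic order so merge ties resolve on the smallest
    id pair; output labels are contiguous from 1 in order of first
    appearance along the matrix's item order.
    """
    if not 0 <= threshold <= 100:
        raise ValidationError(f"threshold {threshold} outside [0, 100]")
    ids = sim.item_ids
    if len(ids) == 1:
        return ClusterAssignment(threshold=threshold, labels={ids[0]: 1})
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    d = sim.dissimilarity()[np.ix_(order, order)]
    z = linkage(squareform(d, checks=False), method="average")
    flat = fcluster(z, t=100.0 - threshold, criterion="distance")
    raw = {ids[order[i]]: int(flat[i]) for i in range(len(ids))}
    relabel: dict[int, int] = {}
    labels = {}
    for item in ids:
        c = raw[item]
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[item] = relabel[c]
    return ClusterAssignment(threshold=threshold, labels=labels)


# -- Kruskal stress-1 and nonmetric SMACOF ----------------------------------


def _disparities(dist: np.ndarray, dissim: np.ndarray) -> np.ndarray:
    """Monotone (PAVA) fit of distances to the dissimilarity rank order.

    Primary tie handling: within blocks of equal dissimilarity the distances
    are pre-sorted ascending, so ties impose no order constraint.
    """
    order = np.lexsort((dist, dissim))
    fitted = isotonic_regression(dist[order], increasing=True).x
    out = np.empty_like(dist)
    out[order] = fitted
    return out


def stress1(coordinates: np.ndarray, sim: SimilarityMatrix) -> float:
    """Kruskal stress-1 of a configuration against a similarity matrix."""
    x = np.asarray(coordinates, dtype=float)
    n = len(sim.item_ids)
    if x.ndim != 2 or x.shape[0] != n:
        raise ValidationError(
            f"coordinates shape {x.shape} does not match {n} items"
        )
    dist = pdist(x)
    dissim = squareform(sim.dissimilarity(), checks=False)
    return _stress1_condensed(dist, dissim)


def _stress1_condensed(dist: np.ndarray, dissim: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom == 0.0:
        return 0.0 if np.allclose(dissim, dissim[0]) else 1.0
    dhat = _disparities(dist, dissim)
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _classical_start(dissim_sq: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling of the dissimilarities (PCoA start)."""
    n = dissim_sq.shape[0]
    j = np.eye(n) - 1.0 / n
    b = -0.5 * j @ (dissim_sq**2) @ j
    evals, evecs = np.linalg.eigh(b)
    idx = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[idx], 0.0, None)
    return evecs[:, idx] * np.sqrt(lam)


def _guttman_step(x: np.ndarray, dhat: np.ndarray, dist: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, dhat / dist, 0.0)
    b = -squareform(ratio, checks=False)
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ x / n


def _nmds_single(
    start: np.ndarray, dissim: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    x = start - start.mean(axis=0)
    dist = pdist(x)
    stress = _stress1_condensed(dist, dissim)
    trace = [stress]
    converged = False
    for _ in range(max_iter):
        dhat = _disparities(dist, dissim)
        x_new = _guttman_step(x, dhat, dist)
        dist_new = pdist(x_new)
        stress_new = _stress1_condensed(dist_new, dissim)
        if stress_new > stress:  # majorization stalled on stress-1; keep best
            break
        improvement = stress - stress_new
        x, dist, stress = x_new, dist_new, stress_new
        trace.append(stress)
        if improvement < tol:
            converged = True
            break
    return x, stress, trace, converged


def nmds(
    sim: SimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NmdsResult:
    """Nonmetric MDS of a percent-similarity matrix into k dimensions.

    One restart starts from classical scaling, the rest from seeded random
    configurations; the configuration with the lowest stress-1 wins and is
    returned centered and rotated to its principal axes.
    """
    n = len(sim.item_ids)
    if n < 3:
        raise ValidationError("NMDS needs at least 3 items")
    if n < k + 1:
        raise ValidationError(f"need more than k+1 = {k + 1} items for k = {k}")
    dissim_mat = sim.dissimilarity()
    dissim = squareform(dissim_mat, checks=False)
    rng = np.random.default_rng(seed)
    scale = max(dissim.max(), 1.0)
    starts = [_classical_start(dissim_mat, k)]
    starts += [
        rng.normal(scale=scale, size=(n, k)) for _ in range(max(n_restarts - 1, 0))
    ]
    best = None
    for start in starts:
        x, stress, trace, conv = _nmds_single(start, dissim, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, trace, conv)
    x, stress, trace, conv = best
    x = x - x.mean(axis=0)
    # principal-axis rotation with a deterministic sign convention
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for a in range(x.shape[1]):
        if x[np.argmax(np.abs(x[:, a])), a] < 0:
            x[:, a] *= -1
    return NmdsResult(
        item_ids=list(sim.item_ids),
        coordinates=x,
        stress=stress,
        n_restarts=len(starts),
        seed=seed,
        converged=conv,
        stress_trace=trace,
    )
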