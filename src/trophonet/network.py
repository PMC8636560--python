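"""Directed trophic networks and PageRank hub scores.

Nodes are predator groups and prey categories (merged into a single
``both``-role node when the labels coincide, e.g. calanoids eaten by other
calanoid families). Edges point predator -> prey, so that random-walk mass
— and hence PageRank importance — accumulates on frequently eaten prey.
Edge weights are either the group's mean standardized-read proportion of
that prey ("reads" mode) or its appearance frequency ("frequency" mode).

PageRank is computed by power iteration on the column-stochastic transition
matrix built from out-edge weights; nodes without out-edges (pure prey)
redistribute their mass uniformly over all nodes, and teleportation is
uniform with probability 1 - damping.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .datamodel import (
    GroupDietSummary,
    PageRankScores,
    TrophicNetwork,
    ValidationError,
)

logger = logging.getLogger(__name__)

MODES = ("reads", "frequency")

#: Default edge thresholds: trace diet fractions below 1% are dropped in
#: reads mode; frequency mode keeps every observed link.
DEFAULT_EDGE_THRESHOLD = {"reads": 0.01, "frequency": 0.0}


def build_network(
    summaries: Iterable[GroupDietSummary],
    mode: str = "reads",
    edge_threshold: float | None = None,
    node_classes: Mapping[str, str] | None = None,
) -> TrophicNetwork:
    """Directed predator -> prey graph from group diet summaries."""
    if mode not in MODES:
        raise ValidationError(f"unknown network mode {mode!r}")
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("need at least one group summary")
    if edge_threshold is None:
        edge_threshold = DEFAULT_EDGE_THRESHOLD[mode]
    if not 0 <= edge_threshold < 1:
        raise ValidationError("edge_threshold must be in [0, 1)")
    node_classes = dict(node_classes or {})
    g = nx.DiGraph()
    predators = {s.group_key for s in summaries}
    for s in summaries:
        g.add_node(s.group_key)
        weights = s.mean_proportions if mode == "reads" else s.appearance_frequency
        for prey, w in sorted(weights.items()):
            if w > edge_threshold:
                if prey == s.group_key:
                    logger.warning(
                        "self-loop: %s appears in its own diet", s.group_key
                    )
                g.add_edge(s.group_key, prey, weight=float(w))
    for node in g.nodes:
        is_pred = node in predators
        is_prey = g.in_degree(node) > 0
        role = "both" if (is_pred and is_prey) else (
            "predator_group" if is_pred else "prey_category"
        )
        g.nodes[node]["role"] = role
        g.nodes[node]["node_class"] = node_classes.get(node, "other_metazoan")
    return TrophicNetwork(graph=g, mode=mode)


def pagerank(
    network: TrophicNetwork,
    damping: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 1000,
    weighted: bool = True,
) -> PageRankScores:
    """Power-iteration PageRank with dangling-node redistribution.

    Iterates r <- (1-d)/n + d * (P r + dangling mass / n) until the L1
    change falls below ``tol``. Scores sum to 1 at every iteration.
    """
    if not 0 < damping < 1:
        raise ValidationError("damping must be in (0, 1)")
    nodes = list(network.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValidationError("network has no nodes")
    index = {v: i for i, v in enumerate(nodes)}
    p = np.zeros((n, n))  # p[j, i]: probability of stepping i -> j
    for u, v, d in network.graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        if w <= 0:
            raise ValidationError(f"non-positive edge weight on {u!r}->{v!r}")
        p[index[v], index[u]] += w if weighted else 1.0
    out = p.sum(axis=0)
    dangling = out == 0
    p[:, ~dangling] /= out[~dangling]
    r = np.full(n, 1.0 / n)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        r_new = (1.0 - damping) / n + damping * (p @ r + r[dangling].sum() / n)
        delta = np.abs(r_new - r).sum()
        r = r_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("PageRank did not converge in %d iterations", max_iter)
    r = r / r.sum()  # remove accumulated float drift
    return PageRankScores(
        scores={v: float(r[index[v]]) for v in nodes},
        damping=damping,
        iterations=iterations,
        converged=converged,
    )


def rank_hubs(scores: PageRankScores, top_n: int = 5) -> list[str]:
    """Nodes by descending PageRank, ties broken lexicographically."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ordered = sorted(scores.scores, key=lambda v: (-scores.scores[v], v))
    return ordered[:top_n]
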