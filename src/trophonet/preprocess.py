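"""Gut-content filtering and per-group diet summarization.

Stages: zero out host/contaminant categories per predator group, keep each
sample's k most abundant prey OTUs, standardize the retained counts to
proportions (standardized sequence reads), aggregate OTU proportions into
prey categories, and summarize each predator group or species by its mean
proportions and per-category appearance frequencies.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    GUT,
    EliminationRuleSet,
    GroupDietSummary,
    MetadataTable,
    OtuCountTable,
    PreyProfile,
    Taxonomy,
    ValidationError,
)

logger = logging.getLogger(__name__)


def eliminate_taxa(
    table: OtuCountTable,
    taxonomy: Taxonomy,
    metadata: MetadataTable,
    rules: EliminationRuleSet,
) -> OtuCountTable:
    """Zero host/contaminant categories out of each gut sample's counts.

    Water samples pass through untouched. OTUs left with zero reads in every
    sample are dropped from the OTU axis.
    """
    counts = table.counts.copy()
    categories = np.array([taxonomy.category(o) for o in counts.columns])
    for sample_id in counts.index:
        meta = metadata[sample_id]
        if meta.sample_kind != GUT:
            continue
        eliminated = rules.eliminated_for(meta.predator_group)
        mask = np.isin(categories, list(eliminated))
        if mask.any():
            removed = counts.loc[sample_id].to_numpy()[mask].sum()
            counts.loc[sample_id, mask] = 0
            for cat in sorted(eliminated & set(categories[mask])):
                logger.info(
                    "eliminated category %s from %s (group %s)",
                    cat,
                    sample_id,
                    meta.predator_group,
                )
            logger.debug("removed %d reads from %s", removed, sample_id)
    keep = counts.columns[(counts.to_numpy() != 0).any(axis=0)]
    return OtuCountTable(counts[keep])


def select_dominant_otus(sample_counts: pd.Series, k: int = 10) -> list[str]:
    """The k highest-count prey OTUs of one sample.

    Only OTUs with nonzero counts are eligible; ties at the cut are broken
    by ascending OTU id for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nonzero = sample_counts[sample_counts > 0]
    order = sorted(nonzero.index, key=lambda o: (-nonzero[o], o))
    return order[:k]


def standardize_reads(sample_counts: pd.Series, selected: Iterable[str]) -> PreyProfile:
    """Counts over the selected OTUs, divided by their total (standardized SRs)."""
    selected = list(selected)
    missing = [o for o in selected if o not in sample_counts.index]
    if missing:
        raise ValidationError(f"selected OTUs absent from sample: {missing}")
    sub = sample_counts.loc[selected]
    total = int(sub.sum())
    name = str(sample_counts.name) if sample_counts.name is not None else ""
    if total == 0:
        return PreyProfile(sample_id=name, proportions={}, n_prey_reads=0)
    return PreyProfile(
        sample_id=name,
        proportions={o: float(c) / total for o, c in sub.items() if c > 0},
        n_prey_reads=total,
    )


def aggregate_by_category(profile: PreyProfile, taxonomy: Taxonomy) -> PreyProfile:
    """Sum OTU-level proportions within prey categories; total is preserved."""
    if profile.is_empty:
        return PreyProfile(profile.sample_id, {}, 0)
    agg: dict[str, float] = {}
    for otu, p in profile.proportions.items():
        agg[taxonomy.category(otu)] = agg.get(taxonomy.category(otu), 0.0) + p
    return PreyProfile(profile.sample_id, agg, profile.n_prey_reads)


def compute_profiles(
    table: OtuCountTable,
    taxonomy: Taxonomy,
    metadata: MetadataTable,
    rules: EliminationRuleSet,
    k_dominant: int = 10,
    aggregate: bool = True,
) -> tuple[list[PreyProfile], list[str]]:
    """Eliminate, select, standardize (and optionally aggregate) every sample.

    Returns the per-sample profiles in table order plus the ids of samples
    that ended up with no prey reads (flagged, kept out of summaries).
    """
    filtered = eliminate_taxa(table, taxonomy, metadata, rules)
    profiles: list[PreyProfile] = []
    empty: list[str] = []
    for sample_id in filtered.sample_ids:
        counts = filtered.sample_counts(sample_id)
        selected = select_dominant_otus(counts, k=k_dominant)
        profile = standardize_reads(counts, selected)
        if aggregate:
            profile = aggregate_by_category(profile, taxonomy)
        if profile.is_empty:
            empty.append(sample_id)
            logger.warning("sample %s has no prey reads after filtering", sample_id)
        profiles.append(profile)
    return profiles, empty


def summarize_group(
    profiles: Iterable[PreyProfile],
    grouping: Mapping[str, str] | Callable[[str], str],
    min_presence: float = 0.0,
) -> list[GroupDietSummary]:
    """Per-group mean proportions and appearance frequencies.

    Means and frequencies are taken over the group's non-empty profiles;
    ``n_replicates`` counts all of its individuals. A category "appears" in
    a sample when its proportion exceeds ``min_presence`` (default: any
    nonzero standardized reads). Groups whose profiles are all empty yield a
    flagged summary with empty mappings.
    """
    if callable(grouping):
        group_of = grouping
    else:
        mapping = dict(grouping)

        def group_of(sample_id: str) -> str:
            try:
                return mapping[sample_id]
            except KeyError:
                raise ValidationError(
                    f"sample {sample_id!r} missing from grouping"
                ) from None

    by_group: dict[str, list[PreyProfile]] = {}
    for p in profiles:
        by_group.setdefault(group_of(p.sample_id), []).append(p)

    summaries = []
    for group in sorted(by_group):
        members = by_group[group]
        nonempty = [p for p in members if not p.is_empty]
        if not nonempty:
            summaries.append(
                GroupDietSummary(
                    group_key=group,
                    n_replicates=len(members),
                    mean_proportions={},
                    appearance_frequency={},
                    n_nonempty=0,
                    flagged_empty=True,
                )
            )
            continue
        cats = sorted({c for p in nonempty for c in p.proportions})
        mean = {
            c: float(np.mean([p.proportions.get(c, 0.0) for p in nonempty]))
            for c in cats
        }
        freq = {
            c: sum(p.proportions.get(c, 0.0) > min_presence for p in nonempty)
            / len(nonempty)
            for c in cats
        }
        summaries.append(
            GroupDietSummary(
                group_key=group,
                n_replicates=len(members),
                mean_proportions=mean,
                appearance_frequency=freq,
                n_nonempty=len(nonempty),
            )
        )
    return summaries


def grouping_by_metadata(
    metadata: MetadataTable, level: str = "group", water_key: str = "water"
) -> dict[str, str]:
    """sample id -> predator group (or species), water samples pooled."""
    if level not in ("group", "species"):
        raise ValueError("level must be 'group' or 'species'")
    out = {}
    for r in metadata:
        if r.sample_kind == GUT:
            out[r.sample_id] = (
                r.predator_group if level == "group" else (r.predator_species or r.predator_group)
            )
        else:
            out[r.sample_id] = water_key
    return out


def summaries_to_frames(
    summaries: Iterable[GroupDietSummary],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two tables (groups x categories): mean proportions and frequencies."""
    summaries = list(summaries)
    cats = sorted({c for s in summaries for c in s.mean_proportions})
    prop = pd.DataFrame(
        [[s.mean_proportions.get(c, 0.0) for c in cats] for s in summaries],
        index=[s.group_key for s in summaries],
        columns=cats,
    )
    freq = pd.DataFrame(
        [[s.appearance_frequency.get(c, 0.0) for c in cats] for s in summaries],
        index=[s.group_key for s in summaries],
        columns=cats,
    )
    return prop, freq
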