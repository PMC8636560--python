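"""Domain types shared by every stage of the diet-analysis pipeline.

The pipeline's raw input is a sample x OTU table of sequencing read counts
from gut-content (or ambient-water) metabarcoding, together with a taxonomy
mapping each OTU to a prey category, per-sample metadata (gut vs. water,
predator group/species, feeding habit), and a rule set saying which
categories are host signal or contamination for each predator group.
Downstream stages exchange per-sample standardized prey profiles,
group-level diet summaries, similarity matrices, ordination results, and
directed trophic networks with node-importance scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

GUT = "gut"
WATER = "water"

FEEDING_HABITS = ("omnivore", "carnivore", "not_applicable")
NODE_CLASSES = (
    "crustacean",
    "gelatinous",
    "autotroph",
    "protozoan",
    "other_metazoan",
)

#: Macro-category keyword expanded by :class:`EliminationRuleSet`.
PHYTOPLANKTON = "Phytoplankton"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {axis} id: {x!r}")
        seen.add(x)


class OtuCountTable:
    """Nonnegative integer read counts, samples on rows, OTUs on columns."""

    def __init__(self, counts: pd.DataFrame):
        _check_unique(list(counts.index), "sample")
        _check_unique(list(counts.columns), "OTU")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            # locate the first offending cell for the error message
            for i, sample in enumerate(counts.index):
                for j, otu in enumerate(counts.columns):
                    v = values[i, j]
                    if v != int(v):
                        raise ValidationError(
                            f"non-integer count {v!r} at sample {sample!r}, OTU {otu!r}"
                        )
            values = values.astype(np.int64)
            counts = pd.DataFrame(values, index=counts.index, columns=counts.columns)
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count {values[i, j]} at sample "
                f"{counts.index[i]!r}, OTU {counts.columns[j]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_counts(self, sample_id: str) -> pd.Series:
        return self.counts.loc[sample_id]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OtuCountTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return (
            f"OtuCountTable({len(self.sample_ids)} samples x "
            f"{len(self.otu_ids)} OTUs)"
        )


@dataclass(frozen=True)
class TaxonomyAssignment:
    """One OTU's lineage (coarse to fine) and its controlled prey category."""

    otu_id: str
    lineage: tuple[str, ...]
    category: str


class Taxonomy:
    """OTU -> :class:`TaxonomyAssignment`, with a closed category vocabulary."""

    def __init__(
        self,
        assignments: Iterable[TaxonomyAssignment],
        vocabulary: Iterable[str] | None = None,
    ):
        self.assignments: dict[str, TaxonomyAssignment] = {}
        for a in assignments:
            if a.otu_id in self.assignments:
                raise ValidationError(f"duplicate taxonomy entry for OTU {a.otu_id!r}")
            self.assignments[a.otu_id] = a
        self.vocabulary = frozenset(
            vocabulary
            if vocabulary is not None
            else (a.category for a in self.assignments.values())
        )
        for a in self.assignments.values():
            if a.category not in self.vocabulary:
                raise ValidationError(
                    f"OTU {a.otu_id!r} has category {a.category!r} "
                    "outside the declared vocabulary"
                )

    def category(self, otu_id: str) -> str:
        try:
            return self.assignments[otu_id].category
        except KeyError:
            raise ValidationError(f"no taxonomy assignment for OTU {otu_id!r}") from None

    def categories(self, otu_ids: Iterable[str]) -> pd.Series:
        return pd.Series({o: self.category(o) for o in otu_ids})

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    sample_kind: str  # gut | water
    predator_group: str = ""
    predator_species: str = ""
    feeding_habit: str = "not_applicable"
    station: str = ""

    def __post_init__(self) -> None:
        if self.sample_kind not in (GUT, WATER):
            raise ValidationError(
                f"sample {self.sample_id!r}: sample_kind must be "
                f"'{GUT}' or '{WATER}', got {self.sample_kind!r}"
            )
        if self.feeding_habit not in FEEDING_HABITS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown feeding habit "
                f"{self.feeding_habit!r}"
            )
        if self.sample_kind == GUT:
            if not self.predator_group:
                raise ValidationError(
                    f"gut sample {self.sample_id!r} has no predator_group"
                )
            if self.feeding_habit == "not_applicable":
                raise ValidationError(
                    f"gut sample {self.sample_id!r} needs a feeding habit"
                )
        elif self.feeding_habit != "not_applicable":
            raise ValidationError(
                f"water sample {self.sample_id!r} must have "
                "feeding_habit = not_applicable"
            )


class MetadataTable:
    """Per-sample metadata keyed by sample id."""

    def __init__(self, records: Iterable[SampleMetadata]):
        self.records: dict[str, SampleMetadata] = {}
        for r in records:
            if r.sample_id in self.records:
                raise ValidationError(f"duplicate metadata for sample {r.sample_id!r}")
            self.records[r.sample_id] = r

    def __getitem__(self, sample_id: str) -> SampleMetadata:
        try:
            return self.records[sample_id]
        except KeyError:
            raise ValidationError(f"no metadata for sample {sample_id!r}") from None

    def __iter__(self):
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    def gut_samples(self) -> list[SampleMetadata]:
        return [r for r in self if r.sample_kind == GUT]

    def water_samples(self) -> list[SampleMetadata]:
        return [r for r in self if r.sample_kind == WATER]


class EliminationRuleSet:
    """Which prey categories to zero out of each predator group's gut reads.

    ``global_eliminations`` apply to every gut sample (typically Craniata and
    Fungi contamination); per-group sets add the host taxon itself and, for
    carnivores, the phytoplankton macro-category, which expands to the
    autotroph categories given in ``phytoplankton_categories``.
    """

    def __init__(
        self,
        per_group: Mapping[str, Iterable[str]],
        global_eliminations: Iterable[str] = (),
        phytoplankton_categories: Iterable[str] = (),
        vocabulary: Iterable[str] | None = None,
    ):
        self.phytoplankton_categories = frozenset(phytoplankton_categories)
        self.global_eliminations = frozenset(global_eliminations)
        self.per_group = {g: frozenset(cats) for g, cats in per_group.items()}
        if vocabulary is not None:
            vocab = frozenset(vocabulary) | {PHYTOPLANKTON}
            for where, cats in [("global", self.global_eliminations)] + [
                (g, c) for g, c in self.per_group.items()
            ]:
                for c in cats:
                    if c not in vocab:
                        raise ValidationError(
                            f"elimination rule for {where!r} names category "
                            f"{c!r} absent from the declared vocabulary"
                        )

    def _expand(self, cats: frozenset[str]) -> frozenset[str]:
        if PHYTOPLANKTON in cats:
            cats = (cats - {PHYTOPLANKTON}) | self.phytoplankton_categories
        return cats

    def eliminated_for(self, predator_group: str) -> frozenset[str]:
        """Full eliminated set (global merged in, macro-category expanded)."""
        if predator_group not in self.per_group:
            raise ValidationError(
                f"no elimination rule for predator group {predator_group!r}"
            )
        return self._expand(self.per_group[predator_group] | self.global_eliminations)

    @property
    def groups(self) -> list[str]:
        return sorted(self.per_group)


@dataclass
class PreyProfile:
    """Per-sample standardized prey proportions.

    ``proportions`` maps a prey key (OTU id or category) to its fraction of
    the sample's retained prey reads; the mapping is empty iff the sample had
    no prey reads left after elimination and dominant-OTU selection.
    """

    sample_id: str
    proportions: dict[str, float]
    n_prey_reads: int

    def __post_init__(self) -> None:
        if self.n_prey_reads < 0:
            raise ValidationError("n_prey_reads must be >= 0")
        if self.n_prey_reads == 0 and self.proportions:
            raise ValidationError(
                f"sample {self.sample_id!r}: nonempty proportions with zero prey reads"
            )
        if self.n_prey_reads > 0:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"sample {self.sample_id!r}: proportions sum to {total}, not 1"
                )

    @property
    def is_empty(self) -> bool:
        return self.n_prey_reads == 0


@dataclass
class GroupDietSummary:
    """Mean prey proportions and appearance frequencies for one predator group.

    ``appearance_frequency[c]`` is the fraction of the group's non-empty gut
    profiles in which category ``c`` occurs at all, regardless of abundance.
    ``n_replicates`` counts all individuals assigned to the group;
    ``n_nonempty`` those that retained any prey reads.
    """

    group_key: str
    n_replicates: int
    mean_proportions: dict[str, float]
    appearance_frequency: dict[str, float]
    n_nonempty: int = 0
    flagged_empty: bool = False


@dataclass
class SimilarityMatrix:
    """Symmetric percent similarities in [0, 100], diagonal 100."""

    item_ids: list[str]
    values: np.ndarray
    zero_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if v.shape != (n, n):
            raise ValidationError(f"similarity matrix shape {v.shape} != ({n},{n})")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("similarity matrix is not symmetric")
        if v.size and (v.min() < -1e-9 or v.max() > 100 + 1e-9):
            raise ValidationError("similarities must lie in [0, 100]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_ids, columns=self.item_ids)

    def dissimilarity(self) -> np.ndarray:
        return 100.0 - self.values


@dataclass
class ClusterAssignment:
    threshold: float
    labels: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


@dataclass
class NmdsResult:
    item_ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    seed: int
    converged: bool
    #: stress-1 after each accepted iteration of the best restart
    stress_trace: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        return pd.DataFrame(
            self.coordinates,
            index=self.item_ids,
            columns=[f"NMDS{i + 1}" for i in range(k)],
        )


@dataclass
class TrophicNetwork:
    """Directed predator -> prey graph with positive edge weights.

    Node attributes: ``role`` in {predator_group, prey_category, both} and
    ``node_class`` in {crustacean, gelatinous, autotroph, protozoan,
    other_metazoan}. Edge weights are mean standardized-read proportions
    (mode "reads") or appearance frequencies (mode "frequency").
    """

    graph: nx.DiGraph
    mode: str

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


@dataclass
class PageRankScores:
    scores: dict[str, float]
    damping: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.scores:
            total = sum(self.scores.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"PageRank scores sum to {total}, not 1")
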