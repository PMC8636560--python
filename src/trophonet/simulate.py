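"""Synthetic gut-content metabarcoding data with planted ground truth.

The generator emulates the downstream structure of an 18S V9 gut-content
sequencing study: per-predator-group replicate individuals whose reads are
dominated by the host taxon plus fungal and craniate contamination, with the
remaining reads spread over a handful of prey categories; ambient-water
samples drawn from a calanoid/dinoflagellate-dominated community profile;
and a taxon-specific rDNA copy-number multiplier that biases read shares
away from true cell proportions.

Each individual's diet is a Dirichlet draw around its group's mean diet
(overdispersion across replicates), and reads are a single multinomial draw
over OTUs, giving Dirichlet-multinomial counts overall. Every sample has
its own RNG substream derived from (seed, sample id), so subsetting samples
never changes the reads of the rest.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    GUT,
    WATER,
    MetadataTable,
    OtuCountTable,
    SampleMetadata,
    Taxonomy,
    TaxonomyAssignment,
    ValidationError,
)
from . import io as tio

#: Within-category OTU abundance ratio: OTU j of a category receives a share
#: proportional to OTU_DECAY**j, so each category has one clearly dominant OTU.
OTU_DECAY = 0.3

HOST_CATEGORY_OF_GROUP = str  # host reads are assigned the group's own category


@dataclass(frozen=True)
class DietSpec:
    """Mean diet and Dirichlet concentration for one predator group."""

    predator_group: str
    mean_diet: Mapping[str, float]
    concentration: float = 20.0
    feeding_habit: str = "omnivore"
    species: str = ""
    guild: str = ""  # defaults to predator_group

    def __post_init__(self) -> None:
        fracs = np.array(list(self.mean_diet.values()), dtype=float)
        if (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"mean_diet for {self.predator_group!r} must be nonnegative "
                f"and sum to 1 (got sum {fracs.sum()})"
            )
        if self.concentration <= 0:
            raise ValidationError("concentration must be > 0")

    @property
    def guild_label(self) -> str:
        return self.guild or self.predator_group


@dataclass
class SimulationConfig:
    diet_specs: list[DietSpec]
    n_individuals_per_group: int = 12
    reads_per_individual: int = 14286
    host_read_fraction: float = 0.30
    contaminant_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"Fungi": 0.27, "Craniata": 0.29}
    )
    copy_number_bias: Mapping[str, float] = field(default_factory=dict)
    otus_per_category: int = 3
    water_profile: Mapping[str, float] = field(default_factory=dict)
    n_water_samples: int = 6
    hub_category: str = ""
    station: str = "St1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.diet_specs:
            raise ValidationError("at least one DietSpec is required")
        if self.n_individuals_per_group < 1 or self.reads_per_individual < 1:
            raise ValidationError("sample sizes must be positive")
        if self.otus_per_category < 1:
            raise ValidationError("otus_per_category must be >= 1")
        nuisance = self.host_read_fraction + sum(self.contaminant_fractions.values())
        if not 0 <= self.host_read_fraction < 1 or nuisance >= 1:
            raise ValidationError(
                "host and contaminant fractions must be in [0,1) and sum to < 1 "
                f"(got {nuisance})"
            )
        if any(v <= 0 for v in self.copy_number_bias.values()):
            raise ValidationError("copy-number multipliers must be > 0")
        if self.water_profile:
            w = np.array(list(self.water_profile.values()), dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValidationError("water_profile must be nonnegative, sum 1")


@dataclass
class GroundTruth:
    """What was planted: realized per-sample diets, guild labels, and hub."""

    diets: dict[str, dict[str, float]]  # gut sample -> category -> fraction
    guilds: dict[str, str]  # predator group -> guild label
    hub_category: str = ""

    def guild_of_sample(self, metadata: MetadataTable) -> dict[str, int]:
        """Gut sample -> integer guild label (for partition-recovery checks)."""
        order = {g: i for i, g in enumerate(sorted(set(self.guilds.values())))}
        return {
            s: order[self.guilds[metadata[s].predator_group]] for s in self.diets
        }


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode("utf-8"))])


def _otu_ids(category: str, n: int) -> list[str]:
    return [f"{category}_OTU{j + 1}" for j in range(n)]


def _otu_split(n: int) -> np.ndarray:
    w = OTU_DECAY ** np.arange(n)
    return w / w.sum()


def _category_probs_to_otu_probs(
    cat_probs: Mapping[str, float], otus_per_category: int
) -> tuple[list[str], np.ndarray]:
    otus: list[str] = []
    probs: list[float] = []
    split = _otu_split(otus_per_category)
    for cat in sorted(cat_probs):
        p = cat_probs[cat]
        if p <= 0:
            continue
        otus.extend(_otu_ids(cat, otus_per_category))
        probs.extend(p * split)
    return otus, np.asarray(probs, dtype=float)


def _apply_bias(
    fractions: Mapping[str, float], bias: Mapping[str, float]
) -> dict[str, float]:
    weighted = {c: f * bias.get(c, 1.0) for c, f in fractions.items()}
    total = sum(weighted.values())
    return {c: w / total for c, w in weighted.items()}


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[OtuCountTable, Taxonomy, MetadataTable, GroundTruth]:
    """Draw a full synthetic dataset (counts, taxonomy, metadata, truth).

    For each gut individual the read-generating composition is
    ``host_read_fraction`` on the host's own category, the configured
    contaminant fractions on Fungi/Craniata, and the remaining mass on the
    individual's Dirichlet diet re-weighted by the per-category copy-number
    multipliers. Reads are one multinomial draw of ``reads_per_individual``
    over OTUs (``otus_per_category`` per category, geometric within-category
    split). Water samples are drawn the same way from ``water_profile``
    without host or contaminants. Identical config and seed give identical
    output.
    """
    nuisance = config.host_read_fraction + sum(config.contaminant_fractions.values())
    prey_mass = 1.0 - nuisance
    rows: dict[str, dict[str, int]] = {}
    metadata: list[SampleMetadata] = []
    truth_diets: dict[str, dict[str, float]] = {}
    guilds: dict[str, str] = {}

    for spec in config.diet_specs:
        guilds[spec.predator_group] = spec.guild_label
        cats = sorted(c for c, f in spec.mean_diet.items() if f > 0)
        alpha = np.array(
            [spec.concentration * spec.mean_diet[c] for c in cats], dtype=float
        )
        for i in range(config.n_individuals_per_group):
            sample_id = f"{spec.predator_group}_{i + 1:02d}"
            rng = _sample_rng(config.seed, sample_id)
            diet = rng.dirichlet(alpha)
            diet_map = dict(zip(cats, diet))
            truth_diets[sample_id] = dict(diet_map)
            biased = _apply_bias(diet_map, config.copy_number_bias)
            composition: dict[str, float] = {
                c: prey_mass * f for c, f in biased.items()
            }
            if config.host_read_fraction > 0:
                host_cat = spec.predator_group
                composition[host_cat] = (
                    composition.get(host_cat, 0.0) + config.host_read_fraction
                )
            for c, f in config.contaminant_fractions.items():
                if f > 0:
                    composition[c] = composition.get(c, 0.0) + f
            otus, probs = _category_probs_to_otu_probs(
                composition, config.otus_per_category
            )
            counts = rng.multinomial(config.reads_per_individual, probs)
            rows[sample_id] = dict(zip(otus, counts))
            metadata.append(
                SampleMetadata(
                    sample_id=sample_id,
                    sample_kind=GUT,
                    predator_group=spec.predator_group,
                    predator_species=spec.species,
                    feeding_habit=spec.feeding_habit,
                    station=config.station,
                )
            )

    if config.water_profile:
        biased_water = _apply_bias(config.water_profile, config.copy_number_bias)
        for i in range(config.n_water_samples):
            sample_id = f"water_{i + 1:02d}"
            rng = _sample_rng(config.seed, sample_id)
            otus, probs = _category_probs_to_otu_probs(
                biased_water, config.otus_per_category
            )
            counts = rng.multinomial(config.reads_per_individual, probs)
            rows[sample_id] = dict(zip(otus, counts))
            metadata.append(
                SampleMetadata(
                    sample_id=sample_id, sample_kind=WATER, station=config.station
                )
            )

    counts_df = (
        pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0)
        .astype(np.int64)
        .sort_index(axis=1)
    )
    counts_df = counts_df.loc[list(rows)]  # keep declared sample order
    table = OtuCountTable(counts_df)
    categories = sorted({o.rsplit("_OTU", 1)[0] for o in counts_df.columns})
    taxonomy = Taxonomy(
        [
            TaxonomyAssignment(
                otu_id=o,
                lineage=("Eukaryota", o.rsplit("_OTU", 1)[0]),
                category=o.rsplit("_OTU", 1)[0],
            )
            for o in counts_df.columns
        ],
        vocabulary=categories,
    )
    truth = GroundTruth(
        diets=truth_diets, guilds=guilds, hub_category=config.hub_category
    )
    return table, taxonomy, MetadataTable(metadata), truth


# -- study-shaped default configurations -------------------------------------

#: Five planted diet guilds over omnivorous copepod families. Calanoida is
#: the universal (hub) prey present in every guild's diet; each guild has two
#: additional guild-specific prey categories.
FIVE_GUILD_DIETS: dict[str, dict[str, float]] = {
    "Calanidae": {"Calanoida": 0.25, "Dinoflagellates": 0.45, "Chlorophyta": 0.30},
    "Oithonidae": {"Calanoida": 0.25, "Hydrozoa": 0.45, "Larvacea": 0.30},
    "Oncaeidae": {"Calanoida": 0.25, "Amphipoda": 0.45, "Poecilostomatoida": 0.30},
    "Temoridae": {"Calanoida": 0.25, "Radiolaria": 0.45, "Thaliacea": 0.30},
    "Paracalanidae": {"Calanoida": 0.25, "Ciliophora": 0.45, "Cyclopoida": 0.30},
}

#: Ambient-water prey availability: calanoid-dominated, then dinoflagellates
#: and poecilostomatoids, with minor gelatinous and protozoan components.
WATER_PROFILE: dict[str, float] = {
    "Calanoida": 0.50,
    "Dinoflagellates": 0.25,
    "Poecilostomatoida": 0.15,
    "Hydrozoa": 0.05,
    "Radiolaria": 0.05,
}


def five_guild_demo_config(
    seed: int = 0,
    n_individuals_per_group: int = 12,
    reads_per_individual: int = 14286,
    concentration: float = 20.0,
    copy_number_bias: Mapping[str, float] | None = None,
) -> SimulationConfig:
    """Study-shaped default scenario: 5 guilds x 12 individuals.

    With the default host (0.30) and contaminant (0.27 + 0.29) fractions,
    14286 reads per individual leave ~2000 expected prey reads each.
    """
    specs = [
        DietSpec(
            predator_group=g,
            mean_diet=d,
            concentration=concentration,
            feeding_habit="omnivore",
        )
        for g, d in FIVE_GUILD_DIETS.items()
    ]
    return SimulationConfig(
        diet_specs=specs,
        n_individuals_per_group=n_individuals_per_group,
        reads_per_individual=reads_per_individual,
        copy_number_bias=dict(copy_number_bias or {}),
        water_profile=WATER_PROFILE,
        hub_category="Calanoida",
        seed=seed,
    )


def make_rules_fixture():
    """Tiny fixture exercising every shipped elimination rule.

    Returns ``(rules, table, taxonomy, metadata)``: the bundled default rule
    set for all 22 predator groups, one toy gut sample per group (plus two
    water samples) whose counts include the group's own host category,
    Craniata, Fungi, two phytoplankton categories and several genuine prey,
    and matching taxonomy/metadata.
    """
    rules = tio.default_rules()
    habits = tio.read_feeding_habits()
    base_counts = {
        "Craniata": 40,
        "Fungi": 35,
        "Dinoflagellates": 20,
        "Chlorophyta": 15,
        "Calanoida": 30,
        "Hydrozoa": 25,
        "Larvacea": 5,
    }
    rows: dict[str, dict[str, int]] = {}
    metadata: list[SampleMetadata] = []
    for group in rules.groups:
        sample_id = f"{group}_gut01"
        counts = {f"{c}_OTU1": n for c, n in base_counts.items()}
        counts[f"{group}_OTU1"] = counts.get(f"{group}_OTU1", 0) + 50  # host signal
        rows[sample_id] = counts
        metadata.append(
            SampleMetadata(
                sample_id=sample_id,
                sample_kind=GUT,
                predator_group=group,
                predator_species=f"{group} sp.",
                feeding_habit=habits[group],
                station="St1",
            )
        )
    for i in (1, 2):
        sample_id = f"water_{i:02d}"
        rows[sample_id] = {
            "Calanoida_OTU1": 50,
            "Dinoflagellates_OTU1": 25,
            "Poecilostomatoida_OTU1": 15,
            "Hydrozoa_OTU1": 5 + i,
            "Radiolaria_OTU1": 5,
        }
        metadata.append(
            SampleMetadata(sample_id=sample_id, sample_kind=WATER, station="St1")
        )
    counts_df = (
        pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0)
        .astype(np.int64)
        .sort_index(axis=1)
    )
    counts_df = counts_df.loc[list(rows)]
    table = OtuCountTable(counts_df)
    vocab = sorted({o.rsplit("_OTU", 1)[0] for o in counts_df.columns})
    taxonomy = Taxonomy(
        [
            TaxonomyAssignment(
                otu_id=o,
                lineage=("Eukaryota", o.rsplit("_OTU", 1)[0]),
                category=o.rsplit("_OTU", 1)[0],
            )
            for o in counts_df.columns
        ],
        vocabulary=vocab,
    )
    return rules, table, taxonomy, MetadataTable(metadata)
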