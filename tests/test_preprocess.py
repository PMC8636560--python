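"""Host/contaminant elimination, dominant-OTU selection, read
standardization and group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trophonet as tn


def _mini_dataset(group="Chaetognatha", habit="carnivore"):
    counts = pd.DataFrame(
        {
            "Chaetognatha_OTU1": [50, 50],
            "Dinoflagellates_OTU1": [20, 20],
            "Calanoida_OTU1": [30, 30],
            "Fungi_OTU1": [10, 10],
        },
        index=["gut1", "water1"],
    )
    table = tn.OtuCountTable(counts)
    taxonomy = tn.Taxonomy(
        [
            tn.TaxonomyAssignment(o, ("Eukaryota",), o.rsplit("_OTU", 1)[0])
            for o in counts.columns
        ]
    )
    metadata = tn.MetadataTable(
        [
            tn.SampleMetadata("gut1", "gut", predator_group=group,
                              feeding_habit=habit, station="St1"),
            tn.SampleMetadata("water1", "water", station="St1"),
        ]
    )
    return table, taxonomy, metadata


class TestEliminateTaxa:
    def test_chaetognath_gut_keeps_only_calanoid_reads(self):
        table, taxonomy, metadata = _mini_dataset()
        out = tn.eliminate_taxa(table, taxonomy, metadata, tn.default_rules())
        gut = out.sample_counts("gut1")
        assert gut["Calanoida_OTU1"] == 30
        # host, phytoplankton (dinoflagellates) and fungi all zeroed
        assert gut.drop("Calanoida_OTU1").sum() == 0 or set(
            gut[gut > 0].index
        ) == {"Calanoida_OTU1"}

    def test_water_sample_passes_through_unchanged(self):
        table, taxonomy, metadata = _mini_dataset()
        out = tn.eliminate_taxa(table, taxonomy, metadata, tn.default_rules())
        before = table.sample_counts("water1")
        after = out.sample_counts("water1")
        assert (after == before[after.index]).all()
        assert after.sum() == before.sum()

    def test_oithonid_sample_untouched_when_rules_match_nothing(self):
        counts = pd.DataFrame(
            {"Calanoida_OTU1": [40], "Dinoflagellates_OTU1": [60]}, index=["g"]
        )
        table = tn.OtuCountTable(counts)
        taxonomy = tn.Taxonomy(
            [tn.TaxonomyAssignment(o, (), o.rsplit("_OTU", 1)[0])
             for o in counts.columns]
        )
        metadata = tn.MetadataTable(
            [tn.SampleMetadata("g", "gut", predator_group="Oithonidae",
                               feeding_habit="omnivore")]
        )
        out = tn.eliminate_taxa(table, taxonomy, metadata, tn.default_rules())
        assert out == table

    def test_unknown_predator_group_rejected(self):
        table, taxonomy, _ = _mini_dataset()
        metadata = tn.MetadataTable(
            [tn.SampleMetadata("gut1", "gut", predator_group="Martians",
                               feeding_habit="carnivore"),
             tn.SampleMetadata("water1", "water")]
        )
        with pytest.raises(tn.ValidationError, match="Martians"):
            tn.eliminate_taxa(table, taxonomy, metadata, tn.default_rules())

    def test_elimination_never_increases_counts(self, rules_fixture):
        rules, table, taxonomy, metadata = rules_fixture
        out = tn.eliminate_taxa(table, taxonomy, metadata, rules)
        assert out.counts.to_numpy().sum() <= table.counts.to_numpy().sum()
        shared = [o for o in out.otu_ids]
        assert (out.counts[shared] <= table.counts[shared]).all().all()


class TestSelectDominant:
    def test_underfull_returns_all_nonzero(self):
        s = pd.Series({"a": 3, "b": 0, "c": 1, "d": 2})
        assert set(tn.select_dominant_otus(s, k=10)) == {"a", "c", "d"}

    def test_top_k_of_descending_counts(self):
        s = pd.Series({f"otu{i:02d}": 12 - i for i in range(12)})
        got = tn.select_dominant_otus(s, k=10)
        assert got == [f"otu{i:02d}" for i in range(10)]

    def test_tie_at_cut_broken_by_ascending_id(self):
        s = pd.Series({"B": 5, "C": 5, "A": 5})
        assert tn.select_dominant_otus(s, k=2) == ["A", "B"]

    def test_empty_input_gives_empty_list(self):
        assert tn.select_dominant_otus(pd.Series(dtype=int), k=10) == []


class TestStandardize:
    def test_single_otu_gives_proportion_one(self):
        s = pd.Series({"a": 37}, name="s1")
        p = tn.standardize_reads(s, ["a"])
        assert p.proportions == {"a": 1.0}
        assert p.n_prey_reads == 37

    def test_direct_normalization(self):
        s = pd.Series({"a": 30, "b": 10, "c": 60}, name="s1")
        p = tn.standardize_reads(s, ["a", "b", "c"])
        assert p.proportions == pytest.approx({"a": 0.3, "b": 0.1, "c": 0.6})

    def test_all_zero_gives_flagged_empty_profile(self):
        s = pd.Series({"a": 0, "b": 0}, name="s1")
        p = tn.standardize_reads(s, [])
        assert p.is_empty and p.n_prey_reads == 0 and p.proportions == {}


class TestAggregate:
    @staticmethod
    def _taxonomy():
        return tn.Taxonomy(
            [
                tn.TaxonomyAssignment("c1", (), "Calanoida"),
                tn.TaxonomyAssignment("c2", (), "Calanoida"),
                tn.TaxonomyAssignment("h1", (), "Hydrozoa"),
            ]
        )

    def test_within_category_additivity(self):
        p = tn.PreyProfile("s", {"c1": 0.2, "c2": 0.3, "h1": 0.5}, 100)
        agg = tn.aggregate_by_category(p, self._taxonomy())
        assert agg.proportions == pytest.approx({"Calanoida": 0.5, "Hydrozoa": 0.5})

    def test_one_otu_per_category_is_identity(self):
        p = tn.PreyProfile("s", {"c1": 0.4, "h1": 0.6}, 10)
        agg = tn.aggregate_by_category(p, self._taxonomy())
        assert agg.proportions == pytest.approx({"Calanoida": 0.4, "Hydrozoa": 0.6})

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=3))
    def test_total_is_conserved(self, weights):
        total = sum(weights)
        otus = ["c1", "c2", "h1"][: len(weights)]
        p = tn.PreyProfile("s", {o: w / total for o, w in zip(otus, weights)}, 50)
        agg = tn.aggregate_by_category(p, self._taxonomy())
        assert sum(agg.proportions.values()) == pytest.approx(1.0, abs=1e-12)


class TestSummarize:
    def test_single_sample_group(self):
        p = tn.PreyProfile("s1", {"Calanoida": 0.7, "Hydrozoa": 0.3}, 100)
        (s,) = tn.summarize_group([p], {"s1": "G"})
        assert s.mean_proportions == pytest.approx(p.proportions)
        assert s.appearance_frequency == {"Calanoida": 1.0, "Hydrozoa": 1.0}
        assert s.n_replicates == 1

    def test_appearance_frequency_counts_presence(self):
        profiles = [
            tn.PreyProfile(f"s{i}", {"Calanoida": 1.0}, 10) for i in range(5)
        ] + [
            tn.PreyProfile(f"s{i}", {"Calanoida": 0.5, "Hydrozoa": 0.5}, 10)
            for i in range(5, 8)
        ]
        (s,) = tn.summarize_group(profiles, {p.sample_id: "G" for p in profiles})
        assert s.appearance_frequency["Hydrozoa"] == pytest.approx(3 / 8)
        assert s.appearance_frequency["Calanoida"] == 1.0

    def test_mean_is_midpoint_for_two_samples(self):
        profiles = [
            tn.PreyProfile("a", {"Calanoida": 0.4, "Hydrozoa": 0.6}, 10),
            tn.PreyProfile("b", {"Calanoida": 0.6, "Hydrozoa": 0.4}, 10),
        ]
        (s,) = tn.summarize_group(profiles, {"a": "G", "b": "G"})
        assert s.mean_proportions["Calanoida"] == pytest.approx(0.5)
        assert sum(s.mean_proportions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_empty_group_is_flagged(self):
        profiles = [tn.PreyProfile("a", {}, 0)]
        (s,) = tn.summarize_group(profiles, {"a": "G"})
        assert s.flagged_empty and s.mean_proportions == {}

    def test_empty_profiles_excluded_from_means(self):
        profiles = [
            tn.PreyProfile("a", {"Calanoida": 1.0}, 10),
            tn.PreyProfile("b", {}, 0),
        ]
        (s,) = tn.summarize_group(profiles, {"a": "G", "b": "G"})
        assert s.n_replicates == 2 and s.n_nonempty == 1
        assert s.mean_proportions["Calanoida"] == 1.0


def test_appearance_frequency_invariant_to_depth_rescaling(rules_fixture):
    """Multiplying a sample's reads by a constant changes no frequency."""
    rules, table, taxonomy, metadata = rules_fixture
    grouping = tn.grouping_by_metadata(metadata)
    p1, _ = tn.compute_profiles(table, taxonomy, metadata, rules)
    scaled = tn.OtuCountTable(table.counts * 10)
    p2, _ = tn.compute_profiles(scaled, taxonomy, metadata, rules)
    s1 = tn.summarize_group(p1, grouping)
    s2 = tn.summarize_group(p2, grouping)
    for a, b in zip(s1, s2):
        assert a.appearance_frequency == pytest.approx(b.appearance_frequency)


def test_group_means_recover_planted_diets_at_scale():
    """Without bias/host/contaminants, group mean standardized proportions
    match the planted per-sample diets' group mean (50 x 1e5 reads)."""
    spec = tn.DietSpec(
        predator_group="Calanidae",
        mean_diet={"Calanoida": 0.5, "Dinoflagellates": 0.3, "Chlorophyta": 0.2},
    )
    cfg = tn.SimulationConfig(
        diet_specs=[spec], n_individuals_per_group=50,
        reads_per_individual=100_000, host_read_fraction=0.0,
        contaminant_fractions={}, seed=21,
    )
    table, taxonomy, metadata, truth = tn.simulate_dataset(cfg)
    profiles, _ = tn.compute_profiles(
        table, taxonomy, metadata, tn.default_rules(), k_dominant=10
    )
    (summary,) = tn.summarize_group(
        profiles, tn.grouping_by_metadata(metadata)
    )
    planted = pd.DataFrame(truth.diets).T.mean()
    for cat, target in planted.items():
        assert abs(summary.mean_proportions.get(cat, 0.0) - target) < 0.02
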