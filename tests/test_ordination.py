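"""Square-root transform, Bray-Curtis similarity, UPGMA threshold cuts,
and nonmetric MDS with Kruskal stress-1."""

import numpy as np
import pandas as pd
import pytest

import trophonet as tn
from trophonet.ordination import _classical_start


def _sim(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"i{k}" for k in range(values.shape[0])]
    return tn.SimilarityMatrix(item_ids=list(ids), values=values)


def brute_force_bray_curtis(x):
    """Independent loop implementation of percent Bray-Curtis similarity."""
    n = x.shape[0]
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(abs(x[i, k] - x[j, k]) for k in range(x.shape[1]))
            den = sum(x[i, k] + x[j, k] for k in range(x.shape[1]))
            s[i, j] = 100.0 * (1.0 - num / den) if den > 0 else 0.0
    np.fill_diagonal(s, 100.0)
    return s


class TestTransform:
    def test_sqrt_values(self):
        p = tn.PreyProfile("s", {"a": 0.04, "b": 0.96}, 100)
        out = tn.transform_profiles([p], transform="sqrt")
        assert out.loc["s", "a"] == pytest.approx(0.2)
        assert out.loc["s", "b"] == pytest.approx(np.sqrt(0.96))

    def test_zero_vector_maps_to_zero(self):
        m = pd.DataFrame([[0.0, 0.0]], index=["s"], columns=["a", "b"])
        assert (tn.transform_profiles(m).to_numpy() == 0).all()

    def test_sqrt_preserves_rank_order(self):
        m = pd.DataFrame([[0.1, 0.5, 0.4]], index=["s"], columns=list("abc"))
        out = tn.transform_profiles(m)
        assert list(np.argsort(out.to_numpy()[0])) == list(
            np.argsort(m.to_numpy()[0])
        )

    def test_negative_input_rejected(self):
        m = pd.DataFrame([[-0.1, 1.1]], index=["s"], columns=["a", "b"])
        with pytest.raises(tn.ValidationError):
            tn.transform_profiles(m)


class TestBrayCurtis:
    def test_identical_rows_are_100(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert tn.bray_curtis_similarity(m).values[0, 1] == pytest.approx(100.0)

    def test_disjoint_supports_are_0(self):
        m = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert tn.bray_curtis_similarity(m).values[0, 1] == pytest.approx(0.0)

    def test_hand_computed_pair(self):
        m = pd.DataFrame([[1, 3], [3, 1]], index=["a", "b"])
        assert tn.bray_curtis_similarity(m).values[0, 1] == pytest.approx(50.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.uniform(0, 5, size=(rng.integers(2, 8), rng.integers(1, 6)))
            got = tn.bray_curtis_similarity(pd.DataFrame(x)).values
            assert np.max(np.abs(got - brute_force_bray_curtis(x))) < 1e-12

    def test_all_zero_pair_flagged_as_zero(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 1]], index=["a", "b", "c"])
        sim = tn.bray_curtis_similarity(m)
        assert sim.values[0, 1] == 0.0
        assert ("a", "b") in sim.zero_pairs

    def test_negative_entry_rejected(self):
        m = pd.DataFrame([[1, -1], [0, 1]])
        with pytest.raises(tn.ValidationError):
            tn.bray_curtis_similarity(m)


class TestUpgmaClusters:
    def test_identical_items_merge(self):
        sim = _sim([[100, 100], [100, 100]])
        assert tn.average_linkage_clusters(sim, 40).n_clusters == 1

    def test_hand_worked_single_merge(self):
        sim = _sim([[100, 80, 10], [80, 100, 10], [10, 10, 100]], ids=list("abc"))
        got = tn.average_linkage_clusters(sim, 40)
        assert got.labels["a"] == got.labels["b"] != got.labels["c"]
        assert got.labels["a"] == 1 and got.labels["c"] == 2

    def test_threshold_zero_gives_single_cluster(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(6, 4))
        sim = tn.bray_curtis_similarity(pd.DataFrame(x))
        assert tn.average_linkage_clusters(sim, 0).n_clusters == 1

    def test_cluster_count_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        sim = tn.bray_curtis_similarity(pd.DataFrame(rng.uniform(0, 1, (10, 5))))
        counts = [
            tn.average_linkage_clusters(sim, t).n_clusters
            for t in (0, 20, 40, 60, 80, 100)
        ]
        assert counts == sorted(counts)

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(tn.ValidationError):
            tn.average_linkage_clusters(_sim([[100, 50], [50, 100]]), 120)


class TestStress1:
    def test_monotone_configuration_has_zero_stress(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        # dissimilarities already in the same rank order as distances
        sim = _sim([[100, 90, 70], [90, 100, 80], [70, 80, 100]])
        assert tn.stress1(coords, sim) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(5, 2))
        sim = tn.bray_curtis_similarity(pd.DataFrame(rng.uniform(0, 1, (5, 3))))
        s1 = tn.stress1(coords, sim)
        s2 = tn.stress1(coords * 7.3, sim)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_four_point_pava_hand_oracle(self):
        """One rank violation pools four distances; stress-1 equals the
        hand-run PAVA arithmetic."""
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 0.0]])
        # pair order (12) < (14) < (13) < (24) < (23) < (34)
        d = np.array(
            [
                [0, 10, 30, 20],
                [10, 0, 50, 40],
                [30, 50, 0, 60],
                [20, 40, 60, 0],
            ],
            dtype=float,
        )
        sim = _sim(100.0 - d, ids=list("pqrs"))
        # distances in dissimilarity order: 1, 3, 2, 2, sqrt(5), sqrt(13)
        m = (3 + 2 + 2 + np.sqrt(5)) / 4  # PAVA pools the violating block
        num = (3 - m) ** 2 + 2 * (2 - m) ** 2 + (np.sqrt(5) - m) ** 2
        expected = np.sqrt(num / 36.0)  # sum of squared distances = 36
        assert tn.stress1(coords, sim) == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(tn.ValidationError):
            tn.stress1(np.zeros((3, 2)), _sim([[100, 50], [50, 100]]))


class TestNmds:
    def test_three_items_embed_perfectly(self):
        sim = _sim([[100, 70, 20], [70, 100, 50], [20, 50, 100]])
        res = tn.nmds(sim, k=2, n_restarts=5, seed=0)
        assert res.stress < 1e-4

    def test_unit_square_recovered(self):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.sqrt(((corners[:, None] - corners[None]) ** 2).sum(-1)) * 30
        res = tn.nmds(_sim(100 - d), k=2, n_restarts=10, seed=0)
        assert res.stress < 1e-3

    def test_stress_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        sim = tn.bray_curtis_similarity(pd.DataFrame(rng.uniform(0, 1, (8, 4))))
        res = tn.nmds(sim, k=2, n_restarts=5, seed=1)
        trace = res.stress_trace
        assert all(a >= b - 1e-15 for a, b in zip(trace, trace[1:]))

    def test_reported_stress_beats_classical_start(self):
        rng = np.random.default_rng(4)
        sim = tn.bray_curtis_similarity(pd.DataFrame(rng.uniform(0, 1, (7, 3))))
        res = tn.nmds(sim, k=2, n_restarts=5, seed=2)
        start = _classical_start(sim.dissimilarity(), 2)
        assert res.stress <= tn.stress1(start, sim) + 1e-12

    def test_coordinates_are_centered(self):
        rng = np.random.default_rng(5)
        sim = tn.bray_curtis_similarity(pd.DataFrame(rng.uniform(0, 1, (6, 4))))
        res = tn.nmds(sim, k=2, n_restarts=3, seed=0)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_too_few_items_rejected(self):
        with pytest.raises(tn.ValidationError):
            tn.nmds(_sim([[100, 50], [50, 100]]), k=2)


def six_item_nonmetric_fixture():
    """A 6-item dissimilarity that is not Euclidean-embeddable (random
    symmetric values with no metric structure)."""
    rng = np.random.default_rng(123)
    d = rng.uniform(10, 90, size=(6, 6))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return _sim(100 - d)


def test_nmds_matches_reference_optimizer_on_hard_fixture():
    """Best stress within 0.01 of sklearn's nonmetric MDS run with 50
    restarts, both scored with the same stress-1 evaluator."""
    from sklearn.manifold import MDS

    sim = six_item_nonmetric_fixture()
    ref = MDS(
        n_components=2, metric=False, n_init=50, max_iter=500,
        dissimilarity="precomputed", random_state=0, normalized_stress=True,
    )
    coords = ref.fit_transform(sim.dissimilarity())
    ref_stress = tn.stress1(coords, sim)
    res = tn.nmds(sim, k=2, n_restarts=20, seed=0)
    assert res.stress <= ref_stress + 0.01
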