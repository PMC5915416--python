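"""Bimodality screening, Ward clustering, elbow, silhouette, Fisher exact."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from astrolayer.cluster import (
    fisher_exact_rxc,
    layer_cluster_stats,
    mmi,
    mmi_table,
    select_features,
    silhouette,
    thorndike_optimal_k,
    ward_cluster,
    within_cluster_distance,
    zscore_normalize,
)
from astrolayer.synth import bimodal_cluster_spec, blob_cluster_spec, simulate_feature_table


class TestZscore:
    def test_closed_form_column(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = zscore_normalize(t)
        assert np.allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_post_hoc_moments(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(5, 3, size=(50, 4)), columns=list("abcd"))
        z = zscore_normalize(t)
        assert np.abs(z.mean(axis=0)).max() < 1e-12
        assert np.allclose(z.std(axis=0, ddof=1), 1.0)

    def test_constant_column_dropped(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]})
        assert list(zscore_normalize(t).columns) == ["a"]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize(pd.DataFrame({"a": [1.0]}))


class TestMMI:
    """Population limits: normal 1/3, uniform 5/9, balanced two-point 1."""

    @pytest.mark.parametrize(
        "sampler,expected",
        [
            (lambda rng, n: rng.normal(size=n), 1.0 / 3.0),
            (lambda rng, n: rng.uniform(size=n), 5.0 / 9.0),
            (lambda rng, n: np.tile([0.0, 1.0], n // 2), 1.0),
        ],
        ids=["normal", "uniform", "two-point"],
    )
    def test_population_limits(self, sampler, expected):
        rng = np.random.default_rng(12345)
        values = sampler(rng, 10_000)
        assert mmi(values).mmi == pytest.approx(expected, abs=0.03)

    @given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0), neg=st.booleans())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b, neg):
        rng = np.random.default_rng(99)
        x = rng.normal(size=500) + rng.exponential(size=500)
        scale = -a if neg else a
        assert mmi(scale * x + b).mmi == pytest.approx(mmi(x).mmi, abs=1e-10)

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            mmi([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            mmi([5.0] * 100)

    def test_finite_sample_correction_term(self):
        # at n=4 the correction 3(n-1)^2/((n-2)(n-3)) = 13.5 dominates
        r = mmi([0.0, 1.0, 2.0, 10.0])
        corr = 3 * 9 / (2 * 1)
        assert r.mmi == pytest.approx((r.m3**2 + 1) / (r.m4 + corr))


class TestSelectFeatures:
    def test_planted_bimodal_features_recovered(self):
        spec = bimodal_cluster_spec(5)
        hits = 0
        for seed in range(20):
            table, _ = simulate_feature_table(spec, 116, seed=seed)
            if tuple(select_features(table, 0.55)) == spec.informative:
                hits += 1
        assert hits >= 19

    def test_threshold_zero_selects_everything_finite(self):
        table, _ = simulate_feature_table(bimodal_cluster_spec(3), 60, seed=1)
        sel = select_features(table, threshold=0.0)
        assert len(sel) == table.shape[1]

    def test_empty_selection_warns(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(116, 6)), columns=list("abcdef"))
        with pytest.warns(UserWarning, match="no feature exceeds"):
            sel = select_features(table, threshold=0.99)
        assert sel == []

    def test_mmi_table_reports_moments(self):
        table, _ = simulate_feature_table(bimodal_cluster_spec(2), 80, seed=0)
        mt = mmi_table(table)
        assert set(mt.columns) == {"m3", "m4", "n", "mmi"}
        assert (mt["n"] == 80).all()


class TestWard:
    def test_blobs_recovered_with_high_ari(self):
        from sklearn.metrics import adjusted_rand_score

        spec = blob_cluster_spec(3, separation=10.0)
        table, truth = simulate_feature_table(spec, 90, seed=4)
        res = ward_cluster(table[list(spec.informative)], range(1, 7))
        assert adjusted_rand_score(truth["cluster"], res.labels[3]) >= 0.99

    def test_k_equals_n_gives_zero_within_distance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        res = ward_cluster(X, k_range=[1, 12])
        assert res.within_distance[12] == pytest.approx(0.0)

    def test_merge_heights_nondecreasing_and_curve_monotone(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        res = ward_cluster(X, range(1, 10))
        assert (np.diff(res.linkage[:, 2]) >= -1e-9).all()
        wss = [res.within_distance[k] for k in sorted(res.within_distance)]
        assert (np.diff(wss) <= 1e-9).all()

    def test_bad_k_range_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.zeros((5, 2)), k_range=[0, 3])
        with pytest.raises(ValueError):
            ward_cluster(np.zeros((5, 2)), k_range=[6])

    def test_duplicated_dataset_preserves_merge_structure(self):
        # duplicating every point keeps the same cluster structure
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2)) * 0.1 + np.repeat([[0, 0], [10, 10]], 5, axis=0)
        X2 = np.vstack([X, X])
        res = ward_cluster(X2, k_range=[2])
        lab = res.labels[2]
        assert (lab[:10] == lab[10:]).all()


class TestThorndike:
    def test_planted_k_found(self):
        spec = blob_cluster_spec(4, separation=10.0)
        table, _ = simulate_feature_table(spec, 116, seed=11)
        res = ward_cluster(table[list(spec.informative)], range(1, 9))
        k, curve = thorndike_optimal_k(res)
        assert k == 4
        assert len(curve) == 8

    def test_linear_curve_has_no_elbow(self):
        from astrolayer.cluster import ClusteringResult

        res = ClusteringResult(
            linkage=np.empty((0, 4)),
            k_range=tuple(range(1, 8)),
            labels={},
            within_distance={k: 100.0 - 10.0 * k for k in range(1, 8)},
        )
        k, curve = thorndike_optimal_k(res)
        assert k is None

    def test_within_cluster_distance_definition(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        labels = np.array([1, 1, 2, 2])
        # each cluster: two points 2 apart -> 2 * (1^2 + 1^2) = 2 per cluster
        assert within_cluster_distance(X, labels) == pytest.approx(4.0)


class TestSilhouette:
    def test_two_tight_clusters_score_one(self):
        X = np.repeat([[0.0, 0.0], [1.0, 0.0]], 5, axis=0)
        labels = np.repeat([1, 2], 5)
        s, mean = silhouette(X, labels)
        assert np.allclose(s, 1.0)

    def test_identical_points_tie_convention_zero(self):
        X = np.zeros((8, 2))
        s, mean = silhouette(X, np.repeat([1, 2], 4))
        assert np.allclose(s, 0.0)

    def test_random_labels_on_one_blob_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        s, mean = silhouette(X, rng.integers(1, 4, size=200))
        assert abs(mean) < 0.1

    def test_values_always_within_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X = rng.normal(size=(30, 2)) * rng.uniform(0.1, 5)
            labels = rng.integers(1, 4, size=30)
            if len(np.unique(labels)) < 2:
                continue
            s, _ = silhouette(X, labels)
            assert (s >= -1.0).all() and (s <= 1.0).all()

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 4))
        labels = rng.integers(0, 3, size=50)
        s, _ = silhouette(X, labels)
        ref = silhouette_samples(X, labels)
        assert np.allclose(s, ref, atol=1e-8)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((5, 2)), np.ones(5))


class TestFisherExact:
    def test_diagonal_2x2_full_enumeration(self):
        p, method = fisher_exact_rxc([[10, 0], [0, 10]])
        assert method == "enumeration"
        assert p == pytest.approx(2.0 / 184_756, rel=1e-9)

    def test_matches_scipy_on_random_2x2(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            T = rng.integers(0, 12, size=(2, 2))
            if (T.sum(0) == 0).any() or (T.sum(1) == 0).any():
                continue
            p_ours, _ = fisher_exact_rxc(T)
            p_scipy = stats.fisher_exact(T)[1]
            assert p_ours == pytest.approx(p_scipy, rel=1e-6)

    def test_monte_carlo_close_to_enumeration(self):
        T = [[8, 2, 1], [2, 7, 3], [1, 2, 9]]
        p_enum, m1 = fisher_exact_rxc(T)
        p_mc, m2 = fisher_exact_rxc(T, max_tables=10, n_mc=100_000, seed=0)
        assert m1 == "enumeration" and m2 == "monte-carlo"
        assert p_mc == pytest.approx(p_enum, rel=0.1)

    def test_null_pvalues_roughly_uniform(self):
        # under independence the exact p is stochastically >= uniform
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(300):
            labels = rng.integers(0, 2, size=30)
            groups = rng.integers(0, 2, size=30)
            T = pd.crosstab(labels, groups).to_numpy()
            if T.shape != (2, 2):
                continue
            ps.append(fisher_exact_rxc(T)[0])
        ps = np.asarray(ps)
        # discrete conservatism: P(p <= a) <= a for all a
        for a in (0.05, 0.1, 0.25, 0.5):
            assert (ps <= a).mean() <= a + 0.05

    def test_layer_cluster_compositions_sum_to_100(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(1, 5, size=116)
        layers = rng.choice(["I", "II/III", "IV", "V", "VI"], size=116)
        res = layer_cluster_stats(labels, layers, max_tables=2000, n_mc=20_000, seed=0)
        assert np.allclose(res.layer_composition.sum(axis=1), 100.0)
        assert np.allclose(res.cluster_composition.sum(axis=0), 100.0)
        assert 0.0 < res.p_value <= 1.0
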