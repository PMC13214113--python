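"""Trial screening, adjacency, cluster-based and sign-proportion
permutation tests.

mne.stats.permutation_cluster_1samp_test serves as the independent oracle
for the cluster test (same paired sign-flip scheme on the differences).
"""

import numpy as np
import pytest

from vigorcoh.bands import BAND_PRESETS
from vigorcoh.containers import FeatureTensor
from vigorcoh.group_stats import (
    build_adjacency,
    paired_cluster_permutation,
    rank_parcels_by_t,
    screen_trials,
    sign_proportion_permutation,
)
from vigorcoh.synth import sensor_positions

PATCH = [0, 1, 2, 8, 9]    # connected on the 32-channel grid montage


def _tensor(values):
    n_tr, n_u, _ = values.shape
    labels = np.array(["Fast", "Slow"] * (n_tr // 2), dtype=object)
    return FeatureTensor(values, [f"u{i}" for i in range(n_u)], "power",
                         BAND_PRESETS["standard"], labels, "sensor")


class TestScreenTrials:
    def test_single_extreme_cell_masked_only_there(self, rng):
        # two-level background (+-0.01): every deviation equals the MAD
        # exactly, so only the planted extreme can be flagged
        pattern = 0.01 * np.where(np.arange(20) % 2 == 0, 1.0, -1.0)
        values = 1.0 + np.tile(pattern[:, None, None], (1, 3, 7))
        values[4, 1, 2] = 100.0                 # trial 4 is Fast
        clean, frac = screen_trials(_tensor(values))
        assert np.isnan(clean.values[4, 1, 2])
        assert np.isfinite(np.delete(clean.values.ravel(),
                                     np.ravel_multi_index((4, 1, 2),
                                                          values.shape))).all()
        assert frac == pytest.approx(1 / values.size)

    def test_homogeneous_tensor_removes_nothing(self):
        clean, frac = screen_trials(_tensor(np.ones((12, 2, 7))))
        assert frac == 0.0
        assert np.isfinite(clean.values).all()

    def test_identical_pattern_gives_identical_cell_masks(self, rng):
        col = np.r_[np.full(9, 1.0), 50.0]      # same pattern in every cell
        values = np.tile(col[:, None, None], (1, 3, 7))
        # make both conditions see the same pattern
        values = np.concatenate([values, values], axis=0)
        clean, _ = screen_trials(_tensor(values))
        masks = np.isnan(clean.values)
        assert (masks == masks[:, :1, :1]).all()

    def test_retained_values_unchanged(self, rng):
        values = rng.normal(size=(16, 2, 7))
        clean, _ = screen_trials(_tensor(values))
        keep = ~np.isnan(clean.values)
        np.testing.assert_array_equal(clean.values[keep], values[keep])

    def test_whole_trial_mode_drops_trial_everywhere(self, rng):
        values = rng.normal(1.0, 0.05, size=(20, 3, 7))
        values[4, 1, 2] = 100.0
        clean, _ = screen_trials(_tensor(values), mode="trial")
        assert np.isnan(clean.values[4]).all()


class TestAdjacency:
    def test_collinear_chain(self):
        pos = np.array([[0.0, 0.0], [0.015, 0.0], [0.030, 0.0]])
        g = build_adjacency(pos, radius=0.02)
        assert sorted(g.edges) == [(0, 1), (1, 2)]

    def test_sparse_and_zero_radius_empty(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert build_adjacency(pos, radius=0.02).edges == []
        assert build_adjacency(pos, radius=0.0).edges == []

    def test_duplicate_positions_warn(self):
        pos = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.warns(RuntimeWarning):
            g = build_adjacency(pos)
        assert (0, 1) in g.edges


class TestPairedClusterPermutation:
    @pytest.fixture(scope="class")
    def graph(self):
        return build_adjacency(sensor_positions(32))

    def test_planted_patch_recovered(self, graph, rng):
        a = rng.standard_normal((20, 32))
        b = rng.standard_normal((20, 32))
        a[:, PATCH] += 2.0
        res = paired_cluster_permutation(a, b, graph, n_perm=500, rng=rng)
        sig = [set(c) for c, p in zip(res.clusters, res.p_values)
               if p < 0.05]
        assert any(len(c & set(PATCH)) >= 4 for c in sig)

    def test_sign_flip_antisymmetry(self, graph, rng):
        a = rng.standard_normal((12, 32))
        b = rng.standard_normal((12, 32))
        a[:, PATCH] += 1.5
        r1 = paired_cluster_permutation(a, b, graph, n_perm=100,
                                        rng=np.random.default_rng(0))
        r2 = paired_cluster_permutation(b, a, graph, n_perm=100,
                                        rng=np.random.default_rng(0))
        np.testing.assert_allclose(r1.t_map, -r2.t_map)
        assert sorted(map(tuple, r1.clusters)) == \
            sorted(map(tuple, r2.clusters))

    def test_no_suprathreshold_units_is_valid_empty(self, graph, rng):
        a = rng.standard_normal((12, 32))
        res = paired_cluster_permutation(a, a.copy(), graph, n_perm=100,
                                         rng=np.random.default_rng(0))
        assert res.clusters == []
        assert res.p_values.size == 0
        np.testing.assert_array_equal(res.t_map, 0.0)

    def test_agreement_with_mne_oracle(self, graph, rng):
        from scipy import stats
        from scipy.sparse import coo_matrix
        from mne.stats import permutation_cluster_1samp_test

        a = rng.standard_normal((20, 32))
        b = rng.standard_normal((20, 32))
        a[:, PATCH] += 1.2
        res = paired_cluster_permutation(a, b, graph, n_perm=2000,
                                         rng=np.random.default_rng(5))
        ij = np.array(graph.edges)
        adj = coo_matrix(
            (np.ones(2 * len(ij)),
             (np.r_[ij[:, 0], ij[:, 1]], np.r_[ij[:, 1], ij[:, 0]])),
            shape=(32, 32))
        thr = stats.t.ppf(0.975, 19)
        t_map, clusters, pvals, _ = permutation_cluster_1samp_test(
            a - b, threshold=thr, n_permutations=2000, adjacency=adj,
            tail=0, out_type="indices", verbose="error", seed=7)
        np.testing.assert_allclose(res.t_map, t_map, atol=1e-10)
        mine = sorted(tuple(sorted(c)) for c in res.clusters)
        theirs = sorted(tuple(sorted(c[0].tolist())) for c in clusters)
        assert mine == theirs
        mp = {tuple(sorted(c)): p
              for c, p in zip(res.clusters, res.p_values)}
        tp = {tuple(sorted(c[0].tolist())): p
              for c, p in zip(clusters, pvals)}
        for k in mp:
            assert mp[k] == pytest.approx(tp[k], abs=0.03)

    def test_too_few_subjects_rejected(self, graph, rng):
        with pytest.raises(ValueError, match="5"):
            paired_cluster_permutation(rng.standard_normal((3, 32)),
                                       rng.standard_normal((3, 32)), graph)


class TestRankParcels:
    def test_known_ordering(self):
        t = np.array([[1.0] * 3, [-5.0] * 3, [3.0] * 3, [0.5] * 3])
        out = rank_parcels_by_t(t, ["a", "b", "c", "d"], k=3)
        assert [name for name, _ in out] == ["b", "c", "a"]
        assert out[0][1] == pytest.approx(-5.0)

    def test_tie_breaks_lexicographic(self):
        t = np.array([[2.0] * 2, [-2.0] * 2, [2.0] * 2])
        out = rank_parcels_by_t(t, ["zeta", "alpha", "beta"], k=3)
        assert [name for name, _ in out] == ["alpha", "beta", "zeta"]

    def test_k_larger_than_count_returns_all(self):
        out = rank_parcels_by_t(np.ones((2, 3)), ["a", "b"], k=10)
        assert len(out) == 2


class TestSignProportion:
    def test_all_negative_is_significant(self, rng):
        # shared negative shift with parcel-level noise: under the
        # subject-flip null a purely parcel-common effect would make the
        # null proportion bimodal, so heterogeneity across parcels is part
        # of the construction
        d = -1.5 + rng.normal(0.0, 2.0, size=(30, 21))
        res = sign_proportion_permutation(d, n_perm=500, rng=rng)
        assert res.proportion_negative == 1.0
        assert res.p < 0.05
        assert res.z > 0

    def test_null_calibration(self):
        rejections = 0
        for i in range(60):
            rng = np.random.default_rng(1000 + i)
            d = rng.normal(0.0, 1.0, size=(12, 21))
            res = sign_proportion_permutation(d, n_perm=300, rng=rng)
            rejections += res.p < 0.05
        assert rejections <= 9      # ~5% of 60 plus binomial slack

    def test_single_subject_warns(self, rng):
        with pytest.warns(RuntimeWarning, match="degenerate|single"):
            sign_proportion_permutation(rng.normal(size=(1, 21)),
                                        n_perm=300, rng=rng)

    def test_low_n_perm_warns(self, rng):
        with pytest.warns(RuntimeWarning, match="n_perm"):
            sign_proportion_permutation(rng.normal(size=(6, 21)),
                                        n_perm=50, rng=rng)
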