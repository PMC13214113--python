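"""Grouped SFS + L1 logistic decoding: calibration, recovery, leakage
safety, bootstrap behavior."""

import numpy as np
import pytest

from vigorcoh.bands import BAND_PRESETS
from vigorcoh.containers import FeatureTensor
from vigorcoh.decoding import (
    CandidateGroups,
    _fit_fold,
    _mad_clean_mask,
    bootstrap_auc,
    cv_auc,
    decode_subject,
    rank_auc,
    selection_frequencies,
    sfs_grouped,
)


def _labels(n_per_class):
    y = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    return y


def _noise_groups(rng, n_groups, n_trials, informative=None, effect=1.5):
    """Candidate groups of pure noise, optionally one with a planted
    class shift on all 7 windows."""
    y = _labels(n_trials // 2)
    feats = {}
    for g in range(n_groups):
        x = rng.standard_normal((n_trials, 7))
        if informative is not None and g == informative:
            x[y == 1] += effect
        feats[f"g{g:02d}"] = x
    return CandidateGroups(sorted(feats), feats), y


class TestRankAuc:
    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(10):
            y = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            s = rng.normal(size=40)
            assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_ties_average(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.0, 1.0, 1.0, 2.0])
        assert rank_auc(y, s) == pytest.approx(0.875)


class TestCvAuc:
    def test_separable_feature_reaches_auc_one(self, rng):
        y = _labels(60)
        x = np.where(y == 1, 5.0, -5.0)[:, None] + rng.normal(0, 0.1,
                                                              (120, 1))
        res = cv_auc(x, y, rng=rng)
        assert res.mean_auc == 1.0

    def test_permuted_labels_are_chance(self, rng):
        y = _labels(60)
        x = np.where(y == 1, 1.0, -1.0)[:, None] + rng.normal(0, 1,
                                                              (120, 1))
        means = []
        for i in range(50):
            yp = rng.permutation(y)
            means.append(cv_auc(x, yp, rng=rng).mean_auc)
        assert np.mean(means) == pytest.approx(0.5, abs=0.03)

    def test_constant_features_give_chance_and_zero_coefficients(self, rng):
        y = _labels(30)
        res = cv_auc(np.ones((60, 3)), y, rng=rng)
        assert res.mean_auc == pytest.approx(0.5, abs=0.15)
        np.testing.assert_allclose(res.fold_coefficients, 0.0)

    def test_nonfinite_features_rejected(self, rng):
        x = np.ones((20, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            cv_auc(x, _labels(10), rng=rng)


class TestLeakageGuard:
    def test_training_statistics_ignore_test_fold(self, rng):
        """Corrupting test-fold values after fitting leaves the training
        z-score parameters and coefficients bit-identical."""
        from sklearn.model_selection import StratifiedKFold
        y = _labels(40)
        x = rng.standard_normal((80, 7))
        skf = StratifiedKFold(5, shuffle=True, random_state=3)
        for tr, te in skf.split(x, y):
            model, mu, sd = _fit_fold(x[tr], y[tr], 1.0)
            x_corrupt = x.copy()
            x_corrupt[te] = 1e6
            model2, mu2, sd2 = _fit_fold(x_corrupt[tr], y[tr], 1.0)
            np.testing.assert_array_equal(mu, mu2)
            np.testing.assert_array_equal(sd, sd2)
            np.testing.assert_array_equal(model.coef_, model2.coef_)

    def test_artifact_trial_removed_from_training(self, rng):
        y = _labels(30)
        x = rng.standard_normal((60, 7))
        x[5] *= 50.0                            # globally extreme trial
        keep = _mad_clean_mask(x, y)
        assert not keep[5]
        assert keep.sum() >= 55                 # healthy trials survive


class TestSfsGrouped:
    def test_single_informative_group_selected_first(self, rng):
        hits = 0
        for rep in range(20):
            groups, y = _noise_groups(rng, 21, 120, informative=7)
            res = sfs_grouped(groups, y, rng=rng)
            hits += bool(res.selected_groups
                         and res.selected_groups[0] == "g07")
        assert hits >= 18

    def test_duplicated_informative_group_not_selected_twice(self, rng):
        groups, y = _noise_groups(rng, 5, 120, informative=2, effect=2.0)
        feats = dict(groups.features)
        feats["g99"] = feats["g02"].copy()      # exact duplicate
        dup = CandidateGroups(sorted(feats), feats)
        res = sfs_grouped(dup, y, rng=rng)
        assert ("g02" in res.selected_groups) ^ ("g99" in res.selected_groups)

    def test_max_three_groups(self, rng):
        groups, y = _noise_groups(rng, 8, 120)
        for g in ["g00", "g01", "g02", "g03"]:
            groups.features[g][y == 1] += 0.8   # several informative
        res = sfs_grouped(groups, y, rng=rng)
        assert len(res.selected_groups) <= 3

    def test_uninformative_groups_flag_empty_selection(self, rng):
        """Constant features score AUC exactly 0.5, below the first-step
        acceptance bar (0.5 + min_gain): selection comes back empty but
        carries the best rejected model's CV result."""
        y = _labels(20)
        feats = {f"g{i}": np.ones((40, 7)) for i in range(4)}
        groups = CandidateGroups(sorted(feats), feats)
        res = sfs_grouped(groups, y, rng=rng)
        assert res.empty_selection
        assert res.selected_groups == []
        assert res.cv.mean_auc == pytest.approx(0.5)


class TestBootstrapAuc:
    def test_separable_lower_bound_high(self, rng):
        y = _labels(50)
        x = np.where(y == 1, 3.0, -3.0)[:, None] + rng.normal(
            0, 0.3, (100, 1))
        lo, hi, _ = bootstrap_auc(x, y, n_boot=100, rng=rng)
        assert lo > 0.9

    def test_noise_ci_covers_chance(self):
        covered = 0
        for rep in range(20):
            rng = np.random.default_rng(900 + rep)
            y = _labels(30)
            x = rng.standard_normal((60, 7))
            lo, hi, _ = bootstrap_auc(x, y, n_boot=100, rng=rng)
            covered += lo <= 0.5 <= hi
        assert covered >= 18

    def test_single_bootstrap_collapses_to_point(self, rng):
        y = _labels(30)
        x = rng.standard_normal((60, 3))
        lo, hi, draws = bootstrap_auc(x, y, n_boot=1, rng=rng)
        assert lo == hi == pytest.approx(draws[0])


class TestDecodeSubject:
    def _tensor(self, rng, effect_units=("u03",), effect=-1.2, n_trials=120,
                n_units=8):
        """Planted effect NEGATIVE in Fast trials (feature lower in Fast)."""
        labels = np.array(["Fast", "Slow"] * (n_trials // 2), dtype=object)
        values = rng.standard_normal((n_trials, n_units, 7))
        unit_ids = [f"u{i:02d}" for i in range(n_units)]
        fast = np.array([l == "Fast" for l in labels])
        for u in effect_units:
            values[fast, unit_ids.index(u), :] += effect
        return FeatureTensor(values, unit_ids, "power",
                             BAND_PRESETS["standard"], labels, "source",
                             subject_id="sub-01")

    def test_planted_lower_in_fast_gives_negative_coefficient(self, rng):
        tensor = self._tensor(rng)
        res = decode_subject(tensor, n_boot=100, rng=rng)
        assert res.mean_auc > 0.8
        assert "u03" in res.selected_groups
        assert res.mean_coefficient < 0
        assert res.above_chance
        assert res.delta_auc == pytest.approx(res.mean_auc - 0.5)

    def test_inverse_coding_flips_coefficient_sign(self, rng):
        tensor = self._tensor(rng)
        res = decode_subject(tensor, n_boot=0,
                             rng=np.random.default_rng(1),
                             positive_class="Slow")
        assert res.mean_coefficient > 0

    def test_nonfinite_trials_dropped(self, rng):
        tensor = self._tensor(rng)
        tensor.values[3] = np.nan
        res = decode_subject(tensor, n_boot=0, rng=rng)
        assert np.isfinite(res.mean_auc)

    def test_selection_frequencies_respect_exclusion(self):
        class R:
            def __init__(self, sel, above):
                self.selected_groups = sel
                self.above_chance = above
        results = [R(["a"], True), R(["a", "b"], True), R(["b"], False)]
        freq = selection_frequencies(results, ["a", "b"])
        assert freq == {"a": 2, "b": 1}
        freq_all = selection_frequencies(results, ["a", "b"],
                                         above_chance_only=False)
        assert freq_all == {"a": 2, "b": 2}
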