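"""Symmetric orthogonalization and imaginary coherence.

The orthogonalization optimality oracle is a brute-force comparison with
sequential Gram-Schmidt; the iCoh small-sample bias oracle is an
independent Monte-Carlo re-implementation of the estimator inside the
test.
"""

import numpy as np
import pytest
from scipy.signal import hilbert

from vigorcoh.bands import BAND_PRESETS
from vigorcoh.connectivity import (
    RankError,
    closest_orthogonal_matrix,
    compute_icoh,
    gram_schmidt,
    seed_icoh_tensor,
    symmetric_orthogonalize,
)
from vigorcoh.containers import ParcelTimeCourses
from vigorcoh.synth import band_limited_noise, quadrature_shift

BAND = BAND_PRESETS["standard"]


def _ptc(data, names=None, seed="p0"):
    n_p = data.shape[1]
    names = names or [f"p{i}" for i in range(n_p)]
    labels = np.array(["Fast", "Slow"] * (data.shape[0] // 2)
                      + ["Fast"] * (data.shape[0] % 2), dtype=object)
    return ParcelTimeCourses(data, 128.0, -1.5, names, seed, BAND, labels)


class TestSymmetricOrthogonalize:
    def test_orthogonal_input_is_a_fixed_point(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((256, 4)))
        x = q * np.array([3.0, 1.5, 2.0, 0.7])    # orthogonal, scaled
        out, report = symmetric_orthogonalize(_ptc(x.T[None, :, :]))
        assert report.frobenius_change < 1e-10
        np.testing.assert_allclose(out.data[0], x.T, atol=1e-8)

    def test_duplicate_parcels_raise_rank_error(self, rng):
        a = rng.standard_normal(256)
        data = np.stack([a, a, rng.standard_normal(256)])[None, :, :]
        with pytest.raises(RankError, match="parcel"):
            symmetric_orthogonalize(_ptc(data))

    def test_beats_gram_schmidt_on_random_instances(self, rng):
        """Closest-orthogonal solution: residual correlations < 1e-8 and
        total change below sequential Gram-Schmidt in >= 90% of draws."""
        wins = 0
        for _ in range(50):
            x = rng.standard_normal((512, 4))
            o, _, converged = closest_orthogonal_matrix(x)
            c = o.T @ o
            off = c - np.diag(np.diag(c))
            denom = np.sqrt(np.outer(np.diag(c), np.diag(c)))
            assert np.abs(off / denom).max() < 1e-8
            gs = gram_schmidt(x)
            if np.linalg.norm(o - x) <= np.linalg.norm(gs - x):
                wins += 1
        assert wins >= 45

    def test_nonconvergence_reported_not_raised(self, rng):
        x = rng.standard_normal((64, 3))[None].transpose(0, 2, 1)
        _, report = symmetric_orthogonalize(_ptc(x), max_iter=1)
        assert report.converged is False


class TestComputeIcoh:
    def _signals(self, rng, n_trials=4):
        x = band_limited_noise(rng, BAND, n_trials, 384, 128.0)
        return hilbert(x, axis=-1)

    def test_zero_lag_gives_zero(self, rng):
        x = self._signals(rng)
        assert np.abs(compute_icoh(x, x)).max() < 1e-6

    def test_quarter_cycle_gives_one(self, rng):
        x = self._signals(rng)
        y = x * np.exp(1j * np.pi / 2)
        np.testing.assert_allclose(compute_icoh(x, y), 1.0, atol=1e-6)

    def test_symmetry_at_machine_precision(self, rng):
        x, y = self._signals(rng), self._signals(rng)
        np.testing.assert_allclose(compute_icoh(x, y), compute_icoh(y, x),
                                   atol=1e-14)

    def test_scale_invariance_machine_precision(self, rng):
        x, y = self._signals(rng), self._signals(rng)
        base = compute_icoh(x, y)
        np.testing.assert_allclose(compute_icoh(3.7 * x, 0.002 * y), base,
                                   atol=1e-12)

    def test_zero_power_window_flagged_nan(self, rng):
        x = self._signals(rng, 2)
        y = x.copy()
        y[:, 64:128] = 0.0                      # first analysis window dead
        out = compute_icoh(x, y)
        assert np.isnan(out[:, 0]).all()
        assert np.isfinite(out[:, 1:]).all()

    def test_small_sample_bias_matches_independent_mc(self, rng):
        """Mean iCoh of independent signals matches an independent
        re-implementation of the estimator, within 2 s.e."""
        n = 2000
        # independent draw, estimator written out by hand on one window
        xw = hilbert(band_limited_noise(rng, BAND, n, 384, 128.0),
                     axis=-1)[:, 64:128]
        yw = hilbert(band_limited_noise(rng, BAND, n, 384, 128.0),
                     axis=-1)[:, 64:128]
        sxy = (xw * np.conj(yw)).mean(axis=-1)
        direct = np.abs(np.imag(sxy)) / np.sqrt(
            (np.abs(xw) ** 2).mean(-1) * (np.abs(yw) ** 2).mean(-1))
        rng2 = np.random.default_rng(999)
        x2 = hilbert(band_limited_noise(rng2, BAND, n, 384, 128.0), axis=-1)
        y2 = hilbert(band_limited_noise(rng2, BAND, n, 384, 128.0), axis=-1)
        vals = compute_icoh(x2, y2)[:, 0]       # one 64-sample window
        se = np.hypot(direct.std() / np.sqrt(n), vals.std() / np.sqrt(n))
        assert abs(vals.mean() - direct.mean()) < 2 * se

    def test_volume_conduction_suppressed_by_orthogonalization(self, rng):
        """Adding a shared zero-lag component biases raw iCoh toward zero;
        orthogonalization recovers most of the planted coupling."""
        n_tr, n_s = 200, 384
        x = band_limited_noise(rng, BAND, n_tr, n_s, 128.0)
        noise = band_limited_noise(rng, BAND, n_tr, n_s, 128.0)
        common = band_limited_noise(rng, BAND, n_tr, n_s, 128.0)
        y = 0.6 * quadrature_shift(x, np.pi / 2) + 0.4 * noise
        clean = compute_icoh(hilbert(x, axis=-1),
                             hilbert(y, axis=-1)).mean()
        xm, ym = x + 0.3 * common, y + 0.3 * common
        raw = compute_icoh(hilbert(xm, axis=-1),
                           hilbert(ym, axis=-1)).mean()
        ptc = _ptc(np.stack([xm, ym, common], axis=1))
        ortho, _ = symmetric_orthogonalize(ptc)
        o = ortho.data
        fixed = compute_icoh(hilbert(np.real(o[:, 0]), axis=-1),
                             hilbert(np.real(o[:, 1]), axis=-1)).mean()
        assert abs(fixed - clean) < abs(raw - clean)
        assert abs(fixed - clean) < 0.05


class TestSeedIcohTensor:
    def test_unit_count_contract_68_parcels(self, rng):
        from vigorcoh.presets import DESIKAN_KILLIANY_PARCELS, SEED_PARCEL
        data = rng.standard_normal((2, 68, 128)) + 0j
        ptc = _ptc(data, names=list(DESIKAN_KILLIANY_PARCELS),
                   seed=SEED_PARCEL)
        from vigorcoh.windows import WindowGrid
        grid = WindowGrid(windows=((-1.5, -1.0),))
        tensor = seed_icoh_tensor(ptc, grid)
        assert len(tensor.unit_ids) == 67
        assert SEED_PARCEL not in tensor.unit_ids

    def test_coupled_margin_grows_with_kappa(self, rng):
        n_tr, n_s = 20, 384
        margins = []
        for kappa in (0.3, 0.6, 0.9):
            seed = band_limited_noise(rng, BAND, n_tr, n_s, 128.0)
            shifted = quadrature_shift(seed, np.pi / 2)
            coupled = kappa * shifted + (1 - kappa) * band_limited_noise(
                rng, BAND, n_tr, n_s, 128.0)
            free = band_limited_noise(rng, BAND, n_tr, n_s, 128.0)
            data = np.stack([seed, coupled, free], axis=1)
            ptc = _ptc(hilbert(data, axis=-1))
            t = seed_icoh_tensor(ptc)
            coupled_m = np.nanmean(t.values[:, t.unit_ids.index("p1")])
            free_m = np.nanmean(t.values[:, t.unit_ids.index("p2")])
            margins.append(coupled_m - free_m)
        assert margins[0] < margins[1] < margins[2]
        assert margins[0] > 0

    def test_independent_parcels_match_null_baseline(self, rng):
        """With all parcels independent, no parcel's mean iCoh deviates
        from the independence baseline (Bonferroni alpha=0.01)."""
        from scipy import stats
        n_tr = 100
        data = band_limited_noise(rng, BAND, n_tr * 6, 384, 128.0)
        data = data.reshape(n_tr, 6, 384)
        t = seed_icoh_tensor(_ptc(hilbert(data, axis=-1)))
        null_draws = band_limited_noise(rng, BAND, 2 * 400, 384, 128.0)
        a = hilbert(null_draws[:400], axis=-1)
        b = hilbert(null_draws[400:], axis=-1)
        baseline = compute_icoh(a, b).mean()
        alpha = 0.01 / len(t.unit_ids)
        for j in range(len(t.unit_ids)):
            vals = t.values[:, j, :].ravel()
            res = stats.ttest_1samp(vals, baseline)
            assert res.pvalue > alpha

    def test_missing_seed_errors(self, rng):
        data = rng.standard_normal((2, 3, 384)) + 0j
        ptc = _ptc(data)
        ptc.seed_name = "p0"
        ptc.parcel_names = ["p0", "p1", "p2"]
        bad = _ptc(data)
        with pytest.raises(ValueError):
            bad.seed_name = "nope"
            seed_icoh_tensor(bad)
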