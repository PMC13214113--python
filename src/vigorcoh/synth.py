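"""Synthetic multi-subject cohort generator with planted, recoverable effects.

The generator emulates the statistical structure of an instructed-speed
(Fast/Slow) hand-opening experiment with simultaneous EEG:

* Parcel-level band-limited oscillations in which coupled parcels receive a
  quarter-cycle-lagged copy of the seed (left precentral) signal, with a
  coupling weight ``kappa`` that depends on the trial condition.  Lower
  coupling in Fast trials plants the "iCoh lower in Fast" effect.
* A per-subject Fast-Slow seed power offset of random sign (dB scale),
  reproducing the across-subject heterogeneity of local beta power effects.
* Behavioral reaction/movement times shorter in Fast than Slow, with each
  subject's Slow-Fast (RT+MT) difference coupled to that subject's planted
  coherence effect through a Gaussian copula targeting ``rho_behavior``.
* Sensor epochs produced by a fixed full-rank linear mixing of the parcel
  signals plus 1/f noise (a stand-in for volume conduction that keeps the
  connectivity ground truth exactly known).

Every planted quantity is stored in a per-subject truth record so each
downstream stage can be tested as a recovery problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bands import Band, get_band
from .containers import EpochSet, KinematicTraces, ParcelTimeCourses
from .presets import FRONTO_PARIETAL_21, SEED_PARCEL

#: Parcels carrying the planted seed coupling by default: the regions with
#: the strongest condition contrast in the motivating dataset.
DEFAULT_COUPLED = [
    "precuneus-lh", "precuneus-rh", "superiorparietal-rh", "postcentral-lh",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    ``kappa_slow - kappa_fast`` is the planted coherence effect (both in
    [0, 1]); equal values give a null cohort.  ``rt_ms`` / ``mt_ms`` give
    (mean, sd) per condition where the sd is the ACROSS-SUBJECT spread of
    subject condition means; trial-to-trial jitter is separate.
    """

    n_subjects: int = 12
    n_trials_per_condition: int = 60
    fs: float = 512.0
    epoch_span: tuple[float, float] = (-1.7, 1.7)
    bands: tuple[str, ...] = ("standard",)
    seed_parcel: str = SEED_PARCEL
    parcel_names: tuple[str, ...] = tuple([SEED_PARCEL] + FRONTO_PARIETAL_21)
    coupled_parcels: tuple[str, ...] = tuple(DEFAULT_COUPLED)
    kappa_slow: float = 0.8
    kappa_fast: float = 0.2
    kappa_sd: float = 0.08           # per-subject spread of the coupling gap
    coupling_phase: float = math.pi / 2
    power_effect_sd: float = 2.0     # dB spread of Fast-Slow power offsets
    rt_ms: dict = field(default_factory=lambda: {
        "Fast": (300.0, 40.0), "Slow": (450.0, 60.0)})
    mt_ms: dict = field(default_factory=lambda: {
        "Fast": (220.0, 25.0), "Slow": (600.0, 70.0)})
    rt_trial_sd_ms: float = 40.0
    mt_trial_sd_ms: float = 30.0
    rho_behavior: float = -0.6
    noise_1f_exponent: float = 1.0
    n_channels: int = 32
    fs_behav: float = 250.0
    rng_seed: int = 0

    MIN_TRIALS: int = 5              # < n_folds is unusable downstream

    def __post_init__(self) -> None:
        lo, hi = self.epoch_span
        if lo > -1.7 + 1e-9 or hi < 1.7 - 1e-9:
            raise ValueError(
                f"epoch_span {self.epoch_span} too short: the seven analysis "
                "windows span [-1.0, +1.0] s, trimming keeps [-1.5, +1.5] s "
                "and filtering needs a 0.2 s margin each side, so the span "
                "must contain [-1.7, +1.7] s")
        if self.n_trials_per_condition < self.MIN_TRIALS:
            raise ValueError(
                f"n_trials_per_condition={self.n_trials_per_condition} < "
                f"{self.MIN_TRIALS}: too few trials for 5-fold "
                "cross-validation downstream")
        if not (0.0 <= self.kappa_fast <= self.kappa_slow <= 1.0):
            raise ValueError(
                "need 0 <= kappa_fast <= kappa_slow <= 1 "
                f"(got kappa_fast={self.kappa_fast}, "
                f"kappa_slow={self.kappa_slow})")
        if self.seed_parcel not in self.parcel_names:
            raise ValueError("seed_parcel must appear in parcel_names")
        unknown = set(self.coupled_parcels) - set(self.parcel_names)
        if unknown:
            raise ValueError(f"coupled_parcels not in parcel_names: "
                             f"{sorted(unknown)}")
        if self.seed_parcel in self.coupled_parcels:
            raise ValueError("the seed cannot be coupled to itself")
        for cond in ("Fast", "Slow"):
            if cond not in self.rt_ms or cond not in self.mt_ms:
                raise ValueError(f"rt_ms/mt_ms must define condition {cond}")

    def band_list(self) -> list[Band]:
        return [get_band(b) for b in self.bands]

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("MIN_TRIALS", None)
        return d


@dataclass
class SubjectData:
    """One subject's generated data."""

    subject_id: str
    epochs: EpochSet
    parcels: dict          # band name -> ParcelTimeCourses (real, at fs)
    kinematics: KinematicTraces


@dataclass
class Cohort:
    config: SimulationConfig
    subjects: list
    truth: pd.DataFrame    # one row per subject, every planted quantity
    mixing: np.ndarray     # fixed (channels x parcels) mixing matrix

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# signal helpers

def band_limited_noise(rng: np.random.Generator, band: Band, n_trials: int,
                       n_samples: int, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to ``band`` (FFT shaping
    with 1 Hz raised-cosine edges)."""
    x = rng.standard_normal((n_trials, n_samples))
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    gain = _band_gain(f, band)
    y = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _band_gain(f: np.ndarray, band: Band, roll: float = 1.0) -> np.ndarray:
    g = np.zeros_like(f)
    g[(f >= band.f_lo) & (f <= band.f_hi)] = 1.0
    for edge, sign in ((band.f_lo, -1), (band.f_hi, +1)):
        m = np.abs(f - edge) < roll
        ramp = 0.5 * (1 + np.cos(np.pi * np.clip(
            sign * (f[m] - edge) / roll, 0, 1)))
        g[m] = np.maximum(g[m], ramp)
    return g


def one_over_f_noise(rng: np.random.Generator, shape: tuple, fs: float,
                     exponent: float = 1.0) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ 1/f**exponent."""
    n = shape[-1]
    x = rng.standard_normal(shape)
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.ones_like(f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    y = np.fft.irfft(spec * amp, n=n, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def quadrature_shift(x: np.ndarray, phase: float) -> np.ndarray:
    """Shift every spectral component of ``x`` (last axis) by ``phase``
    radians via the analytic signal."""
    from scipy.signal import hilbert
    return np.real(hilbert(x, axis=-1) * np.exp(-1j * phase))


# ---------------------------------------------------------------------------
# planted effects

def plant_cohort_effects(config: SimulationConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Draw every subject-level planted quantity.

    Returns one row per subject with the per-subject coupling weights, the
    coherence effect on the Fast-Slow scale (negative when Slow coupling
    exceeds Fast), the dB power offset, condition means of RT and MT, and
    the planted Slow-Fast (RT+MT) difference.  The coherence effect and the
    behavioral difference are tied by a Gaussian copula so their
    across-subject correlation targets ``rho_behavior``.
    """
    n = config.n_subjects
    d_mean = config.kappa_slow - config.kappa_fast
    # copula: coherence effect e = -d, so corr(e, b) = -corr(d, b)
    rho_db = float(np.clip(-config.rho_behavior, -1.0, 1.0))
    cov = np.array([[1.0, rho_db], [rho_db, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n,
                                method="cholesky")
    mid = 0.5 * (config.kappa_slow + config.kappa_fast)
    d_max = 2.0 * min(mid, 1.0 - mid)
    if d_mean == 0.0:
        d = np.zeros(n)                      # strict null cohort
    else:
        d = np.clip(d_mean + config.kappa_sd * z[:, 0], 0.0, d_max)
    kappa_slow_s = mid + d / 2.0
    kappa_fast_s = mid - d / 2.0
    effect = kappa_fast_s - kappa_slow_s     # Fast-Slow scale, <= 0

    power_db = rng.normal(0.0, config.power_effect_sd, size=n)

    rt_f_m, rt_f_sd = config.rt_ms["Fast"]
    rt_s_m, rt_s_sd = config.rt_ms["Slow"]
    mt_f_m, mt_f_sd = config.mt_ms["Fast"]
    mt_s_m, mt_s_sd = config.mt_ms["Slow"]
    rt_fast = np.clip(rng.normal(rt_f_m, rt_f_sd, size=n), 80.0, None)
    mt_fast = np.clip(rng.normal(mt_f_m, mt_f_sd, size=n), 120.0, None)
    diff_mean = (rt_s_m + mt_s_m) - (rt_f_m + mt_f_m)
    diff_sd = math.hypot(rt_s_sd, mt_s_sd)
    behav_diff = diff_mean + diff_sd * z[:, 1]
    # keep the instructed ordering Slow > Fast per subject
    behav_diff = np.clip(behav_diff, 0.2 * abs(diff_mean) + 1.0, None)
    # split the planted difference between RT and MT by the configured shares
    share_rt = (rt_s_m - rt_f_m) / diff_mean if diff_mean else 0.5
    rt_slow = rt_fast + share_rt * behav_diff
    mt_slow = mt_fast + (1.0 - share_rt) * behav_diff

    return pd.DataFrame({
        "subject_id": [f"sub-{i + 1:02d}" for i in range(n)],
        "kappa_slow": kappa_slow_s,
        "kappa_fast": kappa_fast_s,
        "coherence_effect": effect,
        "power_offset_db": power_db,
        "rt_fast_ms": rt_fast,
        "rt_slow_ms": rt_slow,
        "mt_fast_ms": mt_fast,
        "mt_slow_ms": mt_slow,
        "behavior_diff_ms": behav_diff,      # Slow-Fast (RT+MT), planted
    })


# ---------------------------------------------------------------------------
# per-subject generation

def _trial_labels(config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    n = config.n_trials_per_condition
    labels = np.array(["Fast"] * n + ["Slow"] * n, dtype=object)
    rng.shuffle(labels)
    return labels


def _simulate_subject_signals(config: SimulationConfig, truth_row: pd.Series,
                              labels: np.ndarray, mixing: np.ndarray,
                              rng: np.random.Generator
                              ) -> tuple[EpochSet, dict]:
    fs = config.fs
    lo, hi = config.epoch_span
    n_samples = int(round((hi - lo) * fs))
    n_samples -= n_samples % 4          # FFT-friendly epoch length
    n_trials = labels.size
    parcels = list(config.parcel_names)
    n_parcels = len(parcels)
    seed_ix = parcels.index(config.seed_parcel)
    coupled_ix = [parcels.index(p) for p in config.coupled_parcels]
    fast = np.asarray([l == "Fast" for l in labels])

    kappa = np.where(fast, truth_row["kappa_fast"], truth_row["kappa_slow"])
    gain = np.where(fast, 10.0 ** (truth_row["power_offset_db"] / 20.0), 1.0)

    parcel_bands: dict[str, np.ndarray] = {}
    for band in config.band_list():
        sig = np.empty((n_trials, n_parcels, n_samples))
        seed_sig = band_limited_noise(rng, band, n_trials, n_samples, fs)
        shifted = quadrature_shift(seed_sig, config.coupling_phase)
        sig[:, seed_ix, :] = seed_sig
        for j in range(n_parcels):
            if j == seed_ix:
                continue
            noise = band_limited_noise(rng, band, n_trials, n_samples, fs)
            if j in coupled_ix:
                k = kappa[:, None]
                sig[:, j, :] = k * shifted + (1.0 - k) * noise
            else:
                sig[:, j, :] = noise
        # per-condition power gain (does not affect iCoh: scale-invariant)
        sig *= gain[:, None, None]
        # broadband 1/f background so the band-pass stage has work to do
        sig += 0.3 * one_over_f_noise(
            rng, (n_trials, n_parcels, n_samples), fs,
            config.noise_1f_exponent)
        parcel_bands[band.name] = sig

    broadband = sum(parcel_bands.values())
    sensors = np.einsum("cp,tps->tcs", mixing, broadband)
    sensors += 0.5 * one_over_f_noise(
        rng, sensors.shape, fs, config.noise_1f_exponent)

    positions = sensor_positions(config.n_channels)
    channel_ids = [f"CH{i + 1:02d}" for i in range(config.n_channels)]
    epochs = EpochSet(sensors, fs, lo, labels, channel_ids, positions,
                      subject_id=truth_row["subject_id"])
    courses = {
        name: ParcelTimeCourses(
            parcel_bands[name], fs, lo, parcels, config.seed_parcel,
            get_band(name), labels, subject_id=truth_row["subject_id"])
        for name in parcel_bands
    }
    return epochs, courses


def sensor_positions(n_channels: int, spacing: float = 0.012) -> np.ndarray:
    """A compact rectangular montage; neighbor spacing below the 0.02
    adjacency radius used by the cluster statistics."""
    n_cols = int(math.ceil(math.sqrt(n_channels)))
    rows, cols = np.divmod(np.arange(n_channels), n_cols)
    return np.column_stack([cols, rows]).astype(float) * spacing


def _half_sine_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    phase = (t - center) / width
    out = np.cos(np.pi * phase)
    out[np.abs(phase) > 0.5] = 0.0
    return np.clip(out, 0.0, None)


def _simulate_subject_kinematics(config: SimulationConfig,
                                 truth_row: pd.Series, labels: np.ndarray,
                                 rng: np.random.Generator) -> KinematicTraces:
    fs = config.fs_behav
    n_trials = labels.size
    go_t = 1.0
    rt_s_max = (truth_row["rt_slow_ms"] + 4 * config.rt_trial_sd_ms) / 1e3
    mt_s_max = (truth_row["mt_slow_ms"] + 4 * config.mt_trial_sd_ms) / 1e3
    t_max = go_t + rt_s_max + 4 * mt_s_max + 0.5
    n_samples = int(round(t_max * fs))
    t = np.arange(n_samples) / fs

    lux = np.empty((n_trials, n_samples))
    acc = np.empty((n_trials, n_samples))
    go_idx = np.full(n_trials, int(round(go_t * fs)))
    for i, lab in enumerate(labels):
        cond = "fast" if lab == "Fast" else "slow"
        rt = max(truth_row[f"rt_{cond}_ms"]
                 + rng.normal(0, config.rt_trial_sd_ms), 80.0) / 1e3
        mt = max(truth_row[f"mt_{cond}_ms"]
                 + rng.normal(0, config.mt_trial_sd_ms), 140.0) / 1e3
        jitter = rng.normal(0, 5e-3, size=4)
        intervals = mt + (jitter - jitter.mean())   # mean interval == mt
        peak_times = go_t + rt + np.concatenate([[0.0], np.cumsum(intervals)])
        trace = np.full(n_samples, 0.1)
        amp = 0.8 + rng.normal(0, 0.03)
        width = min(0.8 * intervals.min(), 0.25)
        for pt in peak_times:
            trace += amp * _half_sine_bump(t, pt, width)
        lux[i] = trace + rng.normal(0, 0.005, size=n_samples)
        # acceleration bursts scale with movement speed (amplitude / MT)
        move = (t >= go_t + rt - 0.05) & (t <= peak_times[-1] + 0.05)
        a = rng.normal(0, 0.02, size=n_samples)
        a[move] += rng.normal(0, amp / mt, size=move.sum())
        acc[i] = a
    return KinematicTraces(lux, acc, fs, go_idx, labels,
                           subject_id=truth_row["subject_id"])


# ---------------------------------------------------------------------------
# cohort entry point

def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort (deterministic in ``rng_seed``)."""
    master = np.random.SeedSequence(config.rng_seed)
    ss_mix, ss_effects, *ss_subjects = master.spawn(2 + config.n_subjects)

    rng_mix = np.random.default_rng(ss_mix)
    n_parcels = len(config.parcel_names)
    while True:
        mixing = rng_mix.standard_normal((config.n_channels, n_parcels))
        mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
        if np.linalg.matrix_rank(mixing) == min(mixing.shape):
            break

    truth = plant_cohort_effects(config, np.random.default_rng(ss_effects))

    subjects = []
    for i in range(config.n_subjects):
        row = truth.iloc[i]
        rng = np.random.default_rng(ss_subjects[i])
        labels = _trial_labels(config, rng)
        epochs, courses = _simulate_subject_signals(
            config, row, labels, mixing, rng)
        kin = _simulate_subject_kinematics(config, row, labels, rng)
        subjects.append(SubjectData(row["subject_id"], epochs, courses, kin))
    return Cohort(config, subjects, truth, mixing)
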