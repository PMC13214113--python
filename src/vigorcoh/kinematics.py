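"""Behavioral variable extraction and statistics.

Movement time (MT), reaction time (RT), movement amplitude and mean
absolute acceleration are derived from a fingertip light-sensor (luxmeter)
trace and an accelerometer trace per trial.  The hand fully open produces a
luminosity peak; a trial of four hand closures therefore yields five peaks:
the first anchors RT, the four inter-peak intervals give MT.

The sum RT+MT (total movement duration) is the inverse proxy for movement
vigor used by the group-level correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import KinematicTraces

#: Number of luminosity peaks required for a 4-repetition trial.
N_PEAKS_REQUIRED = 5


def detect_luminosity_peaks(lux_trial: np.ndarray, fs_behav: float,
                            go_cue_index: int,
                            prominence_frac: float = 0.5,
                            min_distance_s: float = 0.1) -> np.ndarray:
    """Find post-cue luminosity peaks (hand fully open).

    Local maxima with prominence above ``prominence_frac`` of the trial's
    dynamic range and at least ``min_distance_s`` apart; peaks before the
    go cue are ignored.  Returns an empty array when fewer than
    ``N_PEAKS_REQUIRED`` peaks are found (the trial is invalid, not an
    error).
    """
    lux_trial = np.asarray(lux_trial, dtype=float)
    dyn = np.ptp(lux_trial)
    if dyn <= 0:
        return np.empty(0, dtype=int)
    peaks, _ = signal.find_peaks(
        lux_trial,
        prominence=prominence_frac * dyn,
        distance=max(int(round(min_distance_s * fs_behav)), 1))
    peaks = peaks[peaks >= go_cue_index]
    if peaks.size < N_PEAKS_REQUIRED:
        return np.empty(0, dtype=int)
    return peaks[:N_PEAKS_REQUIRED]


def compute_trial_behavior(peaks: np.ndarray, lux_trial: np.ndarray,
                           acc_trial: np.ndarray, fs_behav: float,
                           go_cue_index: int
                           ) -> tuple[float, float, float, float]:
    """(MT, RT, amplitude, mean|acc|) for one trial from its peak set.

    * RT: time from go cue to the first peak (s).
    * MT: mean of the four inter-peak intervals (s).
    * amplitude: mean over repetitions of (max - min) luxmeter value, each
      repetition spanning a peak up to the sample before the next peak.
    * mean|acc|: mean absolute acceleration from go cue to the last peak.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2 or np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be strictly increasing with >= 2 entries")
    if peaks[0] < go_cue_index:
        raise ValueError("first peak precedes the go cue")
    rt = (peaks[0] - go_cue_index) / fs_behav
    mt = float(np.mean(np.diff(peaks))) / fs_behav
    amps = [np.ptp(lux_trial[a:b]) for a, b in zip(peaks[:-1], peaks[1:])]
    amplitude = float(np.mean(amps))
    mean_abs_acc = float(np.mean(np.abs(acc_trial[go_cue_index:peaks[-1] + 1])))
    return mt, rt, amplitude, mean_abs_acc


def mark_behavioral_outliers(values: np.ndarray) -> np.ndarray:
    """3xMAD rule: True where |x - median| > 3 * MAD.

    MAD is the raw median absolute deviation (no normality constant).  When
    MAD is 0, any nonzero deviation from the median is flagged.  NaNs are
    never flagged; an all-NaN input yields an empty mask with a warning.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        warnings.warn("all-NaN input to mark_behavioral_outliers",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(values.shape, dtype=bool)
    med = np.median(values[finite])
    mad = np.median(np.abs(values[finite] - med))
    dev = np.abs(values - med)
    mask = np.zeros(values.shape, dtype=bool)
    if mad == 0:
        mask[finite] = dev[finite] > 0
    else:
        mask[finite] = dev[finite] > 3.0 * mad
    return mask


@dataclass
class PairedTestResult:
    test: str            # "t" | "wilcoxon"
    statistic: float
    p: float
    effect_size: float   # Cohen's dz (t) or matched-pairs rank-biserial (W)
    shapiro_p: float


def paired_compare(a: np.ndarray, b: np.ndarray,
                   force_test: "str | None" = None) -> PairedTestResult:
    """Paired comparison with a normality gate on the differences.

    Shapiro-Wilk on a-b: p > 0.05 -> paired t with Cohen's
    dz = mean(diff)/sd(diff); otherwise Wilcoxon signed-rank with
    matched-pairs rank-biserial r = (W+ - W-)/(W+ + W-).  ``force_test``
    bypasses the gate ("t" or "wilcoxon").
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    if a.size < 5:
        raise ValueError("need n >= 5 pairs")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero-variance paired differences: test degenerate")
    shapiro_p = float(stats.shapiro(diff).pvalue)
    use_t = shapiro_p > 0.05 if force_test is None else force_test == "t"
    if use_t:
        res = stats.ttest_rel(a, b)
        dz = float(diff.mean() / diff.std(ddof=1))
        return PairedTestResult("t", float(res.statistic), float(res.pvalue),
                                dz, shapiro_p)
    res = stats.wilcoxon(a, b)
    nz = diff[diff != 0]
    ranks = stats.rankdata(np.abs(nz))
    w_pos = ranks[nz > 0].sum()
    w_neg = ranks[nz < 0].sum()
    r = float((w_pos - w_neg) / (w_pos + w_neg))
    return PairedTestResult("wilcoxon", float(res.statistic),
                            float(res.pvalue), r, shapiro_p)


# ---------------------------------------------------------------------------
# cohort-level extraction

MOTOR_VARIABLES = ("MT", "RT", "amplitude", "mean_abs_acc")


def extract_trials(kin: KinematicTraces) -> pd.DataFrame:
    """Per-trial behavioral table for one subject.

    Invalid trials (insufficient peaks) get NaN motor variables and
    ``valid=False``.  ``vigor_proxy`` is RT+MT (s); vigor itself is its
    reciprocal.
    """
    rows = []
    for i in range(kin.n_trials):
        go = int(kin.go_cue_index[i])
        peaks = detect_luminosity_peaks(kin.lux[i], kin.fs_behav, go)
        if peaks.size == 0:
            mt = rt = amp = acc = np.nan
            valid = False
        else:
            mt, rt, amp, acc = compute_trial_behavior(
                peaks, kin.lux[i], kin.acc[i], kin.fs_behav, go)
            valid = True
        rows.append({
            "subject": kin.subject_id, "trial": i,
            "condition": kin.labels[i], "valid": valid,
            "MT": mt, "RT": rt, "amplitude": amp, "mean_abs_acc": acc,
            "vigor_proxy": rt + mt,
        })
    return pd.DataFrame(rows)


def summarize_subject_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Subject x condition means after 3xMAD outlier flagging per variable.

    Outliers are flagged (``<var>_outlier`` columns added to ``trials`` in
    place), then excluded from the means — never removed from the raw
    table.
    """
    for var in MOTOR_VARIABLES:
        trials[f"{var}_outlier"] = False
    for (sub, cond), idx in trials.groupby(
            ["subject", "condition"]).groups.items():
        for var in MOTOR_VARIABLES:
            vals = trials.loc[idx, var].to_numpy(dtype=float)
            mask = mark_behavioral_outliers(vals)
            trials.loc[idx, f"{var}_outlier"] = mask
    rows = []
    for (sub, cond), grp in trials.groupby(["subject", "condition"]):
        row = {"subject": sub, "condition": cond,
               "n_valid": int(grp["valid"].sum())}
        for var in MOTOR_VARIABLES:
            keep = grp.loc[~grp[f"{var}_outlier"], var]
            row[var] = float(keep.mean())
        row["vigor_proxy"] = row["RT"] + row["MT"]
        rows.append(row)
    return pd.DataFrame(rows)


def behavior_tables(kinematics: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial-level and subject x condition tables for a list of
    :class:`KinematicTraces` (one per subject)."""
    trials = pd.concat([extract_trials(k) for k in kinematics],
                       ignore_index=True)
    summary = summarize_subject_behavior(trials)
    return trials, summary


def slow_fast_differences(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-subject Slow-Fast differences in RT, MT and RT+MT (seconds)."""
    wide = summary.pivot(index="subject", columns="condition")
    out = pd.DataFrame({
        "subject": wide.index,
        "d_RT": wide[("RT", "Slow")] - wide[("RT", "Fast")],
        "d_MT": wide[("MT", "Slow")] - wide[("MT", "Fast")],
    }).reset_index(drop=True)
    out["d_total"] = out["d_RT"] + out["d_MT"]
    return out
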