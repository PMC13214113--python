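"""Group-level inference on decoding outputs and behavior.

All tests consume per-subject summaries only.  One-sided p-values follow
the directional hypotheses: decoding above chance (AUC > 0.5, two-sided
reported with dz), coefficient consistency (two-sided), and NEGATIVE
correlations between coefficients and the Slow-Fast vigor difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class OneSampleResult:
    t: float
    p: float
    d: float                 # Cohen's dz
    mean: float
    ci95: tuple
    n: int


@dataclass
class ConsistencyResult:
    t: float
    p: float
    d: float
    n: int
    prop_positive: float
    prop_negative: float


@dataclass
class GroupAssociationResult:
    r: float
    p_one_sided: float
    n: int
    x_name: str = ""
    y_name: str = ""
    partial_r: float = float("nan")
    partial_p: float = float("nan")
    control_name: str = ""


def _one_sample(values: np.ndarray, popmean: float) -> OneSampleResult:
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 5:
        raise ValueError("need n >= 5 subjects")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: one-sample test degenerate")
    out = stats.ttest_1samp(values, popmean)
    dz = float((values.mean() - popmean) / sd)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    mean = float(values.mean())
    return OneSampleResult(float(out.statistic), float(out.pvalue), dz,
                           mean, (mean - half, mean + half), n)


def group_auc_test(mean_aucs: np.ndarray) -> OneSampleResult:
    """One-sample t of subject mean AUCs against chance (0.5); the mean
    and CI are reported on the ΔAUC = AUC - 0.5 scale."""
    res = _one_sample(np.asarray(mean_aucs, dtype=float), 0.5)
    return OneSampleResult(res.t, res.p, res.d, res.mean - 0.5,
                           (res.ci95[0] - 0.5, res.ci95[1] - 0.5), res.n)


def coefficient_consistency_test(mean_coefficients: np.ndarray
                                 ) -> "ConsistencyResult | None":
    """Two-sided one-sample t of the per-subject mean standardized
    coefficients against zero, with sign proportions.

    Only above-chance subjects should be passed in (the exclusion rule);
    with fewer than 5 subjects the test is skipped (returns None with a
    log entry).
    """
    vals = np.asarray(mean_coefficients, dtype=float)
    if vals.size < 5:
        logger.warning("coefficient consistency test skipped: only %d "
                       "subjects after exclusion", vals.size)
        return None
    res = _one_sample(vals, 0.0)
    return ConsistencyResult(res.t, res.p, res.d, res.n,
                             float((vals > 0).mean()),
                             float((vals < 0).mean()))


def _pearson_one_sided(x: np.ndarray, y: np.ndarray,
                       direction: str = "negative",
                       df: "int | None" = None) -> tuple[float, float]:
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    df = df if df is not None else n - 2
    if abs(r) >= 1.0:
        return r, 0.0 if (r < 0) == (direction == "negative") else 1.0
    t = r * np.sqrt(df / (1 - r ** 2))
    p = stats.t.cdf(t, df) if direction == "negative" else stats.t.sf(t, df)
    return r, float(p)


def vigor_correlation(mean_coefficients: np.ndarray,
                      behavior_diff: np.ndarray,
                      direction: str = "negative",
                      x_name: str = "coefficient",
                      y_name: str = "slow_fast_diff"
                      ) -> GroupAssociationResult:
    """Pearson correlation between per-subject mean coefficients and the
    Slow-Fast behavioral difference, one-sided for the expected
    (negative) direction."""
    x = np.asarray(mean_coefficients, dtype=float)
    y = np.asarray(behavior_diff, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be aligned 1-D vectors")
    if x.size < 5:
        raise ValueError("need n >= 5 subjects")
    r, p = _pearson_one_sided(x, y, direction)
    return GroupAssociationResult(r, p, x.size, x_name, y_name)


def partial_vigor_correlation(icoh_coefficients: np.ndarray,
                              behavior_diff: np.ndarray,
                              control: np.ndarray,
                              direction: str = "negative"
                              ) -> GroupAssociationResult:
    """Partial correlation by double residualization on the control
    variable (df = n - 3 for the one-sided test)."""
    x = np.asarray(icoh_coefficients, dtype=float)
    y = np.asarray(behavior_diff, dtype=float)
    c = np.asarray(control, dtype=float)
    if not (x.shape == y.shape == c.shape) or x.ndim != 1:
        raise ValueError("inputs must be three aligned 1-D vectors")
    n = x.size
    rx = float(np.corrcoef(x, c)[0, 1])
    if abs(rx) > 0.999:
        logger.warning("control is collinear with the target (|r|=%.4f); "
                       "partial correlation undefined", abs(rx))
        return GroupAssociationResult(
            float(np.corrcoef(x, y)[0, 1]), float("nan"), n,
            partial_r=0.0, partial_p=float("nan"),
            control_name="collinear")
    design = np.column_stack([np.ones(n), c])
    res_x = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    res_y = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    pr, pp = _pearson_one_sided(res_x, res_y, direction, df=n - 3)
    r, p = _pearson_one_sided(x, y, direction)
    return GroupAssociationResult(r, p, n, partial_r=pr, partial_p=pp)


@dataclass
class ArtifactControlResult:
    per_subject_r: np.ndarray
    t: float
    p: float
    n: int


def artifact_control_correlation(trial_acc: list, trial_feature: list
                                 ) -> ArtifactControlResult:
    """Trial-wise |acceleration| vs trial-mean beta feature, per subject;
    group-level one-sample t of the correlation coefficients vs zero.

    ``trial_acc`` and ``trial_feature`` are per-subject aligned vectors;
    subjects with a constant feature (undefined r) are skipped with a log
    entry.
    """
    rs = []
    for i, (acc, feat) in enumerate(zip(trial_acc, trial_feature)):
        acc = np.asarray(acc, dtype=float)
        feat = np.asarray(feat, dtype=float)
        keep = np.isfinite(acc) & np.isfinite(feat)
        if feat[keep].std() == 0 or acc[keep].std() == 0:
            logger.info("subject %d skipped: constant trial feature", i)
            continue
        rs.append(np.corrcoef(acc[keep], feat[keep])[0, 1])
    rs = np.asarray(rs)
    out = stats.ttest_1samp(rs, 0.0)
    return ArtifactControlResult(rs, float(out.statistic),
                                 float(out.pvalue), rs.size)
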