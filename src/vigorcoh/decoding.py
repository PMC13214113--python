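"""Subject-specific Fast/Slow decoding: grouped sequential forward
selection (SFS) around L1-regularized logistic regression with
leakage-safe cross-validation and bootstrap stability.

A candidate *group* is one spatial unit (channel or parcel) with its seven
time-window features.  SFS greedily adds groups while the mean
cross-validated AUC improves by at least ``min_gain`` (0.002), up to three
groups.  All per-fold preprocessing — per-condition 3xMAD trial rejection
and z-scoring — uses training-fold statistics only.

Outcome coding: by default the positive class is Fast, so a NEGATIVE
standardized coefficient means the feature is LOWER in Fast trials.  (The
inverse coding is available via ``positive_class="Slow"``.)

Because greedy selection is scored by the same cross-validated AUC it
maximizes, that score is optimistically biased (winner's curse over the
candidate set).  The subject-level entry point therefore reports
``mean_auc`` from a nested cross-validation: SFS is re-run inside each
outer training fold and the AUC comes from the untouched outer test fold.
The reported selected groups come from SFS on the full data (they feed the
group-level selection-frequency maps), and the bootstrap CI re-runs CV on
resampled trials with that selection held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import sklearn
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureTensor

logger = logging.getLogger(__name__)

DEFAULT_MIN_GAIN = 0.002
DEFAULT_MAX_GROUPS = 3
DEFAULT_N_FOLDS = 5
DEFAULT_N_BOOT = 1000
DEFAULT_C = 1.0
N_WINDOWS_PER_GROUP = 7


@dataclass
class CandidateGroups:
    """Disjoint candidate feature groups (one unit x its 7 windows each)."""

    group_ids: list
    features: dict            # group_id -> (n_trials, 7) array

    def __post_init__(self) -> None:
        if len(set(self.group_ids)) != len(self.group_ids):
            raise ValueError("candidate group ids must be disjoint")
        widths = {self.features[g].shape[1] for g in self.group_ids}
        if len(widths) > 1:
            raise ValueError(f"groups have unequal widths: {sorted(widths)}")
        # the default window grid gives 7 features per group; the
        # pre-go-cue variant gives 4

    @classmethod
    def from_tensor(cls, tensor: FeatureTensor,
                    unit_subset: "list | None" = None) -> "CandidateGroups":
        units = unit_subset if unit_subset is not None else tensor.unit_ids
        feats = {}
        for u in units:
            ix = tensor.unit_ids.index(u)
            feats[u] = tensor.values[:, ix, :]
        return cls(list(units), feats)

    def stack(self, group_ids: list) -> np.ndarray:
        return np.hstack([self.features[g] for g in group_ids])


@dataclass
class CVResult:
    mean_auc: float
    fold_aucs: np.ndarray
    fold_coefficients: np.ndarray     # (n_folds, n_features), standardized


@dataclass
class SFSResult:
    selected_groups: list
    cv: CVResult
    trace: list = field(default_factory=list)   # (step, group, auc) adopted
    empty_selection: bool = False


@dataclass
class SubjectDecodingResult:
    subject_id: str
    selected_groups: list
    fold_aucs: np.ndarray             # nested outer-fold AUCs
    mean_auc: float                   # nested (leakage-free) estimate
    delta_auc: float                  # mean_auc - 0.5
    bootstrap_ci: tuple               # (lo, hi), 95% percentile
    mean_coefficient: float           # mean over folds and selected features
    per_feature_coefficients: np.ndarray
    above_chance: bool                # CI lower bound > 0.5


def rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic (ties get average ranks)."""
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes in the test fold")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# fold preprocessing (leakage-safe)

def _mad_clean_mask(x: np.ndarray, y: np.ndarray, threshold: float = 3.0,
                    flag_frac: float = 0.5) -> np.ndarray:
    """Keep-mask over training trials: per class, flag cells with
    |x - median| > threshold*MAD per feature column, and drop a trial when
    more than ``flag_frac`` of its columns are flagged.

    The per-trial majority rule targets genuinely artifactual trials
    (extreme across the board) rather than the ~5% per-column tail that
    every trial hits somewhere once tens of columns are stacked.  Columns
    with MAD = 0 are skipped: for continuous features a zero MAD only
    arises from majority-duplicated trials (e.g. bootstrap samples).
    """
    keep = np.ones(len(y), dtype=bool)
    for cls in (0, 1):
        sel = y == cls
        v = x[sel]
        med = np.median(v, axis=0, keepdims=True)
        mad = np.median(np.abs(v - med), axis=0, keepdims=True)
        dev = np.abs(v - med)
        with np.errstate(invalid="ignore"):
            flagged = (mad > 0) & (dev > threshold * mad)
        keep[np.where(sel)[0][flagged.mean(axis=1) > flag_frac]] = False
    return keep


def _fit_fold(x_train: np.ndarray, y_train: np.ndarray, C: float
              ) -> "tuple[LogisticRegression, np.ndarray, np.ndarray] | None":
    """MAD-clean, z-score, and fit L1 logistic on one training fold.

    Returns (model, mu, sd) with z-scoring statistics, or None when the
    cleaning left a single class.
    """
    keep = _mad_clean_mask(x_train, y_train)
    xt, yt = x_train[keep], y_train[keep]
    if len(np.unique(yt)) < 2:
        return None
    mu = xt.mean(axis=0)
    sd = xt.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    # fixed random_state: liblinear's internal shuffling must not leak
    # nondeterminism into otherwise identical fits
    model = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                               max_iter=200, random_state=0)
    model.fit((xt - mu) / sd, yt)
    return model, mu, sd


def cv_auc(features: np.ndarray, y: np.ndarray,
           n_folds: int = DEFAULT_N_FOLDS,
           rng: "np.random.Generator | None" = None,
           C: float = DEFAULT_C, max_redraws: int = 10) -> CVResult:
    """Stratified k-fold CV of L1 logistic regression.

    Within each training fold: per-class 3xMAD trial removal, then
    z-scoring with training statistics applied unchanged to the test
    trials; AUC from test-fold decision scores.  A fold losing a class
    after cleaning triggers a re-draw of the fold split with a fresh seed
    (logged); persistent failure raises.
    """
    rng = rng or np.random.default_rng()
    features = np.asarray(features, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    for attempt in range(max_redraws):
        seed = int(rng.integers(2 ** 31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed)
        aucs, coefs = [], []
        ok = True
        # finiteness already checked above; skip sklearn's re-validation
        with sklearn.config_context(assume_finite=True,
                                    skip_parameter_validation=True):
            for tr, te in skf.split(features, y):
                fit = _fit_fold(features[tr], y[tr], C)
                if fit is None:
                    ok = False
                    break
                model, mu, sd = fit
                scores = model.decision_function((features[te] - mu) / sd)
                aucs.append(rank_auc(y[te], scores))
                coefs.append(model.coef_[0])
        if ok:
            fold_aucs = np.asarray(aucs)
            return CVResult(float(fold_aucs.mean()), fold_aucs,
                            np.asarray(coefs))
        logger.info("fold lost a class after MAD cleaning; re-drawing "
                    "split (attempt %d)", attempt + 1)
    raise RuntimeError("could not form folds with both classes after "
                       f"{max_redraws} re-draws")


# ---------------------------------------------------------------------------
# grouped sequential forward selection

def sfs_grouped(groups: CandidateGroups, y: np.ndarray,
                min_gain: float = DEFAULT_MIN_GAIN,
                max_groups: int = DEFAULT_MAX_GROUPS,
                n_folds: int = DEFAULT_N_FOLDS,
                rng: "np.random.Generator | None" = None,
                C: float = DEFAULT_C) -> SFSResult:
    """Greedy forward selection over candidate groups.

    At each step every remaining candidate is scored by ``cv_auc`` on the
    current selection plus that candidate; the best is adopted iff the
    gain is at least ``min_gain`` (first step: its AUC must beat
    0.5 + min_gain).  Ties break by candidate order.  If no group
    qualifies at the first step the result carries an empty selection and
    the best single rejected model's CV result, flagged.
    """
    if not groups.group_ids:
        raise ValueError("need at least one candidate group")
    rng = rng or np.random.default_rng()
    selected: list = []
    current_auc = 0.5
    current_cv: "CVResult | None" = None
    trace = []
    best_rejected: "tuple[str, CVResult] | None" = None
    while len(selected) < max_groups:
        remaining = [g for g in groups.group_ids if g not in selected]
        if not remaining:
            break
        best = None
        for g in remaining:           # candidate order breaks ties
            cv = cv_auc(groups.stack(selected + [g]), y, n_folds,
                        np.random.default_rng(rng.integers(2 ** 31 - 1)), C)
            if best is None or cv.mean_auc > best[1].mean_auc:
                best = (g, cv)
        g, cv = best
        if cv.mean_auc - current_auc >= min_gain:
            selected.append(g)
            current_auc = cv.mean_auc
            current_cv = cv
            trace.append((len(selected), g, cv.mean_auc))
        else:
            if not selected:
                best_rejected = best
            break
    if not selected:
        logger.info("SFS selected no group (best single AUC %.3f)",
                    best_rejected[1].mean_auc)
        return SFSResult([], best_rejected[1], trace, empty_selection=True)
    return SFSResult(selected, current_cv, trace)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_auc(features: np.ndarray, y: np.ndarray,
                  n_boot: int = DEFAULT_N_BOOT,
                  n_folds: int = DEFAULT_N_FOLDS,
                  rng: "np.random.Generator | None" = None,
                  C: float = DEFAULT_C) -> tuple[float, float, np.ndarray]:
    """95% percentile CI of the mean CV AUC over bootstrap trial samples.

    Resampling is stratified (with replacement within each class,
    preserving class counts) so no sample degenerates to one class; the
    group selection is fixed by the caller and never re-run here.  Folds
    within each bootstrap sample are grouped by original trial index so a
    resampled duplicate never sits in training and test at once (which
    would leak and push the CI optimistically above chance).
    """
    rng = rng or np.random.default_rng()
    y = np.asarray(y)
    features = np.asarray(features, dtype=float)
    n = len(y)
    idx_by_class = [np.where(y == c)[0] for c in (0, 1)]
    boot_aucs = np.empty(n_boot)
    n_degenerate = 0
    with sklearn.config_context(assume_finite=True,
                                skip_parameter_validation=True):
        for b in range(n_boot):
            while True:
                idx = np.concatenate(
                    [rng.choice(ix, size=len(ix), replace=True)
                     for ix in idx_by_class])
                # stratified fold label per ORIGINAL trial, inherited by
                # its bootstrap copies: duplicates never straddle folds
                fold_of = np.empty(n, dtype=int)
                for ix in idx_by_class:
                    perm = rng.permutation(ix)
                    fold_of[perm] = np.arange(len(ix)) % n_folds
                folds = fold_of[idx]
                fold_aucs = []
                for k in range(n_folds):
                    te = folds == k
                    yb_tr, yb_te = y[idx[~te]], y[idx[te]]
                    if (len(np.unique(yb_tr)) < 2
                            or len(np.unique(yb_te)) < 2):
                        continue
                    fit = _fit_fold(features[idx[~te]], yb_tr, C)
                    if fit is None:
                        continue
                    model, mu, sd = fit
                    scores = model.decision_function(
                        (features[idx[te]] - mu) / sd)
                    fold_aucs.append(rank_auc(yb_te, scores))
                if fold_aucs:
                    boot_aucs[b] = float(np.mean(fold_aucs))
                    break
                n_degenerate += 1          # redraw the bootstrap sample
    if n_degenerate:
        logger.info("redrew %d degenerate bootstrap samples", n_degenerate)
    lo, hi = np.percentile(boot_aucs, [2.5, 97.5])
    return float(lo), float(hi), boot_aucs


# ---------------------------------------------------------------------------
# subject-level entry point

def _encode(labels: np.ndarray, positive_class: str) -> np.ndarray:
    return np.asarray([1 if l == positive_class else 0 for l in labels])


def decode_subject(tensor: FeatureTensor, candidates: "list | None" = None,
                   min_gain: float = DEFAULT_MIN_GAIN,
                   max_groups: int = DEFAULT_MAX_GROUPS,
                   n_folds: int = DEFAULT_N_FOLDS,
                   n_boot: int = DEFAULT_N_BOOT,
                   rng: "np.random.Generator | None" = None,
                   C: float = DEFAULT_C,
                   positive_class: str = "Fast") -> SubjectDecodingResult:
    """Full per-subject protocol: nested-CV AUC, full-data SFS selection,
    fold-averaged standardized coefficients, bootstrap CI.

    Trials with any non-finite feature are dropped up front (logged).
    """
    rng = rng or np.random.default_rng()
    groups = CandidateGroups.from_tensor(tensor, candidates)
    all_x = groups.stack(groups.group_ids)
    finite = np.isfinite(all_x).all(axis=1)
    if not finite.all():
        logger.info("%s: dropping %d trials with non-finite features",
                    tensor.subject_id, int((~finite).sum()))
        groups = CandidateGroups(
            groups.group_ids,
            {g: x[finite] for g, x in groups.features.items()})
    y = _encode(tensor.labels[finite], positive_class)

    # nested outer CV: SFS inside each outer-train, score on outer-test
    outer_seed = int(rng.integers(2 ** 31 - 1))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=outer_seed)
    x_index = np.arange(len(y))
    outer_aucs = []
    for tr, te in skf.split(x_index, y):
        sub = CandidateGroups(
            groups.group_ids,
            {g: x[tr] for g, x in groups.features.items()})
        sfs = sfs_grouped(sub, y[tr], min_gain, max_groups, n_folds,
                          np.random.default_rng(rng.integers(2 ** 31 - 1)), C)
        chosen = sfs.selected_groups or _best_single(sfs, sub, y[tr],
                                                     n_folds, rng, C)
        fit = _fit_fold(groups.stack(chosen)[tr], y[tr], C)
        if fit is None:
            continue
        model, mu, sd = fit
        scores = model.decision_function((groups.stack(chosen)[te] - mu) / sd)
        outer_aucs.append(rank_auc(y[te], scores))
    fold_aucs = np.asarray(outer_aucs)
    mean_auc = float(fold_aucs.mean())

    # reported selection + coefficients: SFS on the full data
    sfs_full = sfs_grouped(groups, y, min_gain, max_groups, n_folds,
                           np.random.default_rng(rng.integers(2 ** 31 - 1)),
                           C)
    selected = sfs_full.selected_groups
    if selected:
        sel_x = groups.stack(selected)
    else:
        selected_for_ci = _best_single(sfs_full, groups, y, n_folds, rng, C)
        sel_x = groups.stack(selected_for_ci)
    coefs = sfs_full.cv.fold_coefficients
    per_feature = coefs.mean(axis=0)
    mean_coefficient = float(per_feature.mean())

    if n_boot > 0:
        lo, hi, _ = bootstrap_auc(
            sel_x, y, n_boot, n_folds,
            np.random.default_rng(rng.integers(2 ** 31 - 1)), C)
    else:
        lo = hi = float("nan")
    return SubjectDecodingResult(
        subject_id=tensor.subject_id,
        selected_groups=list(selected),
        fold_aucs=fold_aucs,
        mean_auc=mean_auc,
        delta_auc=mean_auc - 0.5,
        bootstrap_ci=(lo, hi),
        mean_coefficient=mean_coefficient,
        per_feature_coefficients=per_feature,
        above_chance=bool(lo > 0.5),
    )


def _best_single(sfs: SFSResult, groups: CandidateGroups, y: np.ndarray,
                 n_folds: int, rng: np.random.Generator, C: float) -> list:
    """Fallback group when SFS selected nothing: the single candidate with
    the best CV AUC."""
    best, best_auc = None, -1.0
    for g in groups.group_ids:
        cv = cv_auc(groups.features[g], y, n_folds,
                    np.random.default_rng(rng.integers(2 ** 31 - 1)), C)
        if cv.mean_auc > best_auc:
            best, best_auc = g, cv.mean_auc
    return [best]


def selection_frequencies(results: list, candidates: list,
                          above_chance_only: bool = True) -> dict:
    """How often each candidate group was selected across subjects
    (restricted to above-chance subjects by default)."""
    counts = {g: 0 for g in candidates}
    for res in results:
        if above_chance_only and not res.above_chance:
            continue
        for g in res.selected_groups:
            if g in counts:
                counts[g] += 1
    return counts
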