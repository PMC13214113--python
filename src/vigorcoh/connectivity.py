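"""Symmetric orthogonalization and seed-based per-trial imaginary coherence.

Zero-lag mixing (volume conduction / source leakage) produces spurious
instantaneous correlation between parcel time courses.  Symmetric
orthogonalization finds the set of mutually orthogonal (zero-lag
uncorrelated) time courses closest to the originals in total squared
change — the order-independent "closest orthogonal matrix" solution with
per-parcel magnitudes refit, iterated to tolerance.

Imaginary coherence (iCoh) is the magnitude of the imaginary part of the
normalized cross-spectrum; purely zero-lag (real) coupling contributes
nothing to it, so the combination is insensitive to residual leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import FeatureTensor, ParcelTimeCourses
from .windows import WindowGrid

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 50
MIN_WINDOW_SAMPLES = 16


class RankError(ValueError):
    """Parcel matrix is rank deficient (e.g. duplicated parcels)."""


@dataclass
class OrthogonalizationReport:
    max_abs_pairwise_zero_lag_correlation: float
    frobenius_change: float        # ||orthogonalized - original|| / ||original||
    iterations: int
    converged: bool


def closest_orthogonal_matrix(x: np.ndarray, tol: float = DEFAULT_TOL,
                              max_iter: int = DEFAULT_MAX_ITER
                              ) -> tuple[np.ndarray, int, bool]:
    """Closest matrix with mutually orthogonal columns to ``x``
    (samples x parcels), minimizing ||x - o||_F.

    Alternates the polar/Procrustes solution for an orthonormal basis with
    a diagonal magnitude refit: o = p*d with p on the Stiefel manifold and
    d diagonal, iterated until the relative change falls below ``tol``.
    """
    n_samples, n_parcels = x.shape
    if n_samples < n_parcels:
        raise ValueError("need at least as many samples as parcels")
    d = np.ones(n_parcels)
    o_prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(x * d[None, :], full_matrices=False)
        if s[-1] <= s[0] * 1e-10:
            raise RankError(_rank_message(x))
        p = u @ vt
        d = np.einsum("sp,sp->p", p, x)            # diag(p.T @ x)
        o = p * d[None, :]
        if o_prev is not None:
            delta = np.linalg.norm(o - o_prev) / max(np.linalg.norm(o), 1e-30)
            if delta < tol:
                converged = True
                break
        o_prev = o
    return o, it, converged


def _rank_message(x: np.ndarray) -> str:
    # identify the offending (near-duplicate) parcel pairs for the error
    xc = x - x.mean(axis=0, keepdims=True)
    sd = xc.std(axis=0)
    sd[sd == 0] = 1.0
    c = (xc / sd).T @ (xc / sd) / x.shape[0]
    np.fill_diagonal(c, 0.0)
    pairs = np.argwhere(np.abs(c) > 1 - 1e-8)
    pairs = sorted({tuple(sorted(p)) for p in pairs})
    if pairs:
        return (f"rank-deficient parcel matrix; near-duplicate parcel "
                f"index pairs: {pairs}")
    return "rank-deficient parcel matrix"


def symmetric_orthogonalize(parcels: ParcelTimeCourses,
                            tol: float = DEFAULT_TOL,
                            max_iter: int = DEFAULT_MAX_ITER
                            ) -> tuple[ParcelTimeCourses,
                                       OrthogonalizationReport]:
    """Orthogonalize each trial's parcel courses (real-valued, pre-Hilbert).

    Fits are per trial (parcels x samples transposed to samples x parcels).
    The report aggregates the worst residual zero-lag correlation, the mean
    relative change, and the worst-case iteration count.
    """
    if parcels.is_analytic:
        raise ValueError("orthogonalize the real courses before Hilbert")
    data = parcels.data
    n_trials, n_parcels, n_samples = data.shape
    if n_parcels > n_samples:
        raise ValueError("more parcels than samples per trial")
    out = np.empty_like(data)
    max_corr = 0.0
    total_change = 0.0
    worst_iter = 0
    all_converged = True
    for t in range(n_trials):
        x = data[t].T
        try:
            o, it, conv = closest_orthogonal_matrix(x, tol, max_iter)
        except RankError as err:
            raise RankError(f"trial {t}: {err}") from None
        out[t] = o.T
        worst_iter = max(worst_iter, it)
        all_converged &= conv
        total_change += (np.linalg.norm(o - x) /
                         max(np.linalg.norm(x), 1e-30))
        max_corr = max(max_corr, _max_abs_offdiag_corr(o))
    report = OrthogonalizationReport(
        max_abs_pairwise_zero_lag_correlation=max_corr,
        frobenius_change=total_change / n_trials,
        iterations=worst_iter,
        converged=all_converged,
    )
    return replace(parcels, data=out), report


def _max_abs_offdiag_corr(o: np.ndarray) -> float:
    g = o.T @ o
    norms = np.sqrt(np.diag(g))
    norms[norms == 0] = 1.0
    c = g / np.outer(norms, norms)
    np.fill_diagonal(c, 0.0)
    return float(np.abs(c).max())


def gram_schmidt(x: np.ndarray) -> np.ndarray:
    """Sequential (order-dependent) orthogonalization of columns; the
    comparison baseline for the symmetric solution's optimality."""
    o = x.astype(float).copy()
    for j in range(1, x.shape[1]):
        for k in range(j):
            denom = o[:, k] @ o[:, k]
            if denom > 0:
                o[:, j] -= (o[:, j] @ o[:, k]) / denom * o[:, k]
    return o


# ---------------------------------------------------------------------------
# imaginary coherence

def compute_icoh(seed_analytic: np.ndarray, other_analytic: np.ndarray,
                 grid: "WindowGrid | None" = None, fs: float = 128.0,
                 t0: float = -1.5) -> np.ndarray:
    """Per-trial, per-window iCoh between two analytic signals.

    For each window, with sample averages over the window,
    Sxy = <x conj(y)>, Sxx = <|x|^2>, Syy = <|y|^2>:
    iCoh = |Im(Sxy / sqrt(Sxx*Syy))|, in [0, 1] by construction.
    Zero-power windows yield NaN (flagged, excluded downstream).

    ``seed_analytic``/``other_analytic`` are (trials, samples) complex
    arrays (a single trial may be passed as 1-D).
    """
    x = np.atleast_2d(np.asarray(seed_analytic))
    y = np.atleast_2d(np.asarray(other_analytic))
    if not (np.iscomplexobj(x) and np.iscomplexobj(y)):
        raise ValueError("inputs must be analytic (complex) signals")
    if x.shape != y.shape:
        raise ValueError("seed and other signals must have equal shapes")
    grid = grid or WindowGrid()
    slices = grid.slices(fs, t0, x.shape[-1])
    out = np.empty((x.shape[0], len(slices)))
    for w, s in enumerate(slices):
        if s.stop - s.start < MIN_WINDOW_SAMPLES:
            raise ValueError(
                f"window {w} has {s.stop - s.start} samples "
                f"(< {MIN_WINDOW_SAMPLES})")
        xs, ys = x[:, s], y[:, s]
        sxy = (xs * np.conj(ys)).mean(axis=-1)
        sxx = (np.abs(xs) ** 2).mean(axis=-1)
        syy = (np.abs(ys) ** 2).mean(axis=-1)
        denom = np.sqrt(sxx * syy)
        # |Im| taken before the (real) normalization: makes the estimator
        # exactly symmetric under argument swap in floating point
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.abs(np.imag(sxy)) / denom
        val[denom == 0] = np.nan
        out[:, w] = val
    return out


def seed_icoh_tensor(parcels: ParcelTimeCourses,
                     grid: "WindowGrid | None" = None) -> FeatureTensor:
    """iCoh between the seed and every other parcel:
    trials x (n_parcels - 1) x 7 windows."""
    if not parcels.is_analytic:
        raise ValueError("seed_icoh_tensor requires analytic courses")
    grid = grid or WindowGrid()
    seed_ix = parcels.seed_index
    seed = parcels.data[:, seed_ix, :]
    others = [j for j in range(len(parcels.parcel_names)) if j != seed_ix]
    values = np.stack(
        [compute_icoh(seed, parcels.data[:, j, :], grid,
                      fs=parcels.fs, t0=parcels.t0) for j in others],
        axis=1)
    unit_ids = [parcels.parcel_names[j] for j in others]
    return FeatureTensor(values, unit_ids, "icoh", parcels.band,
                         parcels.labels, "source",
                         window_labels=grid.labels(),
                         subject_id=parcels.subject_id)
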