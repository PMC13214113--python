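"""Group-level spatial statistics: MAD trial screening, cluster-based
spatial permutation tests, parcel ranking, and sign-proportion permutation
tests.

The cluster test follows the standard paired scheme: per-unit paired t
across subjects, supra-threshold units clustered by adjacency and sign,
cluster mass = summed t, and a max-mass null built from random
within-subject condition swaps (sign flips of the paired differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .containers import FeatureTensor

DEFAULT_ADJ_RADIUS = 0.02


# ---------------------------------------------------------------------------
# trial screening

def screen_trials(tensor: FeatureTensor, threshold: float = 3.0,
                  mode: str = "cell") -> tuple[FeatureTensor, float]:
    """Flag extreme trials per (unit, window) cell with the |x-median| >
    threshold*MAD rule, per condition; flagged values become NaN.

    ``mode="cell"`` (default) masks a trial only in the cells where it is
    extreme; ``mode="trial"`` drops a trial everywhere once any cell flags
    it.  Returns the masked tensor and the flagged fraction.  Retained
    values are never altered.  Cells where more than half the trials would
    be flagged are kept with a warning.
    """
    values = tensor.values.copy()
    flagged = np.zeros(values.shape, dtype=bool)
    for cond in ("Fast", "Slow"):
        sel = tensor.condition_mask(cond)
        if not sel.any():
            continue
        v = values[sel]                          # (n, units, windows)
        med = np.nanmedian(v, axis=0, keepdims=True)
        mad = np.nanmedian(np.abs(v - med), axis=0, keepdims=True)
        dev = np.abs(v - med)
        with np.errstate(invalid="ignore"):
            mask = np.where(mad > 0, dev > threshold * mad, dev > 0)
        mask &= np.isfinite(v)
        frac_cell = mask.mean(axis=0)
        if (frac_cell > 0.5).any():
            n_bad = int((frac_cell > 0.5).sum())
            warnings.warn(
                f"{n_bad} unit-window cells would lose >50% of trials; "
                "cells retained", RuntimeWarning, stacklevel=2)
            mask[:, frac_cell > 0.5] = False
        flagged[sel] = mask
    if mode == "trial":
        bad_trials = flagged.any(axis=(1, 2))
        flagged[:] = False
        flagged[bad_trials] = True
    elif mode != "cell":
        raise ValueError(f"unknown screening mode {mode!r}")
    values[flagged] = np.nan
    return tensor.with_values(values), float(flagged.mean())


# ---------------------------------------------------------------------------
# adjacency

@dataclass
class AdjacencyGraph:
    n_units: int
    edges: list                       # list of (i, j) with i < j
    neighbors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        nb = [set() for _ in range(self.n_units)]
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            nb[i].add(j)
            nb[j].add(i)
        self.neighbors = [sorted(s) for s in nb]


def build_adjacency(positions: np.ndarray,
                    radius: float = DEFAULT_ADJ_RADIUS) -> AdjacencyGraph:
    """Edges between units closer than ``radius`` (2-D Euclidean)."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be (n_units, 2)")
    n = len(positions)
    if n > 1:
        d = squareform(pdist(positions))
        if (d[np.triu_indices(n, 1)] == 0).any():
            warnings.warn("duplicate unit positions (distance-0 edges "
                          "allowed between distinct units)",
                          RuntimeWarning, stacklevel=2)
        ii, jj = np.where(np.triu(d < radius, k=1))
        edges = list(zip(ii.tolist(), jj.tolist()))
    else:
        edges = []
    return AdjacencyGraph(n, edges)


# ---------------------------------------------------------------------------
# paired cluster permutation test

@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    clusters: list                    # lists of unit indices
    cluster_masses: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    threshold_t: float


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t per unit from subject x unit differences (vectorized over
    any leading axes)."""
    n = diffs.shape[-2]
    mean = diffs.mean(axis=-2)
    sd = diffs.std(axis=-2, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def _connected_components(units: np.ndarray, graph: AdjacencyGraph
                          ) -> list:
    """Connected components of the sub-graph induced by ``units``."""
    in_set = set(units.tolist())
    seen: set = set()
    comps = []
    for u in units.tolist():
        if u in seen:
            continue
        comp = []
        stack = [u]
        seen.add(u)
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in graph.neighbors[v]:
                if w in in_set and w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def _clusters_and_masses(t_map: np.ndarray, t_crit: float,
                         graph: AdjacencyGraph) -> tuple[list, np.ndarray]:
    clusters = []
    for sign in (+1, -1):
        supra = np.where(sign * t_map > t_crit)[0]
        if supra.size:
            clusters.extend(_connected_components(supra, graph))
    masses = np.array([t_map[c].sum() for c in clusters]) if clusters \
        else np.empty(0)
    return clusters, masses


def paired_cluster_permutation(cond_a: np.ndarray, cond_b: np.ndarray,
                               graph: AdjacencyGraph, alpha: float = 0.05,
                               n_perm: int = 1000,
                               rng: "np.random.Generator | None" = None
                               ) -> ClusterTestResult:
    """Paired cluster-based spatial permutation test.

    ``cond_a``/``cond_b`` are subject x unit mean matrices.  Per-unit
    paired t; |t| > two-sided critical t at ``alpha`` (df = n-1) defines
    supra-threshold units, clustered by graph connectivity and sign; the
    null distribution is the max |cluster mass| under random per-subject
    sign flips; p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    rng = rng or np.random.default_rng()
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("cond_a/cond_b must be equal-shape subject x unit")
    n_sub, n_units = a.shape
    if n_sub < 5:
        raise ValueError("need >= 5 paired subjects")
    if n_units != graph.n_units:
        raise ValueError("unit count does not match adjacency graph")
    diffs = a - b
    t_crit = float(stats.t.ppf(1 - alpha / 2, df=n_sub - 1))
    t_map = _paired_t(diffs)
    clusters, masses = _clusters_and_masses(t_map, t_crit, graph)
    if not clusters:
        return ClusterTestResult(t_map, [], np.empty(0), np.empty(0),
                                 n_perm, t_crit)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    t_null = _paired_t(flips[:, :, None] * diffs[None, :, :])
    null_max = np.zeros(n_perm)
    for k in range(n_perm):
        _, m = _clusters_and_masses(t_null[k], t_crit, graph)
        if m.size:
            null_max[k] = np.abs(m).max()
    p = np.array([(1.0 + (null_max >= abs(m)).sum()) / (1.0 + n_perm)
                  for m in masses])
    return ClusterTestResult(t_map, clusters, masses, p, n_perm, t_crit)


# ---------------------------------------------------------------------------
# parcel ranking and sign-proportion test

def rank_parcels_by_t(t_matrix: np.ndarray, parcel_names: list,
                      k: int = 5) -> list:
    """Top-k parcels by |mean-over-windows t|, with signed means.

    ``t_matrix`` is parcels x windows.  Ties broken lexicographically by
    parcel name.
    """
    t_matrix = np.asarray(t_matrix, dtype=float)
    mean_t = t_matrix.mean(axis=1)
    order = sorted(range(len(parcel_names)),
                   key=lambda i: (-abs(mean_t[i]), parcel_names[i]))
    return [(parcel_names[i], float(mean_t[i])) for i in order[:k]]


@dataclass
class SignProportionResult:
    proportion_negative: float
    z: float
    p: float
    n_permutations: int


def sign_proportion_permutation(subject_diffs: np.ndarray,
                                n_perm: int = 1000,
                                rng: "np.random.Generator | None" = None,
                                alternative: str = "greater"
                                ) -> SignProportionResult:
    """Does the proportion of parcels with a negative across-subject mean
    Fast-Slow difference exceed chance?

    ``subject_diffs`` is subject x parcel (Fast-Slow, over the stated
    parcel subset).  The null flips each subject's whole difference map
    (condition-assignment swap); z = (observed - null mean)/null sd; the
    one-sided p is for the proportion-negative exceeding chance
    (``alternative="greater"``, the "Fast < Slow" direction).
    """
    rng = rng or np.random.default_rng()
    d = np.atleast_2d(np.asarray(subject_diffs, dtype=float))
    n_sub = d.shape[0]
    if n_perm < 200:
        warnings.warn(f"n_perm={n_perm} < 200: coarse null",
                      RuntimeWarning, stacklevel=2)
    if n_sub < 2:
        warnings.warn("single-subject input: the sign-flip null is "
                      "degenerate (2 distinct values)",
                      RuntimeWarning, stacklevel=2)
    observed = float((d.mean(axis=0) < 0).mean())
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null = ((flips[:, :, None] * d[None, :, :]).mean(axis=1) < 0).mean(axis=1)
    sd = null.std()
    z = (observed - null.mean()) / sd if sd > 0 else 0.0
    if alternative == "greater":
        p = (1.0 + (null >= observed).sum()) / (1.0 + n_perm)
    else:
        p = (1.0 + (null <= observed).sum()) / (1.0 + n_perm)
    return SignProportionResult(observed, float(z), float(p), n_perm)
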