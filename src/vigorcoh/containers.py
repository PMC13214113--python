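"""In-memory containers for the pipeline's intermediate data.

Arrays are plain numpy; metadata rides along in dataclass fields.  Trial
condition labels are the strings "Fast" / "Slow" everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import Band

CONDITIONS = ("Fast", "Slow")


def _check_labels(labels: np.ndarray, n_trials: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    if labels.shape != (n_trials,):
        raise ValueError(f"labels shape {labels.shape} != ({n_trials},)")
    bad = set(labels) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(map(str, bad))}")
    return labels


@dataclass
class EpochSet:
    """Sensor-space epochs: trials x channels x samples.

    ``t0`` is the event-relative time of the first sample; the time axis is
    strictly increasing at 1/fs.
    """

    data: np.ndarray
    fs: float
    t0: float
    labels: np.ndarray
    channel_ids: list[str]
    positions: np.ndarray      # (channels, 2) montage coordinates
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be trials x channels x samples")
        n_tr, n_ch, _ = self.data.shape
        self.labels = _check_labels(self.labels, n_tr)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (n_ch, 2):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n_ch}, 2)")
        if len(self.channel_ids) != n_ch:
            raise ValueError("channel_ids length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.fs


@dataclass
class ParcelTimeCourses:
    """Parcel-level time courses: trials x parcels x samples.

    Real-valued before the Hilbert transform, complex (analytic) after.
    """

    data: np.ndarray
    fs: float
    t0: float
    parcel_names: list[str]
    seed_name: str
    band: Band
    labels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                "ParcelTimeCourses.data must be trials x parcels x samples")
        n_tr, n_p, _ = self.data.shape
        self.labels = _check_labels(self.labels, n_tr)
        if len(self.parcel_names) != n_p:
            raise ValueError("parcel_names length mismatch")
        if self.seed_name not in self.parcel_names:
            raise ValueError(
                f"seed {self.seed_name!r} not among parcel_names")

    @property
    def is_analytic(self) -> bool:
        return np.iscomplexobj(self.data)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def seed_index(self) -> int:
        return self.parcel_names.index(self.seed_name)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.fs


@dataclass
class FeatureTensor:
    """trials x spatial-units x windows features (power or iCoh).

    The decoding/statistics currency.  NaN marks values masked by trial
    screening or flagged as undefined (e.g. zero-power windows).
    """

    values: np.ndarray
    unit_ids: list[str]
    metric: str                 # "power" | "icoh"
    band: Band
    labels: np.ndarray
    space: str                  # "sensor" | "source"
    window_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("FeatureTensor.values must be trials x units x windows")
        n_tr, n_u, n_w = self.values.shape
        self.labels = _check_labels(self.labels, n_tr)
        if len(self.unit_ids) != n_u:
            raise ValueError("unit_ids length mismatch")
        if self.metric not in ("power", "icoh"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric == "icoh":
            v = self.values[np.isfinite(self.values)]
            if v.size and (v.min() < 0 or v.max() > 1 + 1e-12):
                raise ValueError("iCoh values must lie in [0, 1]")
        # power is not range-checked here: dB-corrected power is negative
        # below baseline, so only raw-power producers can assert >= 0
        if not self.window_labels:
            self.window_labels = [f"w{i}" for i in range(n_w)]

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.asarray([l == condition for l in self.labels])

    def flat_features(self, unit_subset: "list[str] | None" = None) -> tuple[np.ndarray, list[tuple[str, str]]]:
        """Flatten to (trials, units*windows) with (unit, window) names.

        Feature columns are grouped unit-major so that the 7 windows of one
        unit form one contiguous candidate group.
        """
        if unit_subset is None:
            idx = np.arange(len(self.unit_ids))
            units = self.unit_ids
        else:
            missing = [u for u in unit_subset if u not in self.unit_ids]
            if missing:
                raise KeyError(f"units not in tensor: {missing}")
            idx = np.asarray([self.unit_ids.index(u) for u in unit_subset])
            units = list(unit_subset)
        x = self.values[:, idx, :].reshape(self.n_trials, -1)
        names = [(u, w) for u in units for w in self.window_labels]
        return x, names

    def with_values(self, values: np.ndarray) -> "FeatureTensor":
        return replace(self, values=values)


@dataclass
class KinematicTraces:
    """Per-trial behavioral traces from the light sensor and accelerometer.

    ``lux`` and ``acc`` are (trials, samples) arrays at ``fs_behav`` Hz;
    ``go_cue_index`` gives the go-cue sample per trial.
    """

    lux: np.ndarray
    acc: np.ndarray
    fs_behav: float
    go_cue_index: np.ndarray
    labels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.lux = np.asarray(self.lux, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.lux.ndim != 2 or self.acc.ndim != 2:
            raise ValueError("lux/acc must be trials x samples")
        if self.lux.shape[0] != self.acc.shape[0]:
            raise ValueError("lux and acc trial counts differ")
        n_tr = self.lux.shape[0]
        self.go_cue_index = np.asarray(self.go_cue_index, dtype=int)
        if self.go_cue_index.shape != (n_tr,):
            raise ValueError("go_cue_index must have one entry per trial")
        if ((self.go_cue_index < 0)
                | (self.go_cue_index >= self.lux.shape[1])).any():
            raise ValueError("go_cue_index out of bounds")
        self.labels = _check_labels(self.labels, n_tr)

    @property
    def n_trials(self) -> int:
        return self.lux.shape[0]
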