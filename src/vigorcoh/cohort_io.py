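"""Lossless cohort serialization: per-subject HDF5 + JSON manifest + YAML
config echo.

Layout of a cohort directory::

    manifest.json          files, array shapes, container version, config hash
    config.yaml            echo of the SimulationConfig
    truth.csv              per-subject planted quantities
    mixing.npy-like        stored inside manifest-listed HDF5 (cohort.h5)
    sub-01.h5 ...          epochs / parcels_<band> / kinematics groups
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .bands import get_band
from .containers import EpochSet, KinematicTraces, ParcelTimeCourses
from .synth import Cohort, SimulationConfig, SubjectData

CONTAINER_VERSION = 1


class CohortIOError(RuntimeError):
    """Base class for cohort (de)serialization failures."""


class MissingSidecarError(CohortIOError):
    """manifest.json (or a file it lists) is absent."""


class ShapeMismatchError(CohortIOError):
    """An array's stored shape disagrees with the manifest sidecar."""


class UnknownVersionError(CohortIOError):
    """The container version is not one this reader understands."""


def config_hash(config: SimulationConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_labels(grp: h5py.Group, name: str, labels: np.ndarray) -> None:
    grp.create_dataset(name, data=np.asarray(
        [str(l) for l in labels], dtype=h5py.string_dtype()))


def _read_labels(grp: h5py.Group, name: str) -> np.ndarray:
    return np.asarray([s.decode() if isinstance(s, bytes) else s
                       for s in grp[name][()]], dtype=object)


def write_cohort(cohort: Cohort, directory: "str | Path") -> dict:
    """Serialize a cohort; returns the manifest dict."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "container_version": CONTAINER_VERSION,
        "config_hash": config_hash(cohort.config),
        "n_subjects": cohort.n_subjects,
        "files": {},
        "shapes": {},
    }
    (directory / "config.yaml").write_text(
        yaml.safe_dump(cohort.config.to_dict(), sort_keys=True))
    cohort.truth.to_csv(directory / "truth.csv", index=False)
    with h5py.File(directory / "cohort.h5", "w") as f:
        f.create_dataset("mixing", data=cohort.mixing)
    manifest["files"]["cohort"] = "cohort.h5"
    manifest["shapes"]["mixing"] = list(cohort.mixing.shape)

    for sub in cohort.subjects:
        fname = f"{sub.subject_id}.h5"
        with h5py.File(directory / fname, "w") as f:
            ep = f.create_group("epochs")
            ep.create_dataset("data", data=sub.epochs.data)
            ep.attrs["fs"] = sub.epochs.fs
            ep.attrs["t0"] = sub.epochs.t0
            _write_labels(ep, "labels", sub.epochs.labels)
            _write_labels(ep, "channel_ids",
                          np.asarray(sub.epochs.channel_ids, dtype=object))
            ep.create_dataset("positions", data=sub.epochs.positions)
            for band_name, ptc in sub.parcels.items():
                g = f.create_group(f"parcels_{band_name}")
                g.create_dataset("data", data=ptc.data)
                g.attrs["fs"] = ptc.fs
                g.attrs["t0"] = ptc.t0
                g.attrs["seed_name"] = ptc.seed_name
                g.attrs["band"] = band_name
                _write_labels(g, "parcel_names",
                              np.asarray(ptc.parcel_names, dtype=object))
                _write_labels(g, "labels", ptc.labels)
            kin = f.create_group("kinematics")
            kin.create_dataset("lux", data=sub.kinematics.lux)
            kin.create_dataset("acc", data=sub.kinematics.acc)
            kin.attrs["fs_behav"] = sub.kinematics.fs_behav
            kin.create_dataset("go_cue_index", data=sub.kinematics.go_cue_index)
            _write_labels(kin, "labels", sub.kinematics.labels)
        manifest["files"][sub.subject_id] = fname
        manifest["shapes"][f"{sub.subject_id}/epochs"] = list(
            sub.epochs.data.shape)
        for band_name, ptc in sub.parcels.items():
            manifest["shapes"][f"{sub.subject_id}/parcels_{band_name}"] = \
                list(ptc.data.shape)
        manifest["shapes"][f"{sub.subject_id}/kinematics"] = list(
            sub.kinematics.lux.shape)

    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cohort(directory: "str | Path") -> Cohort:
    """Read back a cohort written by :func:`write_cohort`.

    Raises :class:`MissingSidecarError`, :class:`ShapeMismatchError` or
    :class:`UnknownVersionError` on the corresponding defects.
    """
    directory = Path(directory)
    man_path = directory / "manifest.json"
    if not man_path.exists():
        raise MissingSidecarError(f"no manifest.json in {directory}")
    manifest = json.loads(man_path.read_text())
    version = manifest.get("container_version")
    if version != CONTAINER_VERSION:
        raise UnknownVersionError(
            f"container version {version!r} not supported "
            f"(expected {CONTAINER_VERSION})")
    cfg_path = directory / "config.yaml"
    if not cfg_path.exists():
        raise MissingSidecarError(f"no config.yaml in {directory}")
    cfg_dict = yaml.safe_load(cfg_path.read_text())
    for key in ("epoch_span", "bands", "parcel_names", "coupled_parcels"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    config = SimulationConfig(**cfg_dict)
    truth = pd.read_csv(directory / "truth.csv")

    with h5py.File(directory / manifest["files"]["cohort"], "r") as f:
        mixing = f["mixing"][()]
    _check_shape(manifest, "mixing", mixing.shape)

    subjects = []
    for sid in truth["subject_id"]:
        fname = manifest["files"].get(sid)
        if fname is None or not (directory / fname).exists():
            raise MissingSidecarError(f"subject file for {sid} missing")
        with h5py.File(directory / fname, "r") as f:
            ep = f["epochs"]
            data = ep["data"][()]
            _check_shape(manifest, f"{sid}/epochs", data.shape)
            epochs = EpochSet(
                data, float(ep.attrs["fs"]), float(ep.attrs["t0"]),
                _read_labels(ep, "labels"),
                list(_read_labels(ep, "channel_ids")),
                ep["positions"][()], subject_id=sid)
            parcels = {}
            for key in f:
                if not key.startswith("parcels_"):
                    continue
                g = f[key]
                band_name = g.attrs["band"]
                pdata = g["data"][()]
                _check_shape(manifest, f"{sid}/{key}", pdata.shape)
                parcels[band_name] = ParcelTimeCourses(
                    pdata, float(g.attrs["fs"]), float(g.attrs["t0"]),
                    list(_read_labels(g, "parcel_names")),
                    str(g.attrs["seed_name"]), get_band(str(band_name)),
                    _read_labels(g, "labels"), subject_id=sid)
            kin = f["kinematics"]
            lux = kin["lux"][()]
            _check_shape(manifest, f"{sid}/kinematics", lux.shape)
            kinematics = KinematicTraces(
                lux, kin["acc"][()], float(kin.attrs["fs_behav"]),
                kin["go_cue_index"][()], _read_labels(kin, "labels"),
                subject_id=sid)
        subjects.append(SubjectData(sid, epochs, parcels, kinematics))
    return Cohort(config, subjects, truth, mixing)


def _check_shape(manifest: dict, key: str, shape: tuple) -> None:
    expected = manifest["shapes"].get(key)
    if expected is None or tuple(expected) != tuple(shape):
        raise ShapeMismatchError(
            f"{key}: stored shape {tuple(shape)} does not match sidecar "
            f"entry {expected}")
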