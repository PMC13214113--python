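"""End-to-end orchestration: behavior -> features -> group statistics ->
decoding -> inference, with YAML configuration, JSON-lines logging and a
reproducible report bundle.

Stage interfaces are the serialized tables/tensors only; every stochastic
stage is seeded from the master seed, so one seed reproduces the whole
report byte-for-byte (timestamps live only in the run log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, decoding, group_stats, inference, kinematics, spectral
from .bands import get_band
from .cohort_io import read_cohort
from .containers import FeatureTensor
from .presets import CANDIDATE_PRESETS, resolve_candidates
from .synth import Cohort
from .windows import WindowGrid


class ConfigError(ValueError):
    """Invalid run configuration (detected before any compute)."""


@dataclass
class RunConfig:
    cohort_dir: str = "cohort"
    out_dir: str = "out"
    band: str = "standard"
    power_space: str = "source"          # "source" | "sensor"
    candidate_set: str = "fronto-parietal-21"
    window_subset: str = "all"           # "all" | "pre-go-cue"
    min_gain: float = decoding.DEFAULT_MIN_GAIN
    max_groups: int = decoding.DEFAULT_MAX_GROUPS
    n_folds: int = decoding.DEFAULT_N_FOLDS
    n_boot: int = decoding.DEFAULT_N_BOOT
    alpha: float = 0.05
    n_perm: int = 1000
    adjacency_radius: float = group_stats.DEFAULT_ADJ_RADIUS
    screening_mode: str = "cell"
    positive_class: str = "Fast"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.candidate_set not in CANDIDATE_PRESETS:
            raise ConfigError(
                f"unknown candidate preset {self.candidate_set!r}; "
                f"known: {sorted(CANDIDATE_PRESETS)}")
        if self.window_subset not in ("all", "pre-go-cue"):
            raise ConfigError(
                f"window_subset must be 'all' or 'pre-go-cue', "
                f"got {self.window_subset!r}")
        if self.power_space not in ("source", "sensor"):
            raise ConfigError("power_space must be 'source' or 'sensor'")
        get_band(self.band)   # raises on unknown band

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class RunLog:
    """JSON-lines stage log (stage, seed, duration, decision flags)."""

    def __init__(self, path: "Path | None") -> None:
        self.path = path
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text("")

    def record(self, **fields) -> None:
        fields.setdefault("time", time.time())
        if self.path is not None:
            with self.path.open("a") as f:
                f.write(json.dumps(fields, default=str) + "\n")


# ---------------------------------------------------------------------------
# feature extraction

def subject_features(subject, band, grid: WindowGrid,
                     power_space: str = "source") -> dict:
    """Per-subject feature tensors: seed iCoh and power for one band.

    Source path: zero-phase band-pass + decimation, per-trial symmetric
    orthogonalization of the real courses, Hilbert, trim; then per-trial
    seed iCoh and |analytic|^2 window means.  Sensor path: Morlet band
    power with dB baseline correction from the printed pre-event windows.
    """
    out: dict = {}
    courses = subject.parcels[band.name]
    real = spectral.band_filter_decimate(courses, band)
    ortho, report = connectivity.symmetric_orthogonalize(real)
    analytic = spectral.hilbert_trim(ortho)
    out["icoh"] = connectivity.seed_icoh_tensor(analytic, grid)
    out["ortho_report"] = report
    out["source_power"] = spectral.analytic_power(analytic, grid)
    if power_space == "sensor":
        raw = spectral.morlet_band_power(subject.epochs, band, grid)
        base = spectral.morlet_band_power(subject.epochs, band, grid,
                                          baseline=True)
        out["sensor_power"] = spectral.baseline_db(raw, base)
    out["power"] = out.get("sensor_power", out["source_power"])
    return out


def _subset_windows(tensor: FeatureTensor, window_subset: str
                    ) -> FeatureTensor:
    if window_subset == "all":
        return tensor
    sub = tensor.with_values(tensor.values[:, :, :4])
    sub.window_labels = tensor.window_labels[:4]
    return sub


def _condition_means(tensor: FeatureTensor, mode: str) -> dict:
    """Screened per-condition trial means (units x windows) per subject."""
    clean, frac = group_stats.screen_trials(tensor, mode=mode)
    out = {"removal_fraction": frac}
    for cond in ("Fast", "Slow"):
        sel = clean.condition_mask(cond)
        out[cond] = np.nanmean(clean.values[sel], axis=0)
    return out


# ---------------------------------------------------------------------------
# the run

def run_end_to_end(config: RunConfig, cohort: "Cohort | None" = None,
                   write: bool = True) -> dict:
    """Execute the whole pipeline; returns (and optionally writes) the
    report bundle.  A stage failure leaves a machine-readable failure
    record and a partial bundle."""
    out_dir = Path(config.out_dir)
    log = RunLog(out_dir / "run_log.jsonl" if write else None)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "config_hash": config.hash(),
                    "stages": {}, "failures": []}
    master = np.random.SeedSequence(config.master_seed)
    ss_decode, ss_stats = master.spawn(2)
    band = get_band(config.band)
    grid = WindowGrid()

    if cohort is None:
        cohort = read_cohort(config.cohort_dir)

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
                log.record(stage=name, status="ok",
                           duration=round(time.time() - t0, 3))
            except Exception as err:  # noqa: BLE001 — partial bundle contract
                record = {"stage": name, "error": type(err).__name__,
                          "message": str(err),
                          "trace": traceback.format_exc(limit=5)}
                report["failures"].append(record)
                log.record(stage=name, status="failed", error=str(err))
            return fn
        return deco

    state: dict = {}

    @stage("behavior")
    def _behavior():
        trials, summary = kinematics.behavior_tables(
            [s.kinematics for s in cohort.subjects])
        diffs = kinematics.slow_fast_differences(summary)
        tests = {}
        wide = summary.pivot(index="subject", columns="condition")
        for var in kinematics.MOTOR_VARIABLES:
            res = kinematics.paired_compare(
                wide[(var, "Fast")].to_numpy(), wide[(var, "Slow")].to_numpy())
            tests[var] = asdict(res)
        state.update(trials=trials, summary=summary, diffs=diffs)
        report["stages"]["behavior"] = {"tests": tests,
                                        "n_subjects": cohort.n_subjects}
        if write:
            trials.to_csv(out_dir / "behavior_trials.csv", index=False)
            summary.to_csv(out_dir / "behavior_summary.csv", index=False)
            diffs.to_csv(out_dir / "behavior_diffs.csv", index=False)

    @stage("features")
    def _features():
        feats = [subject_features(s, band, grid, config.power_space)
                 for s in cohort.subjects]
        state["features"] = feats
        report["stages"]["features"] = {
            "band": band.name,
            "orthogonalization_converged": all(
                f["ortho_report"].converged for f in feats),
            "max_residual_zero_lag_corr": max(
                f["ortho_report"].max_abs_pairwise_zero_lag_correlation
                for f in feats),
        }

    @stage("group_stats")
    def _group_stats():
        feats = state["features"]
        rng = np.random.default_rng(ss_stats)
        icoh_means = [_condition_means(f["icoh"], config.screening_mode)
                      for f in feats]
        power_means = [_condition_means(f["power"], config.screening_mode)
                       for f in feats]
        # per-parcel x window paired t (iCoh), parcel ranking
        fast = np.stack([m["Fast"] for m in icoh_means])
        slow = np.stack([m["Slow"] for m in icoh_means])
        diffs = fast - slow
        t_matrix = group_stats._paired_t(
            diffs.reshape(len(feats), -1)).reshape(diffs.shape[1:])
        parcel_names = feats[0]["icoh"].unit_ids
        top = group_stats.rank_parcels_by_t(t_matrix, parcel_names)
        cand = resolve_candidates(config.candidate_set, parcel_names) \
            if config.candidate_set != "left-central-21" else parcel_names
        cand_ix = [parcel_names.index(p) for p in cand]
        sign_res = group_stats.sign_proportion_permutation(
            diffs.mean(axis=2)[:, cand_ix], n_perm=config.n_perm, rng=rng)
        # sensor-space cluster test on power (per window)
        cluster = None
        if config.power_space == "sensor":
            graph = group_stats.build_adjacency(
                cohort.subjects[0].epochs.positions, config.adjacency_radius)
            pf = np.stack([m["Fast"] for m in power_means])
            ps = np.stack([m["Slow"] for m in power_means])
            cluster = []
            for w in range(pf.shape[2]):
                res = group_stats.paired_cluster_permutation(
                    pf[:, :, w], ps[:, :, w], graph, config.alpha,
                    config.n_perm, rng)
                cluster.append({
                    "window": w, "n_clusters": len(res.clusters),
                    "min_p": float(res.p_values.min())
                    if res.p_values.size else None})
        state["icoh_t_matrix"] = t_matrix
        # per-subject mean Fast-Slow iCoh over the candidate parcels:
        # unlike decoder coefficients, this tracks the planted coupling
        # monotonically even when decoding saturates
        state["subject_icoh_diff"] = diffs[:, cand_ix, :].mean(axis=(1, 2))
        report["stages"]["group_stats"] = {
            "icoh_removal_fraction": float(np.mean(
                [m["removal_fraction"] for m in icoh_means])),
            "power_removal_fraction": float(np.mean(
                [m["removal_fraction"] for m in power_means])),
            "top_parcels": top,
            "sign_proportion": asdict(sign_res),
            "cluster_tests": cluster,
        }

    @stage("decoding")
    def _decoding():
        feats = state["features"]
        seeds = ss_decode.spawn(2 * len(feats))
        results = {"icoh": [], "power": []}
        for metric in ("icoh", "power"):
            for i, f in enumerate(feats):
                tensor = _subset_windows(f[metric], config.window_subset)
                if metric == "icoh" or config.power_space == "source":
                    cands = resolve_candidates(config.candidate_set,
                                               tensor.unit_ids)
                else:
                    cands = tensor.unit_ids
                rng = np.random.default_rng(
                    seeds[i + (0 if metric == "icoh" else len(feats))])
                res = decoding.decode_subject(
                    tensor, cands, config.min_gain, config.max_groups,
                    config.n_folds, config.n_boot, rng,
                    positive_class=config.positive_class)
                results[metric].append(res)
        state["decoding"] = results
        tables = {}
        for metric, rs in results.items():
            df = pd.DataFrame([{
                "subject": r.subject_id, "mean_auc": r.mean_auc,
                "delta_auc": r.delta_auc, "ci_lo": r.bootstrap_ci[0],
                "ci_hi": r.bootstrap_ci[1],
                "mean_coefficient": r.mean_coefficient,
                "above_chance": r.above_chance,
                "selected_groups": ";".join(map(str, r.selected_groups)),
            } for r in rs])
            tables[metric] = df
            if write:
                df.to_csv(out_dir / f"decoding_{metric}.csv", index=False)
        report["stages"]["decoding"] = {
            metric: {
                "mean_delta_auc": float(df["delta_auc"].mean()),
                "n_above_chance": int(df["above_chance"].sum()),
                "selection_frequencies": decoding.selection_frequencies(
                    rs, sorted({g for r in rs for g in r.selected_groups}),
                    above_chance_only=config.n_boot > 0),
            }
            for metric, (rs, df) in
            ((m, (results[m], tables[m])) for m in results)
        }

    @stage("inference")
    def _inference():
        results = state["decoding"]
        diffs = state["diffs"].set_index("subject")
        order = [s.subject_id for s in cohort.subjects]
        d_total = diffs.loc[order, "d_total"].to_numpy()
        d_mt = diffs.loc[order, "d_MT"].to_numpy()
        d_rt = diffs.loc[order, "d_RT"].to_numpy()
        inf: dict = {}
        coef = {}
        for metric, rs in results.items():
            aucs = np.asarray([r.mean_auc for r in rs])
            inf[f"{metric}_auc_test"] = asdict(
                inference.group_auc_test(aucs))
            if config.n_boot > 0:
                included = [r.above_chance for r in rs]
            else:
                included = [True] * len(rs)
            coefs = np.asarray([r.mean_coefficient
                                for r, ok in zip(rs, included) if ok])
            cons = inference.coefficient_consistency_test(coefs)
            inf[f"{metric}_consistency"] = asdict(cons) if cons else None
            all_coefs = np.asarray([r.mean_coefficient for r in rs])
            coef[metric] = all_coefs
            for dname, dvec in (("total", d_total), ("MT", d_mt),
                                ("RT", d_rt)):
                res = inference.vigor_correlation(
                    all_coefs, dvec, x_name=f"{metric}_coefficient",
                    y_name=f"d_{dname}")
                inf[f"{metric}_vigor_corr_{dname}"] = asdict(res)
        inf["icoh_partial_vigor_corr"] = asdict(
            inference.partial_vigor_correlation(
                coef["icoh"], d_total, coef["power"]))
        inf["icoh_diff_vigor_corr"] = asdict(inference.vigor_correlation(
            state["subject_icoh_diff"], d_total,
            x_name="mean_icoh_fast_minus_slow", y_name="d_total"))
        # artifact control: trial |acc| vs trial-mean beta feature
        trials = state["trials"]
        feats = state["features"]
        accs, pows, icohs = [], [], []
        for s, f in zip(cohort.subjects, feats):
            t = trials[trials["subject"] == s.subject_id]
            acc = t.sort_values("trial")["mean_abs_acc"].to_numpy()
            accs.append(acc)
            pows.append(np.nanmean(f["power"].values, axis=(1, 2)))
            icohs.append(np.nanmean(f["icoh"].values, axis=(1, 2)))
        inf["artifact_control_power"] = dataclasses.asdict(
            inference.artifact_control_correlation(accs, pows))
        inf["artifact_control_icoh"] = dataclasses.asdict(
            inference.artifact_control_correlation(accs, icohs))
        report["stages"]["inference"] = inf

    if write:
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
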