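"""End-to-end orchestration with config, seeding, and provenance.

A run executes: simulate (optional) -> diagnostic maps -> brain features ->
representation matrix -> dynamics -> redundancy/complexity -> recovery
report, writing HDF5/TSV artifacts plus a manifest (config hash, seed,
per-stage wall time) under a run directory.  Each stage draws its random
stream from a named substream of the single top-level seed, so a rerun with
the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import behavior, dynamics, features, io, synthetic

__all__ = ["RunConfig", "run_all", "stage_rng"]

_STAGE_STREAMS = {
    "simulate": 7,
    "activity": 11,
    "diagnostic": 13,
    "features": 17,
    "repmat": 19,
    "dynamics": 23,
    "redundancy": 29,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream of the top-level seed for one pipeline stage."""
    return np.random.default_rng([seed, _STAGE_STREAMS[stage]])


@dataclass
class RunConfig:
    """All tunable parameters of a run; thresholds are never hard-coded."""

    seed: int = 0
    n_trials: int = 800
    n_voxels: int = 200
    mask_size: int = 64
    junction_ms: float = 170.0
    visibility_threshold: float = 0.2
    diag_n_perm: int = 1000
    diag_percentile: float = 99.9
    nmf_k: int = 6
    nmf_threshold_frac: float = 0.15
    reduce_components: int = 20
    reduce_times: int = 40
    repmat_n_perm: int = 100
    repmat_percentile: float = 95.0
    classify_hi_percentile: float = 75.0
    classify_lo_percentile: float = 25.0
    window_ms: float = 10.0
    divergence_n_boot: int = 500
    outlier_sd: float = 3.0
    junction_distance_percentile: float = 75.0
    red_n_perm: int = 100
    red_percentile: float = 95.0
    complexity_start_ms: float = 120.0
    complexity_stop_ms: float = 220.0
    complexity_n_windows: int = 5
    use_true_basis: bool = False
    out_dir: str = "runs/demo"

    def validate(self) -> None:
        positive = [
            ("n_trials", self.n_trials), ("n_voxels", self.n_voxels),
            ("diag_n_perm", self.diag_n_perm), ("repmat_n_perm", self.repmat_n_perm),
            ("red_n_perm", self.red_n_perm), ("nmf_k", self.nmf_k),
            ("divergence_n_boot", self.divergence_n_boot),
        ]
        for name, v in positive:
            if v <= 0:
                raise ValueError(f"config field {name} must be positive, got {v}")
        if not 0.0 < self.visibility_threshold < 1.0:
            raise ValueError("visibility_threshold must lie in (0, 1)")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline on a synthetic observer; returns the run dir."""
    from .diagnostic import binarize_visibility, diagnostic_map

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
    }
    meta = {"seed": config.seed, "config_hash": config.hash()}

    def _stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        manifest["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3)}
        return result

    truth = synthetic.default_ground_truth(
        n_voxels=config.n_voxels,
        mask_size=config.mask_size,
        junction_ms=config.junction_ms,
        seed=config.seed,
    )

    def _simulate():
        trials = synthetic.simulate_trials(
            truth, config.n_trials, stage_rng(config.seed, "simulate")
        )
        activity = synthetic.simulate_activity(
            truth, trials, stage_rng(config.seed, "activity")
        )
        io.save_trials(out / "trials.h5", trials, **meta)
        io.save_activity(out / "meg.h5", activity, **meta)
        return synthetic.SyntheticDataset(trials, activity, truth)

    ds = _stage("simulate", _simulate)

    def _diagnostic():
        vis = binarize_visibility(ds.trials.masks, config.visibility_threshold)
        maps = {}
        rng = stage_rng(config.seed, "diagnostic")
        for contrast in ("nuns_vs_dk", "voltaire_vs_dk"):
            dmap = diagnostic_map(
                vis, ds.trials.decisions, contrast,
                n_perm=config.diag_n_perm, percentile=config.diag_percentile, rng=rng,
            )
            io.save_diagnostic_map(out / f"diagnostic_{contrast}.h5", dmap, **meta)
            maps[contrast] = dmap
        return maps

    dmaps = _stage("diagnostic", _diagnostic)

    def _features():
        rng = stage_rng(config.seed, "features")
        if config.use_true_basis:
            basis = features.BrainFeatureBasis(
                truth.templates_flat().copy(), truth.templates.shape[1:],
                truth.feature_labels(),
            )
        else:
            reduced = features.reduce_activity_pca(
                ds.activity, config.reduce_components, config.reduce_times
            )
            stack = features.reduced_mi_images(ds.trials.masks, reduced)
            basis = features.nmf_basis(
                stack, config.nmf_k, rng, config.nmf_threshold_frac
            )
            coefs0 = features.feature_coefficients(ds.trials.masks, basis)
            basis.labels = features.classify_features(
                coefs0, ds.trials.decisions,
                config.classify_hi_percentile, config.classify_lo_percentile,
            )
        io.save_basis(out / "features.h5", basis, **meta)
        return basis

    basis = _stage("features", _features)
    coefs = features.feature_coefficients(ds.trials.masks, basis)

    def _repmat():
        rep = features.representation_matrix(
            coefs, ds.activity, config.repmat_n_perm, config.repmat_percentile,
            stage_rng(config.seed, "repmat"), feature_labels=list(basis.labels),
        )
        io.save_representation_matrix(out / "repmat.h5", rep, **meta)
        return rep

    rep = _stage("repmat", _repmat)

    def _dynamics():
        rng = stage_rng(config.seed, "dynamics")
        res = {}
        labels = np.asarray(rep.feature_labels)
        has_diag = np.isin(labels, ["diagnostic_nuns", "diagnostic_voltaire"]).any()
        has_nondiag = (labels == "nondiagnostic").any()
        if not (has_diag and has_nondiag):
            return res
        diag_course = dynamics.max_course(rep, "diagnostic", config.window_ms)
        nondiag_course = dynamics.max_course(rep, "nondiagnostic", config.window_ms)
        res["divergence"] = dynamics.divergence(
            diag_course, nondiag_course, config.divergence_n_boot, rng
        )
        # onsets/offsets for the wavefront and junction at time-point resolution
        t = rep.times_ms
        step = float(t[1] - t[0]) if len(t) > 1 else config.window_ms
        nondiag_tp = dynamics.max_course(rep, "nondiagnostic", step)
        try:
            res["regressions"] = dynamics.wavefront_regressions(
                nondiag_tp, ds.activity.coords, config.outlier_sd
            )
            origin = res["regressions"].origin_voxel
            dist = np.linalg.norm(ds.activity.coords - ds.activity.coords[origin], axis=1)
            far, marker = dynamics.junction(
                nondiag_tp, dist, config.junction_distance_percentile
            )
            res["junction_ms"] = marker
            res["junction_voxels"] = far
        except ValueError as exc:
            res["dynamics_note"] = str(exc)
        io.export_voxel_dynamics_tsv(
            out / "dynamics_nondiagnostic.tsv", nondiag_course, ds.activity.coords
        )
        return res

    dyn = _stage("dynamics", _dynamics)

    def _redundancy():
        labels = np.asarray(basis.labels)
        diag_idx = np.flatnonzero(
            np.isin(labels, ["diagnostic_nuns", "diagnostic_voltaire"])
        )
        if diag_idx.size == 0:
            return None
        dcoefs = features.FeatureCoefficients(coefs.coefs[:, diag_idx])
        red = behavior.redundancy_matrix(
            dcoefs, ds.activity, ds.trials.decisions,
            config.red_n_perm, config.red_percentile,
            stage_rng(config.seed, "redundancy"),
            feature_labels=[labels[i] for i in diag_idx],
        )
        io.save_redundancy_matrix(out / "redundancy.h5", red, **meta)
        windows = behavior.default_complexity_windows(
            config.complexity_start_ms, config.complexity_stop_ms,
            config.complexity_n_windows,
        )
        cmap = behavior.representational_complexity(red, windows)
        io.export_complexity_tsv(out / "complexity.tsv", cmap)
        return {"red": red, "complexity": cmap}

    red_out = _stage("redundancy", _redundancy)

    outputs = {"diagnostic_maps": dmaps, "basis": basis}
    if "junction_ms" in dyn:
        outputs["junction_ms"] = dyn["junction_ms"]
    if red_out:
        outputs["complexity"] = red_out["complexity"]
    report = synthetic.recovery_report(ds, outputs)
    manifest["recovery_report"] = report
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
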