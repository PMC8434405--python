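"""Configuration-driven orchestration of the full hydration analysis.

A YAML config selects a trajectory, atom groups, and physical parameters
(shell cutoff 0.6 nm, H-bond criterion 0.35 nm / 30 deg, 200 ps residence
window by default) and the pipeline runs structure -> transport -> hydration
-> hbond stages in order, writing per-stage CSV/JSON artefacts plus a
consolidated JSON report. Stages fail independently; the report records the
diagnostics. Outputs are a pure function of (inputs, config, seed), and every
numeric output file carries the config hash in its metadata header.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import AnalysisError, ConfigError, InputError, ParameterError
from .trajectory import Trajectory, read_trajectory, unwrap_coordinates, write_series

log = logging.getLogger("hydrashell")


class HBondSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    da_cutoff: float = Field(0.35, gt=0, description="D-A distance cutoff, nm")
    angle_cutoff: float = Field(30.0, gt=0, lt=90, description="H-D-A angle cutoff, deg")


class Selections(BaseModel):
    """Atom groups as explicit 0-based index lists, or the named groups
    'protein' (non-water atoms), 'water' (water atoms), 'all'."""

    model_config = ConfigDict(extra="forbid")
    protein: list[int] | str = "protein"
    shell_reference: list[int] | str = "protein"
    water: list[int] | str = "water"
    msd: list[int] | str = "all"


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    structure: bool = True
    transport: bool = True
    hydration: bool = True
    hbonds: bool = True


class Strides(BaseModel):
    """Per-stage frame strides, mirroring analyses run at different saving
    frequencies on one trajectory."""

    model_config = ConfigDict(extra="forbid")
    transport: int = Field(1, ge=1)
    hydration: int = Field(1, ge=1)
    hbonds: int = Field(1, ge=1)


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    coordinate_path: Optional[str] = None
    trajectory_path: Optional[str] = None
    selections: Selections = Selections()
    shell_cutoff: float = Field(0.6, ge=0, description="hydration-shell cutoff, nm")
    local_shell_cutoff: float = Field(0.5, ge=0, description="site-local shell cutoff, nm")
    hbond: HBondSettings = HBondSettings()
    residence_window: float = Field(200.0, gt=0, description="residence window, ps")
    max_lag: Optional[float] = Field(None, description="correlation max lag, ps")
    msd_fit_min: Optional[float] = Field(None, description="diffusion fit range start, ps")
    msd_fit_max: Optional[float] = Field(None, description="diffusion fit range end, ps")
    origin_stride: int = Field(1, ge=1)
    fix_gamma: Optional[float] = Field(None, gt=0, le=1)
    stages: StageToggles = StageToggles()
    strides: Strides = Strides()
    seed: int = 0
    output_dir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(path: str) -> AnalysisConfig:
    """Parse and validate a YAML config file; an empty file yields defaults.

    Violations are reported with their key paths in a :class:`ConfigError`.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except OSError as exc:
        raise InputError(f"cannot read config {path!r}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"config {path!r} is not valid YAML: {exc}") from exc
    return validate_config_dict(raw or {})


def validate_config_dict(raw: dict) -> AnalysisConfig:
    try:
        return AnalysisConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                 for err in exc.errors()]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


def _resolve(traj: Trajectory, spec) -> np.ndarray:
    if isinstance(spec, str):
        water_atoms = set()
        for o, h1, h2 in traj.topology.water_molecules():
            water_atoms.update((o, h1, h2))
        if spec == "all":
            return np.arange(traj.n_atoms)
        if spec == "water":
            return np.array(sorted(water_atoms), dtype=int)
        if spec == "protein":
            return np.array([i for i in range(traj.n_atoms) if i not in water_atoms],
                            dtype=int)
        raise ConfigError(f"unknown named selection {spec!r}")
    sel = np.asarray(spec, dtype=int)
    if sel.size and (sel.min() < 0 or sel.max() >= traj.n_atoms):
        raise ConfigError("selection index out of range")
    return sel


def _strided(traj: Trajectory, stride: int) -> Trajectory:
    if stride == 1:
        return traj
    return Trajectory(traj.topology, traj.coordinates[::stride], traj.box,
                      traj.times[::stride], traj.metadata)


def run_pipeline(config: AnalysisConfig, traj: Trajectory | None = None) -> dict:
    """Execute the configured analysis stages on a trajectory.

    ``traj`` may be supplied directly (e.g. a synthetic system); otherwise it
    is read from the configured paths. Returns a report dict with a
    ``"stages"`` section (status, key numbers, output files) and an
    ``"artifacts"`` section holding the in-memory result objects.
    """
    from . import __version__
    from .hbonds import HBondCriterion, hbond_count_series, hbond_times
    from .hydration import (dipole_autocorrelation, fit_reorientation,
                            fit_residence, residence_correlation, shell_membership)
    from .structure import rmsd_series, rmsf, sasa
    from .transport import diffusion_coefficient, msd

    if traj is None:
        if config.coordinate_path is None:
            raise ConfigError("coordinate_path is required when no trajectory is supplied")
        traj = read_trajectory(config.coordinate_path, config.trajectory_path)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = {"config_hash": chash, "seed": config.seed}
    report: dict = {"tool": f"hydrashell {__version__}", "config_hash": chash,
                    "seed": config.seed, "n_frames": traj.n_frames,
                    "n_atoms": traj.n_atoms, "stages": {}}
    artifacts: dict = {}

    protein = _resolve(traj, config.selections.protein)
    ref = _resolve(traj, config.selections.shell_reference)
    water = _resolve(traj, config.selections.water)
    msd_sel = _resolve(traj, config.selections.msd)
    span = traj.span
    max_lag = config.max_lag if config.max_lag is not None else span / 2

    def run_stage(name, fn):
        if not getattr(config.stages, name):
            report["stages"][name] = {"status": "skipped"}
            return
        t0 = time.perf_counter()
        try:
            summary = fn()
            report["stages"][name] = {"status": "ok", **summary}
        except (ParameterError, AnalysisError, InputError) as exc:
            report["stages"][name] = {"status": "failed",
                                      "error": f"{type(exc).__name__}: {exc}"}
        wall = time.perf_counter() - t0
        report["stages"][name]["wall_time_s"] = round(wall, 3)
        log.info("stage %-10s %-7s %.2fs (config %s)", name,
                 report["stages"][name]["status"], wall, chash)

    def stage_structure():
        prof = rmsf(traj, selection=protein, align_first=True)
        rser = rmsd_series(traj, reference_frame=0, selection=protein)
        write_series({"id": prof.ids, "rmsf_nm": prof.rmsf},
                     outdir / "rmsf.csv", metadata=meta)
        write_series({"time_ps": rser.time, "rmsd_nm": rser.rmsd},
                     outdir / "rmsd.csv", metadata=meta)
        artifacts["rmsf"] = prof
        artifacts["rmsd"] = rser
        return {"rmsf_mean_nm": float(prof.rmsf.mean()),
                "rmsd_final_nm": float(rser.rmsd[-1]),
                "outputs": ["rmsf.csv", "rmsd.csv"]}

    def stage_transport():
        t = _strided(traj, config.strides.transport)
        t = unwrap_coordinates(t)
        series = msd(t, selection=msd_sel, max_lag=min(max_lag, t.span / 2),
                     origin_stride=config.origin_stride)
        fit_min = config.msd_fit_min if config.msd_fit_min is not None else series.lag[-1] * 0.1
        fit_max = config.msd_fit_max if config.msd_fit_max is not None else series.lag[-1]
        diff = diffusion_coefficient(series, fit_min, fit_max)
        write_series({"lag_ps": series.lag, "msd_nm2": series.msd,
                      "n_samples": series.n_samples}, outdir / "msd.csv", metadata=meta)
        artifacts["msd"] = series
        artifacts["diffusion"] = diff
        return {"D_nm2_per_ps": diff.D, "D_stderr": diff.stderr,
                "fit_r_squared": diff.r_squared, "outputs": ["msd.csv"]}

    def stage_hydration():
        t = _strided(traj, config.strides.hydration)
        membership = shell_membership(t, ref, config.shell_cutoff)
        window = min(config.residence_window, t.span / 2)
        corr = residence_correlation(membership, window=window,
                                     origin_stride=config.origin_stride)
        fit = fit_residence(corr, seed=config.seed, fix_gamma=config.fix_gamma)
        acf = dipole_autocorrelation(t, max_lag=min(max_lag, t.span / 2),
                                     origin_stride=config.origin_stride)
        rfit = fit_reorientation(acf)
        write_series({"lag_ps": corr.lag, "C_r": corr.value,
                      "n_origins": corr.n_origins},
                     outdir / "residence.csv", metadata=meta)
        write_series({"lag_ps": acf.lag, "C_mu": acf.value,
                      "n_origins": acf.n_origins},
                     outdir / "reorientation.csv", metadata=meta)
        artifacts["membership"] = membership
        artifacts["residence"] = corr
        artifacts["residence_fit"] = fit
        artifacts["reorientation"] = acf
        artifacts["reorientation_fit"] = rfit
        out = {"mean_shell_count": float(membership.counts.mean()),
               "outputs": ["residence.csv", "reorientation.csv"]}
        if fit.converged:
            out["residence_fit"] = {k: float(v) for k, v in fit.params.items()}
        if rfit.converged:
            out["t_mu_ps"] = rfit.params["t_mu"]
        return out

    def stage_hbonds():
        t = _strided(traj, config.strides.hbonds)
        crit = HBondCriterion(config.hbond.da_cutoff, config.hbond.angle_cutoff)
        counts = hbond_count_series(t, protein, water, crit)
        times = hbond_times(t, protein, water, crit,
                            max_lag=min(max_lag, t.span / 2),
                            origin_stride=config.origin_stride,
                            extrapolate_tau_r=True)
        write_series({"frame": np.arange(len(counts.counts)),
                      "n_hbonds": counts.counts}, outdir / "hbond_counts.csv",
                     metadata=meta)
        write_series({"lag_ps": times.c_curve.lag, "c": times.c_curve.value,
                      "n_origins": times.c_curve.n_origins},
                     outdir / "hbond_ct.csv", metadata=meta)
        artifacts["hbond_counts"] = counts
        artifacts["hbond_times"] = times
        return {"mean_hbonds": counts.mean, "sd_hbonds": counts.sd,
                "tau_hb_ps": times.tau_hb, "tau_r_ps": times.tau_r,
                "tau_r_extrapolated": times.tau_r_extrapolated,
                "outputs": ["hbond_counts.csv", "hbond_ct.csv"]}

    run_stage("structure", stage_structure)
    run_stage("transport", stage_transport)
    run_stage("hydration", stage_hydration)
    run_stage("hbonds", stage_hbonds)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    report["artifacts"] = artifacts
    return report
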