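"""File formats, run configuration, and the end-to-end pipeline.

Conventions are fixed: time in seconds, mass flow in kg/h, impeller speeds
in rpm, and all concentrations in % of target label claim (100 = on
target).  Traces are 2-column CSV (``time_s,value``) with a one-line
header; parameter sets and fit results are JSON; impulse campaigns are a
directory of trace CSVs plus a ``manifest.json``.  Non-uniform time stamps
are rejected, never resampled.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rtdkit import reference
from rtdkit.control import ValidationReport, build_system_kernel, rejection_limits, rmsep
from rtdkit.core import ConcentrationTrace, EtCurve, RTDParams, TimeGrid, default_grid
from rtdkit.empirical import MRTObservation, fit_empirical, parity_stats, predict_mrt
from rtdkit.errors import DependencyError, InvalidInputError, RTDKitError
from rtdkit.fitting import (
    ImpulseExperiment,
    OperatingCondition,
    UnitFitResult,
    deconvolution_sequence,
    goodness_of_fit,
)
from rtdkit.synthetic import (
    CampaignDesign,
    NoiseModel,
    default_campaign,
    default_truth,
    gen_campaign,
    gen_step_validation,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# traces


def read_trace(path: str | Path) -> ConcentrationTrace:
    """Read a 2-column (time_s, value) CSV into a uniform-grid trace."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    # NaN values mark masked samples and are allowed; NaN/inf times are not
    if np.any(~np.isfinite(t)) or np.any(np.isinf(v)):
        bad = int(np.argmax(~np.isfinite(t) | np.isinf(v))) + 2  # 1-based + header
        raise InvalidInputError(f"{path}: non-finite entry at line {bad}")
    if t.size < 2:
        raise InvalidInputError(f"{path}: need at least 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 3
        raise InvalidInputError(f"{path}: non-increasing time stamp at line {bad}")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9))) + 3
        raise InvalidInputError(f"{path}: non-uniform time step at line {bad}")
    grid = TimeGrid(float(t[0]), float(dt[0]), t.size)
    return ConcentrationTrace(grid, v)


def write_trace(trace: ConcentrationTrace | EtCurve, path: str | Path) -> None:
    """Write a trace or density to 2-column CSV (time_s, value)."""
    values = trace.value if isinstance(trace, ConcentrationTrace) else trace.density
    pd.DataFrame({"time_s": trace.grid.times, "value": values}).to_csv(
        Path(path), index=False
    )


# ---------------------------------------------------------------------------
# impulse campaign directories


def write_experiments(experiments: list[ImpulseExperiment], directory: str | Path) -> None:
    """Write impulse traces + manifest.json into a campaign directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, e in enumerate(experiments):
        fname = f"impulse_{i:03d}.csv"
        write_trace(e.trace, directory / fname)
        manifest.append(
            {
                "file": fname,
                "target_unit": e.target_unit,
                "mass_flow": e.condition.mass_flow,
                "speed_b1": e.condition.speed_b1,
                "speed_b2": e.condition.speed_b2,
                "tracer_mass": e.tracer_mass,
                "replicate_id": e.replicate_id,
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_experiments(directory: str | Path) -> list[ImpulseExperiment]:
    """Read a campaign directory written by :func:`write_experiments`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise InvalidInputError(f"{directory}: no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    experiments = []
    for entry in manifest:
        cond = OperatingCondition(
            entry["mass_flow"], entry.get("speed_b1"), entry.get("speed_b2")
        )
        experiments.append(
            ImpulseExperiment(
                target_unit=entry["target_unit"],
                condition=cond,
                tracer_mass=entry["tracer_mass"],
                trace=read_trace(directory / entry["file"]),
                replicate_id=entry.get("replicate_id", "r1"),
            )
        )
    return experiments


def read_kernel_params(path: str | Path) -> dict[str, RTDParams]:
    """Read {'b1': {...}, 'b2': {...}, 'ff': {...}} RTD parameter JSON."""
    d = json.loads(Path(path).read_text())
    out = {}
    for key in ("b1", "b2", "ff"):
        if key not in d:
            raise InvalidInputError(f"{path}: missing unit {key!r}")
        out[key] = RTDParams.from_dict(d[key])
    return out


def write_kernel_params(params: dict[str, RTDParams], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: p.to_dict() for k, p in params.items()}, indent=1)
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs, JSON round-trippable."""

    out_dir: str = "rtdkit_run"
    grid_step: float = 1.0  # seconds
    seed: int = 1234
    n_starts: int = 8
    nir_sigma: float = reference.NIR_RMSECV
    hplc_sigma: float = 1.0
    nir_relative: float = 0.0
    rmsep_acceptance: float = 6.0  # % LC validation acceptance criterion
    sigma_weight: float = 0.0  # % LC tablet-weight variability
    synthetic: bool = True
    campaign: str = "full"  # full | minimal
    input_dir: str | None = None  # campaign directory when synthetic=False

    def __post_init__(self) -> None:
        for name in ("grid_step", "n_starts", "rmsep_acceptance"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.campaign not in ("full", "minimal"):
            raise InvalidInputError("campaign must be 'full' or 'minimal'")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            nir_sigma=self.nir_sigma,
            hplc_sigma=self.hplc_sigma,
            nir_relative=self.nir_relative,
            seed=self.seed,
        )


def minimal_campaign() -> CampaignDesign:
    """A reduced factorial design (6 + 6 + 3 conditions) for quick runs.

    Blender 1 pulses and full-system pulses ride on operating points whose
    downstream units are themselves part of the design (B2 at 150 rpm, B1
    at 180 rpm), so the deconvolution chain stays self-contained.
    """
    flows = (15.0, 50.0, 90.0)
    conditions: list[tuple[str, OperatingCondition, int]] = []
    for flow in flows:
        for s2 in (150.0, 300.0):
            conditions.append(
                ("blender2", OperatingCondition(flow, 180.0, s2), 1)
            )
    for flow in flows:
        for s1 in (180.0, 450.0):
            conditions.append(
                ("blender1", OperatingCondition(flow, s1, 150.0), 1)
            )
    for flow in flows:
        conditions.append(
            ("full_system", OperatingCondition(flow, 180.0, 150.0), 1)
        )
    return CampaignDesign(conditions=conditions)


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Full workflow: (simulate) -> fit units -> surfaces -> validate -> limits.

    Writes five report files under ``config.out_dir`` (unit fits, MRT
    tables, empirical constants, validation samples, rejection limits) plus
    a log recording the seed, and returns the in-memory bundle.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"rtdkit pipeline; seed={config.seed}; n_starts={config.n_starts}"]

    noise = config.noise_model()
    if config.synthetic:
        design = default_campaign() if config.campaign == "full" else minimal_campaign()
        experiments = gen_campaign(design, noise=noise)
        log_lines.append(f"simulated campaign: {len(experiments)} experiments")
    else:
        if not config.input_dir:
            raise InvalidInputError("non-synthetic runs require input_dir")
        experiments = read_experiments(config.input_dir)
        log_lines.append(f"loaded campaign from {config.input_dir}: {len(experiments)}")

    try:
        b2, b1, ff = deconvolution_sequence(
            experiments, n_starts=config.n_starts, seed=config.seed
        )
    except RTDKitError as exc:
        raise DependencyError(f"unit-fit stage failed: {exc}") from exc
    fits = {"blender1": b1, "blender2": b2, "feedframe": ff}
    (out_dir / "unit_fits.json").write_text(
        json.dumps({k: v.to_dict() for k, v in fits.items()}, indent=1)
    )

    tables = []
    for unit, result in fits.items():
        tbl = goodness_of_fit(result)
        tbl.insert(0, "unit", unit)
        tables.append(tbl)
    mrt_table = pd.concat(tables, ignore_index=True)
    mrt_table.to_csv(out_dir / "mrt_tables.csv", index=False)

    constants = {}
    parity = {}
    for unit, result in fits.items():
        form = "feedframe" if unit == "feedframe" else "blender"
        obs = [
            MRTObservation(cond, p.mrt, max(p.eps_mrt, 1e-6))
            for cond, p in result.per_condition
        ]
        constants[unit] = fit_empirical(obs, form=form, unit=unit)
        observed = [o.mrt for o in obs]
        predicted = [predict_mrt(constants[unit], o.condition) for o in obs]
        r2, rmse = parity_stats(observed, predicted)
        parity[unit] = {"r_squared": r2, "rmse": rmse}
    (out_dir / "empirical_constants.json").write_text(
        json.dumps(
            {u: {**c.to_dict(), "parity": parity[u]} for u, c in constants.items()},
            indent=1,
        )
    )

    # validation at three flows through the fitted surfaces
    flows = [15.0, 50.0, 90.0]
    kernels = {}
    for flow in flows:
        cond = OperatingCondition(
            flow, reference.CENTER_SPEED_B1, reference.CENTER_SPEED_B2
        )
        p1 = _surface_params(constants["blender1"], cond, b1.shared_r)
        p2 = _surface_params(constants["blender2"], cond, b2.shared_r)
        pf = _surface_params(constants["feedframe"], cond, ff.shared_r)
        theta = p1.theta + p2.theta + pf.theta
        tau = p1.tau_tank + p2.tau_tank + pf.tau_tank
        grid = default_grid(theta, tau, step=config.grid_step)
        kernels[flow] = build_system_kernel(p1, p2, pf, grid)
    validation = gen_step_validation(flows, kernels, noise=noise)
    validation.to_csv(out_dir / "validation.csv", index=False)
    observed_rmsep = rmsep(validation["measured"], validation["predicted"])
    report = ValidationReport(
        n_samples=len(validation),
        rmsep=observed_rmsep,
        threshold=config.rmsep_acceptance,
        samples=validation[["time_s", "measured", "predicted"]],
    )

    limits = rejection_limits(config.rmsep_acceptance, config.sigma_weight)
    limits_dict = {
        "lower": limits.lower,
        "upper": limits.upper,
        "rmsep_acceptance": config.rmsep_acceptance,
        "sigma_weight": config.sigma_weight,
        "z": limits.z,
        "observed_rmsep": observed_rmsep,
        "n_validation_samples": int(len(validation)),
        "validation_passed": bool(observed_rmsep <= config.rmsep_acceptance),
    }
    (out_dir / "rejection_limits.json").write_text(json.dumps(limits_dict, indent=1))

    log_lines.append(f"observed validation RMSEP: {observed_rmsep:.3f} %LC")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "fits": fits,
        "mrt_table": mrt_table,
        "constants": constants,
        "parity": parity,
        "validation": validation,
        "report": report,
        "rmsep": observed_rmsep,
        "limits": limits,
    }


def _surface_params(constants, condition, shared_r) -> RTDParams:
    from rtdkit.empirical import rtd_params_at

    return rtd_params_at(condition, constants, shared_r)
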