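"""Synthetic tracer campaigns and step-change validation runs.

No experimental raw curves are publicly deposited for lines of this kind, so
the generator emulates the measurements the characterization workflow
consumes:

* tracer-impulse responses — a known tracer mass injected at a unit inlet
  produces an outlet concentration deviation proportional to the composite
  RTD kernel between the injection point and the measurement point (blend
  NIR at the Blender 2 outlet, sampled every second; composite tablet assay
  every ~25 s for full-system pulses);
* step-change validation runs — feeder concentration step sequences pushed
  through the full-line kernel, with composite tablet assays drawn at the
  t10/t50/t90 transition times of each step.

Measurement noise is additive Gaussian (optionally with a multiplicative
component) on % label claim.  Ground truth defaults to the reference line's
regressed MRT tables and shared ratios, converted to (tau, theta) per unit.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rtdkit import reference
from rtdkit.control import SystemKernel, predict_downstream
from rtdkit.core import (
    ConcentrationTrace,
    RTDParams,
    TimeGrid,
    default_grid,
    params_from_mrt_r,
)
from rtdkit.errors import DependencyError, InvalidInputError
from rtdkit.fitting import ImpulseExperiment, OperatingCondition

#: weight fraction of API in the blend; converts tracer mass to % label claim
API_MASS_FRACTION = 0.25

UNIT_KERNEL_CHAIN = {
    "blender2": ("blender2",),
    "blender1": ("blender1", "blender2"),
    "full_system": ("blender1", "blender2", "feedframe"),
}


@dataclass
class NoiseModel:
    """Measurement noise configuration (all magnitudes in % label claim).

    nir_sigma: additive noise of the blend NIR monitor (default the 2.6 %LC
    cross-validation error of the calibration).  hplc_sigma: noise of a
    tablet HPLC assay.  nir_relative: optional multiplicative component
    (fraction of the signal) used for relative-noise studies.
    """

    nir_sigma: float = reference.NIR_RMSECV
    hplc_sigma: float = 1.0
    nir_relative: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nir_sigma < 0 or self.hplc_sigma < 0 or self.nir_relative < 0:
            raise InvalidInputError("noise magnitudes must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class CampaignDesign:
    """Which impulse experiments to run: (target unit, condition, replicates)."""

    conditions: list[tuple[str, OperatingCondition, int]]
    tracer_mass_b1: float = reference.TRACER_MASS_B1
    tracer_mass_b2: float = reference.TRACER_MASS_B2
    nir_cadence: float = 1.0  # seconds
    tablet_cadence: float = 25.0  # seconds

    def __post_init__(self) -> None:
        for unit, _, reps in self.conditions:
            if reps < 1:
                raise InvalidInputError(f"replicates must be >= 1, got {reps} for {unit}")
        if self.nir_cadence <= 0 or self.tablet_cadence <= 0:
            raise InvalidInputError("sampling cadences must be > 0")


def default_truth() -> dict[str, dict[tuple, RTDParams]]:
    """Ground-truth RTD parameters per unit and condition key.

    Reference MRT tables combined with the per-unit shared ratios, inverted
    to (tau, theta).  Keys are (mass_flow, speed) for the blenders and
    (mass_flow,) for the feed frame.
    """
    out: dict[str, dict[tuple, RTDParams]] = {}
    for unit, table, r in (
        ("blender1", reference.MRT_TABLE_B1, reference.R_BLENDER1),
        ("blender2", reference.MRT_TABLE_B2, reference.R_BLENDER2),
        ("feedframe", reference.MRT_TABLE_FF, reference.R_FEEDFRAME),
    ):
        out[unit] = {}
        for row in table.itertuples():
            key = (row.mass_flow,) if unit == "feedframe" else (row.mass_flow, row.speed)
            out[unit][key] = params_from_mrt_r(row.mrt, r)
    return out


def _truth_at(
    truth: dict[str, dict[tuple, RTDParams]], unit: str, condition: OperatingCondition
) -> RTDParams:
    table = truth.get(unit)
    key = condition.key_for(unit)
    if table is None or key not in table:
        raise DependencyError(f"no ground-truth {unit} parameters at condition {key}")
    return table[key]


def default_campaign() -> CampaignDesign:
    """The reference characterization design: 12 + 12 + 4 conditions.

    Blender 2 pulses at every (mass flow, Blender 2 speed) pair; Blender 1
    pulses at every (mass flow, Blender 1 speed) pair with Blender 2 at its
    center speed; full-system (tablet) pulses at the center-point speeds of
    both blenders for each mass flow.
    """
    conditions: list[tuple[str, OperatingCondition, int]] = []
    flows = sorted(reference.MRT_TABLE_FF["mass_flow"])
    for row in reference.MRT_TABLE_B2.itertuples():
        cond = OperatingCondition(
            row.mass_flow, speed_b1=reference.CENTER_SPEED_B1, speed_b2=row.speed
        )
        conditions.append(("blender2", cond, 1))
    for row in reference.MRT_TABLE_B1.itertuples():
        cond = OperatingCondition(
            row.mass_flow, speed_b1=row.speed, speed_b2=reference.CENTER_SPEED_B2
        )
        conditions.append(("blender1", cond, 1))
    for flow in flows:
        cond = OperatingCondition(
            flow,
            speed_b1=reference.CENTER_SPEED_B1,
            speed_b2=reference.CENTER_SPEED_B2,
        )
        conditions.append(("full_system", cond, 1))
    return CampaignDesign(conditions=conditions)


def gen_impulse(
    unit: str,
    condition: OperatingCondition,
    truth: dict[str, dict[tuple, RTDParams]],
    tracer_mass: float,
    noise: NoiseModel,
    cadence: float | None = None,
    replicate_id: str = "r1",
    stream: int = 0,
) -> ImpulseExperiment:
    """Simulate one tracer-impulse experiment.

    A tracer mass ``m`` (grams) injected into a line carrying ``mdot`` kg/h
    produces an outlet concentration deviation

        dC(t) [%LC] = 100 * (m / mdot_g_per_s) * E(t) / w_API

    where E is the kernel between injection and measurement point (Blender 2
    alone; Blender 1 * Blender 2 for Blender 1 pulses, which are measured at
    the Blender 2 outlet; the triple product for tablet data).  The trace is
    the baseline-subtracted deviation, so integrating dC * mdot recovers the
    tracer mass exactly in the noise-free limit.
    """
    if unit not in UNIT_KERNEL_CHAIN:
        raise InvalidInputError(f"unknown impulse target {unit!r}")
    chain = [(u, _truth_at(truth, u, condition)) for u in UNIT_KERNEL_CHAIN[unit]]
    theta_total = sum(p.theta for _, p in chain)
    tau_total = sum(p.tau_tank for _, p in chain)
    if cadence is None:
        cadence = 25.0 if unit == "full_system" else 1.0
    grid = default_grid(theta_total, tau_total, step=cadence)
    kernel = _compose_kernel([p for _, p in chain], grid)

    mdot_gps = condition.mass_flow * 1000.0 / 3600.0
    clean = 100.0 * (tracer_mass / mdot_gps) * kernel.density / API_MASS_FRACTION

    rng = noise.rng(stream)
    sigma = noise.hplc_sigma if unit == "full_system" else noise.nir_sigma
    noisy = clean + rng.normal(0.0, sigma, clean.size) if sigma > 0 else clean.copy()
    if noise.nir_relative > 0:
        noisy = noisy + clean * rng.normal(0.0, noise.nir_relative, clean.size)

    return ImpulseExperiment(
        target_unit=unit,
        condition=condition,
        tracer_mass=tracer_mass,
        trace=ConcentrationTrace(grid, noisy),
        replicate_id=replicate_id,
    )


def _compose_kernel(params: list[RTDParams], grid: TimeGrid):
    from rtdkit.core import convolve_rtd, e_unit

    kernel = e_unit(params[0], grid)
    for p in params[1:]:
        kernel = convolve_rtd(kernel, e_unit(p, grid))
    return kernel


def gen_campaign(
    design: CampaignDesign,
    truth: dict[str, dict[tuple, RTDParams]] | None = None,
    noise: NoiseModel | None = None,
) -> list[ImpulseExperiment]:
    """Simulate every experiment of a campaign design, deterministically."""
    truth = truth if truth is not None else default_truth()
    noise = noise if noise is not None else NoiseModel()
    experiments = []
    stream = 0
    for unit, cond, reps in design.conditions:
        mass = design.tracer_mass_b2 if unit == "blender2" else design.tracer_mass_b1
        cadence = design.tablet_cadence if unit == "full_system" else design.nir_cadence
        for rep in range(reps):
            experiments.append(
                gen_impulse(
                    unit,
                    cond,
                    truth,
                    mass,
                    noise,
                    cadence=cadence,
                    replicate_id=f"r{rep + 1}",
                    stream=stream,
                )
            )
            stream += 1
    return experiments


def gen_tablet_samples(
    system_trace: ConcentrationTrace,
    cadence: float = 25.0,
    composite_n: int = 10,
    noise: NoiseModel | None = None,
    stream: int = 0,
) -> pd.DataFrame:
    """Composite tablet assays drawn from a predicted concentration trace.

    Every ``cadence`` seconds a composite of ``composite_n`` tablets is
    assayed; each tablet carries independent HPLC-scale noise, so the
    composite noise shrinks by 1/sqrt(composite_n).
    """
    noise = noise if noise is not None else NoiseModel()
    span = system_trace.grid.end - system_trace.grid.start
    if cadence > span:
        raise InvalidInputError(f"cadence {cadence} s exceeds the trace span {span} s")
    times = system_trace.grid.start + np.arange(cadence, span + 1e-9, cadence)
    values = np.interp(times, system_trace.grid.times, system_trace.value)
    rng = noise.rng(stream)
    if noise.hplc_sigma > 0:
        tablet_noise = rng.normal(0.0, noise.hplc_sigma, (times.size, composite_n))
        values = values + tablet_noise.mean(axis=1)
    return pd.DataFrame({"time_s": times, "value": values})


def gen_step_validation(
    flows: list[float],
    kernels: dict[float, SystemKernel],
    steps: tuple[float, ...] = (115.0, 100.0, 85.0),
    duplicates: int = 2,
    noise: NoiseModel | None = None,
    start_level: float = 100.0,
) -> pd.DataFrame:
    """Simulate the step-change validation protocol.

    For each mass flow, the feeder concentration starts at ``start_level``
    %LC and steps through ``steps`` in order (default 100 -> 115 -> 100 ->
    85, spanning the 85-115 %LC range).  Composite tablet samples are drawn
    in duplicate at the t10, t50 and t90 times of each transition — the
    kernel-CDF inverse at 10/50/90% measured from the step onset.  Here
    ``hplc_sigma`` is applied per composite assay.  With 3 flows, 3 steps,
    3 time points and 2 duplicates the dataset has 54 samples.

    Returns a table with measured and model-predicted concentration per
    sample, ready for RMSEP computation.
    """
    noise = noise if noise is not None else NoiseModel()
    for s in steps:
        if not 85.0 <= s <= 115.0:
            raise InvalidInputError(f"step level {s} %LC outside the 85-115 range")
    rows = []
    for fi, flow in enumerate(flows):
        kernel = kernels[flow]
        step_s = kernel.grid.step
        settle = kernel.settle_time(0.999)
        hold = math.ceil(settle / step_s) * step_s + 2 * step_s
        # input profile: initial hold then one hold per step level
        levels = [start_level, *steps]
        n_seg = int(round(hold / step_s))
        value = np.concatenate([np.full(n_seg, lv) for lv in levels])
        grid = TimeGrid(0.0, step_s, value.size)
        feeder = ConcentrationTrace(grid, value)
        predicted = predict_downstream(feeder, kernel, mask_startup=False)
        t10, t50, t90 = (kernel.kernel.quantile(q) for q in (0.1, 0.5, 0.9))
        rng = noise.rng(1000 + fi)
        for si in range(len(steps)):
            onset = (si + 1) * n_seg * step_s
            for name, tq in (("t10", t10), ("t50", t50), ("t90", t90)):
                t_sample = onset + tq
                pred = float(np.interp(t_sample, grid.times, predicted.value))
                for dup in range(duplicates):
                    meas = pred + (
                        rng.normal(0.0, noise.hplc_sigma) if noise.hplc_sigma > 0 else 0.0
                    )
                    rows.append(
                        {
                            "mass_flow": flow,
                            "step_index": si,
                            "step_level": steps[si],
                            "time_point": name,
                            "time_s": t_sample,
                            "duplicate": dup + 1,
                            "measured": meas,
                            "predicted": pred,
                        }
                    )
    return pd.DataFrame(rows)
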