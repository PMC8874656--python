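"""Joint constrained RTD regression from tracer-impulse experiments.

Each blending unit is characterized by fitting the tanks-in-series-with-delay
density to measured impulse responses at several operating conditions
simultaneously: one tank time ``tau`` per condition plus a single shared
tank-to-delay ratio ``R`` for the whole unit.  Because the units are in
series, downstream units are characterized first and their fitted kernels
are held fixed ("deconvolution") when fitting the units upstream of the
measurement point:

* Blender 2 pulses are measured at the Blender 2 outlet -> fit E_B2 directly.
* Blender 1 pulses travel through both blenders -> fit E_B1 * E_B2 with the
  Blender 2 kernel known.
* Tablet samples see the whole line -> fit E_B1 * E_B2 * E_FF with both
  blender kernels known, isolating the feed frame.

The deconvolution is always performed forward (convolve the candidate kernel
with the known downstream kernels and compare to data), never by numerical
division, which would amplify measurement noise.

The optimizer is bounded nonlinear least squares on log-parameters with a
Latin-hypercube multi-start, reflecting the strong non-linearity of the
problem.  Per-parameter goodness-of-fit statistics (epsilon) are asymptotic
standard errors from the Jacobian at the optimum, propagated to the MRT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from rtdkit.core import (
    ConcentrationTrace,
    EtCurve,
    RTDParams,
    TimeGrid,
    epsilon_mrt,
    mrt_of_curve,
    normalize_to_E,
)
from rtdkit.errors import DependencyError, FitFailureError, InvalidInputError

UNITS = ("blender1", "blender2", "full_system")

#: optimizer bounds (natural scale)
TAU_BOUNDS = (0.1, 1.0e4)
R_BOUNDS = (1.0e-3, 1.0e6)
DEFAULT_N_STARTS = 8
DEFAULT_SEED = 1234


@dataclass(frozen=True)
class OperatingCondition:
    """Total mass flow (kg/h) and the impeller speeds (rpm) of a run."""

    mass_flow: float
    speed_b1: float | None = None
    speed_b2: float | None = None

    def __post_init__(self) -> None:
        if not 15.0 <= self.mass_flow <= 90.0:
            raise InvalidInputError(
                f"mass_flow {self.mass_flow} kg/h outside studied range [15, 90]"
            )
        if self.speed_b1 is not None and not 180.0 <= self.speed_b1 <= 450.0:
            raise InvalidInputError(
                f"speed_b1 {self.speed_b1} rpm outside studied range [180, 450]"
            )
        if self.speed_b2 is not None and not 150.0 <= self.speed_b2 <= 300.0:
            raise InvalidInputError(
                f"speed_b2 {self.speed_b2} rpm outside studied range [150, 300]"
            )

    def key_for(self, unit: str) -> tuple:
        """Identity of this condition from the point of view of one unit."""
        if unit == "blender1":
            return (self.mass_flow, self.speed_b1)
        if unit == "blender2":
            return (self.mass_flow, self.speed_b2)
        return (self.mass_flow,)  # feed frame varies only with mass flow


@dataclass
class ImpulseExperiment:
    """One tracer-impulse run: where the pulse went in and what was measured."""

    target_unit: str  # blender1 | blender2 | full_system
    condition: OperatingCondition
    tracer_mass: float  # grams
    trace: ConcentrationTrace
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.target_unit not in UNITS:
            raise InvalidInputError(
                f"target_unit must be one of {UNITS}, got {self.target_unit!r}"
            )
        if self.tracer_mass <= 0:
            raise InvalidInputError(f"tracer_mass must be > 0, got {self.tracer_mass}")


@dataclass
class UnitFitResult:
    """Joint-fit output for one unit: per-condition parameters + shared R.

    ``n_parameters`` follows the reporting convention of counting each
    regressed tau, the shared R, and each tau's goodness-of-fit statistic,
    i.e. 2*n_conditions + 1; the free optimizer unknowns are n_conditions + 1.
    """

    unit: str
    per_condition: list[tuple[OperatingCondition, RTDParams]]
    shared_r: float
    eps_r: float
    n_parameters: int
    residual_sse: float
    n_free_parameters: int = field(default=0)

    def params_at(self, condition: OperatingCondition) -> RTDParams:
        key = condition.key_for(self.unit)
        for cond, params in self.per_condition:
            if cond.key_for(self.unit) == key:
                return params
        raise DependencyError(
            f"no fitted {self.unit} parameters at condition {key} "
            f"(mass_flow, speed)"
        )

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "shared_r": self.shared_r,
            "eps_r": self.eps_r,
            "n_parameters": self.n_parameters,
            "residual_sse": self.residual_sse,
            "per_condition": [
                {
                    "mass_flow": c.mass_flow,
                    "speed_b1": c.speed_b1,
                    "speed_b2": c.speed_b2,
                    **p.to_dict(),
                }
                for c, p in self.per_condition
            ],
        }


# ---------------------------------------------------------------------------
# model evaluation (plain arrays for speed inside the objective)


def _erlang2_delay_density(tau: float, theta: float, t: np.ndarray, step: float) -> np.ndarray:
    s = t - theta
    d = np.where(s >= 0, np.maximum(s, 0.0) * np.exp(-np.clip(s, 0.0, None) / tau), 0.0)
    d /= tau**2
    total = np.trapezoid(d, dx=step)
    if total <= 0:
        return d
    return d / total


def _convolve(d1: np.ndarray, d2: np.ndarray, step: float) -> np.ndarray:
    out = np.convolve(d1, d2)[: d1.size] * step
    total = np.trapezoid(out, dx=step)
    if total <= 0:
        return out
    return out / total


def _upstream_kernel(
    experiment: ImpulseExperiment, known_upstream: Sequence[UnitFitResult]
) -> np.ndarray | None:
    """Fixed downstream-of-pulse kernel the candidate unit convolves with.

    Blender 2 pulses need none; Blender 1 pulses need the Blender 2 kernel;
    full-system (tablet) data need Blender 1 * Blender 2.
    """
    if experiment.target_unit == "blender2":
        return None
    by_unit = {r.unit: r for r in known_upstream}
    t = experiment.trace.grid.times
    step = experiment.trace.grid.step
    if "blender2" not in by_unit:
        raise DependencyError(
            f"{experiment.target_unit} fit requires a Blender 2 result "
            f"(condition {experiment.condition.key_for('blender2')})"
        )
    p2 = by_unit["blender2"].params_at(experiment.condition)
    k = _erlang2_delay_density(p2.tau_tank, p2.theta, t, step)
    if experiment.target_unit == "full_system":
        if "blender1" not in by_unit:
            raise DependencyError(
                "full_system (feed frame) fit requires a Blender 1 result"
            )
        p1 = by_unit["blender1"].params_at(experiment.condition)
        k1 = _erlang2_delay_density(p1.tau_tank, p1.theta, t, step)
        k = _convolve(k1, k, step)
    return k


# ---------------------------------------------------------------------------
# joint fit


def _fitted_unit_name(target_unit: str) -> str:
    return "feedframe" if target_unit == "full_system" else target_unit


def fit_unit_joint(
    experiments: Sequence[ImpulseExperiment],
    known_upstream: Sequence[UnitFitResult] = (),
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = DEFAULT_SEED,
) -> UnitFitResult:
    """Jointly regress one unit's tank times and its shared ratio R.

    All experiments must target the same unit.  Replicates at a condition
    contribute residuals simultaneously.  Measured traces are normalized to
    E(t) densities before fitting, and the loss is the sum of squared
    density differences over all conditions and grid points.
    """
    if not experiments:
        raise InvalidInputError("no experiments supplied")
    targets = {e.target_unit for e in experiments}
    if len(targets) > 1:
        raise InvalidInputError(f"experiments target multiple units: {sorted(targets)}")
    target = experiments[0].target_unit
    unit_name = _fitted_unit_name(target)

    # group replicates by condition (keyed by the varied factors of this unit)
    groups: dict[tuple, list[ImpulseExperiment]] = {}
    rep_condition: dict[tuple, OperatingCondition] = {}
    for e in experiments:
        key = e.condition.key_for(unit_name)
        groups.setdefault(key, []).append(e)
        rep_condition.setdefault(key, e.condition)
    keys = sorted(groups, key=lambda k: tuple(-1.0 if v is None else v for v in k))
    n_cond = len(keys)

    # prepare measured densities and fixed upstream kernels once
    prepared: list[tuple[int, np.ndarray, np.ndarray, float, np.ndarray | None]] = []
    for ci, key in enumerate(keys):
        for e in groups[key]:
            measured = normalize_to_E(e.trace).density
            t = e.trace.grid.times
            step = e.trace.grid.step
            upstream = _upstream_kernel(e, known_upstream)
            prepared.append((ci, t, measured, step, upstream))

    def residuals(x: np.ndarray) -> np.ndarray:
        log_tau, log_r = x[:n_cond], x[n_cond]
        tau = np.exp(log_tau)
        r = math.exp(log_r)
        out = []
        for ci, t, measured, step, upstream in prepared:
            theta = tau[ci] / r
            model = _erlang2_delay_density(tau[ci], theta, t, step)
            if upstream is not None:
                model = _convolve(model, upstream, step)
            out.append(model - measured)
        return np.concatenate(out)

    # initial guesses: tau0 = half the empirical curve MRT, R0 = 1
    tau0 = np.empty(n_cond)
    for ci, key in enumerate(keys):
        e = groups[key][0]
        curve = normalize_to_E(e.trace)
        mrt_emp = mrt_of_curve(curve, tol=math.inf)
        tau0[ci] = min(max(mrt_emp / 2.0, TAU_BOUNDS[0] * 1.01), TAU_BOUNDS[1] * 0.99)

    lb = np.concatenate([np.full(n_cond, math.log(TAU_BOUNDS[0])), [math.log(R_BOUNDS[0])]])
    ub = np.concatenate([np.full(n_cond, math.log(TAU_BOUNDS[1])), [math.log(R_BOUNDS[1])]])

    starts = [np.concatenate([np.log(tau0), [0.0]])]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=n_cond + 1, seed=seed)
        unit_pts = sampler.random(n=n_starts - 1)
        # tau within a decade of the moment-based guess, R across 1e-2..1e3
        tau_lo, tau_hi = np.log(tau0 / 3.0), np.log(tau0 * 3.0)
        r_lo, r_hi = math.log(1e-2), math.log(1e3)
        for pt in unit_pts:
            x = np.empty(n_cond + 1)
            x[:n_cond] = tau_lo + pt[:n_cond] * (tau_hi - tau_lo)
            x[n_cond] = r_lo + pt[n_cond] * (r_hi - r_lo)
            starts.append(np.clip(x, lb + 1e-9, ub - 1e-9))

    best = None
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-10)
        except Exception:  # numerical failure of one start is not fatal
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError(
            f"{unit_name} joint fit failed to converge from any of {n_starts} starts"
        )

    sse = float(2.0 * best.cost)
    tau_hat = np.exp(best.x[:n_cond])
    r_hat = math.exp(best.x[n_cond])

    # asymptotic standard errors via the Jacobian (delta method off the log scale)
    n_res = best.fun.size
    p_free = n_cond + 1
    dof = max(n_res - p_free, 1)
    jtj = best.jac.T @ best.jac
    cov_log = (sse / dof) * np.linalg.pinv(jtj)
    se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    eps_tau = tau_hat * se_log[:n_cond]
    eps_r = r_hat * se_log[n_cond]

    per_condition = []
    for ci, key in enumerate(keys):
        params = RTDParams(
            tau_tank=float(tau_hat[ci]),
            theta=float(tau_hat[ci] / r_hat),
            r_ratio=r_hat,
            eps_tau=float(eps_tau[ci]),
            eps_r=float(eps_r),
            eps_mrt=epsilon_mrt(float(tau_hat[ci]), r_hat, float(eps_tau[ci]), float(eps_r)),
        )
        per_condition.append((rep_condition[key], params))

    return UnitFitResult(
        unit=unit_name,
        per_condition=per_condition,
        shared_r=r_hat,
        eps_r=float(eps_r),
        n_parameters=2 * n_cond + 1,
        residual_sse=sse,
        n_free_parameters=p_free,
    )


def deconvolution_sequence(
    all_experiments: Iterable[ImpulseExperiment],
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = DEFAULT_SEED,
) -> tuple[UnitFitResult, UnitFitResult, UnitFitResult]:
    """Characterize the whole line in the only feasible order: B2 -> B1 -> FF.

    Blender 2 is fitted from its own pulses; its kernel then deconvolutes the
    Blender 1 pulses; both blender kernels deconvolute the tablet (full
    system) data to isolate the feed frame.  Returns the three fit results
    in that order.
    """
    by_target: dict[str, list[ImpulseExperiment]] = {u: [] for u in UNITS}
    for e in all_experiments:
        by_target[e.target_unit].append(e)
    for unit in UNITS:
        if not by_target[unit]:
            raise DependencyError(
                f"no {unit} experiments supplied; the sequence needs all three levels"
            )
    b2 = fit_unit_joint(by_target["blender2"], n_starts=n_starts, seed=seed)
    b1 = fit_unit_joint(by_target["blender1"], [b2], n_starts=n_starts, seed=seed)
    ff = fit_unit_joint(by_target["full_system"], [b1, b2], n_starts=n_starts, seed=seed)
    return b2, b1, ff


def goodness_of_fit(result: UnitFitResult) -> pd.DataFrame:
    """Per-condition MRT and propagated goodness-of-fit table.

    Columns mirror the characterization report layout: mass flow, blade
    speed (empty for the feed frame), MRT in seconds, epsilon_MRT in seconds.
    Sorted by mass flow then speed.
    """
    rows = []
    for cond, p in result.per_condition:
        speed = cond.speed_b1 if result.unit == "blender1" else cond.speed_b2
        if result.unit == "feedframe":
            speed = None
        rows.append(
            {
                "mass_flow": cond.mass_flow,
                "blade_speed": float("nan") if speed is None else float(speed),
                "mrt": p.mrt,
                "eps_mrt": p.eps_mrt,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["mass_flow", "blade_speed"], na_position="first", ignore_index=True
    )
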