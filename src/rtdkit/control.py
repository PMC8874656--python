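"""Downstream prediction, disturbance dampability, and validation statistics.

The characterized line acts as a linear time-invariant mixing filter: the
tablet concentration is the feeder concentration convolved with the
three-unit kernel E_B1 * E_B2 * E_FF.  That single fact drives everything
here:

* prediction — convolve a 1 s feeder trace with the kernel;
* dampability — a rectangular inlet disturbance of amplitude ``a`` and
  duration ``T`` produces a peak outlet deviation of
  ``a * max_t [F(t) - F(t - T)]`` where F is the kernel CDF; the funnel
  region is the set of (a, T) pairs this keeps inside outlet limits;
* validation — RMSEP between measured tablet assay and the prediction,
  and the statistically tightened rejection limits
  ``85 + z*sqrt(RMSEP^2 + sigma_w^2)`` / ``115 - z*sqrt(...)`` (% label
  claim, z = 1.645 for a one-sided 95% confidence level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rtdkit.core import (
    ConcentrationTrace,
    EtCurve,
    RTDParams,
    TimeGrid,
    convolve_rtd,
    e_unit,
)
from rtdkit.errors import ContractError, InvalidInputError, RangeError

Z_95_ONE_SIDED = 1.645
SPEC_LOWER = 85.0  # % LC in-process specification
SPEC_UPPER = 115.0


@dataclass
class SystemKernel:
    """Composite RTD of the whole line (triple convolution) on one grid."""

    units: list[RTDParams]
    grid: TimeGrid
    kernel: EtCurve

    def settle_time(self, mass: float = 0.999) -> float:
        """Time for the kernel to pass ``mass`` of its CDF (startup span)."""
        return self.kernel.quantile(mass)


@dataclass
class DisturbanceSpec:
    """Rectangular inlet concentration disturbance: signed amplitude, duration."""

    amplitude: float  # % LC, signed
    duration: float  # seconds
    shape: str = "rectangular"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidInputError(f"duration must be > 0, got {self.duration}")
        if self.shape != "rectangular":
            raise InvalidInputError(f"only rectangular disturbances supported, got {self.shape!r}")


@dataclass
class RejectionLimits:
    """Tightened in-process rejection bounds inside the 85-115 %LC spec."""

    lower: float
    upper: float
    rmsep: float
    sigma_weight: float
    z: float = Z_95_ONE_SIDED

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidInputError(f"limits cross: lower={self.lower}, upper={self.upper}")
        if self.lower < SPEC_LOWER or self.upper > SPEC_UPPER:
            raise InvalidInputError("limits must lie inside the 85-115 %LC specification")


@dataclass
class ValidationReport:
    """Outcome of comparing measured tablet assay to the model prediction."""

    n_samples: int
    rmsep: float
    threshold: float
    samples: pd.DataFrame = field(repr=False)  # time, measured, predicted

    @property
    def passed(self) -> bool:
        return self.rmsep <= self.threshold


def build_system_kernel(
    b1: RTDParams, b2: RTDParams, ff: RTDParams, grid: TimeGrid
) -> SystemKernel:
    """Compose the full-line kernel E_B1 * E_B2 * E_FF on the given grid."""
    total_delay = b1.theta + b2.theta + ff.theta
    if total_delay > grid.end:
        raise RangeError(
            f"grid end {grid.end} s is shorter than the total delay {total_delay} s"
        )
    kernel = convolve_rtd(convolve_rtd(e_unit(b1, grid), e_unit(b2, grid)), e_unit(ff, grid))
    return SystemKernel(units=[b1, b2, ff], grid=grid, kernel=kernel)


def predict_downstream(
    feeder: ConcentrationTrace,
    kernel: SystemKernel | EtCurve,
    mask_startup: bool = True,
) -> ConcentrationTrace:
    """Predict outlet concentration by causal convolution with the kernel.

    The normalized kernel has unit gain: a constant feeder concentration is
    reproduced unchanged once the startup transient has passed.  By default
    the startup window (before the kernel has passed 99.9% of its mass) is
    masked to NaN, since the convolution there still depends on unknown
    pre-trace history; pass ``mask_startup=False`` to keep it.
    """
    e = kernel.kernel if isinstance(kernel, SystemKernel) else kernel
    if not math.isclose(feeder.grid.step, e.grid.step, rel_tol=1e-9):
        raise ContractError(
            f"feeder step {feeder.grid.step} s != kernel step {e.grid.step} s"
        )
    out = np.convolve(feeder.value, e.density)[: feeder.grid.n_points] * feeder.grid.step
    if mask_startup:
        settle = e.quantile(min(0.999, e.cdf()[-1]))
        out[feeder.grid.times < feeder.grid.times[0] + settle] = np.nan
    return ConcentrationTrace(feeder.grid, out)


def max_outlet_deviation(kernel: SystemKernel | EtCurve, disturbance: DisturbanceSpec) -> float:
    """Peak outlet deviation (% LC) caused by a rectangular inlet disturbance.

    For a linear time-invariant mixing system the outlet response to a
    rectangular pulse of amplitude a and duration T is
    a * [F(t) - F(t - T)]; its peak over t is the largest kernel-CDF mass
    captured by any window of width T.
    """
    e = kernel.kernel if isinstance(kernel, SystemKernel) else kernel
    t = e.grid.times
    F = e.cdf()
    F_shift = np.interp(t - disturbance.duration, t, F, left=0.0)
    window_mass = float(np.max(F - F_shift))
    # a window wider than the grid span captures all remaining mass
    window_mass = min(max(window_mass, 0.0), 1.0)
    return abs(disturbance.amplitude) * window_mass


def funnel_region(
    kernel: SystemKernel | EtCurve,
    amplitudes: np.ndarray,
    durations: np.ndarray,
    limits: tuple[float, float] = (95.0, 105.0),
) -> pd.DataFrame:
    """Dampability (funnel) table over an amplitude x duration grid.

    An (amplitude, duration) cell is ``inside`` when the peak outlet
    deviation keeps the outlet within ``limits`` around 100 %LC.  The region
    is monotone: it can only shrink as amplitude or duration grows.
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if amplitudes.size == 0 or durations.size == 0:
        raise InvalidInputError("amplitude and duration grids must be non-empty")
    lo, hi = limits
    margin_neg, margin_pos = 100.0 - lo, hi - 100.0
    rows = []
    for a in amplitudes:
        for T in durations:
            if a == 0:
                dev, inside = 0.0, True
            else:
                dev = max_outlet_deviation(kernel, DisturbanceSpec(a, T))
                # a signed amplitude only pushes the outlet one way
                inside = dev <= (margin_pos if a > 0 else margin_neg)
            rows.append({"amplitude": a, "duration": T, "deviation": dev, "inside": inside})
    return pd.DataFrame(rows)


def rmsep(measured, predicted) -> float:
    """Root mean squared error of prediction, in % LC."""
    x = np.asarray(measured, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ContractError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise InvalidInputError("need at least one sample")
    return math.sqrt(float(np.mean((x - y) ** 2)))


def rejection_limits(
    rmsep_acceptance: float, sigma_weight: float = 0.0, z: float = Z_95_ONE_SIDED
) -> RejectionLimits:
    """Statistically tightened rejection limits inside the 85-115 %LC spec.

    lower = 85 + z*sqrt(RMSEP^2 + sigma_w^2); upper mirrored about 100 %LC.
    sigma_weight is the tablet-weight variability contribution; it defaults
    to 0 and should be configured from product data.
    """
    if rmsep_acceptance < 0 or sigma_weight < 0:
        raise InvalidInputError("rmsep and sigma_weight must be >= 0")
    width = z * math.sqrt(rmsep_acceptance**2 + sigma_weight**2)
    half_spec = (SPEC_UPPER - SPEC_LOWER) / 2.0
    if width >= half_spec:
        raise InvalidInputError(
            f"tightening term {width:.2f} %LC makes the limits cross; "
            "the model error is too large for the specification"
        )
    return RejectionLimits(
        lower=SPEC_LOWER + width,
        upper=SPEC_UPPER - width,
        rmsep=rmsep_acceptance,
        sigma_weight=sigma_weight,
        z=z,
    )


def apply_rejection(predicted: ConcentrationTrace, limits: RejectionLimits) -> pd.DataFrame:
    """Flag every time point whose predicted concentration breaches the limits.

    NaN predictions (masked startup) are never flagged.
    """
    v = predicted.value
    with np.errstate(invalid="ignore"):
        reject = (v < limits.lower) | (v > limits.upper)
    reject &= np.isfinite(v)
    return pd.DataFrame(
        {"time_s": predicted.grid.times, "predicted": v, "reject": reject}
    )
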