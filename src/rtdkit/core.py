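"""Residence-time-distribution mathematics.

A residence time distribution E(t) is the probability density of the time
material spends inside a mixing unit.  Each blending unit of the line is
modeled as a plug-flow delay ``theta`` followed by two equal ideally mixed
tanks of mean time ``tau`` (an Erlang-2 density shifted by the delay):

    E(t) = (t - theta) * exp(-(t - theta)/tau) / tau**2    for t >= theta

The mean residence time (MRT) of the unit is ``theta + 2*tau``; with the
tank-to-delay ratio ``R = tau/theta`` held constant across operating
conditions, ``MRT = tau*(2 + 1/R)``, which lets MRT and R be inverted back
to (tau, theta).

All curves live on a uniform time grid.  Integrals (normalization, first
moment) use the trapezoid rule on that grid; convolution is the direct
discrete convolution scaled by the step and renormalized to absorb
truncation loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from rtdkit.errors import ContractError, InvalidInputError, RangeError

logger = logging.getLogger(__name__)

#: default normalization tolerance for analytically normalized curves
TOL_ANALYTIC = 1e-6
#: looser tolerance for curves truncated on a finite grid
TOL_NUMERIC = 1e-3


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid: ``start + step * [0 .. n_points-1]`` seconds."""

    start: float
    step: float
    n_points: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise InvalidInputError(f"grid step must be > 0, got {self.step}")
        if self.n_points < 2:
            raise InvalidInputError(f"grid needs >= 2 points, got {self.n_points}")

    @property
    def times(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    @property
    def end(self) -> float:
        return self.start + self.step * (self.n_points - 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeGrid):
            return NotImplemented
        return (
            math.isclose(self.start, other.start, rel_tol=0, abs_tol=1e-12)
            and math.isclose(self.step, other.step, rel_tol=1e-12)
            and self.n_points == other.n_points
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass
class EtCurve:
    """A residence-time probability density sampled on a uniform grid (1/s)."""

    grid: TimeGrid
    density: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.grid.n_points,):
            raise ContractError(
                f"density length {self.density.shape} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if np.any(self.density < -1e-12):
            raise InvalidInputError("E(t) density must be non-negative")
        self.density = np.clip(self.density, 0.0, None)

    def integral(self) -> float:
        """Trapezoid integral of the density over the grid."""
        return float(np.trapezoid(self.density, dx=self.grid.step))

    def normalized(self) -> "EtCurve":
        total = self.integral()
        if total <= 0:
            raise InvalidInputError("cannot normalize a zero-mass curve")
        return EtCurve(self.grid, self.density / total)

    def cdf(self) -> np.ndarray:
        """Cumulative distribution F(t) by trapezoid accumulation."""
        from scipy.integrate import cumulative_trapezoid

        return cumulative_trapezoid(self.density, dx=self.grid.step, initial=0.0)

    def quantile(self, q: float) -> float:
        """Time at which the CDF first reaches ``q`` (linear interpolation)."""
        F = self.cdf()
        if not 0.0 <= q <= F[-1]:
            raise RangeError(f"quantile {q} outside reachable CDF range [0, {F[-1]:.4f}]")
        return float(np.interp(q, F, self.grid.times))


@dataclass
class ConcentrationTrace:
    """Time-stamped concentration series, in % of target label claim."""

    grid: TimeGrid
    value: np.ndarray

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != (self.grid.n_points,):
            raise ContractError(
                f"value length {self.value.shape} does not match grid "
                f"({self.grid.n_points} points)"
            )
        # NaN marks masked (startup) samples; infinities are always invalid
        if np.any(np.isinf(self.value)):
            raise InvalidInputError("concentration trace contains infinite values")


@dataclass
class RTDParams:
    """Tanks-in-series-with-delay parameters for one unit at one condition.

    tau_tank and theta are in seconds; r_ratio = tau_tank/theta is the
    dimensionless tank-to-delay ratio; mrt = theta + 2*tau_tank.  The eps_*
    fields carry the regression goodness-of-fit statistics (standard errors)
    for tau, R and the propagated MRT.
    """

    tau_tank: float
    theta: float
    r_ratio: float = field(default=None)  # type: ignore[assignment]
    mrt: float = field(default=None)  # type: ignore[assignment]
    eps_tau: float = 0.0
    eps_r: float = 0.0
    eps_mrt: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_tank <= 0:
            raise InvalidInputError(f"tau_tank must be > 0, got {self.tau_tank}")
        if self.theta < 0:
            raise InvalidInputError(f"theta must be >= 0, got {self.theta}")
        if self.r_ratio is None:
            self.r_ratio = self.tau_tank / self.theta if self.theta > 0 else math.inf
        elif self.theta > 0 and not math.isclose(
            self.r_ratio, self.tau_tank / self.theta, rel_tol=1e-9
        ):
            raise InvalidInputError(
                f"r_ratio {self.r_ratio} inconsistent with tau/theta = "
                f"{self.tau_tank / self.theta}"
            )
        expected_mrt = self.theta + 2.0 * self.tau_tank
        if self.mrt is None:
            self.mrt = expected_mrt
        elif not math.isclose(self.mrt, expected_mrt, rel_tol=1e-9):
            raise InvalidInputError(
                f"mrt {self.mrt} inconsistent with theta + 2*tau = {expected_mrt}"
            )

    def to_dict(self) -> dict:
        return {
            "tau_tank": self.tau_tank,
            "theta": self.theta,
            "r_ratio": self.r_ratio,
            "mrt": self.mrt,
            "eps_tau": self.eps_tau,
            "eps_r": self.eps_r,
            "eps_mrt": self.eps_mrt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RTDParams":
        return cls(**{k: d[k] for k in (
            "tau_tank", "theta", "r_ratio", "mrt", "eps_tau", "eps_r", "eps_mrt"
        ) if k in d})


@dataclass
class GeneralTwoTankParams:
    """Unequal two-tank model parameters (tau1 > tau2 > 0, delay theta)."""

    tau1: float
    tau2: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau1 > self.tau2 > 0:
            raise InvalidInputError(
                f"requires tau1 > tau2 > 0, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.theta < 0:
            raise InvalidInputError(f"theta must be >= 0, got {self.theta}")


# ---------------------------------------------------------------------------
# operations


def default_grid(theta_total: float, tau_total: float, step: float = 1.0) -> TimeGrid:
    """Grid spanning ``theta_total + 15 * tau_total`` from t=0.

    The 15-tau extent keeps truncated Erlang-2 tail mass below 1e-4.
    """
    span = theta_total + 15.0 * tau_total
    n = max(int(math.ceil(span / step)) + 1, 2)
    return TimeGrid(0.0, step, n)


def normalize_to_E(
    trace: ConcentrationTrace,
    baseline: float | None = None,
    baseline_window: int | None = None,
) -> EtCurve:
    """Transform a concentration trace C(t) into the density E(t).

    E(t) = C(t) / integral(C); optionally a constant baseline (given
    explicitly or as the mean of the first ``baseline_window`` pre-pulse
    samples) is subtracted first.  Baseline handling is off by default.
    """
    values = trace.value.astype(float)
    if baseline is None and baseline_window is not None:
        baseline = float(np.mean(values[:baseline_window]))
    if baseline is not None:
        values = values - baseline
    values = np.clip(values, 0.0, None)
    total = float(np.trapezoid(values, dx=trace.grid.step))
    if total <= 0:
        raise InvalidInputError(
            "trace integrates to <= 0 after baseline handling; cannot form E(t)"
        )
    return EtCurve(trace.grid, values / total)


def mrt_of_curve(e: EtCurve, tol: float = TOL_NUMERIC) -> float:
    """Mean residence time: first moment of E(t) by trapezoid quadrature."""
    total = e.integral()
    if abs(total - 1.0) > tol:
        raise ContractError(
            f"E(t) not normalized (integral {total:.6f} deviates by more than {tol})"
        )
    return float(np.trapezoid(e.grid.times * e.density, dx=e.grid.step))


def e_pfr(theta: float, grid: TimeGrid) -> EtCurve:
    """Plug-flow (pure delay) density: a discrete Dirac delta at t=theta.

    The unit mass is apportioned linearly between the two grid nodes
    bracketing theta so the discrete first moment equals theta exactly;
    this keeps MRT additivity exact under convolution on coarse grids.
    """
    if theta < 0:
        raise InvalidInputError(f"theta must be >= 0, got {theta}")
    if theta > grid.end:
        raise RangeError(f"theta={theta} s lies beyond the grid end {grid.end} s")
    pos = (theta - grid.start) / grid.step
    j = int(math.floor(pos))
    frac = pos - j
    # trapezoid quadrature weight of each node (halved at the grid edges)
    def w(i: int) -> float:
        return grid.step / 2.0 if i in (0, grid.n_points - 1) else grid.step

    density = np.zeros(grid.n_points)
    density[j] = (1.0 - frac) / w(j)
    if frac > 0 and j + 1 < grid.n_points:
        density[j + 1] = frac / w(j + 1)
    return EtCurve(grid, density)


def e_cstr(tau: float, grid: TimeGrid) -> EtCurve:
    """Single ideally mixed tank: exponential density exp(-t/tau)/tau."""
    if tau <= 0:
        raise InvalidInputError(f"tau must be > 0, got {tau}")
    t = grid.times
    density = np.exp(-np.maximum(t, 0.0) / tau) / tau
    density[t < 0] = 0.0
    return EtCurve(grid, density).normalized()


def e_unit(params: RTDParams, grid: TimeGrid) -> EtCurve:
    """Equal-two-tank model with delay: shifted Erlang-2 density.

    density = (t - theta) * exp(-(t - theta)/tau) / tau**2 for t >= theta.
    """
    theta, tau = params.theta, params.tau_tank
    if theta > grid.end:
        raise RangeError(f"theta={theta} s lies beyond the grid end {grid.end} s")
    if grid.end < theta + 10.0 * tau:
        logger.warning(
            "grid ends at %.1f s, shorter than theta + 10*tau = %.1f s; "
            "the density is truncated and renormalized",
            grid.end,
            theta + 10.0 * tau,
        )
    t = grid.times
    s = t - theta
    density = np.where(s >= 0, np.maximum(s, 0.0) * np.exp(-np.maximum(s, 0.0) / tau), 0.0)
    density /= tau**2
    return EtCurve(grid, density).normalized()


def e_unit_general(params: GeneralTwoTankParams, grid: TimeGrid) -> EtCurve:
    """Unequal-two-tank model with delay.

    density = (exp(-(t-theta)/tau1) - exp(-(t-theta)/tau2)) / (tau1 - tau2)
    for t >= theta; the mean is theta + tau1 + tau2.
    """
    theta, tau1, tau2 = params.theta, params.tau1, params.tau2
    if theta > grid.end:
        raise RangeError(f"theta={theta} s lies beyond the grid end {grid.end} s")
    t = grid.times
    s = np.maximum(t - theta, 0.0)
    density = np.where(
        t - theta >= 0,
        (np.exp(-s / tau1) - np.exp(-s / tau2)) / (tau1 - tau2),
        0.0,
    )
    return EtCurve(grid, density).normalized()


def convolve_rtd(e1: EtCurve, e2: EtCurve) -> EtCurve:
    """Convolution of two densities on the same grid, renormalized.

    Mixing units in series compose by convolution; the MRT of the result is
    the sum of the individual MRTs (up to grid resolution).
    """
    if e1.grid != e2.grid:
        raise ContractError("convolution requires identical uniform grids")
    full = np.convolve(e1.density, e2.density) * e1.grid.step
    density = full[: e1.grid.n_points]
    return EtCurve(e1.grid, density).normalized()


def mrt_from_tau_r(tau: float, r: float) -> float:
    """MRT = tau * (2 + 1/R) for the equal-two-tank model with ratio R."""
    if tau <= 0:
        raise InvalidInputError(f"tau must be > 0, got {tau}")
    if r <= 0:
        raise InvalidInputError(f"r must be > 0, got {r}")
    return tau * (2.0 + 1.0 / r)


def params_from_mrt_r(mrt: float, r: float) -> RTDParams:
    """Invert (MRT, R) to tanks-in-series parameters: tau = MRT/(2+1/R)."""
    if mrt <= 0:
        raise InvalidInputError(f"mrt must be > 0, got {mrt}")
    if r <= 0:
        raise InvalidInputError(f"r must be > 0, got {r}")
    tau = mrt / (2.0 + 1.0 / r)
    theta = tau / r
    return RTDParams(tau_tank=tau, theta=theta, r_ratio=r)


def epsilon_mrt(tau: float, r: float, eps_tau: float, eps_r: float) -> float:
    """Propagate the fit statistics of tau and R to the MRT.

    eps_MRT**2 = (2 + 1/R)**2 * eps_tau**2 + (tau/R**2)**2 * eps_r**2
    """
    if tau <= 0 or r <= 0:
        raise InvalidInputError("tau and r must be > 0")
    if eps_tau < 0 or eps_r < 0:
        raise InvalidInputError("eps values must be >= 0")
    return math.sqrt((2.0 + 1.0 / r) ** 2 * eps_tau**2 + (tau / r**2) ** 2 * eps_r**2)
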