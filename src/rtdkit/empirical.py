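"""Empirical mean-residence-time surfaces over the operating space.

Once the unit MRTs have been regressed at the studied operating conditions,
they are summarized by empirical inverse-relationship surfaces so the MRT
(and hence the full RTD kernel) can be predicted anywhere inside the studied
region:

    blenders:    MRT(mdot, beta) = A/mdot + B/beta + C/(mdot*beta) + D
    feed frame:  MRT(mdot)       = E/mdot**2 + D

with mdot the total mass flow (kg/h) and beta the unit's impeller speed
(rpm).  Every term is inverse in the operating factors: faster flow and
faster impellers shorten the residence time.  The surfaces are linear in
their constants, so the weighted fit (weight 1/epsilon per observation,
down-weighting poorly determined MRTs) is a closed-form linear solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rtdkit.core import RTDParams, params_from_mrt_r
from rtdkit.errors import DegeneracyError, InvalidInputError, RangeError
from rtdkit.fitting import OperatingCondition

BLENDER_FORM = "blender"
FEEDFRAME_FORM = "feedframe"


@dataclass
class EmpiricalConstants:
    """Surface constants for one unit.

    Blender records carry A (s*kg/h), B (s*rpm), C (s*kg*rpm/h) and D (s);
    feed-frame records carry E (s*kg^2/h^2) and D (s) only.
    """

    unit: str
    D: float
    A: float | None = None
    B: float | None = None
    C: float | None = None
    E: float | None = None

    def __post_init__(self) -> None:
        is_blender = self.A is not None or self.B is not None or self.C is not None
        if is_blender and self.E is not None:
            raise InvalidInputError("record mixes blender (A,B,C) and feed-frame (E) constants")
        if is_blender and None in (self.A, self.B, self.C):
            raise InvalidInputError("blender records need all of A, B, C, D")
        if not is_blender and self.E is None:
            raise InvalidInputError("feed-frame records need E and D")

    @property
    def form(self) -> str:
        return FEEDFRAME_FORM if self.E is not None else BLENDER_FORM

    def to_dict(self) -> dict:
        d = {"unit": self.unit, "D": self.D}
        if self.form == BLENDER_FORM:
            d.update(A=self.A, B=self.B, C=self.C)
        else:
            d.update(E=self.E)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EmpiricalConstants":
        return cls(**{k: d.get(k) for k in ("unit", "D", "A", "B", "C", "E") if k in d})


@dataclass
class MRTObservation:
    """One regressed MRT with its goodness-of-fit, at one operating condition."""

    condition: OperatingCondition
    mrt: float
    eps: float = 1.0

    def __post_init__(self) -> None:
        if self.mrt <= 0:
            raise InvalidInputError(f"mrt must be > 0, got {self.mrt}")
        if self.eps <= 0:
            raise InvalidInputError(f"eps must be > 0 to act as a weight, got {self.eps}")


def _speed_of(condition: OperatingCondition, unit: str) -> float:
    speed = condition.speed_b2 if unit == "blender2" else condition.speed_b1
    if speed is None:
        raise InvalidInputError(
            f"condition at {condition.mass_flow} kg/h lacks the impeller speed "
            f"required by the {unit} surface"
        )
    return speed


def predict_mrt(constants: EmpiricalConstants, condition: OperatingCondition) -> float:
    """Evaluate the unit's MRT surface at an operating condition, in seconds."""
    mdot = condition.mass_flow
    if constants.form == FEEDFRAME_FORM:
        return constants.E / mdot**2 + constants.D
    beta = _speed_of(condition, constants.unit)
    return (
        constants.A / mdot
        + constants.B / beta
        + constants.C / (mdot * beta)
        + constants.D
    )


def fit_empirical(
    observations: Sequence[MRTObservation], form: str, unit: str | None = None
) -> EmpiricalConstants:
    """Weighted least-squares fit of the surface constants.

    Each residual is weighted by 1/epsilon, so MRTs with large fit
    uncertainty contribute less.  The surfaces are linear in the constants;
    the solve is closed form (scaled-design lstsq).
    """
    if form not in (BLENDER_FORM, FEEDFRAME_FORM):
        raise InvalidInputError(f"form must be '{BLENDER_FORM}' or '{FEEDFRAME_FORM}'")
    min_n = 4 if form == BLENDER_FORM else 2
    if len(observations) < min_n:
        raise InvalidInputError(
            f"{form} surface needs >= {min_n} observations, got {len(observations)}"
        )
    unit = unit or (FEEDFRAME_FORM if form == FEEDFRAME_FORM else "blender")
    y = np.array([o.mrt for o in observations])
    w = np.array([1.0 / o.eps for o in observations])
    if form == BLENDER_FORM:
        mdot = np.array([o.condition.mass_flow for o in observations])
        beta = np.array([_speed_of(o.condition, unit) for o in observations])
        X = np.column_stack([1.0 / mdot, 1.0 / beta, 1.0 / (mdot * beta), np.ones_like(mdot)])
    else:
        mdot = np.array([o.condition.mass_flow for o in observations])
        X = np.column_stack([1.0 / mdot**2, np.ones_like(mdot)])
    Xw = X * w[:, None]
    yw = y * w
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        raise DegeneracyError(
            f"design matrix for the {form} surface is rank deficient "
            "(vary more operating factors)"
        )
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    if form == BLENDER_FORM:
        return EmpiricalConstants(unit=unit, A=coef[0], B=coef[1], C=coef[2], D=coef[3])
    return EmpiricalConstants(unit=unit, E=coef[0], D=coef[1])


def rtd_params_at(
    condition: OperatingCondition, constants: EmpiricalConstants, shared_r: float
) -> RTDParams:
    """Predict the MRT surface, then invert to (tau, theta) via the shared R."""
    if shared_r <= 0:
        raise InvalidInputError(f"shared_r must be > 0, got {shared_r}")
    mrt = predict_mrt(constants, condition)
    if mrt <= 0:
        raise RangeError(
            f"predicted MRT {mrt:.1f} s is non-positive at mass_flow="
            f"{condition.mass_flow}, speeds=({condition.speed_b1}, {condition.speed_b2}); "
            "the condition lies outside the usable surface region"
        )
    return params_from_mrt_r(mrt, shared_r)


def parity_stats(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float]:
    """Parity-plot statistics: (r_squared, rmse).

    r_squared is the squared Pearson correlation between observed and
    predicted; rmse is the root mean squared difference.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InvalidInputError("observed and predicted must have equal length")
    if obs.size < 2:
        raise InvalidInputError("need at least 2 points for parity statistics")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise InvalidInputError("zero variance in observed or predicted values")
    r = np.corrcoef(obs, pred)[0, 1]
    rmse = math.sqrt(float(np.mean((obs - pred) ** 2)))
    return float(r**2), rmse
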