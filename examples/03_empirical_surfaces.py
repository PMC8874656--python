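"""Fit and evaluate the empirical MRT-vs-operating-condition surfaces.

The feed-frame MRT follows an inverse-square law in mass flow,
MRT = E/mdot^2 + D; the blenders follow A/mdot + B/beta + C/(mdot*beta) + D.
The fit weights each observation by the inverse of its goodness-of-fit
statistic, so poorly determined MRTs count less.
"""

from rtdkit import reference
from rtdkit.empirical import MRTObservation, fit_empirical, parity_stats, predict_mrt, rtd_params_at
from rtdkit.fitting import OperatingCondition

observations = [
    MRTObservation(OperatingCondition(row.mass_flow), row.mrt, row.eps)
    for row in reference.MRT_TABLE_FF.itertuples()
]
constants = fit_empirical(observations, form="feedframe")
print(f"fitted feed-frame constants: E = {constants.E:.3g} s*kg^2/h^2, "
      f"D = {constants.D:.1f} s")

observed, predicted = [], []
for obs in observations:
    pred = predict_mrt(constants, obs.condition)
    observed.append(obs.mrt)
    predicted.append(pred)
    print(f"  {obs.condition.mass_flow:5.0f} kg/h: observed {obs.mrt:6.1f} s, "
          f"surface {pred:6.1f} s")

r2, rmse = parity_stats(observed, predicted)
print(f"parity: r^2 = {r2:.4f}, rmse = {rmse:.2f} s")

# the surface plus the unit's shared ratio gives a full RTD model anywhere
p = rtd_params_at(OperatingCondition(35.0), constants, shared_r=reference.R_FEEDFRAME)
print(f"interpolated RTD at 35 kg/h: tau = {p.tau_tank:.1f} s, theta = {p.theta:.1f} s, "
      f"MRT = {p.mrt:.1f} s")
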