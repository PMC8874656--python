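"""Published characterization results for the reference direct-compression line.

These constants describe a commercial three-unit continuous direct-compression
rig (linear Blender 1 -> linear Blender 2 -> tablet-press feed frame) whose
residence-time behavior was characterized by tracer-impulse experiments over
15-90 kg/h total mass flow, 180-450 rpm Blender 1 impeller speed and
150-300 rpm Blender 2 impeller speed.  They serve two purposes in the toolkit:

* ground truth for the synthetic-data generator (the simulated line behaves
  like the characterized one), and
* verification fixtures for the empirical MRT surfaces.

Each MRT table row is (mass flow kg/h, impeller speed rpm, regressed MRT s,
goodness-of-fit epsilon s).  The shared tank-to-delay ratios R are constant
per unit: Blender 1 is overwhelmingly back-mixed (R >> 1) while Blender 2 and
the feed frame are transport/delay dominated (R < 1).
"""

from __future__ import annotations

import pandas as pd

#: shared tank-to-delay ratio per unit (tau_tank / theta)
R_BLENDER1 = 2.03e4
R_BLENDER2 = 0.378
R_FEEDFRAME = 0.389

#: tracer masses used for impulse experiments, grams
TRACER_MASS_B1 = 100.0
TRACER_MASS_B2 = 30.0

#: measurement characteristics: NIR blend monitoring cross-validation error,
#: % of target label claim
NIR_RMSECV = 2.6

#: studied operating ranges
MASS_FLOW_RANGE = (15.0, 90.0)  # kg/h
SPEED_B1_RANGE = (180.0, 450.0)  # rpm
SPEED_B2_RANGE = (150.0, 300.0)  # rpm

#: center-point impeller speeds used whenever a unit is not being varied
CENTER_SPEED_B1 = 315.0
CENTER_SPEED_B2 = 210.0

_B1_ROWS = [
    (15, 180, 209.0, 10.9),
    (15, 315, 198.0, 6.10),
    (15, 450, 91.0, 4.02),
    (25, 180, 106.0, 4.25),
    (25, 315, 104.0, 2.26),
    (25, 450, 66.0, 2.45),
    (50, 180, 90.5, 2.37),
    (50, 315, 74.5, 1.34),
    (50, 450, 56.6, 1.74),
    (90, 180, 70.8, 2.35),
    (90, 315, 57.0, 1.07),
    (90, 450, 39.0, 1.02),
]

_B2_ROWS = [
    (15, 150, 224.0, 12.6),
    (15, 210, 137.0, 4.84),
    (15, 300, 85.2, 3.41),
    (25, 150, 194.0, 10.3),
    (25, 210, 94.6, 2.95),
    (25, 300, 76.7, 3.16),
    (50, 150, 155.0, 6.13),
    (50, 210, 55.4, 1.67),
    (50, 300, 45.8, 1.55),
    (90, 150, 99.3, 4.17),
    (90, 210, 39.9, 1.11),
    (90, 300, 31.6, 1.02),
]

_FF_ROWS = [
    (15, None, 292.5, 22.9),
    (25, None, 145.0, 14.8),
    (50, None, 82.8, 7.05),
    (90, None, 68.5, 4.29),
]


def _table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["mass_flow", "speed", "mrt", "eps"])


#: regressed MRT and goodness-of-fit per operating condition, one table per unit
MRT_TABLE_B1 = _table(_B1_ROWS)
MRT_TABLE_B2 = _table(_B2_ROWS)
MRT_TABLE_FF = _table(_FF_ROWS)

#: empirical MRT-surface constants per unit.
#: blenders:   MRT = A/mdot + B/beta + C/(mdot*beta) + D
#: feed frame: MRT = E/mdot**2 + D
EMPIRICAL_CONSTANTS = {
    "blender1": {"A": 4.65e2, "B": 3.54e3, "C": 3.49e5, "D": 23.2},
    "blender2": {"A": -2.70e2, "B": 1.48e4, "C": 4.12e5, "D": -34.6},
    "feedframe": {"E": 5.19e4, "D": 62.1},
}
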