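# rtdkit

Residence-time-distribution (RTD) modeling and control-strategy toolkit for
continuous direct-compression pharmaceutical lines.

## The problem

A continuous direct-compression line feeds powders through two linear
blenders into a tablet-press feed frame. Because the line never stops,
quality control cannot rely on batch release: the process must *predict*
the active-ingredient (API) concentration of every tablet from upstream
feeder data and reject non-conforming material in real time. The key to
that prediction is the line's residence time distribution — the probability
density `E(t)` of the time material spends in each mixing unit.

`rtdkit` implements the full characterization and control workflow for a
three-unit line:

1. **Unit RTD models.** Each unit is a plug-flow delay `θ` followed by two
   equal ideally mixed tanks of mean time `τ` (a shifted Erlang-2 density):

   `E(t) = (t − θ) · exp(−(t − θ)/τ) / τ²` for `t ≥ θ`,

   with mean residence time `MRT = θ + 2τ = τ(2 + 1/R)` where `R = τ/θ` is
   the tank-to-delay ratio. Large `R` means back-mixing dominates; small
   `R` means the unit mostly transports.
2. **Joint impulse fitting with sequential deconvolution.** Tracer pulses
   are fitted across all operating conditions simultaneously with one `τ`
   per condition and a single shared `R` per unit, in the only feasible
   order — Blender 2 first, then Blender 1 through the known Blender 2
   kernel, then the feed frame through both (`E_B1∗E_B2`, `E_B1∗E_B2∗E_FF`).
3. **Empirical MRT surfaces.** `MRT = A/ṁ + B/β + C/(ṁβ) + D` for the
   blenders and `MRT = E/ṁ² + D` for the feed frame (`ṁ` mass flow kg/h,
   `β` impeller speed rpm), fitted by 1/ε-weighted linear least squares so
   the RTD kernel can be predicted anywhere in the studied operating region.
4. **Prediction, dampability, and rejection limits.** Downstream
   concentration is the feeder trace convolved with the composite kernel;
   funnel plots map which rectangular inlet disturbances the mixing absorbs
   to within 95–105% of label claim; validation RMSEP tightens the 85–115%
   in-process limits to `85 + 1.645·√(RMSEP² + σ_w²)` and its mirror image.

A synthetic-data module simulates tracer campaigns (blend NIR at 1 s,
composite tablet assays every 25 s) and step-change validation runs with
configurable measurement noise, so the whole workflow is exercisable and
testable without proprietary plant data.

## Worked example

Simulate Blender 2 tracer pulses at all 12 operating conditions with 2%
measurement noise and refit them jointly (`examples/02_impulse_fitting.py`):

```
shared R recovered: 0.3781 (generating value 0.378)
parameters reported: 25 (12 tank times + shared R + 12 fit statistics)

 mass_flow  blade_speed    mrt  eps_mrt
        15       150.00 224.00     0.15
        15       210.00 137.16     0.08
        ...
        90       300.00  31.66     0.01
```

The shared tank-to-delay ratio comes back within 0.1% of the generating
value, and each condition's fitted mean residence time matches the table
the campaign was generated from; `eps_mrt` is the propagated standard
error of the fitted MRT in seconds.

The other example scripts cover the unit models and MRT identities
(`01`), the empirical surfaces and their inversion to RTD parameters
(`02`, `03`), dampability funnels for slow vs fast operation (`04`), and
the 54-sample step-change validation with tightened rejection limits
(`05`). Each prints the numbers it computes and a line on what they mean.

There is also a thin CLI:

```sh
rtdkit run-all --out run1 --seed 7           # simulate -> fit -> validate
rtdkit limits --rmsep 6 --sigma-weight 0     # {"lower": 94.87, "upper": 105.13, ...}
```

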