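# blendsim

Quality-by-design (QbD) workflow and soft-sphere discrete-element (DEM)
simulator for pharmaceutical powder-blending scale-up.

Blending a low-dose drug product must deliver a homogeneous mixture —
drug content near label claim and content uniformity (CU, the %RSD of
drug content across samples) within specification — and the operating
window found at laboratory scale shifts when the batch size or blender
geometry changes. `blendsim` implements both halves of a scale-up
strategy for this problem, built around the direct-compression
amlodipine formulation (6.935 % w/w API with four excipients):

- **Statistical layer.** FMEA risk scoring (`RPN = S·P·D` on the
  {1,3,5,7,9} scale, levels low/medium/high at 82 and 246, Pareto
  threshold `729·(1−0.9) = 72.9`); Box–Behnken response-surface models
  fitted by OLS on coded factors,

  `y = b₀ + Σᵢ bᵢxᵢ + Σᵢ<ⱼ bᵢⱼxᵢxⱼ`,

  with full ANOVA (R², adjusted R², PRESS-based predicted R²),
  design-space mapping against specifications (content 95–105 %,
  CU ≤ 5 %), and a Monte-Carlo operating space keeping setpoints whose
  simulated failure probability under factor perturbation stays below
  1 % (10,000 draws).

- **Mechanistic layer.** A soft-sphere DEM engine with Hertz–Mindlin
  (no-slip) contacts — `F_n = (4/3)E*√R*·δ^{3/2}`, Mindlin tangential
  springs with Coulomb friction, restitution-tied damping, rolling
  resistance — plus JKR cohesion
  `F = −4√(πγE*)a^{3/2} + (4E*/3R*)a³` for the cohesive lubricant;
  triangle-mesh walls with prescribed rotation (V-blender, double-cone,
  drum, funnel/plate, FT4-style rheometer); virtual bulk tests (static
  and dynamic angle of repose, basic flow energy
  `E = ∫(T/(R·tanα) + F)dh`) with an iterative friction-calibration
  loop; and a blending pipeline measuring per-bin drug content, CU and
  the T-index from simulated tumbling.

See `docs/methods.md` for the models, estimators and numerical choices.

## Worked example

Fit the published 15-run blending design and predict the optimum:

```python
from blendsim.fixtures import reference_factors, reference_runs
from blendsim.rsm import fit_rsm

runs = reference_runs()
factors = reference_factors()
fit = fit_rsm(runs, "drug_content", factors,
              ["x1", "x2", "x3", "x1x2", "x2x3"])
print(fit.summary())
print("optimum:", round(fit.predict([[32, 24, 24]]), 2))
```

prints

```
Response surface fit: drug_content
  n = 15, model df = 5, residual df = 9
  R2 = 0.9829  adj R2 = 0.9733  pred R2 = 0.9274
  F = 103.25  (p = 1.143e-07)
  term         coef        SE
  intercept    94.1093    0.0690
  x1           -0.4962    0.0945
  x2           -0.9088    0.0945
  x3            0.8000    0.0945
  x1x2         -2.3700    0.1336
  x2x3          0.4225    0.1336
optimum: 96.67
```

— the drug-content model in coded factors (filling level x₁, speed x₂,
time x₃), its goodness of fit, and the predicted drug content (96.67 %)
at the optimal setting of 32 % filling, 24 rpm, 24 min.

The same stages are scriptable from the shell:

```sh
blendsim doe-fit runs.csv --response drug_content --terms x1,x2,x3,x1x2,x2x3
blendsim ospace runs.csv --pin-time 24 --out surface.csv
blendsim calibrate --static-angle 32 --mu-s 0.3 --mu-r 0.1
blendsim blend --particles 2000 --revolutions 6
blendsim run --config run.yaml
```

A miniature blending demonstration (a few thousand particles in a
scaled V-blender) is in `blendsim.fixtures.mini_scene("v_blender")`;
`blendsim.blending.t_index_series` reports mean drug content and CU per
revolution, showing CU falling from the segregated start toward the
sampling floor.

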