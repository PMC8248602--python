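# Methods

This note records the modeling assumptions, defaults and numerical
choices behind `occmot`, and what the synthetic validation does and does
not establish about real data.

## Study design being modeled

The package targets a within-subject pharmacology design: dopamine
D1-like or D2-like receptors are blocked systemically (e.g. SCH23390;
haloperidol or raclopride), blockade is quantified as PET receptor
occupancy against a no-drug baseline, and motivation is read out in two
cued bar-release tasks. In the reward-size task a cue announces 1, 2, 4
or 8 drops of water; in the work/delay task a cue announces the
remaining cost — 0, 1 or 2 additional instrumental trials (workload) or
a duration-matched delay (0.3, 3.6 or 7.2 s) — for a fixed reward.
A release inside the (200, 1000] ms window after the go signal is
correct; releases at or before 200 ms (or before the go signal) are
early errors and failures to release within 1 s are late errors. Both
error types are treated as refusals — the animal declining the offer —
and their per-cell rate `E` is the motivational measure. Within each
session, trials preceding the first success are discarded (impatient
session openings), then refusals and presentations are counted per
(monkey, session, condition, trial type, level) cell; an empty cell is
reported as missing, never as a zero rate.

## PET kinetics

**SRTM.** One-tissue-compartment kinetics with a reference region
devoid of specific binding gives
`C_t = R1·C_r + (k2 − R1·k2a)·C_r ⊗ e^(−k2a·t)`, `k2a = k2/(1+BP_ND)`.
Assumptions inherited from the model: identical non-displaceable
distribution volume in target and reference, one effective tissue
compartment, no blood-volume term.

**Basis-function estimation.** `k2a` is scanned on a 100-point
log-spaced grid over [0.006, 0.6] /min (generous for small-molecule
antagonist tracers); at each grid point the remaining parameters are a
weighted linear least-squares solve, with frame weights proportional to
frame duration. The best grid point is refined by bounded scalar
minimization between its neighbors; a winner on the grid boundary is
flagged and warned. Convolutions use a uniform 0.05-min internal grid
with trapezoidal quadrature; measured TACs are linearly interpolated
onto that grid anchored at (0, 0), and model curves are sampled at frame
midpoints. On noiseless forward-simulated data this recovers BP_ND to
well under 1% and agrees with a direct 3-parameter nonlinear fit to
better than 10⁻³ (both are tested).

**Occupancy.** Per-region occupancy is the fractional BP_ND reduction.
For multi-region input the pipeline's headline estimate is the modified
Lassen plot — OLS of `BP_base − BP_treat` on `BP_base` with free
intercept (zero-intercept variant available), slope × 100 = occupancy,
with the OLS standard error reported — because it pools regions and is
exact under uniform blockade. The single-region fractional reduction is
reported alongside for the highest-binding (striatal proxy) region.
Estimates outside [0, 100]% are reported as computed and flagged.

**Calibration.** The Hill dose model fixes the asymptote at 100%
(complete blockade at infinite dose) and fits only ED50 by bounded least
squares; a single (dose, occupancy) anchor is inverted algebraically,
`ED50 = dose·(100−Occ)/Occ`. The washout model `Occ_day0·e^(−λ·day)` is
fit by nonlinear least squares in natural (percentage) scale — not by
log-linear OLS, which noise truncation near zero would bias — with a
log-linear fit on the positive observations used only to initialize.
A constant series returns λ = 0 exactly.

## Behavioral model families

**Reward-size family.** `E_c(R) = clip(1/(a_c·R) + e_c, 0, 1)` under
four parameter-sharing structures: (1) condition-specific `a`, no
intercept; (2) condition-specific `a`, shared `e`; (3) shared `a`,
condition-specific `e`; (4) both condition-specific. Structure #1 sets
`e ≡ 0` (the pure inverse law). The default likelihood is binomial on
pooled per-(condition, size) refusal counts — the principled choice for
rates — with BIC sample size `n` equal to total presentations; a
gaussian-on-cell-rates mode mirrors the mixed-model framing (BIC `n` =
number of cells, one extra parameter for the residual SD) and the
reports print `n` alongside BIC. Probabilities are clipped to
[10⁻⁶, 1−10⁻⁶] inside the likelihood. Optimization is bounded L-BFGS-B
from deterministic multi-starts (`a ∈ {0.5, 2, 8}`); the full model is
additionally started from each nested solution, which guarantees the
nesting inequality `logL(#4) ≥ logL(#1–#3)` at the optima. BIC ties
(Δ < 10⁻⁶) resolve to the fewer-parameter structure. The incentive
impact per condition is normalized by the control condition's value, so
control is exactly 1.

**Cost family.** `E = k_w·CU` (work) / `k_d·CU` (delay) `+ E0`, with a
single `E0` shared by the two trial types within each fitting unit — a
design constraint of the task, since a CU-0 work offer and a CU-0 delay
offer are the same offer. The nested structures differ in the grouping
of units: per condition × subject, per subject, per condition, or
pooled; each unit is an OLS fit on cell rates and the structure's BIC is
the sum over its unit fits (gaussian likelihood, 4 parameters per unit
including the residual SD). The reported parameter table always comes
from the fully grouped fits. Fitted rates outside [0, 1] at observed CU
are counted and flagged but the linear fit is retained.

**Refusal–RT relation.** Per-cell mean RT of correct trials regressed
on the cell's refusal rate, under the same kind of nested grouping
(none / subject / condition / both), BIC-summed as above, 3 parameters
per group fit. Group-specific coefficients are reported when a grouped
structure wins. Structure recovery (condition-specific slopes selected
in ≥ 90% of seeded simulations) is part of the test suite.

**"Random effects" as group-specific parameters.** With a handful of
treatment conditions, a Gaussian random-effect marginal likelihood and
per-group ML parameters give practically indistinguishable selection
surfaces, so the package implements the latter only, counting each
group-specific parameter in the BIC penalty. This keeps every family a
transparent bounded-ML problem; a quadrature-based marginal mode was
considered and deliberately omitted.

## Synthetic-data generator

The generator exists so that every estimator is exercised against known
truth; its defaults are the study conditions above.

- **TACs.** The reference curve is the closed-form convolution of a
  gamma-variate plasma input `A·t·e^(−t/τ)` (A = 400 kBq/mL/min²,
  τ = 0.7 min) with a two-exponential tissue response
  (0.18·e^(−0.30t) + 0.035·e^(−0.02t)); any smooth, realistically shaped
  curve suffices for recovery testing. Targets follow the SRTM forward
  model with condition BP_ND = baseline × (1 − blockade). Default
  regions span BP_ND 0.4–2.8 (striatal high, cortical low); the default
  schedule is a 60-min dynamic scan (4×1, 4×2, 4×4, 4×8 min frames).
  Frame noise is Gaussian, scaled to a fraction of the curve peak.
  Noise substreams are keyed by (region, blockade fraction), so a
  zero-occupancy "treatment" reproduces the baseline scan exactly — an
  identity used by the validation suite.
- **Behavior.** Refusals are independent Bernoulli draws at the model
  probability; each session presents a balanced deck (exactly
  `trials_per_cell` presentations per level, order randomized), so any
  level is equally likely at any point while cell counts stay exact.
  An optional mode repeats each refused presentation until success, as
  the task program does; aggregation counts presentations either way.
  Delay-trial reward latencies are uniform on 0.2–0.4, 3.0–4.2 or
  6.0–8.4 s by cost level. RTs on correct trials are
  `intercept + slope·E(cell) + condition offset·E + Gaussian noise`,
  clipped into the correct-release window; refused trials carry a null
  RT. No overdispersion, satiety drift, or learning across sessions is
  simulated — recovery results therefore speak to estimator
  correctness, not to robustness against those real-data features.
- **Occupancy series.** Hill or washout means plus Gaussian noise in
  percentage points, truncated to [0, 100].
- **Determinism.** One master seed per config; every stream is a
  `SeedSequence` substream keyed by stage and cell, so identical configs
  give byte-identical tables.

## Pipeline and problem sizes

`run_pipeline` chains simulate → SRTM → occupancy → Hill/washout →
behavior fits → incentive-vs-occupancy join, with provenance (config
hash, seed, versions) in the report; the config hash covers exactly the
semantic fields, and a fixed config + seed reproduces the report
payload bit-for-bit. Default problem sizes — 10 regions × 3 conditions
of PET, 5 sessions × 100 presentations/cell of reward trials, 3 × 60 of
work/delay trials, 3 replicates per occupancy design point — run the
whole pipeline in about a second while leaving every estimate's
recovery error well inside the tested tolerances; the validation suite
uses 2,000 presentations per cell where it checks MLE recovery
tolerances of ±0.2 drop⁻¹ and 100 replicate series for washout
recovery of ±2 pp.

## Known limitations

- SRTM inherits its usual biases when reference-region kinetics violate
  the one-compartment assumption; no blood-volume or partial-volume
  correction is attempted (out of scope, as is image reconstruction).
- The Hill model has no slope parameter and a fixed 100% ceiling;
  occupancy data with cooperativity or incomplete maximal blockade will
  misfit.
- Refusal aggregation assumes presentations are exchangeable within a
  cell; sequential effects (fatigue, satiety late in a session) are not
  modeled.
- Model selection among "random-effect" structures is BIC on fixed
  group-specific parameters; with many groups or few cells per group
  this approximation to a true mixed model degrades.
- Bootstrap/standard-error machinery is limited to the Lassen OLS
  standard error; parameter uncertainty for the behavioral families is
  best obtained by re-running the generator (parametric bootstrap),
  which the seeded configs make cheap.
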