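# occmot

Receptor-occupancy kinetics and cost–benefit motivation modeling for
pharmacological PET + operant-behavior studies.

`occmot` is aimed at researchers who manipulate dopamine (or other
G-protein-coupled receptor) transmission with systemic antagonists,
measure the resulting receptor blockade with dynamic PET, and quantify
its behavioral consequences in cued operant tasks. It provides, as one
tested pipeline:

1. **PET kinetics** — binding-potential estimation from time–activity
   curves with the simplified reference tissue model (SRTM), occupancy
   estimation (direct fractional reduction and the modified Lassen
   plot), and calibration of occupancy against antagonist dose (Hill)
   or days since injection (exponential washout).
2. **Behavioral model families** — refusal-rate aggregation from
   trial-level records and maximum-likelihood fits of three nested model
   families compared by BIC: the inverse reward-size model, linear
   workload/delay cost discounting, and the refusal-rate–reaction-time
   relation.
3. **Synthetic data** — generators for SRTM-consistent TACs, occupancy
   series, and Bernoulli trial records with known ground truth, so every
   estimator in the package is validated by parameter recovery.

## The models

**SRTM.** A target region's activity is written in terms of a
receptor-free reference region (cerebellum):

    C_t(t) = R1·C_r(t) + (k2 − R1·k2a)·C_r(t) ⊗ exp(−k2a·t),   k2a = k2/(1 + BP_ND)

Basis-function estimation scans a log-spaced `k2a` grid, solves a
weighted linear least-squares problem at each point, and polishes the
winner by bounded 1-D optimization.

**Occupancy.** `Occ(%) = 100·(1 − BP_treat/BP_base)` per region; across
regions with uniform blockade, the slope of the regression of
`BP_base − BP_treat` on `BP_base` (Lassen plot). Dose and time courses
are calibrated as `Occ(dose) = 100·dose/(ED50 + dose)` and
`Occ(day) = Occ_day0·e^(−λ·day)`.

**Behavior.** The refusal rate `E` (trials released too early or too
late) indexes motivation: `E = 1/(aR) + e` over reward sizes
`R ∈ {1,2,4,8}` drops, where `a` is the incentive impact of reward;
`E = k·CU + E0` over remaining cost units `CU ∈ {0,1,2}` with separate
workload (`k_w`) and delay (`k_d`) discounting slopes and one intercept
`E0` shared by both trial types. Each family is fit under nested
parameter-sharing structures ("random effects" over conditions/subjects
as group-specific ML parameters) and the structure with minimal
`BIC = p·ln(n) − 2·logL` is selected.

## Worked example

```python
from occmot import RunConfig, run_pipeline, fit_hill, predict_occupancy

# calibrate the dose–occupancy curve from one measured anchor
model = fit_hill([30.0], [57.0])        # 57% occupancy at 30 μg/kg
print(f"ED50 = {model.ed50:.2f} ug/kg")
print(f"predicted occupancy at 100 ug/kg = {predict_occupancy(model, 100.0):.1f}%")

# full synthetic study: simulate → fit PET → fit behavior → report
report = run_pipeline(RunConfig(seed=7))
print(report.occupancy_table.round(2).to_string(index=False))
print({k: round(v, 3) for k, v in report.reward_fit.normalized_a.items()})
```

prints

```
ED50 = 22.63 ug/kg
predicted occupancy at 100 ug/kg = 81.5%
condition         method  occupancy_pct  se_pct
       MO   lassen_slope          49.98     0.0
       MO per_region_eq3          49.99     NaN
       HO   lassen_slope          79.99     0.0
       HO per_region_eq3          79.99     NaN
{'CON': 1.0, 'MO': 0.691, 'HO': 0.526}
```

The half-maximal dose implied by the anchor is 22.63 μg/kg, so the
high dose is predicted to block ~81% of receptors. In the synthetic
study the moderate- and high-occupancy conditions (true blockade 50%
and 80%) are recovered by both occupancy estimators, and the incentive
impact `a` — normalized to the control condition — drops to 0.69 and
0.53 under moderate and high blockade (generator truth: 5.4/8 = 0.675
and 4/8 = 0.5).

The same stages are scriptable from the shell:

```bash
occmot run --seed 7 --out results/demo
occmot simulate --out data/          # synthetic tables only
occmot fit-pet --tacs data/tacs.csv --ref-region cerebellum
occmot fit-behavior --trials data/trials_reward.csv --task reward_size
occmot schema --which run            # JSON schema for config files
```

## Layout

- `occmot.config` — pydantic configs; a config + seed determines every output.
- `occmot.simulate` — synthetic TACs, occupancy series, trial records.
- `occmot.kinetics` — SRTM, occupancy estimators, Hill/washout fits.
- `occmot.behavior` — trial classification, refusal aggregation, model families.
- `occmot.pipeline` / `occmot.cli` — end-to-end runs, reports, CLI.

See `docs/methods.md` for modeling assumptions, parameter defaults, and
numerical choices.
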