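# vectorplan

Temperature-driven, stage- and genotype-structured mosquito population
dynamics with genetic-biocontrol (RIDL-style) releases, plus release-schedule
optimization by deterministic and scenario-weighted stochastic nonlinear
programming — in one framework, so an optimized policy can be re-evaluated
under alternative climate scenarios ("build once, solve twice").

## What is in the box

| Module | Purpose |
| --- | --- |
| `vectorplan.thermal` | Thermal performance curves (constant / linear / quadratic / Brière), species parameter bundles, editable presets for *Aedes aegypti* and *Anopheles gambiae* |
| `vectorplan.genetics` | Genotype sets, Mendelian inheritance cube, dominant-lethal (RIDL) fitness modifiers, cube validation |
| `vectorplan.dynamics` | Egg/larva/pupa/adult ODE model per geographic node with larval density dependence, mating by male competitiveness, adult migration; adaptive (`simulate_ode`) and explicit-Euler (`rollout_discrete`) integration over daily temperature series |
| `vectorplan.decision` | The release-scheduling NLP: continuous release amounts on a weekly / bi-weekly / custom day mask, minimizing releases plus squared tracking error of wild adult females against a `psi`-scaled day-1 baseline over the policy window; deterministic (one series) and stochastic (weighted scenario set, one shared schedule) forms |
| `vectorplan.scenarios` | Synthetic daily-temperature scenarios (annual sinusoid + warming offset + seeded AR(1) noise) with probability weights, and regime presets (historic/future x median/high variability) |
| `vectorplan.config`, `vectorplan.io`, `vectorplan.cli` | YAML run configuration, CSV/JSON file formats, command-line workflow |

The optimizer and the simulator share one Euler update code path: the NLP is
solved in reduced space (states substituted by the rollout), so re-simulating
a returned schedule through `rollout_discrete` reproduces the optimizer's
states to machine precision (`verify_consistency`). Gradients are exact
adjoints of the rollout (cross-checked against batched finite differences in
the test suite). SciPy's L-BFGS-B solves bound-constrained instances; SLSQP
is used when a total-release budget is configured.

## CLI

All commands take `--config config.yaml --out OUTDIR [--seed N] [--log-level L]`.

```bash
vectorplan scenarios --config config.yaml --out out/scen     # write scenario CSVs + manifest
vectorplan simulate  --config config.yaml --out out/sim      # ODE baseline (optional --schedule)
vectorplan optimize  --config config.yaml --out out/opt      # deterministic NLP (mean scenario)
vectorplan optimize  --config config.yaml --out out/opt --stochastic   # weighted scenario set
vectorplan evaluate  --config config.yaml --out out/ev --schedule out/opt/schedule_raw.csv
```

A minimal configuration:

```yaml
species: {preset: aedes_aegypti}
genetics: {mechanism: ridl, penetrance: 1.0, release_genotype: RR}
network:
  nodes: [{name: site, K: 300.0}]
scenarios:
  t_end: 365
  generate:
    - {preset: historic_median, seed: 1}
    - {preset: historic_high,   seed: 2}
decision:
  t_end: 365
  t_0: 200        # suppression goal applies from this day onward
  psi: 0.20       # target: 20% of the day-1 wild female population
  mask: weekly    # or biweekly, or an explicit list of days
  c_max: 100000.0
solver: {maxiter: 300}
```

Every run writes a `manifest.json` (config hash, seed, package version).
Schedules are rounded to whole organisms in `schedule.csv`; raw solver values
are kept in `schedule_raw.csv`. Trajectories are tidy CSVs with columns
`(day, node, stage, genotype_female, genotype_male_or_NA, count)`; day
indexing is 1-based throughout.

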