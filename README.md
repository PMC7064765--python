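# mucodyn

Temperature-forced, network-coupled dynamics of coral surface-mucus-layer
microbiomes.

The package couples three pieces:

1. **Dynamic model** (`mucodyn.model_core`): a multi-taxon logistic ODE
   system in which each taxon's growth rate is a Gaussian function of a
   sinusoidally varying seawater temperature, all taxa compete for one
   shared carrying capacity, and pairwise interaction coefficients
   modulate net growth.
2. **Network inference** (`mucodyn.network_inference`): pairwise Spearman
   co-occurrence networks over taxon abundance profiles, thresholded at
   |rho| >= 0.7 and p <= 0.001, with eigenvector/betweenness centrality,
   unweighted diameter and component summaries. The retained signed
   correlations are the interaction coefficients fed into the ODE model.
3. **Scenario grid and validation** (`mucodyn.scenario_engine`,
   `mucodyn.validation_stats`): the six {specific, generalized network} x
   {specific, generalized, constant temperature} scenarios per reef zone
   (12 runs), each compared against observed composition by OLS of
   fourth-root transformed relative abundances plus a joint Wald F-test
   of slope = 1, intercept = 0.

Supporting modules: `mucodyn.community_metrics` (fourth-root transform,
Bray-Curtis, SIMPER decomposition, the 1% mean-abundance class filter),
`mucodyn.synthetic_data` (Gaussian-copula compositional tables with
planted rank-correlation blocks, growth-parameter tables, paired
validation vectors) and `mucodyn.io` / `mucodyn.cli`.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: analytic
forcing facts, closed-form/brute-force oracle equivalences (logistic
integration, Spearman, centralities, diameter, Bray-Curtis, SIMPER),
property suites, and planted-structure recovery on synthetic data.

## CLI

```bash
# synthetic fixtures: a 6x17 percentage table with a planted block
mucodyn --seed 1 synth --n-samples 6 --n-taxa 17 --block 0,1,2:0.95 \
    --out-table inner.csv --out-growth growth.csv

# co-occurrence network + summaries
mucodyn network inner.csv --out-edges edges.csv --out-summary summary.csv

# one integration of the dynamic model
mucodyn simulate --growth growth.csv --mean-temp 24 --amplitude 7 \
    --years 3 --out trajectory.csv

# the full 12-run scenario grid
mucodyn scenarios --inner inner.csv --outer outer.csv \
    --growth growth.csv --out report.csv

# regression + Wald identity test on paired vectors
mucodyn validate --observed obs.txt --predicted pred.txt --out val.json
```

All subcommands accept a YAML `--config` (keys mirror
`mucodyn.scenario_engine.SolverConfig`: carrying capacity, initial
conditions, years simulated, sampling day, solver tolerances, threshold
parameters, thermal-response form) and a global `--seed`.

## Conventions and defaults

- The thermal response integrates to `r_max` over all temperatures (it
  is `r_max` times a Gaussian density); set `response: peak` to make
  `r_max` the literal peak rate instead.
- The forcing phase is chosen so the annual minimum falls on day 45
  (mid-February); configurable.
- Carrying capacity defaults to 100 so abundances read as percent of
  capacity; initial conditions default to equal abundances totaling k/2.
- Scenario runs integrate 3 years and report composition on day-of-year
  150 of the final year.
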