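# policyfx

Bayesian state-year panel estimation of policy effects on mortality counts.

The package implements a full pipeline for evaluating state firearm-policy
effects on annual death counts:

1. **Law coding** (`policyfx.policy_coding`) — converts law effective-date
   records into state-year **exposure** fractions (share of the calendar year
   a law is in force) and **phase-in** covariates (linear ramp reaching 1 five
   years after implementation), for 10 policies grouped into 6 classes and
   higher-level combinations.
2. **Model core** (`policyfx.model_core`) — negative-binomial counts with a
   log-population offset, year effects, 5 confounder + 23 other covariates,
   and first/second-order autoregression on lagged log death rates with
   *counterfactually adjusted* lags, so a fully phased-in policy shifts the
   equilibrium log rate by exactly its total effect θ.
3. **Inference** (`policyfx.inference`) — informative policy priors (zero-mean
   normal on each total log-IRR with a 95% band of IRR 0.82–1.22, split
   equally between instant and slope coefficients), a bayesian lasso on the 23
   non-confounder covariates, and a built-in No-U-Turn sampler with dense
   mass-matrix adaptation, split-R̂/ESS diagnostics, and byte-reproducible
   seeding. An `uninformative` prior mode is available as a config switch.
4. **Effects** (`policyfx.effects`) — per-draw combination of policy
   coefficients into class/combination log effects, summarized as median IRRs
   with equal-tailed 80%/95% credible intervals and the posterior probability
   of reduced deaths; effect-versus-time curves; deaths-averted translation.
5. **Synthetic data** (`policyfx.synthetic_data`) — forward-simulates panels
   from the same model family with AR(1) covariates and policy adoption
   driven by a logistic hazard on a confounder (confounded by construction),
   with serializable ground truth.
6. **Evaluation** (`policyfx.evaluation`) — simulation-based calibration,
   parameter recovery, and the debiased-versus-naive attenuation experiment,
   emitting reproducible JSON reports.

Real mortality/law/covariate data are not bundled; the pipeline ingests them
as CSV panels with the documented column layout.

## CLI

All stages are exposed under one entry point:

```sh
# expand law records into exposure/phase covariates
policyfx code-laws --laws laws.csv --years 1979:2019 --out policy.csv

# generate a synthetic panel with known ground truth
policyfx simulate --config sim.yaml --seed 1 \
    --out-panel panel.csv --out-laws laws.csv --out-truth truth.json

# fit the model (draws as tidy CSV, diagnostics as a sidecar CSV)
policyfx fit --panel panel.csv --laws-panel policy.csv --config model.yaml \
    --outcome total --seed 1 --out draws.csv

# combine draws into reported quantities
policyfx summarize --draws draws.csv --t 5 --out summary.csv
policyfx curve --draws draws.csv --combo most_restrictive --grid 0:6:0.25 \
    --out curve.csv

# calibration / attenuation experiment harness
policyfx recover --mode calibration --config eval.yaml --seed 1 \
    --out report.json
```

`model.yaml` may contain `model:` (outcome, analysis_years, horizon,
continuity, lag_center, covariate column names), `priors:` (mode plus either
`sigma_total` or `irr_lower`/`irr_upper`/`mass`, and nuisance scales), and
`mcmc:` (chains, warmup, draws, target_accept) sections; all have defaults.

## Panel CSV layout

One row per state-year: `state, year, population, deaths_total`
(optionally `deaths_suicide`, `deaths_homicide`), 5 confounder columns
(`gun_ownership, political_control, violent_crime_rate, incarceration_rate,
income_inequality`) and 23 further covariate columns (`cov_01..cov_23`);
column names are configurable. The panel must include two lead-in years
before the first analysis year to supply the autoregressive lags.

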