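# srmpt

Storage–retrieval multinomial processing tree (MPT) analysis of
recognition + cued-recall memory experiments.

The package decomposes memory performance into latent storage (`s`),
recognition retrieval (`r1`), guessing (`g`), and cued-recall retrieval
(`r2`) probabilities using the classic storage–retrieval MPT for a
20-target/20-distractor recognition + cued-recall test (distractor
detection identified via `d = s*r1`). It covers the full analysis chain of
a three-condition (waking rest / social media / vocabulary) between-
participants design:

- **`srmpt.model`** — EQN model files (read/write), exact category
  probabilities by branch enumeration, constraints (product substitutions,
  fixations, within/cross-group equalities), degrees-of-freedom accounting,
  and a numerical local-identifiability check. The built-in model ships as
  a packaged EQN fixture.
- **`srmpt.ml`** — aggregated maximum-likelihood fitting (logit-scale
  multi-start L-BFGS with analytic gradients from a sympy-compiled model),
  G² goodness of fit, nested ΔG² comparisons with one-tailed
  `z = sqrt(ΔG²(1))` tests, Wald and profile-likelihood CIs, and a
  closed-form inversion of the saturated model that serves as an
  independent check on the optimizer.
- **`srmpt.bayes`** — hierarchical latent-trait estimation
  (θ_ik = Φ(μ_k + δ_ik), δ_i ~ N(0, Σ), scaled inverse-Wishart prior) via an
  adaptive Metropolis-within-Gibbs sampler with conjugate and interweaving
  steps; split-chain R-hat, effective sample size, posterior-predictive
  T1/T2 checks, and posterior group differences with Bayesian p-values and
  95% credibility intervals.
- **`srmpt.behavior`** — retention and recognition scoring, MAD-based
  outlier screening (scaled or unscaled MAD), one-way ANOVA with planned
  contrasts, and noncentral-F power analysis / sample-size planning.
- **`srmpt.simulate`** — synthetic experiment generator: probit-normal
  participant heterogeneity, immediate-recall learning criterion (7/20, up
  to three study-test cycles), multinomial delayed-test counts, expected-
  frequency fixtures with largest-remainder rounding.
- **`srmpt.pipeline` / `srmpt.cli`** — end-to-end orchestration
  (simulate/load → score → exclude → ANOVA/contrasts → ML MPT → Bayes MPT →
  JSON report) with deterministic, seeded outputs.

## CLI

```bash
srmpt power --k 3 --f 0.25 --alpha 0.05 --power 0.80 --oversample 0.10
srmpt simulate --seed 1 --n 53 --out data.csv
srmpt score --input data.csv --out scores.csv
srmpt fit-ml --input data.csv --constraint 'r1[waking_rest]=r1[social_media]'
srmpt compare --input data.csv --parameter s --larger waking_rest \
      --smaller vocabulary --tail one
srmpt fit-bayes --input data.csv --condition waking_rest --chains 4
srmpt run --config config.yaml --out results/
```

Constraint syntax: `d:=s*r1` (product substitution), `g=0.5` or
`g[vocabulary]=0.5` (fixation), `r1[waking_rest]=r1[social_media]`
(equality; a bare `g=g` equates a parameter across all groups).

## Library example

```python
import srmpt

spec = srmpt.storage_retrieval_model()
records = srmpt.simulate_experiment(seed=1)
counts = srmpt.aggregate_counts(records, spec, session=1)

baseline = srmpt.fit_ml(spec, counts, constraints=["r1[waking_rest]=r1[social_media]"])
restricted = srmpt.fit_ml(spec, counts, constraints=[
    "r1[waking_rest]=r1[social_media]", "s[waking_rest]=s[vocabulary]"])
test = srmpt.compare_nested(baseline, restricted, tail="one",
                            direction=("s", "waking_rest", "vocabulary"))
print(baseline.g2, baseline.df, test.z, test.p_one_tailed)
```

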