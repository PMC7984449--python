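# pdstart

Causal effect of treatment-initiation timing in early Parkinson's disease,
estimated from longitudinal observational cohort data.

## The problem

In de novo Parkinson's disease, patients and physicians often delay
dopaminergic therapy. Observational cohorts with biannual visits contain
natural variation in when treatment starts, which can be exploited to ask a
policy question: *if every patient were treated for duration d within the
first two years of follow-up, how would the mean motor outcome at years
2–4 change per additional treatment-year?*

The difficulty is **time-varying confounding**: disease severity drives both
treatment initiation (sicker patients start earlier) and later outcomes, and
severity itself evolves after treatment starts. Baseline adjustment is not
enough; comparing duration groups naively attributes the worse disease state
of early starters to the treatment itself.

`pdstart` implements and compares four estimators of the linear effect
β of +1 treatment-year on an annual outcome Y measured at horizon
h ∈ {2, 3, 4} years, restricted to patients already on treatment at h:

- **naive** — OLS of `Y_h` on duration `D` (no adjustment);
- **baseline-adjusted** — OLS of `Y_h` on `D` and `Y_0`, optionally with
  inverse-probability-of-missingness weights;
- **IPTW MSM** — a linear marginal structural model `E[Y_h(d)] = β₀ + β·d`
  fit by weighted least squares with stabilized weights
  `sw = Π_t [num_t / den_t]`, where `den_t = P(start at t | L_{t−0.5})` from
  per-visit (unpooled) logistic models on the previous visit's covariates,
  and `num_t` is the marginal per-visit initiation fraction;
- **parametric g-formula** — per-visit (unpooled) linear progression models
  for each time-varying score given the previous visit and current
  treatment; Monte Carlo simulation of covariate trajectories under each
  fixed-duration policy; β is the OLS slope of policy means over policy
  durations.

Treatment duration follows the preceding-period convention: treatment
recorded at visit t covers (t − 0.5, t], so duration within 2 years is
0.5 × (number of treated visits in (0, 2]). Uncertainty comes from a
patient-level bootstrap (resample whole trajectories, refit everything,
report point ± 2 SD).

A synthetic cohort generator provides panels with the same structure —
confounded monotone initiation, additive per-treated-year effects on a
progressing severity score, outcome missingness — and a known ground-truth
effect, plus an exhaustive-enumeration oracle on discrete toy processes for
exact verification of the g-formula.

## Worked example

```python
from pdstart import (DGPConfig, simulate_cohort, apply_missingness,
                     fit_naive, fit_iptw_msm, fit_gformula, bootstrap_estimate)

cfg = DGPConfig(n_patients=2000, seed=1)     # true effect: -1.5 per treatment-year
panel, truth = simulate_cohort(cfg)
panel = apply_missingness(panel, cfg, seed=2)

print(fit_naive(panel, horizon=2).effect_per_year)
print(fit_gformula(panel, horizon=2, seed=3).effect_per_year)
boot = bootstrap_estimate(panel, "iptw_msm", horizon=2, repeats=200, seed=4)
print(boot.point, boot.interval)
```

prints (motor-score points per +1 treatment-year; negative = benefit):

```
2.3619   # naive: confounding masquerading as harm
-1.5523  # g-formula: recovers the true -1.5
-1.858 (-3.6014, -0.1145)  # IPTW point and +/-2 SD bootstrap interval
```

The naive contrast is strongly positive (early starters are sicker), while
both causal estimators recover the simulated benefit.

The same pipeline runs from the shell:

```bash
pdstart simulate --n 2000 --seed 1 --out-panel panel.csv --out-truth truth.json
pdstart estimate --panel panel.csv --seed 2 --method naive --method iptw_msm \
    --horizon 2 --out estimates.tsv
pdstart run --config examples/run.yaml   # simulate -> estimate -> bootstrap -> plot
```

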