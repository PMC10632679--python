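# metacog

Local and global metacognition across the adult lifespan: a tested,
end-to-end reimplementation of a staircased two-alternative forced-choice
(2AFC) confidence study and its full analysis battery — type-2 signal
detection, hierarchical Bayesian group inference, and the age-regression
suite — runnable entirely on synthetic cohorts.

## Who this is for

Researchers studying metacognition (the ability to evaluate one's own
decisions) who want to

* simulate realistic staircased confidence experiments in two cognitive
  domains (short-term memory and perceptual discrimination),
* estimate **metacognitive efficiency** (meta-d'/d', the "M-ratio") per
  subject by maximum likelihood and at the group level with hierarchical
  Bayesian models,
* test how local confidence bias, global self-performance estimates
  (SPEs), first-order performance, and the domain-generality of
  metacognition behave across age groups.

## The model

First-order decisions follow an equal-variance Gaussian signal detection
model: on each 2AFC trial, evidence `x ~ N(±d'/2, 1)` and the response is
given by `x` against a criterion `c`, with

```
d' = z(HR) − z(FAR),        c = −(z(HR) + z(FAR)) / 2
```

where `z` is the inverse standard-normal CDF and the left response is
designated the "signal". Confidence ratings, binned into 6 per-subject
quantiles, form the type-2 data: the counts of each (response ×
confidence) cell per stimulus class. **meta-d'** is the type-1 sensitivity
that best explains those confidence counts under the same model — fitted
by maximizing the response-conditional multinomial likelihood with the
type-1 criterion held at its fitted relative position and free ordered
type-2 criteria. An observer whose confidence uses exactly the decision
evidence has meta-d' = d' (M-ratio 1); second-order noise pushes the
M-ratio below 1.

Group-level inference places subject log M-ratios under a group normal
(per age group), a hierarchical regression on standardized covariates
(age, age², staircased-difficulty mean and SD), or a bivariate normal
across task domains whose correlation ρ quantifies domain-generality.
Posteriors are summarized by their mean and 95% highest-density interval
(HDI).

Task difficulty is controlled by a 2-down-1-up staircase (two consecutive
correct → one step harder, any error → one step easier), which converges
to ≈70.7% correct for any monotone psychometric observer.

## Worked example

```python
from metacog import (CohortConfig, PipelineConfig, run_full_pipeline,
                     sign_pattern)

cfg = PipelineConfig(cohort=CohortConfig(n_per_group=50, rng_seed=42),
                     chains=2, warmup=500, draws=1000,
                     group_fits=False, subject_mle=False, seed=42)
report = run_full_pipeline(cfg)
print(report.bias_regressions.query("covariate == 'age'")
      [["outcome", "beta", "se", "p_value"]].head(2).to_string(index=False))
print(report.posterior_summary.query("parameter == 'cross_domain_rho_all'")
      [["parameter", "mean", "hdi_lo", "hdi_hi"]].to_string(index=False))
```

prints (seed 42):

```
               outcome      beta       se  p_value
mean_confidence_memory -0.267656 0.055815 0.000003
  sd_confidence_memory  0.066630 0.057800 0.249930
           parameter     mean  hdi_lo  hdi_hi
cross_domain_rho_all 0.732414 0.59418 0.85801
```

Reading: over a 300-subject synthetic cohort, mean slider confidence in
the memory task declines with age (normalized beta −0.27, p < 0.001)
while its spread does not, and metacognitive efficiency correlates
positively across the two task domains (ρ ≈ 0.73, 95% HDI above zero) —
confidence falls with age even though the staircase holds objective
performance constant.

The same battery is available from the shell:

```bash
metacog simulate --seed 42 --out data/
metacog preprocess --in data/ --out prep/
metacog fit-subjects --counts prep/counts.csv --out fits.csv
metacog run-all --seed 42 --out report/
```

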