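# Methods

This note documents the generative model behind the synthetic cohorts, the
estimation machinery, the numerical choices, and the known limits of what
the test suite demonstrates.

## Generative model of a subject

Each synthetic subject performs two staircased 2AFC sessions (memory,
perception) of 100 trials each, gives a −100..+100 slider confidence
rating after every trial, and reports global self-performance estimates
(SPEs, 0–10 Likert) before and after each task.

**First-order decisions.** On a trial at difficulty level `L`, evidence is
`x ~ N(±d'(L)/2, 1)` with the left stimulus positive; the subject responds
"left" when `x` exceeds their criterion. The difficulty→d' laws are the
simplest monotone maps anchored at the printed starting levels:

* memory: `d' = sens_memory × (2 / set_size)` — larger memorization sets
  are harder; the staircase starts at 2 items (bounds 2–15);
* perception: `d' = sens_perception × (difference / 15)` — larger red/blue
  count differences are easier; the staircase starts at a difference of 15
  (bounds 1–30).

The staircase is 2-down-1-up: two consecutive correct responses step one
level harder, any error one level easier, clipped to the bounds, with the
consecutive-correct counter reset on every error and every step. This rule
converges to ≈70.7% correct for any monotone observer; the test suite
checks the simulated asymptote against the exact stationary distribution
of the (level × counter) Markov chain. The perception staircase follows
the canonical 2-down-1-up direction (error → easier, i.e. a larger colour
difference): the alternative reading of the task description is internally
inconsistent with a 2-down-1-up procedure.

**Confidence.** Second-order evidence is `x₂ = x + ε`, `ε ~ N(0, σ_meta)`.
Confidence derives from the signed distance of `x₂` from the criterion in
the direction of the chosen response (evidence contradicting the response
gives low confidence, as in the standard meta-d' generative family),
squashed logistically onto the slider:

```
conf = round( 200·σ(g·u) − 100 + bias ),   u = ±(x₂ − c)
```

clipped to [−100, 100]. The additive bias is applied after the squashing
so that a configured linear age trend in bias propagates approximately
linearly to mean slider confidence; `g` (conf_gain) controls how sharply
confidence saturates. Because downstream binning is rank-based, neither
bias nor gain affects efficiency estimates — they are separate,
independently recoverable characteristics, as intended.

**Metacognitive efficiency.** Efficiency is parameterised through a
target M-ratio with two complementary mechanisms. Targets below 1 use
second-order noise: the naive mapping `M = 1/√(1+σ²)` is inaccurate under
response-conditional confidence, so the implemented map
`σ(M) = √((1/M² − 1)/k)` uses the empirically calibrated constant
`k = 2.5`. Targets above 1 use first-order decision noise instead:
response jitter `δ` added to the evidence after the confidence signal is
formed degrades d' but not meta-d', producing supra-optimal efficiency
with the calibrated map `δ(M) = √((M² − 1)/k₂)`, `k₂ = 2.6`. Both maps
make the large-sample fitted M-ratio track the configured target to
within a few percent, and together they span the empirically observed
M-ratio range (roughly 0.3–2) rather than capping it at 1.
Within-session difficulty variation (the staircase bounces between
levels) inflates fitted M-ratio above the nominal target, most visibly in
the memory domain where low-sensitivity subjects sit at small set sizes
with coarse d' steps. This is a real property of staircased designs — the
same mechanism motivates including the staircase-difficulty SD as a
regression covariate — and the realized group-level M-ratios
(≈0.9–1.0 memory, ≈0.45–0.55 perception) are close to values reported for
this kind of task battery.

**Population structure.** Subject parameters are drawn per age bracket
(6 brackets × 50 subjects by default, ages 18–83): log-normal sensitivity
and confidence gain, normal confidence bias and SPE level, log-normal
M-ratio targets (memory centred at 1.0, perception at 0.55, SD 0.4 on the
log scale) truncated to [0.1, 2.5]. Cross-domain correlations are
induced by shared latent factors (efficiency ρ = 0.8, bias ρ = 0.8,
SPE ρ = 0.7) to produce the domain-generality the analysis should detect.
Default age trends: confidence bias −0.3 slider units/year and SPE −0.025
Likert units/year (declines), with sensitivity and efficiency flat in
age. These effect sizes sit at the comfortably detectable end of the
plausible range so that the qualitative conclusion pattern (declining
bias/SPE, stable performance/efficiency, positive domain-generality)
reproduces reliably across replicate cohorts rather than hovering at the
significance boundary. Response times are log-normal (median ≈1.2 s) with
a 0.0025 probability of a >30 s outlier so the exclusion stage has work
to do. One master seed fans out to per-subject streams via
`SeedSequence.spawn`; identical seeds give bit-identical cohorts.

**Direct meta-d' simulation.** For parameter-recovery work,
`simulate_metad_counts` draws confidence count tables directly from the
meta-d' model (type-1 responses from (d', c); confidence bins from the
response-conditional meta-d' distribution), with type-2 criteria at
equal-occupancy quantile positions by default — mirroring what per-subject
quantile binning feeds the estimators.

## Preprocessing

The first 20 trials per subject × domain are removed (staircase burn-in),
then any trial whose decision or confidence response time exceeds 30 s.
Subjects whose confidence never varies within a domain are excluded from
both domains. Burn-in is applied before the RT rule; the order affects
only the report's per-rule tallies, not the analyzed set. Slider
confidence is binned into 6 equal-probability quantile bins per subject ×
domain, with ties broken by stable rank order — deterministic, invariant
to monotone transforms of the slider, and maximally balanced. The
response-conditional counts per stimulus class (2 × 6 cells, left response
from highest to lowest confidence then right from lowest to highest) are
the sufficient statistic for everything downstream.

## Single-subject estimation

`fit_type1` applies the z-difference formula. Padding (1/(2·2·n_bins) per
count cell) is applied only when a hit/false-alarm rate would otherwise be
0 or 1 ("auto"), and unconditionally inside meta-d' fits, following the
convention of the standard toolbox lineage. `fit_meta_d` maximizes the
response-conditional multinomial likelihood over meta-d' and the 2×5
ordered type-2 criteria (L-BFGS-B on increment parameters; start at
meta-d' = d' with distribution-matched criteria; likelihood tolerance
below 1e−9). The type-1 criterion is held at the fitted relative position
`meta_c = (c/d')·meta-d'` — the standard identifiability constraint. The
fit is response-pooled (one M-ratio per subject × domain). AUROC2 is
computed nonparametrically by cumulating the correct/incorrect conditional
confidence distributions and integrating by trapezoids.

Numerical care: response-region and cell probabilities are computed from
tail-accurate `ndtr` calls (upper tails for the left-response side), and
conditional probabilities are normalised by the summed side mass. Naive
`1 − Φ` subtraction underflows at extreme meta-d' while cell numerators
retain denormal precision, which produces spurious conditional
probabilities ≫ 1 and runaway likelihoods.

## Hierarchical models

Three models share a subject block in which each subject contributes the
type-2 likelihood of their **raw** counts (no padding — the multinomial
handles empty cells; padded pseudo-counts placed in near-impossible cells
measurably bias meta-d' downward), with d' and c fixed at their point
estimates and the ordered type-2 criteria treated as subject-level latent
parameters (log-increment parameterisation, prior `N(log 0.5, 1.5²)`),
sampled jointly with log M-ratio:

* **group**: `log M_i ~ N(μ, σ²)`; reported group M-ratio is `exp(μ)`;
* **regression**: `log M_i ~ N(β₀ + X·β, σ²)`, X standardized per
  covariate (age² is computed from centred age — raw age and age² are
  nearly collinear over an adult age range);
* **cross-domain**: `(log M_mem, log M_per) ~ BVN` with correlation ρ.

Priors: μ, β₀, β ~ N(0, 1); σ ~ half-Normal(1); ρ uniform on [−1, 1].

The sampler is blocked Metropolis-within-Gibbs: conjugate draws for group
means/coefficients; random-walk Metropolis on log σ and atanh ρ;
vectorised elementwise random-walk updates for the conditionally
independent subject parameters, with Robbins–Monro step adaptation during
warm-up. Because the centred hierarchy has a funnel geometry, two
interweaved moves are added: a joint translation of all subject log
M-ratios with the group location, and a joint rescaling of the residuals
with the group SD (the group-normal terms cancel against the Jacobian).
These moves raise the effective sample size by an order of magnitude at
study sizes. Runs use 3 chains (2 in reduced settings), with split-R̂ and
ESS recorded for every reported parameter; R̂ > 1.1 flags the result as
unconverged. Per-group fits derive all randomness from their own seed, so
a group's posterior is bitwise independent of any other group's data.

Defaults: 1,000 warm-up + 2,000 retained draws per chain; reduced budgets
(300–1,000 draws) are used inside the test suite and the full pipeline,
chosen so each fit completes in seconds at n = 50–300 subjects while
R̂ stays near 1.

## What the tests show — and don't

Recovery tests simulate from the meta-d' model itself: group M-ratio at
the study's per-group size (50 subjects × 80 analyzed trials) recovers
0.6 and 1.0 within ±0.1 with ≈95% HDI coverage; a +0.3 SD age slope on
log M-ratio at n = 300 is detected with the HDI excluding zero. The
cross-domain correlation is tested at n = 100 subjects with long
(1,000-trial) sessions and between-subject log M-ratio SD 0.5 truncated
to [0.3, 3]: at 80-trial sessions the meta-d' information per subject
(log-scale SE ≈ 0.3) swamps realistic between-subject spread, and the ρ
posterior — correctly — widens and shrinks toward its uniform prior, so
short-session recovery of ρ to ±0.15 is not an achievable benchmark for
any estimator; the long-session setting isolates the correlation model
itself. The end-to-end check runs 20 replicate study-like cohorts
(6 × 50 subjects, 100 trials/domain) and requires the full qualitative
sign pattern in at least 18; "stable" is operationalized as no effect
that is both significant (α = 0.05) and non-negligible (|normalized
beta| ≥ 0.15).

The synthetic cohorts emulate the study design (age-stratified brackets,
staircase clamping, slider confidence, pre/post SPEs, rare slow trials,
balanced stimulus sides) but not everything about real data: no learning
or fatigue across the session, no miniblock structure or gamified
feedback effects, no lapses or response biases that drift over time, no
relationship between SPE updating and objective difficulty (available as
a config hook but off by default). Passing tests therefore
demonstrate the correctness and power of the estimation pipeline under
the stated model, not the behaviour of any particular empirical dataset.

## Degenerate inputs and edge rules

Subjects with d' ≤ 0 (below-chance responders) are rejected by the
hierarchical models — the M-ratio is undefined there. `fit_meta_d` raises
when d' = 0 exactly; non-convergence of the optimizer is flagged but
parameters are still returned. The type-2 ROC requires at least one
correct and one incorrect trial. Quantile binning requires at least as
many trials as bins and names the offending subject otherwise. HDI
computation requires two finite samples; it returns the shortest sorted
window containing ⌈mass·n⌉ samples, which is exact for unimodal samples
and degrades gracefully (zero width) for constant input.
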