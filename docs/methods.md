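# Methods

## The model

`driftprime` analyses two-choice response-time data from a 2 (prime–target
association) × 2 (category congruence) × 2 (target type) word–picture priming
experiment with a hierarchical Bayesian drift-diffusion model.

Each trial is modelled as a Wiener diffusion process with unit diffusion
coefficient: evidence accumulates from a starting point `z = w·a` between two
absorbing boundaries at 0 and `a`, with constant drift `v`, and the observed
response time is the first-passage time plus a non-decision time `t0`
(encoding + motor execution). Response coding is used: the upper boundary is
the "living" response, the lower boundary "non-living", so drift is positive
for living and negative for non-living targets.

With effect codes `A ∈ {−1,+1}` (non-associated/associated) and
`C ∈ {−1,+1}` (category-incongruent/congruent), the per-trial parameters for
person *i* on trial *j* are

```
e(ij)           = v_a(i)·A(j) + v_c(i)·C(j) + v_int(i)·A(j)·C(j)
v(ij)           = v_living(i) + e(ij)         (living targets)
                = v_nonliving(i) − e(ij)      (non-living targets)
t0(ij)          = t0(i) + t0_a(i)·A + t0_c(i)·C + t0_int(i)·A·C
```

so that both priming effects always push drift toward the *correct* boundary.
Two baseline drifts are carried (one per target type); a model variant with a
single shared baseline cannot reproduce the asymmetric drift magnitudes real
data show. An optional starting-point effect (Models 5/9) shifts `w` on the
logit scale toward the boundary matching the *prime's* category (a living
prime biases the start toward the living boundary). Coding this by prime
category rather than by the congruence code is deliberate: a `C`-coded shift
would reverse direction between target types and be confounded with drift.

Ten model variants form the comparison family, from the 5-parameter baseline
(Model 0: `a, w, v_living, v_nonliving, t0`) through single-effect models to
the full main-effects + interactions model (Model 8) and the full model plus
starting-point bias (Model 9). `driftprime models` lists them.

## Likelihood numerics

The first-passage density is evaluated by the standard pair of series
expansions of the standardized Wiener FPT density (small-time sum of Gaussian
images, large-time Fourier sine series), selecting whichever expansion needs
fewer terms at a per-term truncation tolerance of 1e−10. The upper-boundary
density is obtained from the lower-boundary one by the reflection map
(`v → −v, w → 1−w`). Accuracy is validated against adaptive quadrature
(normalization to 1 within 1e−5) and against Euler–Maruyama simulation.
`rt ≤ t0` returns −∞ log density rather than raising, so MCMC proposals
implying impossibly fast responses are rejected gracefully.

Closed forms used as independent oracles and for fast simulation:
absorption probability `P(upper) = (1 − e^{−2vaw}) / (1 − e^{−2va})`
(limit `w` at `v = 0`) and mean decision time `E[T] = (a·P(upper) − z)/v`
(limit `z(a−z)` at `v = 0`).

Two simulators are provided. The Euler reference integrates the SDE at
`dt = 1e−4 s` (configurable) with a Brownian-bridge within-step crossing
correction, which removes the leading `O(√dt)` discretization bias; paths
exceeding a 20 s cap are flagged censored, never dropped. The fast simulator
draws the boundary from the closed-form absorption probability and the
decision time by inverse-CDF lookup on a square-root-spaced grid of the exact
density (1024 points by default); the two agree in distribution
(Kolmogorov–Smirnov below the 1% critical value in the test suite).

## Hierarchy, priors, and sampling

Person-level parameters are modelled on unconstrained scales — log for
`a` and `t0`, logit for `w`, identity for drifts and effect slopes — as
`raw_ik = μ_k + σ_k·z_ik`, `z_ik ~ N(0,1)` (non-centered), with all random
effects mutually uncorrelated. Reported group means for `a`, `w`, `t0` are
the back-transformed `μ` (the group median on the natural scale); the
synthetic generator uses the same convention, so recovery checks are
self-consistent.

Priors (weakly informative, overridable via the `priors` argument):
`μ_log a ~ N(log 1.5, 0.6)` (approximating a truncated N(1.5, 1) on the
natural scale), `μ_logit w ~ N(0, 0.5)`, baseline drifts `~ N(0, 5)`,
`μ_log t0 ~ N(log 0.3, 0.5)` (approximating a truncated N(0.3 s, 0.2 s)),
all effect means `~ N(0, 0.5)`; group SDs half-normal(0.5) except all
non-decision-time SDs, half-normal(0.1). The original analysis's exact prior
table is in its supplementary material, which is not redistributed here;
these defaults are a declared approximation of "weakly informative".

Sampling is adaptive Metropolis-within-Gibbs. One sweep updates (i) each
`z` column across all persons jointly — the likelihood factorizes over
persons given the group level, so a single vectorized likelihood pass serves
per-person accept/reject decisions — (ii) each group mean, (iii) each group
log-SD, and (iv) an interweaved centered-frame step that Gibbs-updates
`μ_k` (conjugate normal) and Metropolis-updates `σ_k` at *fixed person-level
values*, then maps back to the non-centered frame. Step (iv) costs no
likelihood evaluations and is essential: for parameters the data pin down
tightly (notably `t0` and `a`), the non-centered frame alone mixes an order
of magnitude more slowly. Proposal scales adapt in batches of 50 during
warmup toward 0.44 acceptance and are frozen afterwards. The likelihood
kernel is numba-compiled.

Initialization is data-informed: per-person EZ-style moment estimates
(accuracy, RT mean/variance per target type) seed the baseline parameters,
with `t0` capped at 0.9 × the person's fastest response — starting above the
fastest RT would make the initial likelihood −∞. Non-finite initialization
triggers up to 5 jittered restarts, then fails loudly.

Defaults mirror the original analysis: 4 chains × 5000 iterations, first
half discarded, 10,000 kept draws. Convergence is summarized by split-chain
R-hat and bulk/tail ESS (via arviz) with pass thresholds R-hat < 1.01 and
ESS > 400. Per-trial non-decision time is floored at 1e−3 s if effect
combinations would drive it negative (warned, not silent).

## Model comparison

Trial-level PSIS-LOO: importance ratios are the reciprocal pointwise
likelihoods; the upper ~20% tail of log-ratios per trial is replaced by
generalized-Pareto quantiles (arviz's `psislw` performs the smoothing), and
`elpd_loo` sums the smoothed-weight predictive densities.
`LOOIC = −2·elpd_loo` (exact identity), smaller is better. The Pareto shape
`k` is reported per trial with a 0.7 warning threshold; no refit fallback is
attempted for high-`k` trials (deterministic cost — documented limitation).
Ranking SEs for ΔLOOIC come from the pointwise elpd differences.
Leave-one-out is at the trial level, matching the pointwise structure of the
likelihood.

## Synthetic data

The generator reproduces the study design exactly: default 44 participants ×
40 items (half living), each item shown once per (A, C) prime condition →
160 trials per participant, balanced cells. Group-truth defaults are the
posterior means reported for the winning model (a = 1.398, w = 0.514,
v_nonliving = −2.909, v_living = 3.030, t0 = 0.296, v_a = 0.049,
v_c = 0.264, v_int = −0.018, t0_a = −0.003, t0_c = 0.000, t0_int = −0.003).
Between-person SDs are configurable stand-ins (the study's random-effect
table is supplementary): log/logit-scale values chosen to give natural-scale
spreads of roughly SD(a) ≈ 0.28, SD(t0) ≈ 0.05 s, baseline-drift SD 0.5,
drift-slope SDs 0.05 — except 0.3 for the congruence-on-drift slope, which
showed large between-person variability — and t0-slope SDs 0.01 s. Optional
contamination (fast guesses uniform on [0.05, 0.19] s with random responses;
lapses on [3.05, 8] s) exists solely to exercise the pre-treatment stage and
is off by default.

What the generator does *not* emulate: item random effects (the diffusion
models carry none; items exist for design bookkeeping), target-repetition
learning across an item's four presentations, time-on-task dynamics,
sequential dependencies, and real contaminant structure beyond the two
stylized types. Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not robustness
to these real-data features.

A note on the design: the study describes 44 target pictures but 160
experimental trials per participant; 160 = 40 × 4, so the generator's
default is 40 items per participant.

## Pre-treatment

Two filters in fixed order. (1) Absolute bounds: RTs outside [0.2 s, 3 s]
removed, boundary values kept; percentage reported against all input trials.
(2) Per-participant Tukey fences on natural-log RT among the survivors:
values more than 1.5 IQR beyond the quartiles removed, strict comparison
(values exactly on a fence are kept), single pass (no cascading);
percentage reported against the bounds survivors. Quartiles use linear
interpolation between order statistics — the common default; the choice
moves borderline trials and is therefore configurable in spirit by filtering
manually. The log base is irrelevant to fence membership (affine on the log
scale). Error trials are included by default. Participants with fewer than 4
kept trials are left unfiltered with a warning. Participant-level exclusions
(non-completion, technical failure) are accepted as an explicit id list, not
inferred.

## Validation sizes and scaled conditions

The package's own validation runs use scaled designs chosen to keep the
suite at desk runtimes while preserving the hierarchical structure:
recovery fits use 10 participants × 80 trials with 2 chains × 1400
iterations (10 seeded replicates for the coverage check); the acceptance
script uses 16 participants × 160 trials with 2 chains × 1500 iterations;
Euler oracle comparisons use 1e5 paths at dt = 1e−4 s. All simulation-based
tolerances are expressed in Monte-Carlo standard errors and scale with these
sizes.

## Known limitations

- Random-walk-based MCMC needs more iterations per effective draw than
  gradient-based samplers; at the default (paper-scale) settings this is
  immaterial, but very short chains can under-disperse tail quantiles.
- Inter-trial variability parameters (sv, st0, sz) of the "full" diffusion
  model are deliberately absent: across-trial heterogeneity is carried by
  the hierarchy, matching the modelled family.
- No item random effects; no WAIC or alternatives to LOOIC.
- High Pareto-k trials are reported, not refitted.
- The exact priors of the original analysis are approximated (see above);
  posterior summaries on real data may differ accordingly in the tails.
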