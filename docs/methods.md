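# Methods

This note documents the models, the generative assumptions behind the
synthetic data, and the numerical and design choices the package makes.

## Task model

A session has 84 trials in 7 blocks of 12. A conditioning prefix pairs the
original high-pain cue with high heat exactly 3 times and the original
low-pain cue with low heat 2–3 times (`conditioning_low_count`, default 3).
All later trials present one of the two cues followed by either its
currently contingent heat (a reinforced trial) or the common medium heat (a
test trial). Contingencies reverse three times, before trial 7 of blocks 2,
4 and 6 ("halfway through" those blocks; trial 7 is the deterministic
choice). Instructed-group schedules carry an instruction event at each
reversal; uninstructed schedules are trial-identical with the events
removed.

Within every post-conditioning phase, each cue is reinforced on exactly
half of its presentations whenever its presentation count is even. The
generator keeps per-cue counts even wherever arithmetic allows: with the
default 6-trial conditioning prefix the four phase segments contain 12, 24,
24 and 18 test trials, split per cue as 6+6, 12+12, 12+12 and 10+8, all
even. With a 5-trial prefix the first segment has 13 trials, one cue
necessarily receives an odd count, and its reinforced count is
floor(n/2) — an exact 50% rate is arithmetically impossible there, and the
validator accepts the floor.

Ordering constraints are satisfied by seeded rejection sampling: no
(cue, heat) condition on three consecutive trials (checked across segment
boundaries), the first test segment opens with a medium trial (so the
conditioning prefix ends where designed), and after each reversal the first
occurrence of each cue is a medium trial before the new contingency is
reinforced. The study's two literal pseudorandom orders are not published;
`order_id` 1 and 2 select stored canonical seeds, which reproduces the
constraint structure deterministically — only the constraints, not the
literal sequences, affect any downstream computation.

Trial timing: 2 s cue, 6 s anticipation, 8 s heat, an 8–10 s jitter,
8 s rating period and a 4–6 s jitter; the two jitters always sum to 14 s
and onsets are spaced 48 s apart (the remaining interval is un-modeled
intertrial time).

### Contingency coding

Medium trials are coded `x_original` (+1 original-high cue, −1
original-low) and `x_current` (+1 currently-high cue). "Current" is
relative to instructed reversals in the instructed group and to
*experienced* reversals in the uninstructed group: the experienced phase
flips at the first reinforced pairing that contradicts the previous
contingency, found by a forward scan from each designed reversal.

## Learning models

All expected values live on [0, 1] with heat outcomes coded low = 0,
medium = 0.5, high = 1. Four variants:

| model | free parameters | initial values |
|---|---|---|
| `irw_fixed_init` | α, ρ | instructed: (1, 0); uninstructed: (0.5, 0.5) |
| `irw_free_init` | α, ρ, v0 | (v0, 1 − v0) |
| `rw` | α, v0 | (v0, 1 − v0); no reversal events |
| `hybrid` | ρ, η, κ | fixed-init policy; associability a0 = 1 |

The single free initial value v0 is interpreted as the original-high cue's
starting EV with the other cue at 1 − v0; this nests the fixed instructed
start (v0 = 1) and the symmetric uninstructed start (v0 = 0.5) in one
parameter.

Reversal events apply the symmetric simultaneous exchange
`(EV_a, EV_b) ← (ρ EV_b + (1−ρ) EV_a, ρ EV_a + (1−ρ) EV_b)` before the
trial's cue presentation. For uninstructed schedules the events are the
first incongruent reinforced pairings (both groups' fitted ρ are therefore
meaningful). In the hybrid model only EVs are exchanged; associability is
a per-cue attention quantity and is left untouched at reversal.

Medium trials record EV and a prediction error against r = 0.5 but do not
drive updates by default (`update_on_medium` flag available): the medium
temperature is constant, so those trials read out expectation rather than
feedback. RW-family EVs remain in [0, 1] without clipping; the hybrid's
associability-scaled step can overshoot, and its EV is clipped — whether
the original hybrid clipped or relied on κ·A ≤ 1 is not documented, and
clipping is the conservative choice (flagged for sensitivity testing).

## Fitting

For a candidate learning-parameter vector the EV trace is simulated and
pain on included medium trials (first-in-block and missing-response trials
omitted; the first trial of each block lands on a fresh skin site and is
contaminated by novelty) is regressed on [1, EV] by OLS. Because the
observation model is conditionally linear, profiling (β0, β1) out by OLS
inside the learning-parameter search is exact. The objective (residual sum
of squares, the deviance) is minimized by L-BFGS-B within the unit box
from 20 uniform random starts; the best start wins, with exact ties broken
toward the lexicographically smallest parameter vector (flat regions occur
when β1 ≈ 0). AIC is `n ln(RSS/n) + 2k` with k counting the free learning
parameters plus β0 and β1; the Gaussian noise variance is an equal
constant across models at fixed n and is omitted. RSS is floored at
machine epsilon before the log so perfect fits stay finite.

Group fits share one learning-parameter vector across subjects (summed
per-subject profiled deviance, betas per subject). The jack-knife refits
the group n times leaving one subject out; the standard error is
`sqrt(((n−1)/n) Σ (θ_(i) − mean)²)`. Group comparisons use pooled-variance
two-sample t-tests (df = n1 + n2 − 2), with the zero-variance/equal-means
degenerate case returning p = 1 by convention. The comparison can be run
on individual-subject fits or on jack-knife leave-one-out estimates; the
jack-knife route is far less noisy because α is weakly identified for
individual instructed subjects (with ρ near 1 their EVs sit at the bounds,
prediction errors vanish on reinforced trials, and α barely moves the
objective).

## Model comparison

Per-subject AIC is converted to approximate log evidence −AIC/2,
row-centered for numerical stability (per-subject constants cancel in the
posterior). Random-effects selection uses the variational Dirichlet
fixed-point iteration

    u_nk = exp(L_nk + ψ(α_k) − ψ(Σα)),  g_nk = u_nk / Σ_k u_nk,
    α_k = α0 + Σ_n g_nk,

with prior α0 = 1, convergence at max |Δα| < 1e−8 (cap 10,000 iterations,
warning and `converged=False` beyond). Expected probabilities are
α/Σα; exceedance probabilities are Monte-Carlo frequencies of being the
largest sampled model frequency over 1e6 seeded Dirichlet draws (chunked
to bound memory).

## Multilevel mediation

Per subject, three OLS regressions estimate the total effect c, path a
(cue → mediator), and paths b and c′ (mediator → pain controlling cue);
any covariates are appended to all three designs, and rank-deficient
subjects are excluded with a warning. Within each subject the OLS identity
c = c′ + a·b holds to numerical precision and is asserted in tests. The
population mediated effect is the mean of subject-level products a_j b_j,
which decomposes exactly as mean(a)·mean(b) + cov(a, b) (population-
normalized covariance) — mediation can be carried by the between-subject
covariance of the paths alone.

Significance comes from a percentile bootstrap that resamples subjects
(the exchangeable unit in the multilevel formulation) with replacement,
default 10,000 draws; two-tailed p floored at 2/(n_boot + 1). Moderated
mediation regresses each subject-level path on the centered moderator by
OLS (centering keeps the intercept equal to the overall effect). When a
mediator table carries several regions, BH FDR at q = 0.05 is applied
across regions separately per path family. The original-contingency
analysis sets X = x_original and adds x_current as a covariate to all
paths; subjects with trials in only one experienced phase have the two
codings collinear and are excluded as degenerate.

## Synthetic data

The generator inverts the assumed observation model:
`pain = β0 + β_temp·level + β_ev·EV + N(0, σ)`, with heat levels coded by
their calibrated rating targets (low 2, medium 5, high 8). Defaults —
β0 = −2, β_temp = 1, β_ev = 2, σ = 0.5 — put medium-trial ratings near 4
with a cue effect of up to 2 rating points, comparable to the magnitudes
such tasks elicit, and keep high-trial means at the scale top. Ratings are
truncated to the 0–8.5 range by default (the visual scale has "no
sensation" and "too hot" ends); with the default coefficients truncation
never binds on the medium trials used for fitting, so recovery statistics
are unaffected, and moment-checking tests disable it.

Group-level learning parameters emulate the manipulated dissociation:
instructed agents α = 0 with ρ ~ U(0.7, 1); uninstructed agents
α ~ U(0.1, 0.5) with ρ ~ U(0, 0.4). 20 subjects per group, orders 1/2
counterbalanced within group.

Mediators follow the forward model of the path regressions on included
medium trials: per subject (a_j, b_j) is bivariate normal with
configurable means, SDs and correlation; m = d1 + a_j x + noise and
y = d2 + c′x + b_j m + noise. The recorded population truth is
mean_a·mean_b + corr·sd_a·sd_b. An overlay mode adds the mediated effect
on top of an existing subject's learning-based pain so one cohort carries
both structures (path-b truth is preserved because the mediator is
independent of the learning component given x).

What the generator does *not* emulate: rating drift and anchoring,
heteroscedastic or autocorrelated noise, missing responses, the
novelty response on fresh skin sites (first-in-block trials are generated
like any other and simply masked in fitting, as in analysis), or any
physiological/hemodynamic structure in the mediators. Passing tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to these real-data features.

## Problem sizes and numerical choices

The shipped end-to-end checks use: parameter recovery at 20+20 subjects
(noise SD 0.5); fitter-vs-grid comparison on 5 subjects against a 101×101
(α, ρ) grid; model-selection consistency over 20 replications of 6+6
subject cohorts fit with all four models; mediation calibration over 500
null datasets of 36 subjects (the mediation sample size) with 1,000
bootstrap draws each. These sizes
make the whole suite run in a few minutes on one CPU while leaving the
statistical conclusions stable across seeds. All randomness flows from
explicit integer seeds (numpy `SeedSequence` expansion per stage/fold, so
adding a stage never perturbs earlier streams), and identical seeds give
bit-identical results.

## Known limitations

- The two shipped trial orders are canonical constraint-satisfying
  sequences, not the study's literal orders (which are unpublished).
- α is weakly identified for individual instructed subjects (see Fitting);
  individual-fit group tests on α are underpowered at n = 20 per group,
  and the jack-knife comparison is the recommended group-level test.
- The hybrid model's equations follow the standard associability-gated
  form; the exact variant used elsewhere may differ in whether
  associability updates on unreinforced trials (here it does not, by
  default) and in clipping.
- Exceedance probabilities carry Monte-Carlo noise (~1e−3 at the default
  1e6 draws).
- Bootstrap p-values are percentile-based; a bias-corrected variant is not
  implemented. Because subject-level a_j·b_j products are heavy-tailed, the
  percentile bootstrap of their mean is mildly anticonservative at small
  cohort sizes (measured type-I rate ≈ 0.086 at n = 20 versus ≈ 0.068 at
  the n = 36 used here); with cohorts much below ~30 subjects its p-values
  should be read accordingly.
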