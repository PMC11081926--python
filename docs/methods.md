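# Methods

`patchleave` simulates a social patch-leaving experiment and the analysis
pipeline that goes with it: an economic game in which a participant is
connected to a dictator-game partner whose sharing proportion decays over
time, decides when to disconnect, travels (8 s) to the next partner, and
does so inside 300 s blocks ("groups") whose composition sets the
opportunity cost of staying.  The package has no human data; every stage is
driven by seeded generators so that the estimators can be validated against
planted ground truth.

## 1. Task generator

**Sharing trajectories.**  A partner's proportion on trial *t* (0-based) is
`p_t = s·exp(k·t)` with `s = 0.5`; trial 0 is replaced by a uniform first
offer (bounds 0.475–0.525, or 0.47–0.53 in the S4 variant).  Variant rules
for proportions below 0.05: replaced by zero (S12), clamped to 0.05 (S3 and
S4).  S4 adds i.i.d. `N(0, 0.015)` noise to trials 1–29 before clamping and
draws each partner's decay rate from a 17-value continuum (nine fair rates
−0.075…−0.115, eight unfair rates −0.140…−0.175); S12/S3 use the two rates
−0.125 (fair) and −0.2 (unfair).

**Credits and stakes.**  S12/S3 credit values are integers in [50, 200]
whose every consecutive six-decision block sums to exactly 500 — this makes
the offered reward rate identical for fair and unfair partners, so leaving
early is always economically suboptimal.  The sampler draws six i.i.d.
uniforms, rescales to the target sum, repairs bound violations by clipping
and redistributing, and rounds by largest remainder preserving the total.
Stakes are `credits / proportion`; zero-proportion offers display a stake
drawn uniformly from [200, 2000] and share nothing.  S4 credits are
`N(400, 30)`.

**Schedules and composition.**  Decisions appear every 3.5 s (S12/S3) or
after 1 s display plus a uniform [2, 3] s jitter (S4; the jitter
distribution is unstated upstream, so uniform with the stated 2.5 s mean is
used and only the mean is contract-bearing).  Groups last 300 s with an 8 s
travel delay; every consecutive window of four partners contains 3 fair
(high generosity) or 1 fair (low generosity); effort environments (S3) are
1:1 in every pair.  Sessions hold 8 groups (S12/S3) or 10 (S4; split 5 + 5,
a symmetric assumption since the split is not printed).  Partner queues are
pre-built longer (60) than a block can consume.

## 2. Leaving model

The decision to leave is a drift-diffusion process

    dEA = (k − X(t)) dt + noise,  EA(0) = ε,  EA(t) ≥ 0,  leave when EA > θ,

with variant-specific input `X`: the current shared proportion
(fairness model), the scaled credits `a·R(t)` with `a = 0.01 ≈ 1/max(R)`
(reward model), or zero (standard model).  Parameters: threshold θ, drift
gain k, diffusion σ, starting bias ε; `dt = 0.001 s` by default.

**Noise discretization.**  A literal per-step `N(0, σ)` term at
`dt = 0.001` would integrate to a standard deviation of roughly `245·σ`
over a minute, which no threshold in the search range could contain; the
package therefore uses the Euler–Maruyama scaling (per-step s.d. `σ·√dt`),
with `noise_scaling="literal"` available for comparison.

**Exact step-averaged input.**  Each Euler step uses the exact time-average
of the piecewise-constant input over that step (not the left endpoint), so
the noiseless discrete path equals the continuous integral at every step
edge and first-passage times match the analytic segment solver to within
one `dt` even when decision onsets fall inside a step (as in the jittered
S4 schedule).  This average is parameter-free and precomputed once per
simulated partner, which is also what makes grid fitting cheap.

**Conventions.**  The accumulator resets to ε at each new partner; the
first offer is visible at connection, so `X` on `[0, first onset)` equals
the first decision's value; the zero bound is enforced by truncation;
crossings are checked after each step.  Interactions with no crossing
before the horizon (last onset + one interval) are censored and enter all
analyses at the onset of the final decision (101.5 s on the 3.5 s grid).
Session walks advance interaction time + 8 s travel until the block ends.

## 3. Fitting and model comparison

Each variant is fitted per participant and per environment by exhaustive
search over θ ∈ {1…30}, k ∈ {0.1…1.5 step 0.1}, σ ∈ {0.1…1 step 0.1},
ε ∈ {0…0.8 step 0.2} (22,500 points; a reduced 8×8×5×3 grid with 200
simulations per point serves the desk-scale recovery studies).  The score
of a grid point is the log of the asymptotic two-sample Kolmogorov–Smirnov
p-value between the observed leaving times and the point's simulated
distribution, summed over environments; p-values are floored at 1e−300
before the log.  Ties break by lexicographic grid order (θ, k, σ, ε
ascending).  Model LT distributions are simulated from the environment's
partner mixture, not from replayed individual experiences, so one simulated
grid per (variant, environment) serves every participant.  Common random
numbers are used throughout: the same partner draws and the same noise
increments across all grid points *and* across the three variants, so
likelihood differences reflect model structure rather than simulation
luck.  Variants are compared by summed BIC (`4·ln n − 2·LL` per
environment, four free parameters each) and by the proportion of
participants each variant wins.

**Top-decile refinement.**  The recovery studies run the search in its
coarse-to-fine mode: the top decile of grid points selected on one
simulated bank is re-scored on an independently simulated bank, and the
final argmax and reported likelihood come from the re-scoring.  A maximum
over ~10³ noisy likelihoods is optimistically biased, and the bias grows
with a family's distributional variety — without the refit the flexible
fairness family can outscore the standard model *on standard-generated
data* purely through selection luck.  Selecting on one sample and scoring
on another removes that optimism at the cost of one extra bank per
(variant, environment).

**Parameter identifiability.**  Threshold recovery is studied in the
σ ≤ 0.5 regime (`parameter_recovery_grid`): with larger diffusion noise in
the search range, high-θ/high-k/high-σ points generate leaving-time
distributions that are within KS distance ~0.1 of low-θ/moderate-k
distributions, and at realistic per-subject sample sizes (~40 leaving
times per environment) the observed empirical CDF is often genuinely
closer to such a ridge point than to the generating one.  This is a
property of fitting marginal LT distributions per environment with four
free parameters, not of the implementation; the methods note in
`recovery.py` and the recovery studies quantify it.

## 4. Synthetic cohorts

Cohorts draw per-participant parameters as the base values plus Normal
between-subject deviations (clipped to grid-representable ranges), a
planted threshold increase in the low-generosity environment (the
opportunity-cost effect), and zero-mean per-environment threshold jitter
(`between_subject_sd["threshold_env"]`).  The jitter gives participants
heterogeneous environment responses without any mean effect, which keeps
the random-slope structure of the analysis model non-degenerate — without
it the slope variance is exactly zero by construction and the Wald test
calibration study would sit on a boundary case.

Depression (DASS-21 subscale, range 0–42, mean 6.2, SD 5.9) and loneliness
(DGLS, range 0–6, mean 3.4, SD 1.8) scores are correlated (Gaussian copula,
default ρ = 0.5) truncated normals whose *truncated* moments are matched to
the targets by a small root solver.  One physical limit: no unimodal
truncated normal on [0, 6] can exceed the uniform-limit SD of ≈1.73, so the
loneliness SD saturates just below the instrument's reported 1.8.

**Covariate mechanism.**  The three-way pattern (stronger fairness
sensitivity among high scorers in the poor environment) is planted as a
score-proportional increase of the drift gain in the low-generosity
environment only.  This is one of several mechanisms consistent with the
observed pattern and is a modelling choice.  Its implied three-way
regression sign is *negative* under this package's coding: a higher drift
gain compresses all leaving times toward `θ/k`, flattening the
LT-versus-fairness slope in the low environment.  Tests assert that
planted sign.

S4 attention checks are modelled as three checks among the first five
partner slots of each group; a check counts only if the participant reached
that slot, and failures are Bernoulli draws at the profile's failure rate.

## 5. Behavioural statistics

Preparation order: censor substitution → participant exclusions (S12/S3:
fewer active leaves than environments; S4: attention failure fraction
strictly above 25%) → 2.5 SD within-participant, within-condition trimming
(sample SD, cells under two rows untouched) → design encoding.  Every
input row ends up exactly one of retained / excluded / trimmed.

Models are `LT ~ partner * environment + (1 + partner + environment | ID)`,
optionally crossed with a z-scored covariate.  Coding: sum-to-zero with
±0.5 scores (so a main effect is the level difference averaged over the
other factor; ±1 is selectable and halves the coefficients), environment
coded toward the low-quality setting, partner toward unfair (S12/S3) or as
the z-scored decay rate (S4, fairer = higher).  Inference fits use REML
with Wald χ² per single-df term — the `lme4` + `car::Anova` workflow this
emulates — while covariate-model BIC comparisons refit by ML.  Estimation
tries L-BFGS, BFGS and Powell in turn and falls back to a random-intercept
model only if all fail; the fallback is recorded on the results object.
Simple effects are linear contrasts of the fitted coefficients
(environment difference at each partner level, or at ±1 SD of a continuous
partner score), exact on balanced data.

## 6. Desk-scale study sizes and numerical choices

Recovery and calibration studies use `dt = 0.005 s` for both generation
and fitting (the Euler–Maruyama scaling makes the LT distribution
dt-consistent, and generation/fitting share the discretization), the
reduced grid, 20–30 subjects, ~40 leaving times per environment (about
what a real 40–50 min session yields), 4–6 groups per session, and
pre-built partner queues of 24.  The Type-I calibration uses 100
replications of 20-subject zero-effect cohorts; sign-recovery studies use
20 replications.  These sizes are the package's own desk-scale choices;
the defaults exposed by the API remain the full task (8/10 groups, 60
partners, `dt = 0.001`).

## Known limitations

- Synthetic cohorts are generated by the fairness model itself; passing
  recovery tests shows the estimators work when the model class is true,
  not that the model describes human behaviour.
- The KS-likelihood grid search cannot separate ridge-related parameter
  sets at realistic sample sizes (Section 3); threshold estimates should
  be read as distribution summaries, not point identifications.
- Scores match instrument moments only; no item-level psychometrics.
- Wald χ² inference is asymptotic in the number of participants; at 20
  subjects the environment-term Type-I error is near but not exactly
  nominal (the calibration test brackets it in [0.01, 0.10]).
- The `standard` variant can mimic either input-driven variant's marginal
  LT distribution in a single environment; discrimination rests on
  distribution shape and cross-environment structure, so subject-level
  confusion is nonzero even when cohort-level BIC ranks variants
  correctly.
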