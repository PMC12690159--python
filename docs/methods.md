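# Methods

## Task environment

The two-step environment has two stage-1 options and two stage-2 states
with two options each. The transition map is fixed within a session
(option 0 → state 0 common, option 1 → state 1 common) with
common-transition probability 0.70; there is no counterbalancing within
a session. The four reward probabilities follow independent Gaussian
random walks (per-trial sd 0.025, configurable) reflected at
[0.250, 0.750]. Only the bounds of the walk are part of the task
specification; the Gaussian-with-reflection mechanism and its step size
are the convention of the two-step literature and are exposed as
parameters. Initial reward probabilities are drawn uniformly inside the
bounds from the session RNG.

Sessions default to 200 trials in blocks of 50. Blocks are bookkeeping
only: the reward walk continues across block boundaries, and stay-
probability pairs may span them. One drift step is applied per trial
*after* the outcome, so each trial's stored probability snapshot is the
one in force when its reward was sampled; the drift step is taken on
missed trials too, keeping the walk a pure function of the trial index.

Missed responses: a missed stage-1 response aborts the trial (no
transition, no reward); a missed stage-2 response after a valid stage-1
choice records the transition but no outcome. Misses are generated by
the agents as an independent per-stage Bernoulli lapse, independent of
values.

## Agents

The hybrid agent is the standard two-system temporal-difference
formulation: stage-2 values `Q2[s, c]` are updated by
`Q2 += α (r − Q2)`; the model-free stage-1 value of the chosen option is
updated toward the observed stage-2 value (`α (Q2 − Q1)`) plus the
eligibility-weighted stage-2 prediction error (`α λ δ2`). The
model-based value is the transition-probability-weighted maximum of
stage-2 values, with the transition matrix fixed at the true 0.70/0.30
structure (the task is taught explicitly, so beliefs are not learned).
Net stage-1 values mix the two systems with weight `w` and add a
perseveration bonus κ for repeating the previous stage-1 choice; choices
are softmax with inverse temperature β at both stages, sharing β. Values
initialise at 0. Missed or outcome-less trials leave values unchanged
(the attempted stage-1 choice still updates the perseveration state).

The WSLS agent repeats its previous stage-1 choice iff that trial was
rewarded and switches otherwise, ignoring transitions; without a
completed trial in its history (including at session start) it chooses
uniformly, and it always chooses uniformly at stage 2.

Default cohort (42 subjects): controls are hybrid learners
(w = 0.5, α = 0.7, λ = 0.6, β = 5, lapse 0); the synthetic clinical
group is a low-β (0.5), lapse-prone (0.1) stand-in that produces a flat
stay pattern. This reproduces the *qualitative* group contrast (hybrid
signature vs. no signature); it is one of several parameter regimes that
could do so and is not a mechanistic claim about ADHD.

## Stay probabilities and ANOVA

A consecutive trial pair contributes to the stay table iff the earlier
trial has a valid stage-1 choice *and* outcome and the later trial has a
valid stage-1 choice; pairs failing this are dropped because either the
conditioning cell or the stay outcome is undefined. Cells with fewer
than `min_cell_count` (default 4) pairs are flagged and flagged subjects
are excluded listwise from ANOVAs by default (policy configurable:
`error` or `include`).

The 2 (group) × 2 (reward) × 2 (transition) mixed ANOVA is computed by
the per-subject contrast decomposition, which is exact for two-level
within factors: each within effect reduces to one contrast score per
subject tested against its own subject-level error stratum, and the
between effect is the one-way ANOVA of subject means. Group tests use
unweighted (Type III) marginal means, so unequal group sizes are
handled; sphericity is trivially satisfied with two-level factors, so no
correction applies. Partial eta squared is SS_effect / (SS_effect +
SS_error) within the effect's stratum — invariant to the contrast
scaling. Equivalence with the textbook split-plot sums-of-squares
partition and with an independent repeated-measures ANOVA implementation
is asserted in the test suite.

Strategy labels at α = 0.05 (two-sided): significant reward main effect
only → model-free; significant reward × transition interaction only →
model-based; both → hybrid; neither → neither.

## Questionnaire scoring and screening

SNAP-IV is scored as the item mean over 26 items (0–3); the published
group means on a 0–3 metric force item-mean rather than sum scoring, and
the control-group screening threshold ("retain if strictly below 1.8")
applies to this mean. CFS (12 items, 1–6), PSSES (25 items, 1–5) and the
SDQ emotional-symptoms / conduct-problems subscales (5 items, 0–2) are
sums. Scoring validates completeness and response ranges. Screening also
removes any participant outside ages 6–15 and logs every exclusion with
its reason.

## Mediation

All variables are standardized once (sample SD, n−1) before fitting; the
bootstrap resamples the standardized rows without re-standardizing,
matching a "standardize first, then test" protocol. The indirect effect
is the product of coefficients a·b — the identity total = direct + a·b
is asserted in tests (to machine precision), not used as the estimator.
The bootstrap is percentile-only (5000 resamples, 95% CI by default;
resample count must be ≥ 1000); bias-corrected variants are deliberately
out of scope because the original protocol names only "the bootstrap
method", and percentile is the simplest defensible default. Both
analytic OLS standard errors and bootstrap SEs are reported for every
path, since published tables of this kind are ambiguous about which they
print. Degenerate (singular) resamples are redrawn and logged; with
continuous data this is effectively unreachable. p-values are two-sided
and t-based; no multiple-testing correction is applied.

Bootstrap resampling is vectorised (batched normal equations over index
matrices, chunked to bound memory), which keeps 500-replication coverage
experiments at n = 200 × 5000 resamples within a couple of minutes on
one CPU.

## Synthetic questionnaire cohorts

Per participant the generator draws a standard-normal conduct latent C,
an ADHD latent X correlated ρ = 0.3 with C (clinical group mean shifted
by +3.2 latent SD, which then propagates through the structural paths),
a CF latent M = aX + 0.3C + e (residual sd 0.7) and outcome latents for
social self-efficacy (c′X + bM + 0.3C + e) and emotional symptoms (with
reversed-sign paths, default c′ = 0.3, b = −0.5). Default structural
paths a = −0.6, b = 0.5, c′ = −0.3 qualitatively mimic the clinical
pattern (signs and rough magnitudes), with group sizes 20/23 — they are
not calibrated to reproduce any published coefficient.

Latents are standardized by their model-implied SDs and mapped affinely
onto each instrument's range, clipping when necessary (clips are
counted and logged; the emotional-symptoms floor at 0 clips noticeably,
mirroring the floor effects of real low-symptom samples). Scores are
then integerised and split into item responses as evenly as possible
with the remainder on the first items, so re-scoring the items
reproduces every score exactly. Because the score maps are positive
affine transforms, the standardized regression paths implied by the
latent model carry over to the scores;
`PathModelSpec.implied_standardized_effects()` returns them in closed
form and is the ground truth for parameter-recovery and
bootstrap-coverage checks. What the generator does **not** emulate:
ordinal item-response processes, missing data, measurement error
distinct from the structural residuals, and non-linear floor/ceiling
behaviour beyond clipping — so passing tests demonstrate correctness of
the estimators under a well-specified linear path model, not robustness
to real questionnaire pathologies.

## Problem sizes and numerical choices

Validation experiments use: 10,000 draws for binomial checks of the
0.70 transition rate and reward rates (±1 percentage point); 100,000
drift steps for boundedness; 100 seeded cohort replications (21 agents ×
200 trials) for strategy-signature recovery with a ≥ 80% detection
criterion; n = 10,000 cohorts for path recovery within ±0.05; and 500
seeded replications (n = 200, 5000 resamples) for 93–97% bootstrap
coverage of the true indirect effect. Coverage is evaluated on the
latent columns so that the target value is exact rather than perturbed
by score clipping. Seeds derived from a user seed are drawn below 2^31.

## Known limitations

- No likelihood-based fitting of agent parameters to observed sessions;
  `w` is a generative ground truth, not an estimand.
- The mixed ANOVA supports exactly two groups and 2×2 within designs —
  the design of this paradigm — not general factorial layouts.
- The clinical-group generator parameters (both behavioral and
  questionnaire) are plausible stand-ins chosen for qualitative pattern
  matching; inferences about mechanism require real data.
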