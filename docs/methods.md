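# Methods

This note documents the models, estimation machinery, and simulation
conventions implemented in `cwcst`, together with the numerical choices and
the places where the design was genuinely open.

## Task model

The computerized Wisconsin Card Sorting Test (cWCST) is modeled as follows.
Four key cards are fixed, with key card *k* carrying the *k*-th color,
shape, and number (*k* = 1..4). A stimulus card is a triple of key-card
indices (color, shape, number); the deck holds the 24 triples with pairwise
distinct entries, so each card matches exactly three key cards on exactly
one dimension each and one key card on none. A key press therefore applies
a uniquely identifiable sorting category (color, shape, or number), or no
category at all (the unmatched key). Feedback is +1 when the applied
category equals the scheduled target, −1 otherwise (including unmatched-key
responses).

The target category switches after a run of consecutive correct sorts whose
length (the *criterion*) is drawn per episode. Only the constraints
"two or more" and a mean of 3.5 are fixed by the task description, so the
default criterion distribution is uniform on {2, 3, 4, 5} (mean exactly
3.5); it is configurable. Each new target is uniform over the two
categories differing from the current one, and the first target is uniform
over all three. A session ends after 41 completed switches or 250 trials,
whichever comes first; sessions hitting the trial cap are valid and
flagged. Cards are drawn uniformly from the deck without immediate
repetition (the original software's card sequencing is unpublished; this
rule is a package choice and is configurable). A practice block (6
switches) can be produced by setting `switch_count=6`; it is never part of
any analysis.

## Reinforcement-learning models

Model-based (MB) learning maintains a 3-vector **Q**_C of feedback
expectations for applying each category. Each trial the expectations first
decay by the inertia, **Q**′_C = γ_MB **Q**_C, then the applied category *u*
is updated by a delta rule, Q_C,u ← Q′_C,u + α_MB^{sign(r)} (r − Q′_C,u),
with r ∈ {+1, −1} and separate learning rates after positive and negative
feedback. Non-applied categories only decay. MB expectations are projected
onto responses through the current card: the response applying category *u*
inherits Q_C,u and the unmatched key is assigned −1 (it predicts certain
negative feedback).

Model-free (MF) learning maintains a 4-vector **Q**_MF over the motor
responses with the same decay-then-delta structure (γ_MF, α_MF^±), indexed
by the executed key rather than the applied category.

Choice follows a softmax on the integrated expectations divided by the
temperature τ: **Q**_sum = **Q**_MB (MB-RL), **Q**_MB + **Q**_MF (P-RL), or
w **Q**_MB + (1 − w) **Q**_MF (wP-RL). All expectations start at 0.

Two exact identities follow and are enforced by tests: wP-RL with w = 1
equals MB-RL, and wP-RL with w = 0.5 and temperature τ/2 equals P-RL with
temperature τ.

When a generative agent presses the unmatched key (possible under the RL
models, vanishingly rare at realistic temperatures), no category was
applied, so the MB kernel has no prediction error: the MB state only
decays, while the MF kernel updates the executed key with α_MF^−. Fitted
data never contain such trials because they are removed in preprocessing
(the AU model assigns them probability zero, making their log-probability
undefined).

## Attentional-updating benchmark

The AU model tracks a 3-vector **a** of attentional category
prioritizations on the unit simplex, initialized at 1/3. After positive
feedback the signal concentrates on the applied category; after negative
feedback it redistributes over the non-applied categories, weighted by
**a**^f (attentional focus f). Attention moves a fraction p⁺ or p⁻ of the
way toward the signal. Response probabilities are proportional to
**a**^d read through the card's category mapping (decision consistency d);
the unmatched key has probability exactly zero. A reduced configuration
(f = 1, p⁺ = 0.9999) is available behind a flag and is not part of the
default model space.

## Hierarchical estimation

Each parameter is estimated on an unconstrained scale and mapped to its
support by the standard normal CDF Φ ("Probit" transform): learning rates,
inertias, updating ratios, and the MB weight via Φ(x) ∈ (0,1); the
temperature, focus, and consistency via 5·Φ(x) ∈ (0,5). The hierarchy is
non-centered: subject *i*'s constrained value of parameter *k* is
transform(μ_k + σ_k z_ik) with priors μ_k ~ Normal(0,1), σ_k ~
half-Cauchy(0,5) (the scale prior is truncated to positive values), and
z_ik ~ Normal(0,1).

Sampling uses a blocked adaptive Metropolis-within-Gibbs scheme written for
this package:

* per-subject random-walk updates of the standardized effects z_i, with the
  proposal shaped by each subject's empirical warmup covariance (the
  within-subject parameter correlations are strong for these models);
* per-parameter joint random-walk updates of (μ_k, log σ_k);
* a joint group-level move whose proposal covariance is adapted to the
  warmup history of (μ, log σ);
* likelihood-free interweaving moves — a location shift (μ_k, z_k) →
  (μ_k + ε, z_k − ε/σ_k) and a scale move (σ_k, z_k) → (σ_k e^h, z_k e^{−h})
  — that leave every constrained individual value invariant and are
  accepted on the priors alone. These decouple the group level from the
  effects and are what gives the group locations acceptable mixing.

Proposal scales adapt during warmup toward ~30% acceptance (25% for the
joint move) and are frozen afterwards. Chains start by default from
jittered per-subject penalized point estimates, which removes most of the
warmup transient; a diffuse start is available (`init="random"`).
Convergence is monitored with split-R̂ on all group-level parameters; a
warning is emitted above 1.1 (no cutoff is canonical; 1.1 is the package
default). The reference protocol is 3 chains × 1,000 post-warmup and 500
warmup iterations; recovery tests use a reduced profile (2 chains,
600/400). Likelihoods inside the sampler are computed by a vectorized numpy
engine; tests cross-check it against the readable scalar recursions to
1e−9.

Per-subject point estimation (`fit_subject_point`) maximizes, by
multi-start L-BFGS-B on the unconstrained scale, the log-likelihood
penalized by the same Normal(0,1) term the hierarchy places on individual
effects. The penalty is not cosmetic: near-deterministic responding
identifies the *ordering* of feedback expectations far better than their
magnitude, leaving a scaling ridge between learning rates and temperature
along which the raw likelihood is nearly flat; unpenalized estimates
wander along that ridge. Plain maximum likelihood is available with
`prior_scale=None`. Single-sequence likelihoods in this path use
numba-compiled kernels (identical recursions, cross-checked in tests).

## Model comparison

Subjects are partitioned into K = 5 near-equal folds (seeded). For a
held-out subject, each posterior draw's group level (μ_s, σ_s) is turned
into an individual parameter vector by sampling a fresh standardized effect
z ~ Normal(0,1) per draw (default; the plug-in z = 0 construction is
available behind a flag — the original held-out construction is not
derivable from its description, so both are implemented). The subject's
elpd is the log of the across-draw mean of the product of predicted
response probabilities. Group elpd sums over subjects; Δelpd is measured
against the model with the highest total elpd, with SE = √N × the sample
SD of per-subject elpd differences (the cross-validation convention).
Per-subject winner ties are credited to the model with fewer parameters.

## Post-hoc absolute fit (one-trial-ahead simulation)

For each of n_iter = 1,000 iterations, a parameter vector is drawn from
the subject's individual posterior; on every trial *t* the latent state is
rebuilt from the *observed* history 1..t−1 and a response is sampled from
the model's probabilities. Simulated responses never feed back into the
state, so iterations are independent given the parameters. Scoring uses
the observed context of trial t−1 (feedback, applied category, where the
previous key maps on the current card) and only the trial-t response is
simulated; a simulated unmatched-key press counts as a non-error on its
opportunity trial. Feeding the observed responses through this scorer
reproduces the observed conditional error probabilities exactly (tested).

## Behavioral scoring

Perseveration: repeating the applied category after negative feedback.
Set-loss: switching the applied category after positive feedback. Each
scored trial is stratified by response demand, derived from where the
previously executed key maps on the current card: if it maps to the
previously applied category, then after negative feedback the error
(repeating the category) would repeat the key — a demanded response
alternation — while after positive feedback the correct repetition repeats
the key — a demanded repetition; if it maps to a different category the
roles flip; if it maps to no category the trial joins neither stratum
("unclassified", a case the 2×2 design has no cell for). The "correct
response" after negative feedback is read as *any* category-switch
response, so demand scoring never needs the scheduled target; a
target-only reading is available behind a flag. Trials following a removed
(unmatched-key) trial have no valid predecessor and are unscored.
Conditional probabilities divide committed errors by opportunities per
cell; empty cells are missing, not zero.

Participant screening excludes a subject iff any category's application
count lies strictly outside the cohort mean ± 3 SD for that category
(on-boundary kept). Note the rule is meaningful only for reasonably large
cohorts: in a cohort of n the largest possible standardized deviation from
the full-sample mean is (n−1)/√n, which is below 3 for n ≤ 10.

The group-level inferential test on the 2×2 table (Bayesian
repeated-measures ANOVA) is out of scope; the package reports cell means,
the perseveration-demand contrast, and per-subject contrasts instead.

## Synthetic cohorts

The generator emulates the study conditions: the 24-card deck, 41 switches
with criterion mean 3.5, 250-trial cap, binary feedback, and agents
governed by the generative models with group means at the reported
hierarchical group-location estimates of the wP-RL model (boundary values
">0.99" and "<0.01" are taken as 0.995 and 0.005); P-RL and MB-RL cohorts
reuse the shared subset. Individual parameters are drawn on the
unconstrained scale around the group means with dispersion 0.5 (a free
choice producing visible heterogeneity), then transformed, so bounds hold
by construction. Master seed → per-subject seeds via `default_rng([seed,
subject, stream])`.

What the generator does not emulate: reaction times, fatigue or practice
effects, and the human marginal statistics — agents at the group means
complete sessions in ~210–240 trials, above the human mean of ~168,
because the fitted models' full generative behavior is more error-prone
than the humans they were fitted to one step ahead. Passing tests on these
cohorts therefore show internal consistency of the machinery, not fidelity
of the generative models to human data. Two further caveats: with the
default dispersion 0.5 the heavy right tail of the temperature produces a
subset of near-random agents whose set-loss propensity (≈2/3 at chance)
exceeds their perseveration propensity (≈1/3 at chance), which can invert
the group-mean ordering of the two error types; the qualitative signature
checks are therefore run on cohorts at the group means (dispersion 0),
where wP-RL agents show higher perseveration than set-loss propensity and
a positive repetition-minus-alternation perseveration contrast while
matched MB-RL agents show none.

## Numerical choices

* Softmax uses max-subtraction; probability vectors sum to 1 within 1e−12.
* τ is floored at 1e−10 inside the likelihood kernels (the transform keeps
  it positive; the floor only guards saturated draws).
* AU attention entries are floored at 1e−12 before exponentiation by f or d
  (avoids 0^0 and underflow); an implementation tolerance, not model
  content.
* Φ is `scipy.special.ndtr` (exact to machine precision). At |x| ≳ 8 the
  constrained value saturates to the closed interval bound in floating
  point; all kernels tolerate the boundary values.
* HDIs use an exact shortest-interval search on the sorted sample
  (cross-checked against arviz).
* Optimizer: L-BFGS-B, `ftol=1e-12`, 4 starts (origin + 3 random).

## Problem sizes used by the test suite

Equivalence and conservation checks use 100 and 10 sessions of 8–10
switches; point-estimate recovery uses 50 full-length (41-switch) MB-RL
sessions; the behavioral-signature check uses two 100-agent cohorts at the
group means; hierarchical recovery uses a 20-subject P-RL cohort at the
reduced sampler profile. These sizes are the package's documented defaults
for its own validation and keep the full suite in the minutes range.

## Known limitations

* The sampler is a random-walk scheme, not a gradient-based one; its
  effective sample size per iteration is far below NUTS-style samplers, and
  group scales (σ) for weakly identified parameters mix slowest. The
  interweaving moves mitigate but do not remove this.
* The wP-RL model's weight w is poorly identified from single sessions
  (the identity wP-RL(w=0.5, τ/2) = P-RL(τ) shows w trades off against τ
  exactly at w = 0.5); recovery studies should prefer P-RL.
* Generative sessions are longer and more error-prone than human sessions
  (see above), so absolute session-level statistics from cohorts should
  not be read as human-calibrated.
* The exclusion screen assumes a large cohort (see Behavioral scoring).
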