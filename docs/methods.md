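# Methods

This note documents the models, conventions, numerical choices and known
limitations of `ipdbridge`, module by module.

## Responder model (`svo_model`)

Responders are stochastic social-value agents: an offer giving the
responder R_S and the proposer R_O is accepted with probability
`q_A = expit(β (α R_S − δ R_O + ρ |R_S − R_O|))`. α weights own reward,
δ the other's reward, ρ the absolute self–other inequality; β (per monetary
unit) scales determinism. The bundled presets — individualistic
(1.096, 0.382, −2.512, 0.037) and prosocial (1.368, −0.644, −3.798, 0.045) —
are the hyper-parameter vectors of the two opponent types the synthetic
cohorts emulate. The inequality term is read as |R_S − R_O|, consistent
with the prosocial agent's stronger inequality aversion. The logistic is
evaluated through `scipy.special.expit`; exponents beyond ±~700 saturate at
the 0/1 machine boundaries rather than overflowing. Offers are kept in the
dataset's arbitrary monetary units; no rescaling of β is applied.

A consequence worth knowing: with these presets, acceptance probability
peaks at the equal split and collapses quickly for *either* direction of
inequality, so offers chosen "defectively" (against the responder's
interest) are nearly always rejected. In synthetic sessions the outcome
"proposer defected, responder accepted" is therefore rare to absent, which
is exactly the situation the missing-cell machinery below exists for.

## Synthetic cohorts (`synthetic_cohort`)

The generator emulates the study design the analysis assumes: each
participant plays one 120-trial binary-ultimatum session against each of
the two preset opponents, and one offer list is drawn once per cohort and
reused bit-identically in every session, so condition contrasts cannot come
from the stimuli.

Offers split a fixed stake (default 100 units) on a grid. The default grid
step is 5, giving 21 offers and 420 ordered pairs, enough to draw 120
distinct stimuli without replacement; a coarser 10-unit grid only supports
110 and is rejected with a configuration error at the default trial count.

The proposer is a configurable stand-in for a value-based choice model:
inferred acceptance probability `q̂ = clip(q_true + N(0, σ_belief), 10⁻⁶,
1 − 10⁻⁶)`, subjective expected value `EV = w(q̂) · r_other^γ` with the
Prelec weighting `w(q) = exp(−(−ln q)^τ)`, and a two-option softmax at
temperature T (T = 0 is a hard argmax with ties to the left offer). This
matches the qualitative shape of proposer behaviour in such experiments —
nonlinear utility, inverse-S probability weighting, near-greedy choice —
without claiming to reproduce any particular fitted model. Defaults, chosen
once as plausible for this literature and documented rather than tuned:
γ, τ ~ LogNormal(0, 0.2) per participant (mild heterogeneity around risk
neutrality and linear weighting), T = 3 monetary units, σ_belief = 0.05.

Randomness: one `numpy` generator per session, seeded by
`SeedSequence([master_seed, participant_index, stream])`, so cohorts are
exactly reproducible and sessions independent; per-participant proposer
parameters are drawn once and reused against both opponents.

What the generator does *not* emulate: within-session learning, the
observational learning phase that precedes the choice session in the real
design, and any particular empirical offer-pair distribution. Passing tests
on synthetic cohorts therefore validates the estimators and the pipeline's
internal consistency, not cohort-level quantitative claims about human
data; cohort-level assertions in the test suite are directional only.

## Game recovery (`ipd_recovery`)

Move coding: the proposer cooperates when the chosen offer's q̂ is ≥ the
unchosen offer's (a tie is not a choice of the strictly
worse-for-the-opponent option, hence C); the responder cooperates by
accepting. Every recovered 4-vector is stored in its *owner's* perspective
— first letter of the outcome is the owner's own move — and module
boundaries apply the explicit index permutation σ = (CC, DC, CD, DD) when a
vector changes perspective. This is the indexing under which the joint
transition matrix takes its standard memory-one form (see below).

Payoff cells average realized rewards for accepted trials and forgone
amounts for rejected ones; `forgone_mask` marks the rejected-trial cells
semantically (responder played D) so the downstream sign rule is
perspective-proof. Transition probabilities condition on the previous
trial's joint outcome; trial 1 only conditions trial 2. Outcomes never
visited produce NaN entries with zero counts — never a silent 0 — and each
session is treated as one uninterrupted sequence.

## Markov engine (`markov_engine`)

For strategies a (player 1) and b (player 2), row k of the joint transition
matrix is the outer-product row of (a_k, 1 − a_k) with (b_σ(k), 1 − b_σ(k)):
conditional on the previous state the players move independently, and
player 2's conditioning entry is the perspective-transposed one in the CD
and DC rows.

The stationary vector solves v᷀(M − I) = 0: a null-space solve (SVD,
singular-value tolerance 10⁻¹⁰) normalized to sum 1. When the eigenvalue-1
space is not one-dimensional or the candidate is not a valid distribution —
which happens for empirical strategies containing exact 0/1 entries — the
solver falls back to the Cesàro time-average of the chain started from the
uniform distribution (10⁵ steps), and the diagnostics record the fallback
and the residual ‖v᷀M − v᷀‖∞. Strategy entries of exactly 0 or 1 are never
perturbed, so absorbing cases (e.g. mutual always-cooperate → v = (1,0,0,0))
stay exact; entries below 10⁻¹³ in magnitude are clipped to zero before the
final normalization for the same reason. The batched solver used by the
ensemble experiment solves the equivalent constrained least-squares normal
equations `[(M−I)(M−I)᷀ + 11᷀] v = 1` for a whole stack of chains at once
and reroutes any instance with residual above 10⁻¹⁰ through the robust
scalar path.

Missing strategy entries must be completed before a chain is built. The
default fill is 0.5 — the maximum-entropy completion, keeping every pair in
the cohort — with `owner_mean` as the alternative; fills are logged.

## Fitness (`fitness_analysis`)

Signed payoff vectors negate the forgone cells (by mask, not by label),
re-index into the chain's player-1 perspective, and enter `v·S`. Payoff
cells never observed enter as 0: an unobserved outcome should carry ~0
stationary mass, and a warning is emitted whenever the stationary vector
puts more than 1% mass on a zero-filled cell so that the approximation is
visible. Extinction is strict inequality (ties favour the participant), and
the cohort extinction rate is a plain fraction per opponent type. The
descriptive-statistics helpers (Welch/paired t, Pearson r, an explicit
Bonferroni multiplier) summarize synthetic cohort tables only.

## Random-strategy ensembles (`strategy_simulation`)

All eight conditional cooperation probabilities of a pair are i.i.d.
uniform(0, 1). Pairs are ranked by the stationary CC probability — the only
defensible reading of "long-term mutual cooperation" given the stationary
vector — with stable descending sort, and the top/bottom `⌊fraction·n⌋`
pairs form the groups. Within-group correlations (computed within groups to
avoid Simpson's paradox) default to the per-player convention: each member
of each pair contributes its own conditional cooperation probability as one
observation, so a 1000-pair group yields 2000 agents. The pair-mean variant
is computed alongside for sensitivity; it is systematically larger (pooling
the two members' rates removes within-pair disagreement) and is not the
default because the per-agent reading is what the group sizes and reported
effect sizes of this experiment correspond to.

Group profiles report mean ± SE stationary entries and cooperation rates,
plus the *realized* DD-escape frequency `v_DD × p(C | DD)`. That last
quantity, not the raw cooperation-after-DD probability, is what separates
the groups in the expected direction: the best-faring pairs have higher
cooperation-after-DD *parameters* than the worst-faring ones, but they
essentially never visit DD, so they almost never realize a
defection-breaking event, while the worst-faring pairs sit in DD and escape
it comparatively often.

## ZD detection (`zd_detector`)

The tilde transform is (p₁−1, p₂−1, p₃, p₄) in the owner's perspective.
Because the ZD membership condition is linear in (φ, κ, ε), it is fitted by
exact linear least squares against [S_own, S_other, 1] rather than by a
bounded nonlinear optimizer; the infinity-norm residual decides membership
(default tolerance 10⁻⁶, configurable), and the reported scalar
`l = −ln(1 − min(Σ|residual|, 1 − 10⁻¹²))` is a monotone transform of the
summed residual that is exactly zero iff the determinant condition holds.
The payoff vectors entering the fit are the signed (forgone-negated) ones,
since those are the payoffs whose linear relation is being probed; raw
vectors can be passed for sensitivity analysis. Degenerate inputs (S_own,
S_other, 1 linearly dependent) are flagged but still fitted. Cohort scans
test both directions per pair (either player as would-be enforcer).

## Problem sizes and tolerances used in the test suite

Ensemble assertions use n = 2×10⁴ pairs (groups of 1000) averaged over 10
seeds, the scale at which the tail correlations are stable to ±0.02 or so
seed-to-seed; stationary-solver properties are checked on 10³ random chains
at 10⁻¹⁰ (residual) and 10⁻⁸ (agreement with an independent power-iteration
oracle); estimator-recovery checks use 10⁴-trial simulated sessions at 3
binomial standard errors per cell; cohort-level directional checks use the
full 50-participant × 2-opponent × 120-trial design at 3 SE.

## Known limitations

* The memory-one representation factorizes each trial's joint outcome as
  conditionally independent moves. Ultimatum trials correlate the two
  players' moves *within* a trial (a cooperative choice is precisely one
  that is likelier to be accepted), so the stationary CC probability of the
  recovered chain sits systematically below the in-session CC frequency.
  The stationary analysis inherits this "erosion" property by construction;
  it is a feature of the model class, and the directional cohort test
  asserts it rather than hiding it.
* Printed cohort-level statistics from human experiments (ANOVA F and t
  values, empirical extinction rates, ZD prevalence) depend on the original
  human dataset and are out of reach of synthetic cohorts; the pipeline
  accepts externally deposited trial tables in the documented CSV schema,
  but no numeric claims are made for them here.
* Zero-count cells and 0/1 strategy entries are handled by documented
  policies (fill, Cesàro fallback, zero-with-warning) rather than by
  perturbation; results for near-degenerate empirical sessions depend
  mildly on those policies, all of which are selectable.
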