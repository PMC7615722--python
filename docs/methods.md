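# Methods

## Task schedules

All schedules are pure functions of an integer seed: the multiset of
trial types is fixed by the design and only the ordering and residual
side assignments are random. Seeds feed `numpy.random.SeedSequence`
streams namespaced per generator, so the same seed can safely drive
training, test, and simulation without stream collisions.

**Reward Pairs.** Stimuli `s1, s3f, s3r, s5f, s5r, s7f, s7r, s9` carry
deterministic rewards {1, 3, 3, 5, 5, 7, 7, 9}; `f`/`r` mark the frequent
and rare member at each intermediate level. The training pairing table
pairs each frequent stimulus 30× per session with its value−2 neighbor
and 10× with its value+2 neighbor (rare stimuli reversed). The printed
row/column constraints admit a small family of pairing tables; we fix the
canonical member in which frequent(v) meets rare(v+2) and rare(v) meets
frequent(v+2). Every session total that the design prints — 160 trials,
40 appearances per stimulus, 640–960 obtainable points — is invariant
across that family. The 136-trial test presents each of the 28 stimulus
pairs 4×, plus 8 extra trials per same-reward pair. Side assignment is
balanced within pair (odd remainders by seeded coin flip); trial order is
a uniform seeded permutation, with no run-length constraint.

**Unrewarded Habit.** Four stimuli in two pairs with fixed (per
participant) screen sides. Each session interleaves six 20-trial blocks
per pair, alternating pairs from a seeded starting pair; cue counts are
exact per block (16/4 in the 80/20 pair, 10/10 in the even pair), so five
sessions give exactly 600 trials and a 480/120 cue split per pair. The
64-trial test comprises 10 trials per trained pair in trained locations,
then 24 all-pairs trials (every pair 4×, locations balanced) randomly
interleaved with 10 switched-location trials per trained pair. Because
the balanced all-pairs block necessarily shows trained pairs in both
locations, trial objects carry an internal `segment` tag
(`initial`/`all_pairs`/`switched`) so the composition is auditable; the
tag is not part of the CSV schema.

**Two-step.** Alien payoffs follow an integer Gaussian random walk
(start 0, step sd 2, reflecting boundaries at −4 and +5, emitted values
rounded). Transitions are deterministic and crossed (ships A, C → alien
1; B, D → alien 2), making the two initial states informationally
equivalent — the lever that dissociates model-based from model-free
control.

## Choice models

Rewards are rescaled to [0, 1] by dividing points by 9 so the Q-values
and the choice kernel share a scale; this is what makes the reduced
model's constraint β_q = 10 − β_h interpretable, with β_h = 5 the
equal-weighting point. Initial values are Q = CK = 0.5 (midpoint,
unbiased; 0 available via configuration). Training feedback updates both
presented stimuli (both outcomes are displayed in the task);
`chosen_only` is exposed for sensitivity analyses. The test phase shows
no outcomes, so Q freezes while the kernel keeps updating — choices
happen either way. Kernel updates touch only the two presented stimuli.

A consequence worth knowing when simulating: the frequent/rare labels of
the Reward Pairs design are only meaningful if training choices track
value. An agent whose kernel weight dominates training (large β_h,
moderate β_q) perseverates on arbitrary stimuli and erases the intended
frequency manipulation, and a fast kernel (large α_h) overwrites the
training frequencies within a few test trials. The packaged "habitized"
parameter regime (`habitized_param_priors`: β_q ∈ [6, 9], α_h ∈
[0.05, 0.3], β_h ∈ [3, 7]) therefore combines value-guided training with
a slow, persistent, moderately weighted kernel — the regime in which the
frequency-based habit the tasks were built to detect actually expresses
itself.

The two-step hybrid uses SARSA(λ) model-free values, model-based values
read off the deterministic transition (Q_mb(s, a) = V(alien)), a net
value w·Q_mb + (1 − w)·Q_mf, and a logistic rule with inverse
temperature β plus π for repeating the previously visited alien and ρ
for repeating the previous response key. The reported habit measure is
1 − w. The assignment of π to target-alien repetition and ρ to key
repetition follows the published code structure of the task variant the
schedule emulates and is an assumption of this implementation.

## Fitting

The likelihood replays a participant's chronologically ordered log —
five training sessions plus test, learning state carried across sessions
(per-session reset available) — scoring each completed free-choice
trial. Missed trials contribute neither likelihood nor updates (no
action was taken); instructed trials of the Unrewarded Habit training
update the kernel but not the likelihood. BIC uses n = the number of
likelihood-contributing trials, since the likelihood is defined only
over them.

Likelihood kernels are numba-compiled; a pure-Python replayed likelihood
built from the agent primitives serves as an independent cross-check in
the tests, alongside a brute-force parameter-grid oracle for the
optimizer. Optimization is L-BFGS-B from 10 seeded uniform starts within
bounds (α ∈ [0, 1], β ∈ [0, 10]; two-step β ∈ [0, 20], π, ρ ∈ [−5, 5]),
ftol 1e-8, 500 iterations per start, ties broken by start index. Fits
with fewer than 30 usable trials are refused with a distinct error, not
flagged as non-converged. The random model is evaluated in closed form
(nll = n·ln 2 exactly).

## Group model selection

Subject-wise log evidences (−AIC/2 registered, −BIC/2 optional) enter a
variational random-effects scheme with a uniform Dirichlet prior
(concentration 1 per model): responsibilities u_nk ∝ exp(L_nk +
ψ(α_k) − ψ(Σα)), α = 1 + column sums, iterated to |Δα| < 1e-6.
Exceedance probabilities are estimated from 10⁵ seeded Dirichlet draws
(analytic Beta tail for two models). Individual-level evidence uses
absolute BIC differences: < 6 insufficient, 6–10 strong, > 10 very
strong.

## Scores

Score formulas operate on proportions, medians (seconds), and rating
changes; trial logs store integer milliseconds and the pipeline discards
responses faster than 50 ms and requires at least 3 trials per median
cell (the design is silent on cell minima; 3 is this package's floor).
Reward Pairs choice/RT/rating scores average the frequent-minus-rare
contrast over the three same-reward pairs, conditioning on those pairs'
12 test presentations each; Unrewarded Habit scores are the single-pair
analogues over all test trials showing the 80/20 pair (a
location-stratified variant is exposed through the log filters).
Devaluation scores (DVAL choice and RT switch cost) are computed per
previously-high/low-valued condition and averaged unweighted, with
per-condition values retained; the behavioral adaptation index and
degradation ratio take aggregate response rates directly, since
free-operant tasks have no trial-log representation here. Training
effects are (last − first)/2 for choice/RT scores and unscaled for the
degradation ratio. Missing inputs propagate as NaN, never as silent
zeros. SRHI scoring applies the frequency filter (behaviors with the
"I do frequently" item ≥ 3; fewer than three such behaviors → missing);
COHS yields automaticity/routine means and HTQ total plus 4/4/3 subscale
sums — the instruments' item keys are configurable because the split is
a published convention not reproduced in the package.

## Synthetic cohorts

`generate_cohort` draws a generating model and parameters per
participant (defaults: four-model mixture 25% each; learning rates
Beta(2, 2); temperatures Uniform(1, 9); compliance Beta(20, 2)), plays
the full two-task protocol including day-1 baseline tests, and fills in
response times, ratings, and questionnaires. RTs follow a log-scale
Gaussian with mean decreasing in the chosen-minus-unchosen value and
kernel differences, truncated to (50 ms, window] — matching the log-RT
analysis model's assumptions, not a mechanistic RT model (no
drift-diffusion dynamics, no sequential effects). Post ratings shrink
toward the pre rating plus value and kernel contributions, clipped to
[0, 100]. Questionnaire items load on one latent trait (loading
configurable to zero). What passing tests on these cohorts shows is that
the pipeline detects the structure it was built to detect — not that
human data will contain it.

Default problem sizes used in the verification suite: 50-subject
cohorts at the full task length (5 × 160 + 136 Reward Pairs trials,
5 × 240 + 64 Unrewarded Habit trials) for parameter recovery and the
habit-direction sign tests; model-recovery confusion matrices are
computed on scaled-down schedules (single training day) where only
qualitative ordering is asserted.

## Power

Two-sample t-test power uses the exact noncentral-t distribution with
df = N − 2 and noncentrality d·√(N/4), equal allocation; the required-N
search walks even totals upward. The exact computation matters: a normal
approximation can flip the returned N at the boundary.

## Known limitations

- The pairing table and the model equations of the original study's
  supplement are not public; both are reconstructed from the printed
  constraints and verbal descriptions, with the alternatives
  parameterized (`feedback`, initial values, per-session reset).
- The two-step π/ρ definitions are an assumption (see above).
- The printed test-phase earnings range of 248–424 points is not
  derivable from the 136-trial structure (always-max yields 856,
  always-min 504) and is not used as a check.
- No hierarchical/empirical-Bayes fitting, no protected exceedance
  probabilities, no RT process models, and no mixed-model analyses of
  real data — these are outside the package's scope.
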