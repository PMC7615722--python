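# habitlab

Tools for studying **frequency-based habit formation** in the lab: trial
schedules, generative choice models, maximum-likelihood fitting, group-level
Bayesian model selection, per-participant habit scores, and synthetic
cohorts — everything needed to run the computational pipeline of a
multi-task habit study end-to-end without any participant data.

## The scientific problem

Habits are often defined by what they ignore — outcome value (devaluation
insensitivity) or action–outcome contingency (degradation insensitivity).
An alternative account holds that habit strength grows with *behavioral
frequency* itself: choosing an option often makes it more likely to be
chosen again, independent of its value. The package implements tasks and
models built to isolate that frequency pathway:

- **Reward Pairs task** — eight stimuli with deterministic rewards
  {1, 3, 3, 5, 5, 7, 7, 9} points. At each intermediate reward level one
  stimulus is *frequent* (paired 30×/session with a less valuable partner,
  10× with a more valuable one) and one is *rare* (the reverse), so a
  reward maximizer chooses them unequally often while their values stay
  identical. Five daily 160-trial training sessions (each stimulus appears
  40×; obtainable earnings 640–960 points), then a 136-trial test phase in
  which the same-reward pairs finally meet.
- **Unrewarded Habit task** — two stimulus pairs, no rewards, instructed
  choices (80/20 within one pair, 50/50 within the other), 600 training
  trials per pair over five days, then a 64-trial free-choice test under a
  500 ms response deadline.
- **Two-step task** — two equivalent initial states whose spaceships fly
  deterministically to one of two aliens with random-walk payoffs; the
  model-based weight *w* of a hybrid learner indexes goal-directed control
  (the reported habit measure is 1 − *w*).

## Models

Choices in the binary-choice tasks are modeled by combining a delta-rule
Q-learner with a **choice kernel** (CK) that tracks recent choice
frequency:

```
Q_s  ← Q_s  + α_q (r_s − Q_s)          r_s = points / 9 ∈ [0, 1]
CK_s ← CK_s + α_h (1[s chosen] − CK_s)
P(left) = σ( β_q (Q_L − Q_R) + β_h (CK_L − CK_R) )
```

Candidate models: `random` (P = ½), `rl`, `ck`, `rl_ck`, and
`rl_ck_reduced`, in which the temperatures are tied by **β_q = 10 − β_h**
so that β_h = 5 weights the two systems equally. Fitting is multi-start
bounded MLE over the replayed likelihood (training + test, learning state
carried across sessions; missed trials excluded; instructed trials update
learning but not the likelihood). Group-level selection uses
random-effects Bayesian model selection on −AIC/2 evidences, reporting
expected model frequencies and exceedance probabilities.

## Worked example

Simulate a 20-participant cohort whose members all carry a choice kernel
(the "habitized" regime: value-guided training, slow persistent kernel),
fit all four registered models, and run group model selection:

```bash
habitlab simulate --task cohort --n 20 --seed 42 --out demo/
habitlab fit  --logs demo/trial_logs.csv --model random --model rl \
              --model ck --model rl_ck --out demo/fits.jsonl
habitlab compare --fits demo/fits.jsonl --criterion aic --seed 1 \
              --out demo/bms.json
habitlab score --logs demo/trial_logs.csv --ratings demo/ratings.csv \
              --out demo/scores.csv
```

On a kernel-bearing cohort the comparison is unambiguous — the combined
model's exceedance probability is 1:

```
{"ck": 0.0, "random": 0.0, "rl": 0.0, "rl_ck": 1.0}
```

and the habit scores point in the frequency direction (positive =
preference for the previously more frequently chosen stimulus):

```
participant_id  rp_choice  rp_rt  uh_choice  uh_rating
          p001      0.879    NaN      0.913      8.490
          p002      0.667    NaN      0.565     -0.806
          p003      0.106  0.079      0.833     -4.945
mean rp_choice: 0.504   mean uh_choice: 0.686
```

(`rp_rt` is NaN when a participant chose the rare member too rarely to
form a median-RT cell — itself a signature of strong habit.) Sample-size
planning for the devaluation/degradation group contrasts uses the exact
noncentral-*t* computation:

```bash
$ habitlab power --d 0.912
{"n_total": 66, "achieved_power": 0.954338}
$ habitlab power --d 0.789
{"n_total": 86, "achieved_power": 0.951173}
```

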