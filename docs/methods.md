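# Methods

## Scope and model family

The package implements trial-wise models of instrumental conditioning in a
task whose critical manipulation is the *withholding of reward feedback*.
All six models share the feedback-phase machinery — Rescorla–Wagner value
updates driven by reward prediction errors, softmax choice — and differ
only in the no-feedback phase. The family spans the hypothesis space from
"nothing happens" (`Static`) through value-free response biases
(`Perseveration`), value changes without confidence (`Choice`, `Deval`), to
the confidence-prediction-error models (`ConfSpec`, `ConfUnspec`) in which
reported confidence is compared against a running expectation and the
resulting prediction error, scaled by the transfer parameter γ, changes the
value of the chosen option.

States are per-block: expected values and expected confidence are
initialized to zero at every block start (each block introduces new CS),
and the perseveration model's previous-choice memory is cleared with them.
That memory is keyed on the unordered CS pair and recorded in *all* phases
— a phase-2 pair's most recent encounter may lie in phase 1 — while the η
bias enters the choice rule only in the no-feedback phase. This
phase-spanning memory is a design choice; the alternative (resetting at
phase-2 onset) discards information for no behavioral reason.

## Parameters

| parameter | meaning | bounds | notes |
|---|---|---|---|
| α_r | reward learning rate | [0, 1] | all models |
| β | inverse decision noise (1/€) | [0, 2] | 0 = random choice |
| α_c | confidence learning rate | [0, 1] | confidence models |
| α_d | devaluation rate | [0, 1] | `Deval` |
| γ | confidence transfer (€ per unit CPE) | ≥ 0 | no natural upper bound; fitting caps it at 100, the top of the recovery grid |
| λ | choice reinforcement (€) | ≥ 0 | capped likewise |
| η | perseveration bias (€-equivalent) | [−5, 5] | positive = repeat |

## Task generator

The generator reproduces the study conditions exactly where they are
determinate: 11 blocks × 27 trials, 5 CS on 4 value levels (one level
duplicated, the duplicate drawn uniformly), 2 control blocks without a
no-feedback phase, phase-1 lengths {9, 12, 15, 18}, phase-2 lengths
{5, 10, 15}, block mean levels {18, 23, 28} €, CS "difficulty" {3, 6} €,
half fractal / half symbol stimulus types, and integer-euro rewards from a
normal(mean, 10 €) truncated to [0, 50] (sampled by exact inverse-CDF).
Three points are under-determined and were fixed once as follows:

* **CS value spacing.** The four levels are equally spaced, centered on the
  block mean, with adjacent spacing equal to the difficulty (level 23,
  difficulty 3 → 18.5/21.5/24.5/27.5). A config switch
  (`spacing_mode="mean_pairwise"`) instead makes the *average pairwise*
  difference equal the difficulty, for sensitivity analyses.
* **Condition balancing.** Factor levels are cycled and shuffled so each
  level appears as evenly as 11 blocks allow. Long phase-2 lengths only fit
  behind short phase 1s (phase 3 needs at least one trial), so phase-2
  lengths are assigned most-constrained-block-first under that feasibility
  cap; marginal balance is preserved as far as arithmetic permits.
* **Pair schedules.** Each trial pairs the two currently least-presented
  CS (ties broken randomly, sides randomized), which guarantees per-phase
  appearance counts within a spread of 2 and excludes self-pairs.

Note that truncation shifts the reward mean: at a nominal CS mean of 18 €
the truncated distribution's mean is ≈ 18.8 €. The generator makes no
attempt to correct this; it is a property of the stated reward scheme, and
tests compare sample means against the analytic truncated mean.

## Simulation

Simulated subjects sample each choice from the model's probability and
report the deterministic *model confidence* 2·(p_chosen − 0.5), clipped at
zero when the sampled choice went against the model's preference. No
confidence noise is added and the rating is kept continuous (an optional
discretizer to the 11-point scale exists, off by default): nothing in the
observed data constrains a confidence noise model, and adding one would
smuggle a free parameter into the generative analyses. Rewards are drawn
for the chosen CS on every trial but flagged unobserved in phase 2. All
phase-2 updates target the *sampled* choice — in generative mode there is
no information leak to guard against.

Because the generated confidence is a deterministic function of the choice
probability, simulated cohorts are cleaner than human data in two respects:
real confidence ratings carry report noise and scale-use idiosyncrasies,
and real learners may drift in parameters over a session. Passing
generative tests therefore demonstrates internal consistency of the
model-fitting pipeline, not that human confidence is noiseless.

## Fitting

Each subject is fitted individually over all blocks by minimizing the
summed −log p(observed choice) (floored at 1e-12 per trial). A coarse
exhaustive grid (5 points per rate, 5 log-spaced points for β, γ, λ, 7 for
η) initializes two local optimizers — bounded L-BFGS-B and Powell — and the
better result is kept, never worse than the grid optimum. The likelihood
recursion is strictly sequential, so the hot path is a numba-compiled
kernel over packed trial arrays; the test suite pins it to an independent
from-scratch replay of the pure transition functions at machine precision.

Update-target conventions during fitting:

* Reward updates use the participant's actual choice and observed reward.
* The confidence-value transfer targets the **model-predicted** CS (the
  right CS iff p_right ≥ 0.5, ties to the right). The actually chosen CS is
  the very observation the likelihood must predict; feeding it back into
  the value update would let perseverative choice streaks explain
  themselves.
* `Choice` and `Deval` update the participant's **actually chosen** CS.
  These updates are functions of the choice alone (no confidence
  modulation), which makes them choice-kernel-style terms; the standard
  convention conditions them on the observed choice history, exactly as the
  perseveration model conditions on previous actual choices. Applying the
  predicted-target rule here instead makes the `Choice` model brittle
  against its own generative data (a mispredicted target receives the full
  +λ boost, while the confidence models' γ·Δc boost self-attenuates when
  confidence is low), which empirically collapses `Choice` model recovery.
* Expected-confidence updates use the reported confidence and, in the
  stimulus-specific model, the actually chosen CS as reference — c̄ never
  enters the choice likelihood, so no leak is possible.

Model evidence is summarized by AIC = 2k + 2·nll (BIC available
throughout); cohort comparison reports mean ± SEM per model, the minimum-
mean winner, and two-tailed paired t-tests on per-subject criteria.

## Recovery studies

Model recovery simulates datasets per generative model (designs freshly
drawn per dataset), fits all six candidates, and tallies lowest-AIC wins
into p(fit|gen) and, after seeded subsampling to equal per-model dataset
counts, p(gen|fit). The generative grids are: rates 5 equidistant values in
[0.1, 1]; β five doubling steps 0.1–1.6; γ five exponential steps 1–100; λ
five exponential steps 0.5–5; η six equidistant values in [−1.5, 1.5]. The
full study (250 datasets × every k^N configuration) is cluster-sized; the
scaled preset used by the tests runs 20 datasets per model at the grid
midpoint of each parameter.

A known property of the scaled mid-grid run: the mid-grid perseveration
bias (η = 0.3 at β = 0.4) shifts the choice drive by 0.12 over roughly 90
informative phase-2 trials, an expected log-likelihood gain of ~0.2 against
a 2-point AIC complexity penalty — such datasets are, by construction,
best described as Static. Fitted η is unbiased, and at strong grid nodes
(η = 1.5, β = 0.8) the perseveration model does win its own data; the
confusion is an information limit of weak-bias datasets, not an estimation
failure, and the same Static confusion affects the full-scale study.

Parameter recovery varies one generative parameter over an equidistant
range (defaults α_r 0.01–1, β 0.02–2, α_c 0–1, γ 0–10), one simulated
subject per value, others held at an anchor, and correlates generative
against fitted values. Two reproducible edge cases: a near-zero γ anchor
degrades α_c recovery (the confidence learning rate carries no weight when
confidence barely transfers), and small β degrades everything (choices
carry little information).

## Effect statistics, sweeps, power

Four statistics summarize no-feedback behavior; slopes are ordinary least
squares on the 0-based within-phase-2 trial index, computed per block,
averaged over blocks then subjects, with SEM across subjects/datasets.
Equal-value CS pairs are excluded from the performance statistic (no
defined correct answer) but retained for consistency (which needs none).
The confidence-by-value interaction requires a CS to be chosen at least
twice in a block's phase 2; blocks yielding fewer than two CS slopes or no
value spread are skipped.

The generative sweeps fix α_r = β = 0.2 and vary the phase-2 parameters
(α_c over {0, 0.5, 1} with log γ over 0–4 in 8 equidistant steps; λ over
0.5–10 in 7 exponential steps; η over −1.5–1.5 in 0.5 steps), 250 datasets
per node in the full analysis and 50 in the scaled performance-bound check.
When checking that the performance slope stays at the 0.001 order across
the sweep, the maximum is taken over 24 noisy node means, so the test uses
a 3-SEM (Bonferroni-style) margin per node — a 2-SEM margin on a 24-fold
maximum would be exceeded about half the time by pure Monte-Carlo noise
even if every true mean were at the bound.

The forward power analysis simulates cohorts from a generative model at
educated-guess parameters (α_r = 0.1, α_c = 0.1, β = 1/3, γ = 1), fits the
generative and Static models to every subject, and applies a two-tailed
paired t-test to the per-subject AIC values; power is the fraction of
replications with p below the test level. A replication counts as a
dissociation whatever the sign of the mean difference, as a two-tailed
criterion implies.

## Numerical choices

* Logistic probabilities via `scipy.special.expit` (kernel: exponent
  clipped to ±700); per-trial likelihood floor 1e-12.
* Truncated-normal rewards by inverse CDF (`ndtr`/`ndtri`), rounded to
  whole euros.
* Softmax tie at p_right = 0.5 resolves to the right CS.
* All randomness flows from `numpy.random.SeedSequence` spawning: a master
  seed reproduces designs, cohorts and analyses bit-for-bit.
* Optimizer tolerance 1e-6; optimizer results are clipped to bounds and
  re-evaluated before comparison with the grid optimum.

## Problem sizes in the bundled analyses

Scaled study sizes used by the test suite and the acceptance script: 250
datasets for the null-backbone and signature cohorts, 50 datasets per sweep
node for the performance bound, 20 datasets per model for model recovery,
30–40 values per varied parameter for parameter recovery, and 10
replications × 64 subjects for the power analysis. These sizes keep each
analysis in the minutes range on one CPU while leaving the Monte-Carlo
error well inside the asserted margins.

## Known limitations

* Confidence is generated noiselessly; empirical confidence–value analyses
  on human data would face report noise these simulations do not model.
* The mixed-effects regression layer used for hypothesis tests on human
  cohorts is out of scope; the package computes the slope/proportion
  statistics only.
* γ and λ are unbounded above in principle; the fitting cap of 100 is a
  practical choice and estimates at the cap should be treated as censored.
* Weak-parameter regimes (small β, small |η|, small γ) are genuinely
  under-identified at single-experiment trial counts; recovery analyses
  quantify, not remove, this limit.
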