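# cpelearn

Computational models of **value-based learning without external feedback**,
built around the idea that subjective choice confidence acts as an internal
reinforcement signal.

The package is for computational cognitive scientists who study instrumental
conditioning: it generates the full synthetic task, simulates artificial
subjects from six competing trial-wise learning models, fits every model to
trial data by maximum likelihood, compares them by AIC/BIC, and runs the
surrounding methodology — model/parameter recovery, generative effect
analyses and forward power simulation.

## The task

A block-structured two-alternative choice task: in each of 11 blocks a
learner faces 5 new conditioned stimuli (CS) with monetary mean values on 4
levels. Each 27-trial block has a feedback phase (phase 1, 9–18 trials), a
critical **no-feedback phase** (phase 2, 5–15 trials; omitted in 2 control
blocks) and a closing feedback phase. Rewards are integer-euro scratch-card
payouts, drawn from a normal distribution (SD 10 €) truncated to [0, 50].
On every trial the subject chooses between two CS and reports confidence on
a 0–10 scale (analysed normalized to [0, 1]).

## The models

In feedback phases all models learn expected values v̄ᵢ by a Rescorla–Wagner
rule with reward learning rate α_r and choose via a softmax with inverse
decision noise β:

    v̄ᵢ ← v̄ᵢ + α_r (r − v̄ᵢ),    p_right = 1 / (1 + e^{−β (v̄_right − v̄_left)})

They differ in what happens when feedback is withheld:

| model | no-feedback dynamics | free parameters |
|---|---|---|
| `Static` | values unchanged | α_r, β |
| `Deval` | chosen CS devalued: v̄ ← (1 − α_d) v̄ | α_r, β, α_d |
| `Choice` | chosen CS reinforced by a constant: v̄ ← v̄ + λ | α_r, β, λ |
| `ConfSpec` | v̄ ← v̄ + γ Δc with a **per-CS** confidence reference | α_r, β, α_c, γ |
| `ConfUnspec` | v̄ ← v̄ + γ Δc with a **single global** reference | α_r, β, α_c, γ |
| `Perseveration` | values static; choice rule gains a repeat bias η | α_r, β, η |

The confidence models track expected confidence c̄ ← c̄ + α_c (c − c̄) on
every trial; the **confidence prediction error** Δc = c − c̄ is the internal
teaching signal that substitutes for the reward prediction error, scaled
into value by the confidence transfer parameter γ.

## Worked example

```python
import cpelearn as cl

# simulate one subject from the confidence-prediction-error model
design = cl.generate_experiment_design(seed=1)
params = cl.ParameterSet("ConfUnspec", alpha_r=0.2, beta=0.2,
                         alpha_c=0.5, gamma=5.0)
subject = cl.simulate_subject("ConfUnspec", params, design, seed=2)

# fit it back, statsmodels-style
model = cl.ValueLearningModel(subject.to_frame(), kind="ConfUnspec")
res = model.fit()
print(res.summary())
```

prints

```
ConfUnspec value-learning model (maximum likelihood)
  n trials: 297    optimizer: L-BFGS-B
  -log L: 141.215   AIC: 290.43   BIC: 305.20
  grid-init -log L: 143.150
  parameters:
    alpha_r      0.0908
    beta         0.3740
    alpha_c      0.9455
    gamma        2.5491
```

297 is 11 blocks × 27 trials; the AIC is 2k + 2·nll with k = 4 free
parameters. A single synthetic subject carries limited information, so the
point estimates deviate from the generative values — across a cohort the
fitted parameters correlate strongly with the true ones (see the recovery
tests). `res.latents()` returns the fitted model's trial-by-trial expected
values, expected confidence and confidence prediction errors;
`res.simulate(design, seed)` draws posterior-predictive data.

Cohort-level comparison:

```python
from cpelearn import simulate_cohort, fit_cohort, compare_models, MODEL_KINDS
subs = simulate_cohort("ConfUnspec", params, 12, seed=77)
fits = fit_cohort(MODEL_KINDS, {s.subject_id: s.to_frame() for s in subs})
print(compare_models(fits, pairs=[("ConfUnspec", "Static")]).summary())
```

A command-line interface mirrors the pipeline
(`cpelearn design | simulate | fit | compare | effects | sweep |
recover-models | recover-params | power`); every command takes `--seed` and
writes a JSON run log for bit-for-bit reproducibility.

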