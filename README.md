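# bayesq

Bayesian and standard Q-learning analysis of two-choice probabilistic
reward (bandit) behavior with adaptive, performance-gated blocks.

In tasks of this kind an animal repeatedly chooses between a left and a
right option whose reward probabilities are drawn from six settings —
(100%, 66%), (66%, 33%), (33%, 0%) and their mirrors — and the setting
changes once the animal picks the richer side on ≥ 80% of the last 20
trials (blocks are at least 20 trials long). The scientific question this
package is built around: does the *uncertainty* of the learner's reward
estimate — not just its mean — shape both action choice and the speed of
learning?

## Models

Standard Q-learning tracks point action values

    Q_chosen   ← (1 − α₁) Q + α₁ (k₁ r − k₂ (1 − r))
    Q_unchosen ← (1 − α₂) Q
    P(L) = 1 / (1 + exp(−β (Q_L − Q_R)))

with variants: original Q (α₂ = k₂ = 0), forgetting Q (FQ, α₂ = α₁) and
differential FQ (all four update parameters free).

Bayesian Q-learning tracks a full beta distribution Beta(x_a, y_a) over
each action's reward probability. Every trial applies:

1. **Prediction step** — both distributions are pushed through the
   forgetting kernel Beta(1 + G q′, 1 + G (1 − q′)) (mode-preserving, with
   concentration G) and moment-matched back to a beta distribution. This
   models a changing environment: small G forgets quickly.
2. **Choice** — soft-max on uncertainty-augmented values:
   P(L) = 1 / (1 + exp(−β[(μ_L + ϕσ_L) − (μ_R + ϕσ_R)])). Positive ϕ is an
   exploration (uncertainty-seeking) bonus.
3. **Updating step** — the chosen action's distribution is updated:
   reward → (x+1, y); non-reward → (x, y+k). k = 1 is strict Bayes
   (original BQ), k = 0 ignores non-rewards (asymmetric BQ), k free is the
   generalized model.

The *effective learning rate* eα = (μ_after − μ_before)/(r − μ_before)
emerges from the posterior's concentration — 1/(x+y+1) after a reward,
k/(x+y+k) after a non-reward — rather than being a free parameter: flat
(uncertain) distributions learn fast, sharp ones slowly.

Model fit is scored by the normalized likelihood Z = exp(mean log z(t)),
the geometric mean of per-trial choice likelihoods (0.5 = chance, 1 =
perfect), and models are compared by 2-fold cross-validation over
sessions, which penalizes extra parameters implicitly.

Because no public trial-level dataset accompanies this task, the package
ships a first-class synthetic-session generator: a closed-loop simulator
of the adaptive-block task driven by any of the implemented models, with
per-session seeds and a manifest of true generating parameters, so every
analysis can be validated by parameter recovery.

## Worked example

```python
import numpy as np
from bayesq import task, fitting, analysis

specs = [{"rat_id": "r0", "variant": "asymmetricBQ",
          "params": {"G": 20.0, "k": 0.0, "beta": 12.0, "phi": 1.0},
          "n_sessions": 20}]
sessions, manifest = task.generate_cohort(specs, seed=101)
print(len(sessions), "sessions,",
      round(np.mean([len(b) for s in sessions for b in s.blocks()]), 1),
      "trials per block")

cv = fitting.cross_validate(sessions, ["FQ", "asymmetricBQ"], split_seed=0, n_starts=8)
report = analysis.model_comparison_report(cv, pairs=(("asymmetricBQ", "FQ"),))
print(report["summary"][["variant", "mean_Z"]].round(4).to_string(index=False))
print("wins:", report["pairwise"][["wins_a", "wins_b"]].iloc[0].tolist())
```

prints

```
20 sessions, 45.0 trials per block
     variant  mean_Z
asymmetricBQ  0.5662
          FQ  0.5512
wins: [20.0, 0.0]
```

The synthetic rats complete blocks at the pace of well-trained animals
(~40 trials per block), and held-out normalized likelihood correctly
prefers the generating Bayesian model over forgetting Q-learning in all
20 sessions — the cross-validated model-comparison pattern the pipeline
is designed to measure.

The same API exposes the rest of the battery: experience-conditioned
optimal-choice tables (`analysis.conditional_optimal_choice`), blockwise
learning-rate re-estimation (`analysis.blockwise_fq_learning_rates`),
effective-learning-rate windows and regressions
(`analysis.blockwise_effective_learning_rates`,
`analysis.regression_report`) and the ϕ distribution
(`analysis.phi_distribution_report`). A `bayesq` CLI wraps the pipeline:
`bayesq simulate | fit | crossval | analyze | report`.

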