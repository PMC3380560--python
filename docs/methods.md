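# Methods

## The task and what the simulator emulates

The simulated task is a free-choice two-armed bandit with adaptive
blocks. Six reward-probability settings — (1, 2/3), (2/3, 1/3), (1/3, 0)
for (left, right) and their mirrors — are scheduled so that every aligned
window of six blocks is a permutation of all six settings and no setting
repeats back to back (ties between admissible next settings are broken
uniformly at random, seeded). Within a block, rewards are Bernoulli draws
from the chosen side's probability. A block ends once it has at least 20
trials *and* the agent chose the richer side on at least 16 of the last
20 ("reached 80%" is read as ≥, i.e. attaining the threshold counts).
Trial and block indices are 1-based.

The generator emits *completed* trials only: center-poke failures,
response-timeout errors, hold durations, tones and inter-trial timing are
not modelled, and no within-session motivation drift exists. Sessions are
driven by a known model agent in a closed loop (emit P(left) → sample
choice → sample reward → update), so every emitted session carries a
manifest entry with its true generating parameters and seeds. A safety
cap (`max_trials`, default 5000) bounds sessions whose agent never
reaches the performance criterion; hitting it sets `truncated=True`
rather than raising.

Consequences for interpretation: passing tests show that the *pipeline*
recovers what a known model-generated cohort contains. They cannot show
that real animals follow any of these models — real data add error
trials, satiety, session-to-session parameter drift and individual
differences that the generator deliberately omits.

## Model equations

Standard Q-learning (variants Q / FQ / dFQ):

    chosen:   Q ← (1 − α₁) Q + α₁ (k₁ r − k₂ (1 − r))
    unchosen: Q ← (1 − α₂) Q
    P(L) = σ(β (Q_L − Q_R)),  initial Q = 0.5 for both actions

The chosen-option target k₁r − k₂(1−r) with decay-to-zero forgetting
follows the differential-forgetting lineage of these models; 0.5 is the
across-settings average reward probability, anchoring the initial value.

Bayesian Q-learning keeps Beta(x_a, y_a) per action (initially
Beta(1, 1)), independent across actions, and per trial runs prediction →
choice → update:

* **Prediction.** Both actions pass through the transition kernel
  Beta(1 + G q′, 1 + G (1 − q′)) — the unique single-parameter beta
  kernel whose mode is the previous value q′ and whose spread shrinks
  with G. The mixed marginal is not a beta distribution, but its first
  two moments are analytic:

      E[q]  = (1 + G m) / (2 + G)
      E[q²] = (2 + 3 G m + G² m₂) / ((2 + G)(3 + G))

  with m, m₂ the prior's first two moments; the state is moment-matched
  back to Beta(x, y) via x = m(m(1−m)/v − 1), y = (1−m)(m(1−m)/v − 1).
  The predicted mean therefore contracts toward 0.5 by the factor
  G/(2+G) each trial, which bounds how far means can drift from 0.5 (the
  "ceiling" visible in long reward streaks) and caps the posterior
  concentration at about G + 2. `G = inf` disables the step exactly,
  which the tests exploit: without forgetting and with k = 1 the
  posterior must equal Beta(1 + #rewards, 1 + #non-rewards) by conjugate
  counting.

* **Choice.** P(L) = σ(β[(μ_L + ϕσ_L) − (μ_R + ϕσ_R)]) on the
  post-prediction moments. ϕ > 0 is an exploration bonus.

* **Update.** Chosen action only: reward → (x+1, y); non-reward →
  (x, y+k). k = 1 strict Bayes (originalBQ), k = 0 reward-only
  (asymmetricBQ, also with a ϕ = 0 restriction), k free (generalizedBQ).

The effective learning rate eα = (μ′ − μ)/(r − μ) is evaluated on the
post-prediction pair (the prediction step precedes choice and update
within a trial); closed forms 1/(x+y+1) for rewards and k/(x+y+k) for
non-rewards. Note that for k = 0 every non-reward trial has eα = 0
exactly — see "Analysis cohorts" below.

Numerical guards: beta hyperparameters are floored at 1e−6, choice
probabilities clipped to [1e−10, 1 − 1e−10] before logs, and soft-max
arguments beyond ±700 saturate instead of overflowing.

## Fitting

The fit score is the normalized likelihood Z = exp(mean_t log z(t)),
z(t) the model's probability of the observed choice. Free parameters per
variant: Q (α₁, k₁, β), FQ (α, k₁, k₂, β), dFQ (α₁, α₂, k₁, k₂, β),
originalBQ / asymmetricBQ (G, β, ϕ), asymmetricBQ ϕ=0 (G, β),
generalizedBQ (G, k, β, ϕ). Initial states are fixed, never fitted.

Optimization is multi-start bounded Powell search on −log Z (the surface
is mildly multimodal), starting from the bound-box midpoint plus
scrambled-Sobol points; the whole procedure is deterministic given its
seed. Bounds (package choices, wide relative to fitted values):
α ∈ [0, 1], k₁, k₂ ∈ [0, 2], β ∈ [0, 50], G ∈ [0.01, 1000] searched on a
log₁₀ scale, k ∈ [0, 5], ϕ ∈ [−20, 20]. Powell's line searches can probe
marginally outside the box, so the objective clips its argument to the
bounds. The forward passes used inside the objective are numba-compiled
scalar loops; the test suite asserts they are bit-identical to the pure
Python reference implementation.

Model comparison is 2-fold cross-validation over sessions: a seeded
random equal split (odd counts leave the folds differing by one; an
option stratifies the split within rats), one shared parameter vector per
fold maximizing the mean over training sessions of log Z (pooled across
rats by default, per-rat optional), each session scored exactly once with
out-of-sample parameters. Per-session fits — used for the ϕ distribution
and the learning-rate analyses — are separate from the pooled CV fits;
both interfaces exist because they answer different questions
(parameter inference per session vs. penalized model ranking).

## Behavioral analyses

* **Experience-conditioned choice.** P(optimal at t | experience at t−1
  [, t−2]) in the first and last 10 trials of blocks with ≥ 20 trials,
  where an experience is (optimal?, rewarded?). Conditioning trials must
  lie in the same block *and window* as the conditioned trial, so
  cross-block histories never contaminate a cell; empty cells are
  flagged, not dropped. The unconditional window probability ("Choice0")
  is always included. First-vs-last comparisons use Mann–Whitney U over
  per-session probabilities. No multiple-testing correction is applied by
  default (per-cell tests at the stated threshold); a flag enables one.

* **Blockwise learning rates.** For each block of ≥ 20 trials the FQ
  rate is re-optimized (bounded Brent) separately on the first-10 and
  last-10 windows, all other parameters frozen at the session fit; the
  value trajectory enters the window propagated from trial 1 under
  session-fit parameters, and within the evaluated window updates use
  the candidate rate. This keeps windows comparable while "other
  parameters constant". Windows with near-constant behavior do not
  identify α and pin it at a bound; such estimates are flagged. The
  pileup is asymmetric — stable last windows are the degenerate ones — and
  biases α_last *upward*, i.e. against the "first > last" hypothesis,
  which is why the positive-control test on all blocks is credible and
  the negative control asserts the absence of a first-window excess.

* **Effective-learning-rate windows and regression.** Mean eα per
  first/last window under a single session-level Bayesian fit, and a
  per-session OLS of eα(t) on intercept + μ_chosen(t) + σ_chosen(t) (the
  chosen action, because eα is defined only there), with coefficient
  t-tests at P < 0.01 and plain correlations reported alongside. Exactly
  collinear or constant designs are flagged, never silently solved.

* **ϕ distribution.** Median of per-session fitted ϕ plus a location
  test against zero. The default is a Wilcoxon signed-rank test; a
  Mann–Whitney reading (fitted values vs. an equal-size zero sample) is
  available behind a flag, since for a one-sample question the two are
  sometimes conflated in the literature and neither reading is asserted
  as canonical.

## Analysis cohorts and design choices

The reference synthetic rat is an asymmetric (k = 0) Bayesian Q-learner
with G = 20, β = 12, ϕ = 1.0. These values were calibrated once so that
simulated sessions match the task statistics of well-trained animals —
roughly 14 blocks per session and a mean block length of ~40 trials with
a long right tail (max a few hundred) and no truncation. Under this
model family larger ϕ is incompatible with those statistics: because
k = 0 pins the never-rewarded side's mean at 0.5, the mean-value
advantage of the optimal side is small (the forgetting ceiling), and an
uncertainty bonus of the size that per-session fits typically report
(~3.5) cancels it in the low-probability settings, so blocks essentially
never reach the 80% criterion. The dedicated parameter-recovery study
therefore uses ϕ = 3.5 (with G = 20, β = 7) on 5000-trial sessions,
where task completion is irrelevant, and recovery of the sign of ϕ is
required in ≥ 90% of 50 replicates; the FQ recovery tolerance
(|α̂ − α| ≤ 0.05 in ≥ 90% of replicates) was fixed from pilot repeat-fit
spread (max error ~0.02) before the test was frozen. Note the k₁–β pair
is only weakly identified (the soft-max sees β·ΔQ, and Q scales with
k₁, k₂); α and α's analyses do not depend on that degeneracy.

The uncertainty-driven learning-rate analyses use a *strict-Bayes*
cohort (originalBQ, k = 1, G = 10, β = 12, ϕ = 1.0, 30 sessions): with
k = 1 the effective learning rate 1/(x+y+1) is outcome-independent, so
window means isolate the uncertainty signal. On k = 0 cohorts the
outcome-dependent eα is zero on every non-reward trial and first windows
have lower reward rates, which flips the window means by reward
composition even though the underlying uncertainty signal (chosen-action
SD, reward-conditioned eα) still peaks in first windows — a genuine
property of the asymmetric model, documented here so nobody mistakes the
strict-Bayes choice for convenience.

Other choices made where the design was open: six-block schedule
windows are aligned (blocks 1–6, 7–12, …) rather than sliding; the
block-change criterion is evaluated on a per-trial sliding 20-trial
window within the current block; cohort seeds derive from a single
master seed via `numpy` seed sequences, keeping every artifact
reproducible from one integer.

## Problem sizes

Default analysis cohorts are 20–60 sessions of ~14 blocks (~500–700
trials per session); the recovery study uses 50 replicates of
5000-trial sessions per variant; the structural task quantities are
measured on a 200-session cohort. These sizes give stable majorities and
p-values for every property the suite asserts while keeping a full run
in the minutes range on one CPU.

## Known limitations

* The fitted k₁/k₂/β scale degeneracy in standard-Q variants (above).
* Session-level fits of weak uncertainty bonuses (ϕ ≈ 1) are noisy on
  ~500-trial sessions; group-level and majority statistics are reliable,
  individual ϕ estimates are not.
* The blockwise-α window protocol is a re-fit of one parameter on 10
  trials and is intrinsically noisy; its bound flags must be respected.
* Only binary rewards and beta posteriors are supported; no Gaussian or
  higher-moment (skewness) extensions, and no model-based
  (block-change-predicting) agents.
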