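"""Value-learning models for the two-choice probabilistic reward task.

Two model families are implemented as pure, stepwise operations:

* **Standard Q-learning** tracks a point estimate of each action's value
  (its expected reward) and updates the chosen action toward the outcome
  while the unchosen action decays toward zero.  Variants: original
  Q-learning (no forgetting), forgetting Q-learning (FQ, tied learning and
  forgetting rates) and differential FQ (dFQ, all four update parameters
  free).

* **Bayesian Q-learning** tracks a full beta distribution ``Beta(x, y)``
  over each action's reward probability.  Each trial applies a *prediction
  step* — a forgetting transition kernel that flattens both distributions,
  modelling a changing environment — followed by a soft-max choice on
  ``mean + phi * sd`` and a *updating step* that applies a (possibly
  asymmetric) Bernoulli-beta conjugate update to the chosen action only.
  Variants: original BQ (strict Bayes, ``k = 1``), asymmetric BQ
  (``k = 0``, non-rewards ignored), asymmetric BQ with ``phi = 0`` and
  generalized BQ (``k`` free).

All choice labels are integers: 0 = left, 1 = right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VARIANTS",
    "Q_VARIANTS",
    "BQ_VARIANTS",
    "QParams",
    "BQParams",
    "BetaPair",
    "QState",
    "BQState",
    "InfeasibleMomentsError",
    "q_step",
    "q_choice_prob",
    "transition_kernel",
    "bq_predict",
    "moment_match",
    "bq_update",
    "effective_learning_rate",
    "bq_choice_prob",
    "run_model_forward",
    "Trajectory",
]

LEFT, RIGHT = 0, 1

#: Hyperparameters are never allowed below this floor (numerical guard).
XY_MIN = 1e-6

Q_VARIANTS = ("Q", "FQ", "dFQ")
BQ_VARIANTS = ("originalBQ", "asymmetricBQ", "asymmetricBQ_phi0", "generalizedBQ")
VARIANTS = Q_VARIANTS + BQ_VARIANTS


class InfeasibleMomentsError(ValueError):
    """Raised when a (mean, variance) pair lies outside the beta family."""


def _check_action(action: int) -> int:
    if action in ("L", "l"):
        return LEFT
    if action in ("R", "r"):
        return RIGHT
    if action not in (LEFT, RIGHT):
        raise ValueError(f"action must be 0 (left), 1 (right), 'L' or 'R'; got {action!r}")
    return int(action)


def _check_reward(reward: int) -> int:
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1; got {reward!r}")
    return int(reward)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QParams:
    """Free parameters of the standard Q-learning family.

    alpha1 : learning rate of the chosen option, in [0, 1].
    alpha2 : forgetting rate of the unchosen option, in [0, 1].
    k1, k2 : reinforcement strength of reward / non-reward outcomes, >= 0.
    beta   : soft-max inverse temperature, >= 0.
    """

    alpha1: float
    alpha2: float
    k1: float
    k2: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha1 <= 1.0 and 0.0 <= self.alpha2 <= 1.0):
            raise ValueError("alpha1 and alpha2 must lie in [0, 1]")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    @classmethod
    def original_q(cls, alpha1: float, k1: float, beta: float) -> "QParams":
        """Original Q-learning: no forgetting, no non-reward reinforcement."""
        return cls(alpha1=alpha1, alpha2=0.0, k1=k1, k2=0.0, beta=beta)

    @classmethod
    def fq(cls, alpha: float, k1: float, k2: float, beta: float) -> "QParams":
        """Forgetting Q-learning: learning and forgetting rates tied."""
        return cls(alpha1=alpha, alpha2=alpha, k1=k1, k2=k2, beta=beta)


@dataclass(frozen=True)
class BQParams:
    """Free parameters of the Bayesian Q-learning family.

    G    : concentration of the forgetting transition kernel, > 0.  Small G
           flattens the action-value distributions strongly each trial;
           ``G = inf`` disables the prediction step (stationary world).
    k    : reinforcement strength of non-reward relative to reward, >= 0.
           ``k = 1`` is strict Bayes; ``k = 0`` ignores non-rewards.
    beta : soft-max inverse temperature, >= 0.
    phi  : weight of the action-value standard deviation in the choice rule;
           positive = uncertainty seeking (exploration bonus), negative =
           uncertainty aversion.
    """

    G: float
    k: float
    beta: float
    phi: float

    def __post_init__(self) -> None:
        if not self.G > 0:
            raise ValueError("G must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    @classmethod
    def original_bq(cls, G: float, beta: float, phi: float) -> "BQParams":
        return cls(G=G, k=1.0, beta=beta, phi=phi)

    @classmethod
    def asymmetric_bq(cls, G: float, beta: float, phi: float) -> "BQParams":
        return cls(G=G, k=0.0, beta=beta, phi=phi)


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaPair:
    """Hyperparameters ``(x, y)`` of one action-value beta distribution."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (self.x > 0 and self.y > 0 and math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"beta hyperparameters must be positive and finite; got ({self.x}, {self.y})")

    @property
    def mean(self) -> float:
        return self.x / (self.x + self.y)

    @property
    def var(self) -> float:
        s = self.x + self.y
        return self.x * self.y / (s * s * (s + 1.0))

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)

    @property
    def second_moment(self) -> float:
        s = self.x + self.y
        return self.x * (self.x + 1.0) / (s * (s + 1.0))

    @property
    def mode(self) -> float:
        if self.x <= 1.0 or self.y <= 1.0:
            raise ValueError("mode undefined unless x > 1 and y > 1")
        return (self.x - 1.0) / (self.x + self.y - 2.0)


@dataclass(frozen=True)
class QState:
    """Point action values of the left and right choices."""

    qL: float = 0.5
    qR: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.qL) and math.isfinite(self.qR)):
            raise ValueError("action values must be finite")

    def value(self, action: int) -> float:
        return self.qL if action == LEFT else self.qR


@dataclass(frozen=True)
class BQState:
    """Beta-distributed action values of the left and right choices."""

    left: BetaPair = field(default_factory=lambda: BetaPair(1.0, 1.0))
    right: BetaPair = field(default_factory=lambda: BetaPair(1.0, 1.0))

    def pair(self, action: int) -> BetaPair:
        return self.left if action == LEFT else self.right


# ---------------------------------------------------------------------------
# Standard Q-learning operations
# ---------------------------------------------------------------------------


def q_step(state: QState, params: QParams, action: int, reward: int) -> QState:
    """One standard-Q update.

    The chosen option moves toward ``k1 * r - k2 * (1 - r)`` at rate
    ``alpha1``; the unchosen option decays toward 0 at rate ``alpha2``.
    """
    action = _check_action(action)
    reward = _check_reward(reward)
    target = params.k1 * reward - params.k2 * (1 - reward)
    q_chosen = (1.0 - params.alpha1) * state.value(action) + params.alpha1 * target
    q_other = (1.0 - params.alpha2) * state.value(1 - action)
    if action == LEFT:
        return QState(qL=q_chosen, qR=q_other)
    return QState(qL=q_other, qR=q_chosen)


def q_choice_prob(state: QState, params: QParams) -> float:
    """Soft-max probability of choosing left: ``1 / (1 + exp(-beta (qL - qR)))``."""
    u = params.beta * (state.qL - state.qR)
    # guard against overflow for extreme beta * value differences
    if u > 700.0:
        return 1.0
    if u < -700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-u))


# ---------------------------------------------------------------------------
# Bayesian Q-learning operations
# ---------------------------------------------------------------------------


def transition_kernel(q_prev: float, G: float) -> BetaPair:
    """Forgetting kernel ``Beta(1 + G q', 1 + G (1 - q'))``.

    Its mode equals the previous value ``q_prev`` and its spread shrinks as
    the concentration ``G`` grows; ``G -> 0`` recovers the uniform
    distribution regardless of ``q_prev``.
    """
    if not (0.0 < q_prev < 1.0):
        raise ValueError(f"q_prev must lie strictly in (0, 1); got {q_prev}")
    if not G > 0:
        raise ValueError("G must be positive")
    return BetaPair(1.0 + G * q_prev, 1.0 + G * (1.0 - q_prev))


def moment_match(mean: float, variance: float) -> BetaPair:
    """Beta distribution with the given first two moments.

    Solves ``mean = x / (x + y)`` and ``variance = xy / ((x+y)^2 (x+y+1))``:
    ``x = mean * s`` and ``y = (1 - mean) * s`` with
    ``s = mean (1 - mean) / variance - 1``.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"mean must lie in (0, 1); got {mean}")
    if variance <= 0.0:
        raise ValueError(f"variance must be positive; got {variance}")
    bound = mean * (1.0 - mean)
    if variance >= bound:
        raise InfeasibleMomentsError(
            f"variance {variance} >= mean(1-mean) = {bound}: no beta distribution has these moments"
        )
    s = bound / variance - 1.0
    return BetaPair(max(mean * s, XY_MIN), max((1.0 - mean) * s, XY_MIN))


def bq_predict(prior: BetaPair, G: float) -> BetaPair:
    """Prediction step: push the prior through the forgetting kernel.

    The marginal ``integral kernel(q | q') * prior(q') dq'`` is not a beta
    distribution, but its first two moments are analytic; the result is the
    beta distribution matching them.  The predicted mean is
    ``(1 + G m) / (2 + G)`` — a contraction toward 0.5 whose strength grows
    as G shrinks.  ``G = inf`` returns the prior unchanged.
    """
    if not G > 0:
        raise ValueError("G must be positive")
    if math.isinf(G):
        return prior
    m = prior.mean
    m2 = prior.second_moment
    e1 = (1.0 + G * m) / (2.0 + G)
    e2 = (2.0 + 3.0 * G * m + G * G * m2) / ((2.0 + G) * (3.0 + G))
    var = e2 - e1 * e1
    if var <= 0.0 or var >= e1 * (1.0 - e1):
        # unreachable for valid priors; guard against numerical degeneracy
        raise InfeasibleMomentsError(
            f"predicted moments (mean={e1}, var={var}) are not beta-feasible"
        )
    return moment_match(e1, var)


def bq_update(predicted: BetaPair, reward: int, k: float) -> BetaPair:
    """Updating step for the *chosen* action's distribution.

    Reward increments ``x`` by 1; non-reward increments ``y`` by ``k``, the
    relative reinforcement strength of non-reward outcomes (``k = 1`` is the
    strict Bernoulli-beta conjugate update).  The unchosen action's
    distribution keeps its predicted form and never passes through here.
    """
    reward = _check_reward(reward)
    if k < 0:
        raise ValueError("k must be non-negative")
    if reward == 1:
        return BetaPair(predicted.x + 1.0, predicted.y)
    if k == 0.0:
        return predicted
    return BetaPair(predicted.x, predicted.y + k)


def effective_learning_rate(predicted: BetaPair, reward: int, k: float) -> float:
    """Fraction of the prediction error absorbed by one update.

    Defined as ``(mean_after - mean_before) / (reward - mean_before)`` on
    the post-prediction-step pair; closed forms are ``1 / (x + y + 1)``
    after a reward and ``k / (x + y + k)`` after a non-reward.  Sharply
    peaked distributions (large ``x + y``) yield low effective rates.
    """
    reward = _check_reward(reward)
    if k < 0:
        raise ValueError("k must be non-negative")
    s = predicted.x + predicted.y
    if reward == 1:
        return 1.0 / (s + 1.0)
    return k / (s + k)


def bq_choice_prob(state: BQState, params: BQParams) -> float:
    """Soft-max on the uncertainty-augmented values ``mean + phi * sd``.

    Positive ``phi`` favors the option with the wider action-value
    distribution (exploration bonus); negative ``phi`` avoids it.
    """
    uL = state.left.mean + params.phi * state.left.sd
    uR = state.right.mean + params.phi * state.right.sd
    u = params.beta * (uL - uR)
    if u > 700.0:
        return 1.0
    if u < -700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-u))


# ---------------------------------------------------------------------------
# Forward simulation over an observed session
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Per-trial model trajectory over an observed choice/reward sequence.

    ``p_left[t]`` is the model's left-choice probability computed *before*
    observing trial ``t``'s choice and reward.  For Bayesian variants the
    per-action means/SDs are those of the post-prediction-step
    distributions (the ones the choice rule sees), and ``ealpha[t]`` is the
    chosen action's effective learning rate on that trial.
    """

    variant: str
    p_left: np.ndarray
    states: list
    mu: np.ndarray | None = None  # (n, 2) post-prediction means, BQ only
    sd: np.ndarray | None = None  # (n, 2) post-prediction SDs, BQ only
    ealpha: np.ndarray | None = None  # (n,) chosen-action eff. rate, BQ only

    def __len__(self) -> int:
        return len(self.p_left)

    def mu_chosen(self, choices: np.ndarray) -> np.ndarray:
        return self.mu[np.arange(len(self)), choices]

    def sd_chosen(self, choices: np.ndarray) -> np.ndarray:
        return self.sd[np.arange(len(self)), choices]


def _as_arrays(choices: Sequence, rewards: Sequence) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray([_check_action(a) for a in choices], dtype=np.int64)
    r = np.asarray([_check_reward(x) for x in rewards], dtype=np.int64)
    if c.size == 0:
        raise ValueError("empty session: at least one trial is required")
    if c.shape != r.shape:
        raise ValueError("choices and rewards must have equal length")
    return c, r


def resolve_params(variant: str, params) -> QParams | BQParams:
    """Validate ``params`` against ``variant`` and its equality constraints."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant in Q_VARIANTS:
        if not isinstance(params, QParams):
            raise TypeError(f"variant {variant} requires QParams")
        if variant == "Q" and not (params.alpha2 == 0.0 and params.k2 == 0.0):
            raise ValueError("original Q-learning requires alpha2 = k2 = 0")
        if variant == "FQ" and params.alpha2 != params.alpha1:
            raise ValueError("FQ-learning requires alpha2 = alpha1")
    else:
        if not isinstance(params, BQParams):
            raise TypeError(f"variant {variant} requires BQParams")
        if variant == "originalBQ" and params.k != 1.0:
            raise ValueError("original BQ-learning requires k = 1")
        if variant in ("asymmetricBQ", "asymmetricBQ_phi0") and params.k != 0.0:
            raise ValueError("asymmetric BQ-learning requires k = 0")
        if variant == "asymmetricBQ_phi0" and params.phi != 0.0:
            raise ValueError("this variant requires phi = 0")
    return params


def run_model_forward(choices: Sequence, rewards: Sequence, variant: str, params) -> Trajectory:
    """Run one model over an observed session, trial by trial.

    Per trial the model emits its left-choice probability *before* seeing
    that trial's choice and reward, then conditions on them.  Bayesian
    variants follow the prediction -> choose -> update order within each
    trial, with *both* actions' distributions flattened by the prediction
    step and only the chosen action's distribution updated afterward.
    """
    params = resolve_params(variant, params)
    c, r = _as_arrays(choices, rewards)
    n = c.size
    p_left = np.empty(n)
    states: list = []

    if variant in Q_VARIANTS:
        state = QState()
        for t in range(n):
            p_left[t] = q_choice_prob(state, params)
            states.append(state)
            state = q_step(state, params, int(c[t]), int(r[t]))
        return Trajectory(variant=variant, p_left=p_left, states=states)

    mu = np.empty((n, 2))
    sd = np.empty((n, 2))
    ealpha = np.empty(n)
    state = BQState()
    for t in range(n):
        predicted = BQState(
            left=bq_predict(state.left, params.G),
            right=bq_predict(state.right, params.G),
        )
        p_left[t] = bq_choice_prob(predicted, params)
        mu[t, LEFT] = predicted.left.mean
        mu[t, RIGHT] = predicted.right.mean
        sd[t, LEFT] = predicted.left.sd
        sd[t, RIGHT] = predicted.right.sd
        states.append(predicted)
        chosen = predicted.pair(int(c[t]))
        ealpha[t] = effective_learning_rate(chosen, int(r[t]), params.k)
        updated = bq_update(chosen, int(r[t]), params.k)
        if c[t] == LEFT:
            state = BQState(left=updated, right=predicted.right)
        else:
            state = BQState(left=predicted.left, right=updated)
    return Trajectory(variant=variant, p_left=p_left, states=states, mu=mu, sd=sd, ealpha=ealpha)
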