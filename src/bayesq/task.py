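"""Adaptive-block two-choice task simulator and synthetic cohort generator.

The task is a free-choice two-armed bandit: on each trial the agent picks
the left or right hole and is rewarded stochastically.  Six
reward-probability settings are used — (100%, 66%), (66%, 33%), (33%, 0%)
for left vs. right and their mirrors — so the two sides always differ and
an optimal choice exists.  Trials with a fixed setting form a *block* of at
least 20 trials; the block ends (and the setting changes) once the agent
has picked the more rewarding side on at least 80% of the last 20 trials.
Settings are scheduled so that every aligned window of six blocks covers
all six settings and no setting repeats back to back.

Sessions emitted here stand in for recorded animal sessions: one row per
completed trial, error trials never represented.  A typical synthetic
session runs ~14 blocks of ~37 trials, generated by a known model agent so
that downstream fitting can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Protocol, Sequence

import numpy as np

from . import models
from .models import BQParams, BQState, QParams, QState

__all__ = [
    "SETTINGS",
    "Setting",
    "Trial",
    "Session",
    "Agent",
    "ModelAgent",
    "make_schedule",
    "block_should_change",
    "run_session",
    "generate_cohort",
]

#: Trials needed in a block before it may end, and the criterion window.
MIN_BLOCK_TRIALS = 20
CRITERION_WINDOW = 20
#: Optimal choices required within the criterion window (80% of 20).
CRITERION_COUNT = 16


@dataclass(frozen=True)
class Setting:
    """Reward probabilities of the left and right holes for one block."""

    pL: float
    pR: float

    def __post_init__(self) -> None:
        allowed = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)
        if not any(math.isclose(self.pL, v) for v in allowed) or not any(
            math.isclose(self.pR, v) for v in allowed
        ):
            raise ValueError(f"reward probabilities must be in {{0, 1/3, 2/3, 1}}; got {self}")
        if math.isclose(self.pL, self.pR):
            raise ValueError("pL and pR must differ so an optimal choice exists")

    @property
    def optimal_action(self) -> int:
        """0 (left) or 1 (right), whichever side pays more often."""
        return models.LEFT if self.pL > self.pR else models.RIGHT

    def prob(self, action: int) -> float:
        return self.pL if action == models.LEFT else self.pR


#: The six reward-probability settings: high / mid / low and their mirrors.
SETTINGS: tuple[Setting, ...] = (
    Setting(1.0, 2.0 / 3.0),
    Setting(2.0 / 3.0, 1.0 / 3.0),
    Setting(1.0 / 3.0, 0.0),
    Setting(2.0 / 3.0, 1.0),
    Setting(1.0 / 3.0, 2.0 / 3.0),
    Setting(0.0, 1.0 / 3.0),
)


@dataclass(frozen=True)
class Trial:
    """One completed behavioral trial (1-based indices)."""

    index: int
    block: int
    setting: Setting
    choice: int  # 0 = left, 1 = right
    reward: int  # 0 or 1

    @property
    def optimal(self) -> bool:
        return self.choice == self.setting.optimal_action


@dataclass
class Session:
    """An ordered trial sequence from one synthetic (or imported) session."""

    trials: list[Trial]
    session_id: str = "s0"
    rat_id: str = "rat0"
    seed: int | None = None
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> np.ndarray:
        return np.asarray([t.choice for t in self.trials], dtype=np.int64)

    @property
    def rewards(self) -> np.ndarray:
        return np.asarray([t.reward for t in self.trials], dtype=np.int64)

    @property
    def optimal(self) -> np.ndarray:
        return np.asarray([t.optimal for t in self.trials], dtype=bool)

    @property
    def n_blocks(self) -> int:
        return self.trials[-1].block if self.trials else 0

    def blocks(self) -> Iterator[list[Trial]]:
        """Yield trials grouped by block, in order."""
        current: list[Trial] = []
        for t in self.trials:
            if current and t.block != current[-1].block:
                yield current
                current = []
            current.append(t)
        if current:
            yield current

    def block_settings(self) -> list[Setting]:
        return [b[0].setting for b in self.blocks()]

    def validate(self, min_blocks: int = 7) -> None:
        """Check structural invariants; raise ValueError on violation.

        A session must have at least ``min_blocks`` blocks (sessions with
        fewer than seven are excluded from analysis), complete blocks of at
        least 20 trials, all six settings in the first six blocks and no
        setting repeated back to back.  The final block of a truncated
        session is exempt from the length check.
        """
        if not self.trials:
            raise ValueError(f"session {self.session_id}: empty")
        for i, t in enumerate(self.trials):
            if t.index != i + 1:
                raise ValueError(f"session {self.session_id}: trial indices not 1-based consecutive")
        blocks = list(self.blocks())
        if len(blocks) < min_blocks:
            raise ValueError(
                f"session {self.session_id}: only {len(blocks)} blocks (minimum {min_blocks})"
            )
        for j, b in enumerate(blocks):
            if len({t.setting for t in b}) != 1:
                raise ValueError(f"session {self.session_id}: mixed settings within block {j + 1}")
            is_last = j == len(blocks) - 1
            if len(b) < MIN_BLOCK_TRIALS and not (is_last and self.truncated):
                raise ValueError(
                    f"session {self.session_id}: block {j + 1} has {len(b)} trials (< {MIN_BLOCK_TRIALS})"
                )
        settings = [b[0].setting for b in blocks]
        if len(set(settings[:6])) != 6:
            raise ValueError(f"session {self.session_id}: first six blocks do not cover all settings")
        for j in range(1, len(settings)):
            if settings[j] == settings[j - 1]:
                raise ValueError(f"session {self.session_id}: setting repeats at block {j + 1}")


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------


class Agent(Protocol):
    """Closed-loop agent protocol used by :func:`run_session`.

    ``reset`` restores the initial state, ``step`` returns the left-choice
    probability for the upcoming trial (advancing any within-trial
    prediction step), and ``observe`` conditions on the realized choice and
    reward.
    """

    def reset(self) -> None: ...

    def step(self) -> float: ...

    def observe(self, choice: int, reward: int) -> None: ...


class ModelAgent:
    """Agent driven by one of the implemented value-learning models."""

    def __init__(self, variant: str, params: QParams | BQParams):
        self.variant = variant
        self.params = models.resolve_params(variant, params)
        self._is_bq = variant in models.BQ_VARIANTS
        self.reset()

    def reset(self) -> None:
        self._state: QState | BQState = BQState() if self._is_bq else QState()

    def step(self) -> float:
        if self._is_bq:
            self._state = BQState(
                left=models.bq_predict(self._state.left, self.params.G),
                right=models.bq_predict(self._state.right, self.params.G),
            )
            return models.bq_choice_prob(self._state, self.params)
        return models.q_choice_prob(self._state, self.params)

    def observe(self, choice: int, reward: int) -> None:
        if self._is_bq:
            updated = models.bq_update(self._state.pair(choice), reward, self.params.k)
            if choice == models.LEFT:
                self._state = BQState(left=updated, right=self._state.right)
            else:
                self._state = BQState(left=self._state.left, right=updated)
        else:
            self._state = models.q_step(self._state, self.params, choice, reward)


#: Reference synthetic-rat agent: an asymmetric Bayesian Q-learner with a
#: positive uncertainty bonus, calibrated so that simulated sessions match
#: the task statistics of well-trained animals (~37 trials per block on
#: average, block lengths ranging from 20 to a few hundred trials over ~14
#: blocks).  Because non-rewards are ignored (k = 0), the never-rewarded
#: side's value mean stays pinned near 0.5 and only a moderate uncertainty
#: bonus is compatible with reliably reaching the 80% block criterion.
DEFAULT_AGENT_VARIANT = "asymmetricBQ"
DEFAULT_AGENT_PARAMS = BQParams.asymmetric_bq(G=20.0, beta=12.0, phi=1.0)

#: Default session shape: ~14 blocks of ~20-50 trials.
DEFAULT_N_BLOCKS = 14


def default_agent() -> ModelAgent:
    return ModelAgent(DEFAULT_AGENT_VARIANT, DEFAULT_AGENT_PARAMS)


# ---------------------------------------------------------------------------
# Schedule and block-change rule
# ---------------------------------------------------------------------------


def make_schedule(n_blocks: int, rng: np.random.Generator) -> list[Setting]:
    """Draw a block-setting schedule satisfying the task's two constraints.

    Every aligned window of six blocks (1-6, 7-12, ...) is a permutation of
    the six settings, and no two adjacent blocks share a setting (also
    across window boundaries).  Among schedules satisfying both, windows
    are drawn uniformly by rejection.
    """
    if n_blocks < 6:
        raise ValueError("n_blocks must be at least 6")
    out: list[Setting] = []
    while len(out) < n_blocks:
        while True:
            perm = [SETTINGS[i] for i in rng.permutation(len(SETTINGS))]
            if not out or perm[0] != out[-1]:
                break
        out.extend(perm)
    return out[:n_blocks]


def block_should_change(optimal_flags: Sequence[bool], trials_in_block: int) -> bool:
    """True once the block may end: at least 20 trials, and the more
    rewarding side chosen on at least 16 of the last 20 (80%)."""
    if trials_in_block < MIN_BLOCK_TRIALS:
        return False
    recent = list(optimal_flags)[-CRITERION_WINDOW:]
    if len(recent) < CRITERION_WINDOW:
        return False
    return sum(recent) >= CRITERION_COUNT


# ---------------------------------------------------------------------------
# Closed-loop session simulation
# ---------------------------------------------------------------------------


def run_session(
    agent: Agent,
    schedule: Sequence[Setting],
    rng: np.random.Generator,
    max_trials: int = 5000,
    session_id: str = "s0",
    rat_id: str = "rat0",
    seed: int | None = None,
) -> Session:
    """Simulate one closed-loop session over the given block schedule.

    Per trial: the agent emits P(left), the choice is sampled, the reward is
    sampled Bernoulli(setting probability of the chosen side), the agent
    observes both, and the block advances once the 80%-in-last-20 criterion
    fires.  If ``max_trials`` is reached before the schedule is exhausted
    (possible for poorly performing agents) the session is returned with
    ``truncated=True`` rather than raising.
    """
    agent.reset()
    trials: list[Trial] = []
    block_optimal: list[bool] = []
    block_idx = 0
    truncated = False
    while block_idx < len(schedule):
        if len(trials) >= max_trials:
            truncated = True
            break
        setting = schedule[block_idx]
        p_left = agent.step()
        choice = models.LEFT if rng.random() < p_left else models.RIGHT
        reward = 1 if rng.random() < setting.prob(choice) else 0
        agent.observe(choice, reward)
        trial = Trial(
            index=len(trials) + 1,
            block=block_idx + 1,
            setting=setting,
            choice=choice,
            reward=reward,
        )
        trials.append(trial)
        block_optimal.append(trial.optimal)
        if block_should_change(block_optimal, len(block_optimal)):
            block_idx += 1
            block_optimal = []
    return Session(
        trials=trials,
        session_id=session_id,
        rat_id=rat_id,
        seed=seed,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _agent_from_spec(spec: dict) -> ModelAgent:
    variant = spec["variant"]
    p = spec["params"]
    if variant in models.Q_VARIANTS:
        params = QParams(**p)
    else:
        params = BQParams(**p)
    return ModelAgent(variant, params)


def generate_cohort(
    rat_specs: Sequence[dict],
    seed: int,
    n_blocks: int = DEFAULT_N_BLOCKS,
    max_trials: int = 5000,
) -> tuple[list[Session], dict]:
    """Generate a reproducible multi-rat cohort of synthetic sessions.

    ``rat_specs`` is a sequence of dicts with keys ``rat_id``, ``variant``,
    ``params`` (a dict of the variant's full parameter fields) and
    ``n_sessions``.  Per-session seeds are derived from the master seed, so
    the same master seed yields an identical cohort and manifest.  Returns
    the session list and a manifest recording the true generating
    parameters for parameter-recovery work.
    """
    ids = [spec["rat_id"] for spec in rat_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate rat_id in cohort spec")
    n_total = sum(int(spec["n_sessions"]) for spec in rat_specs)
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_total) % (2**31)
    sessions: list[Session] = []
    manifest: dict = {"master_seed": int(seed), "n_blocks": int(n_blocks), "sessions": []}
    i = 0
    for spec in rat_specs:
        for j in range(int(spec["n_sessions"])):
            sched_seed = int(child_seeds[2 * i])
            loop_seed = int(child_seeds[2 * i + 1])
            i += 1
            session_id = f"{spec['rat_id']}_s{j:03d}"
            schedule = make_schedule(n_blocks, np.random.default_rng(sched_seed))
            session = run_session(
                _agent_from_spec(spec),
                schedule,
                np.random.default_rng(loop_seed),
                max_trials=max_trials,
                session_id=session_id,
                rat_id=spec["rat_id"],
                seed=loop_seed,
            )
            sessions.append(session)
            manifest["sessions"].append(
                {
                    "session_id": session_id,
                    "rat_id": spec["rat_id"],
                    "variant": spec["variant"],
                    "params": dict(spec["params"]),
                    "schedule_seed": sched_seed,
                    "loop_seed": loop_seed,
                    "n_trials": len(session),
                    "n_blocks": session.n_blocks,
                    "truncated": session.truncated,
                }
            )
    return sessions, manifest
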