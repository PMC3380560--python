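import numpy as np
import pytest

from bayesq import task
from bayesq.models import BQParams, QParams
from bayesq.task import ModelAgent, Session, Setting, Trial


@pytest.fixture(scope="session")
def default_cohort():
    """20 sessions from the reference asymmetric-BQ synthetic rat."""
    specs = [
        {
            "rat_id": "rat0",
            "variant": task.DEFAULT_AGENT_VARIANT,
            "params": {"G": 20.0, "k": 0.0, "beta": 12.0, "phi": 1.0},
            "n_sessions": 20,
        }
    ]
    sessions, manifest = task.generate_cohort(specs, seed=101)
    return sessions, manifest


@pytest.fixture(scope="session")
def random_agent_sessions():
    """Truncated sessions from a chance-level (beta=0) agent, for
    empirical reward-rate and structural checks."""
    out = []
    for seed in range(60):
        rng = np.random.default_rng(900 + seed)
        agent = ModelAgent("FQ", QParams.fq(alpha=0.3, k1=1.0, k2=0.0, beta=0.0))
        schedule = task.make_schedule(6, rng)
        out.append(task.run_session(agent, schedule, rng, max_trials=200, session_id=f"rnd{seed}"))
    return out


def session_from_arrays(choices, rewards, setting=None, block_len=None, session_id="toy"):
    """Build a Session directly from choice/reward arrays (single setting,
    equal-length blocks) without running the simulator."""
    setting = setting or Setting(2.0 / 3.0, 1.0 / 3.0)
    n = len(choices)
    block_len = block_len or n
    trials = [
        Trial(
            index=i + 1,
            block=i // block_len + 1,
            setting=setting,
            choice=int(choices[i]),
            reward=int(rewards[i]),
        )
        for i in range(n)
    ]
    return Session(trials=trials, session_id=session_id)
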