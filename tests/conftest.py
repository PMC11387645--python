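import numpy as np
import pandas as pd
import pytest

from twostep_eeg.hybrid import AgentParams
from twostep_eeg.task import SubjectBehavior, TaskConfig, simulate_subject


@pytest.fixture(scope="session")
def cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def prob_cfg():
    """Binary-reward / probability-walk reading of the task."""
    return TaskConfig(walk_mode="probability")


def make_behavior(trials, subject_id="s000", **traits):
    """Build a SubjectBehavior from (a1, s2, a2, points) tuples."""
    label = {1: "B", 2: "C"}
    rows = []
    for i, (a1, s2, a2, pts) in enumerate(trials):
        preferred = 1 if a1 == 0 else 2
        rows.append({"subject_id": subject_id, "trial": i, "a1": a1,
                     "s2": label[s2],
                     "transition": "common" if s2 == preferred else "rare",
                     "a2": a2, "reward_points": pts,
                     "rt1_ms": 500.0, "rt2_ms": 450.0})
    return SubjectBehavior(subject_id, pd.DataFrame(rows), **traits)


def random_trials(rng, n, points_lo=-4, points_hi=5):
    return [(int(rng.integers(2)), int(rng.integers(1, 3)), int(rng.integers(2)),
             int(rng.integers(points_lo, points_hi + 1))) for _ in range(n)]


@pytest.fixture(scope="session")
def mid_agent():
    return AgentParams(alpha=0.6, lam=0.6, beta=5.0, w=0.5, pi=0.25)


@pytest.fixture(scope="session")
def simulated_subject(cfg, mid_agent):
    return simulate_subject(mid_agent, cfg, np.random.default_rng(42))
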