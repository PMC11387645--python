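"""Two-step task environment and generative RL agents.

The task: a stage-1 choice between two options ("spaceships") leads to one of
two stage-2 states ("planets") through a fixed probabilistic transition
structure (80% common / 20% rare by default); a stage-2 choice then yields an
integer point outcome that drifts across trials as a reflective random walk
bounded at -4 and +5 points.  Sessions are 500 trials in four blocks.

Agents are hybrid SARSA(lambda)/model-based learners (see
:mod:`twostep_eeg.hybrid`) playing the task generatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._kernels import simulate_kernel
from .hybrid import AgentParams, ModelVariant, HYBRID_CHOICE

BEHAVIOR_COLUMNS = [
    "subject_id", "trial", "a1", "s2", "transition", "a2",
    "reward_points", "rt1_ms", "rt2_ms",
]

_STATE_LABEL = {1: "B", 2: "C"}
_STATE_INDEX = {"B": 1, "C": 2}


@dataclass(frozen=True)
class TaskConfig:
    """Environment parameters of the two-step task."""

    n_trials: int = 500
    p_common: float = 0.8
    reward_min: int = -4
    reward_max: int = 5
    walk_step: int = 1
    walk_step_prob: float = 0.2
    # the task description conflates drifting point magnitudes with drifting
    # reward probabilities; "magnitude" is the default reading, "probability"
    # (binary 1/0-point outcomes, Gaussian probability walk) the alternative
    walk_mode: str = "magnitude"
    prob_min: float = 0.25
    prob_max: float = 0.75
    prob_step_sd: float = 0.025
    response_window_ms: float = 2000.0
    n_blocks: int = 4          # metadata only; no analysis distinguishes blocks
    reward_scale: Optional[float] = None  # default: 1 / reward_max
    # synthetic response-time model (log-normal with a rare-transition shift)
    rt1_median_ms: float = 500.0
    rt2_median_ms: float = 450.0
    rt_sigma: float = 0.25
    rare_rt_shift_ms: float = 30.0
    # optional degradation to exercise downstream filters
    miss_rate: float = 0.0
    fast_rate: float = 0.0
    shuffle_positions: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError("p_common must lie in (0.5, 1]")
        if not (self.reward_min < 0 < self.reward_max):
            raise ValueError("reward bounds must straddle zero")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.walk_mode not in ("magnitude", "probability"):
            raise ValueError("walk_mode must be 'magnitude' or 'probability'")

    @property
    def scale(self) -> float:
        if self.reward_scale is not None:
            return self.reward_scale
        return 1.0 if self.walk_mode == "probability" else 1.0 / self.reward_max


@dataclass
class SubjectBehavior:
    """One subject's trial sequence plus trait scores."""

    subject_id: str
    trials: pd.DataFrame
    bis_score: float = np.nan
    oci_score: float = np.nan
    gender: Optional[str] = None

    def __post_init__(self):
        tr = self.trials["trial"].to_numpy()
        if len(tr) and not np.array_equal(tr, np.arange(tr[0], tr[0] + len(tr))):
            raise ValueError("trial indices must be consecutive and increasing")


def sample_transition(a1: int, cfg: TaskConfig, rng: np.random.Generator):
    """Draw the stage-2 state for a stage-1 action.

    Returns ``(s2_label, transition_label)``; the action's preferred stage is
    reached with probability ``cfg.p_common``.
    """
    if a1 not in (0, 1):
        raise ValueError(f"invalid stage-1 action {a1!r}")
    preferred = 1 if a1 == 0 else 2
    other = 3 - preferred
    common = rng.random() < cfg.p_common
    s2 = preferred if common else other
    return _STATE_LABEL[s2], ("common" if common else "rare")


def step_reward_walk(current: np.ndarray, cfg: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Advance the four stage-2 point values one step of the reflective walk."""
    cur = np.asarray(current)
    if cur.min() < cfg.reward_min or cur.max() > cfg.reward_max:
        raise ValueError("reward values outside configured bounds")
    out = cur.copy()
    for j in range(out.size):
        if rng.random() < cfg.walk_step_prob:
            step = cfg.walk_step if rng.random() < 0.5 else -cfg.walk_step
            v = out.flat[j] + step
            if v > cfg.reward_max:
                v = 2 * cfg.reward_max - v
            if v < cfg.reward_min:
                v = 2 * cfg.reward_min - v
            out.flat[j] = v
    return out


def simulate_subject(params: AgentParams, cfg: TaskConfig,
                     rng: np.random.Generator,
                     variant: ModelVariant = HYBRID_CHOICE,
                     subject_id: str = "s000",
                     bis_score: float = np.nan,
                     oci_score: float = np.nan) -> SubjectBehavior:
    """Simulate a full session of one hybrid agent.

    Choices are sampled from the stickiness softmax over hybrid Q values,
    transitions from the 80/20 structure, and outcomes from the reflective
    point walk; Q values are updated by SARSA(lambda) after every trial.
    Response times are log-normal with an additive slowing of the stage-2 RT
    on rare transitions.
    """
    variant.check_params(params)
    n = cfg.n_trials
    mode = 0 if cfg.walk_mode == "magnitude" else 1
    if mode == 0:
        rewards0 = rng.integers(cfg.reward_min, cfg.reward_max + 1, size=4).astype(float)
    else:
        rewards0 = rng.uniform(cfg.prob_min, cfg.prob_max, size=4)
    pos_map = (rng.integers(0, 2, size=n) if cfg.shuffle_positions
               else np.zeros(n, np.int64)).astype(np.int64)
    u1, ut, u2, ur = rng.random(n), rng.random(n), rng.random(n), rng.random(n)
    uw = rng.random((n, 4))
    us = rng.random((n, 4)) if mode == 0 else rng.standard_normal((n, 4))
    a1, s2, a2, points, _ = simulate_kernel(
        n, cfg.p_common, params.alpha, params.lam, params.beta, params.w,
        params.pi, params.rho, rewards0, cfg.walk_step,
        cfg.walk_step_prob, cfg.reward_min, cfg.reward_max, cfg.scale,
        mode, cfg.prob_step_sd, cfg.prob_min, cfg.prob_max,
        pos_map, u1, ut, u2, uw, us, ur)
    preferred = np.where(a1 == 0, 1, 2)
    transition = np.where(s2 == preferred, "common", "rare")
    rt1 = cfg.rt1_median_ms * np.exp(rng.normal(0.0, cfg.rt_sigma, n))
    rt2 = cfg.rt2_median_ms * np.exp(rng.normal(0.0, cfg.rt_sigma, n))
    rt2 = rt2 + np.where(transition == "rare", cfg.rare_rt_shift_ms, 0.0)
    df = pd.DataFrame({
        "subject_id": subject_id,
        "trial": np.arange(n),
        "a1": a1, "s2": [_STATE_LABEL[s] for s in s2],
        "transition": transition, "a2": a2,
        "reward_points": points,
        "rt1_ms": rt1, "rt2_ms": rt2,
        "block": np.minimum(np.arange(n) * cfg.n_blocks // n, cfg.n_blocks - 1),
    })
    if cfg.fast_rate > 0:
        fast = rng.random(n) < cfg.fast_rate
        df.loc[fast, "rt2_ms"] = rng.uniform(20, 90, fast.sum())
    if cfg.miss_rate > 0:
        miss = rng.random(n) < cfg.miss_rate
        df.loc[miss, ["a1", "a2"]] = -1
        df.loc[miss, ["rt1_ms", "rt2_ms"]] = np.nan
    return SubjectBehavior(subject_id, df, bis_score, oci_score)


def behavior_arrays(trials: pd.DataFrame):
    """Convert a behavior table to the integer arrays the kernels consume.

    Returns ``(a1, s2_index, a2, points, valid)``; trials with a missing
    response (action coded -1 or NaN RT) are marked invalid.
    """
    a1 = trials["a1"].to_numpy(np.int64)
    a2 = trials["a2"].to_numpy(np.int64)
    s2 = np.array([_STATE_INDEX[s] for s in trials["s2"]], np.int64)
    points = trials["reward_points"].to_numpy(np.int64)
    valid = (a1 >= 0) & (a2 >= 0)
    return a1, s2, a2, points, valid


def write_behavior_csv(subjects: list[SubjectBehavior], path) -> None:
    pd.concat([s.trials[BEHAVIOR_COLUMNS] for s in subjects]).to_csv(path, index=False)


def read_behavior_csv(path, traits: Optional[pd.DataFrame] = None) -> list[SubjectBehavior]:
    """Load a behavior CSV (one row per trial) into per-subject records.

    ``traits`` may supply columns subject_id, bis_score, oci_score, gender.
    """
    df = pd.read_csv(path)
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    tr = traits.set_index("subject_id") if traits is not None else None
    out = []
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("trial").reset_index(drop=True)
        kw = {}
        if tr is not None and sid in tr.index:
            row = tr.loc[sid]
            kw = dict(bis_score=row.get("bis_score", np.nan),
                      oci_score=row.get("oci_score", np.nan),
                      gender=row.get("gender", None))
        out.append(SubjectBehavior(str(sid), g, **kw))
    return out
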