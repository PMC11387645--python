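"""Hybrid model-free/model-based RL model of the two-step task.

Model-free values are learned by SARSA(lambda): with both updates applied at
the second stage,

    delta1 = Q_MF(s2, a2) - Q_MF(s1, a1)          (stage-1 RPE; r1 = 0)
    delta2 = r - Q_MF(s2, a2)                      (stage-2 RPE)
    Q_MF(s1, a1) += alpha * delta1 + alpha * lam * delta2
    Q_MF(s2, a2) += alpha * delta2

Model-based stage-1 values plan over the true transition matrix:

    Q_MB(s_A, a) = P(s_B|a) max_a' Q_MF(s_B, a') + P(s_C|a) max_a' Q_MF(s_C, a')

and a hybrid agent mixes them with weight ``w``:

    Q_net = w * Q_MB + (1 - w) * Q_MF.

Choices follow a softmax with inverse temperature ``beta`` plus choice
stickiness ``pi`` (repeat the previous stage-1 stimulus) and response
stickiness ``rho`` (repeat the previous response key):

    P(a) ~ exp(beta * (Q_net(a) + pi * rep(a) + rho * resp(a))).

At stage 2 model-free and model-based values coincide and no stickiness
applies.  The signed stage-2 prediction error ``delta2`` is the trial-wise
RPE used by the EEG analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import loglik_kernel

N_STATES, N_ACTIONS = 3, 2


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of one model variant.

    alpha : learning rate in [0, 1]
    lam   : eligibility-trace decay in [0, 1]
    beta  : softmax inverse temperature >= 0
    w     : model-based weight in [0, 1] (0 = pure MF, 1 = pure MB)
    pi    : choice stickiness (unbounded)
    rho   : response stickiness (unbounded)
    """

    alpha: float
    lam: float
    beta: float
    w: float
    pi: float = 0.0
    rho: float = 0.0

    def __post_init__(self):
        for name in ("alpha", "lam", "w"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("alpha", "lam", "beta", "w", "pi", "rho")}


@dataclass(frozen=True)
class ModelVariant:
    """One of the 3 families x 3 stickiness levels compared by BIC.

    ``fixed`` pins parameters that the family removes (w for MF/MB, lam for
    MB where it is unidentified, pi/rho for the reduced stickiness levels);
    ``free`` lists the fitted parameters in a fixed order.
    """

    name: str
    free: tuple
    fixed: dict

    @property
    def k(self) -> int:
        return len(self.free)

    def build_params(self, values: Sequence[float]) -> AgentParams:
        d = dict(zip(self.free, values))
        d.update(self.fixed)
        return AgentParams(**d)

    def check_params(self, params: AgentParams) -> None:
        for k, v in self.fixed.items():
            if getattr(params, k) != v:
                raise ValueError(
                    f"variant {self.name!r} fixes {k}={v}, got {getattr(params, k)}")


def _make_variants():
    fam = {
        "mf": (("alpha", "lam", "beta"), {"w": 0.0}),
        "mb": (("alpha", "beta"), {"w": 1.0, "lam": 1.0}),
        "hybrid": (("alpha", "lam", "beta", "w"), {}),
    }
    sticky = {"pure": ((), {"pi": 0.0, "rho": 0.0}),
              "choice": (("pi",), {"rho": 0.0}),
              "choice_resp": (("pi", "rho"), {})}
    out = {}
    for fname, (ffree, ffix) in fam.items():
        for sname, (sfree, sfix) in sticky.items():
            name = f"{fname}_{sname}"
            out[name] = ModelVariant(name, ffree + sfree, {**ffix, **sfix})
    return out


MODEL_VARIANTS = _make_variants()
HYBRID_CHOICE = MODEL_VARIANTS["hybrid_choice"]


@dataclass
class QState:
    """Model-free value table (3 states x 2 actions) plus eligibility trace."""

    q_mf: np.ndarray = field(default_factory=lambda: np.zeros((N_STATES, N_ACTIONS)))
    eligibility: np.ndarray = field(default_factory=lambda: np.zeros((N_STATES, N_ACTIONS)))

    def copy(self) -> "QState":
        return QState(self.q_mf.copy(), self.eligibility.copy())


def mf_update(q: QState, s1: int, a1: int, s2: int, a2: int, reward: float,
              alpha: float, lam: float):
    """One SARSA(lambda) trial update; returns ``(new_q, delta1, delta2)``.

    ``reward`` is the (scaled) stage-2 outcome; both prediction errors use
    pre-update values, and only the two visited (state, action) pairs change.
    """
    out = q.copy()
    out.eligibility[:] = 0.0
    delta1 = q.q_mf[s2, a2] - q.q_mf[s1, a1]
    delta2 = reward - q.q_mf[s2, a2]
    out.eligibility[s1, a1] = lam   # decayed stage-1 trace at the stage-2 update
    out.eligibility[s2, a2] = 1.0
    out.q_mf[s1, a1] += alpha * delta1 + alpha * lam * delta2
    out.q_mf[s2, a2] += alpha * delta2
    return out, delta1, delta2


def mb_values(q: QState, p_common: float) -> np.ndarray:
    """Stage-1 model-based values planned over the true transition matrix."""
    if not 0.5 < p_common <= 1.0:
        raise ValueError("p_common must lie in (0.5, 1]")
    mx = q.q_mf[1:3].max(axis=1)  # max over actions at s_B, s_C
    p = np.array([[p_common, 1.0 - p_common], [1.0 - p_common, p_common]])
    return p @ mx


def hybrid_values(q_mb: np.ndarray, q_mf_stage1: np.ndarray, w: float) -> np.ndarray:
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    return w * np.asarray(q_mb) + (1.0 - w) * np.asarray(q_mf_stage1)


def choice_probabilities(q_net: np.ndarray, beta: float, pi: float = 0.0,
                         rho: float = 0.0, prev_choice: Optional[int] = None,
                         prev_key: Optional[int] = None,
                         key_of: Sequence[int] = (0, 1)) -> np.ndarray:
    """Stickiness softmax over the available actions.

    ``rep(a)`` is 1 when ``a`` equals the previous stage-1 choice, ``resp(a)``
    when the key mapped to ``a`` equals the previously pressed key; both are 0
    on the first trial.  Computed via log-sum-exp, so stable for large beta.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    q_net = np.asarray(q_net, float)
    rep = np.array([1.0 if prev_choice == a else 0.0 for a in range(len(q_net))])
    resp = np.array([1.0 if prev_key is not None and key_of[a] == prev_key else 0.0
                     for a in range(len(q_net))])
    u = beta * (q_net + pi * rep + rho * resp)
    u -= u.max()
    e = np.exp(u)
    return e / e.sum()


@dataclass
class TrialLikelihood:
    """Per-trial likelihood terms and signed prediction errors."""

    trial: int
    loglik_stage1: float
    loglik_stage2: float
    delta1: float
    delta2: float


def sequence_loglik(params: AgentParams, behavior, cfg, variant: Optional[ModelVariant] = None):
    """Total choice log-likelihood of one subject plus per-trial traces.

    Iterates trials in order, accumulating ``log P(a1) + log P(a2)`` with Q
    updated after each trial.  Returns ``(total, DataFrame)`` where the frame
    carries columns trial, loglik_stage1, loglik_stage2, delta1, delta2 (the
    delta2 column is the signed RPE series used by the EEG analyses).
    Invalid (missed/filtered) trials contribute no likelihood; Q is carried
    forward and the stickiness indicators reset.
    """
    from .task import behavior_arrays  # local import to avoid a cycle

    if variant is not None:
        variant.check_params(params)
    trials = behavior.trials if hasattr(behavior, "trials") else behavior
    a1, s2, a2, points, valid = behavior_arrays(trials)
    r = points * cfg.scale
    pos_map = np.zeros(len(a1), np.int64)
    total, ll1, ll2, d1, d2 = loglik_kernel(
        a1, s2, a2, r.astype(float), valid, pos_map, cfg.p_common,
        params.alpha, params.lam, params.beta, params.w, params.pi, params.rho)
    if not np.isfinite(total):
        bad = int(np.flatnonzero(~np.isfinite(np.nan_to_num(ll1 + ll2, nan=0.0)))[0])
        raise FloatingPointError(f"non-finite log-likelihood at trial {bad}")
    frame = pd.DataFrame({
        "trial": trials["trial"].to_numpy(),
        "loglik_stage1": ll1, "loglik_stage2": ll2,
        "delta1": d1, "delta2": d2,
    })
    return total, frame


def export_rpe_csv(behavior, frame: pd.DataFrame, path) -> None:
    """Write the per-trial signed RPE series (column ``rpe``) for joining
    with epoch metadata."""
    out = frame[["trial"]].copy()
    out.insert(0, "subject_id", behavior.subject_id)
    out["rpe"] = frame["delta2"]
    out.to_csv(path, index=False)
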