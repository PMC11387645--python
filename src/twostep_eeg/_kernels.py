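"""Numba-compiled trial-loop kernels for the two-step hybrid RL model.

The two-step task has three states (stage 1: s_A; stage 2: s_B, s_C) and two
actions per state.  Stage-2 states are indexed 1 (B) and 2 (C); stage 1 is
state 0.  Action 0 leads to s_B with probability ``p_common``, action 1 to
s_C.  Rewards are pre-scaled by the caller.

Both the likelihood kernel and the generative kernel implement the same
SARSA(lambda) + model-based planning + stickiness-softmax equations; the
likelihood path is additionally cross-checked in the test suite against a
pure-Python step-by-step trace.
"""

import math

import numpy as np
from numba import njit

__all__ = ["loglik_kernel", "simulate_kernel"]


@njit(cache=True)
def _log_softmax2(u0, u1, choice):
    """log P(choice) for a 2-way softmax over utilities (u0, u1)."""
    m = u0 if u0 > u1 else u1
    lz = m + math.log(math.exp(u0 - m) + math.exp(u1 - m))
    return (u0 if choice == 0 else u1) - lz


@njit(cache=True)
def _stage1_utils(q, p_common, alpha_unused, w, beta, pi, rho, prev_a1, prev_key, pos_map, out):
    """Softmax utilities beta*(Qnet + pi*rep + rho*resp) for stage-1 actions."""
    q_b_max = q[1, 0] if q[1, 0] > q[1, 1] else q[1, 1]
    q_c_max = q[2, 0] if q[2, 0] > q[2, 1] else q[2, 1]
    for a in range(2):
        if a == 0:
            q_mb = p_common * q_b_max + (1.0 - p_common) * q_c_max
        else:
            q_mb = (1.0 - p_common) * q_b_max + p_common * q_c_max
        q_net = w * q_mb + (1.0 - w) * q[0, a]
        rep = 1.0 if a == prev_a1 else 0.0
        key = a ^ pos_map
        resp = 1.0 if key == prev_key else 0.0
        out[a] = beta * (q_net + pi * rep + rho * resp)


@njit(cache=True)
def loglik_kernel(a1, s2, a2, r, valid, pos_map, p_common,
                  alpha, lam, beta, w, pi, rho):
    """Sequence log-likelihood plus per-trial traces.

    Parameters
    ----------
    a1, a2 : int arrays, stage-1/stage-2 actions (0/1; ignored where invalid)
    s2 : int array, realized stage-2 state (1 or 2)
    r : float array, scaled reward
    valid : bool array; invalid trials contribute no likelihood, carry Q
        forward and reset the stickiness indicators
    pos_map : int array; physical key of stage-1 action a on trial t is
        ``a ^ pos_map[t]`` (all-zero = fixed positions)

    Returns
    -------
    total loglik, ll1, ll2, delta1, delta2 (per-trial; NaN where invalid)
    """
    n = a1.shape[0]
    q = np.zeros((3, 2))
    ll1 = np.full(n, np.nan)
    ll2 = np.full(n, np.nan)
    d1 = np.full(n, np.nan)
    d2 = np.full(n, np.nan)
    util = np.zeros(2)
    total = 0.0
    prev_a1 = -1
    prev_key = -1
    for t in range(n):
        if not valid[t]:
            prev_a1 = -1
            prev_key = -1
            continue
        _stage1_utils(q, p_common, alpha, w, beta, pi, rho,
                      prev_a1, prev_key, pos_map[t], util)
        ll1[t] = _log_softmax2(util[0], util[1], a1[t])
        s = s2[t]
        ll2[t] = _log_softmax2(beta * q[s, 0], beta * q[s, 1], a2[t])
        total += ll1[t] + ll2[t]
        # prediction errors with pre-update values
        d1[t] = q[s, a2[t]] - q[0, a1[t]]
        d2[t] = r[t] - q[s, a2[t]]
        # SARSA(lambda): both updates occur at stage 2; the stage-1 value
        # receives the stage-2 error weighted by the eligibility decay
        q[0, a1[t]] += alpha * d1[t] + alpha * lam * d2[t]
        q[s, a2[t]] += alpha * d2[t]
        prev_a1 = a1[t]
        prev_key = a1[t] ^ pos_map[t]
    return total, ll1, ll2, d1, d2


@njit(cache=True)
def simulate_kernel(n_trials, p_common, alpha, lam, beta, w, pi, rho,
                    rewards0, walk_step, walk_step_prob, reward_min, reward_max,
                    reward_scale, walk_mode, prob_step_sd, prob_min, prob_max,
                    pos_map, u1, ut, u2, uw, us, ur):
    """Generate one subject's choices/transitions/outcomes.

    ``rewards0`` is the initial 4-vector for (state, action) in order
    (B0, B1, C0, C1): integer point values in walk_mode 0 (drifting point
    magnitudes, reflective at the point bounds) or reward probabilities in
    walk_mode 1 (binary 1/0-point outcomes, Gaussian-step probability walk
    reflective at [prob_min, prob_max]).  ``u1, ut, u2, ur`` are pre-drawn
    uniforms for the sampling steps; ``uw`` (n x 4) gates magnitude-walk
    moves; ``us`` (n x 4) supplies step signs (mode 0) or standard normals
    (mode 1).

    Returns (a1, s2, a2, points, reward_trace) where reward_trace is the
    (n x 4) reward table *before* each trial's outcome.
    """
    a1 = np.zeros(n_trials, np.int64)
    s2 = np.zeros(n_trials, np.int64)
    a2 = np.zeros(n_trials, np.int64)
    points = np.zeros(n_trials, np.int64)
    trace = np.zeros((n_trials, 4))
    rew = rewards0.astype(np.float64)
    q = np.zeros((3, 2))
    util = np.zeros(2)
    prev_a1 = -1
    prev_key = -1
    for t in range(n_trials):
        trace[t] = rew
        _stage1_utils(q, p_common, alpha, w, beta, pi, rho,
                      prev_a1, prev_key, pos_map[t], util)
        p0 = 1.0 / (1.0 + math.exp(util[1] - util[0]))
        c1 = 0 if u1[t] < p0 else 1
        # action 0 commonly -> B (state 1), action 1 commonly -> C (state 2)
        preferred = 1 if c1 == 0 else 2
        other = 2 if c1 == 0 else 1
        s = preferred if ut[t] < p_common else other
        p0 = 1.0 / (1.0 + math.exp(beta * (q[s, 1] - q[s, 0])))
        c2 = 0 if u2[t] < p0 else 1
        j_out = 2 * (s - 1) + c2
        if walk_mode == 0:
            pts = int(rew[j_out])
        else:
            pts = 1 if ur[t] < rew[j_out] else 0
        rr = pts * reward_scale
        dd1 = q[s, c2] - q[0, c1]
        dd2 = rr - q[s, c2]
        q[0, c1] += alpha * dd1 + alpha * lam * dd2
        q[s, c2] += alpha * dd2
        a1[t] = c1
        s2[t] = s
        a2[t] = c2
        points[t] = pts
        prev_a1 = c1
        prev_key = c1 ^ pos_map[t]
        # reflective random walk on the four reward entries
        for j in range(4):
            if walk_mode == 0:
                if uw[t, j] < walk_step_prob:
                    step = walk_step if us[t, j] < 0.5 else -walk_step
                    v = rew[j] + step
                    if v > reward_max:
                        v = 2 * reward_max - v
                    if v < reward_min:
                        v = 2 * reward_min - v
                    rew[j] = v
            else:
                v = rew[j] + prob_step_sd * us[t, j]
                if v > prob_max:
                    v = 2 * prob_max - v
                if v < prob_min:
                    v = 2 * prob_min - v
                rew[j] = v
    return a1, s2, a2, points, trace
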