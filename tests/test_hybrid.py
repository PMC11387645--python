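"""Equation-level tests of the hybrid RL model against hand and trace oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twostep_eeg.hybrid import (AgentParams, QState, choice_probabilities,
                                hybrid_values, mb_values, mf_update,
                                sequence_loglik)
from twostep_eeg.task import TaskConfig

from _trace_oracle import trace_loglik
from conftest import make_behavior, random_trials


class TestMfUpdate:
    def test_hand_evaluated_single_trial(self):
        # all Q=0, r=1, alpha=0.5, lam=0.5
        q, d1, d2 = mf_update(QState(), 0, 0, 1, 1, reward=1.0, alpha=0.5, lam=0.5)
        assert d1 == 0.0 and d2 == 1.0
        assert q.q_mf[1, 1] == 0.5          # stage-2: alpha * delta2
        assert q.q_mf[0, 0] == 0.25         # stage-1: alpha * lam * delta2
        visited = np.zeros((3, 2), bool)
        visited[0, 0] = visited[1, 1] = True
        assert np.all(q.q_mf[~visited] == 0)

    def test_zero_learning_rate_reports_delta_but_freezes_q(self):
        q0 = QState()
        q0.q_mf[1, 0] = 0.4
        q, d1, d2 = mf_update(q0, 0, 1, 1, 0, reward=1.0, alpha=0.0, lam=0.5)
        assert d2 == pytest.approx(0.6)
        assert np.array_equal(q.q_mf, q0.q_mf)

    def test_zero_trace_updates_only_current_stage(self):
        # lam=0: the stage-2 error does not reach the stage-1 value
        q, d1, d2 = mf_update(QState(), 0, 0, 1, 1, reward=1.0, alpha=0.5, lam=0.0)
        assert q.q_mf[0, 0] == 0.0
        assert q.q_mf[1, 1] == 0.5


class TestMbValues:
    def test_plans_over_transition_matrix(self):
        q = QState()
        q.q_mf[1, 0] = 1.0  # max at s_B = 1, s_C = 0
        np.testing.assert_allclose(mb_values(q, 0.8), [0.8, 0.2])

    def test_equal_stage2_maxima_give_equal_values(self):
        q = QState()
        q.q_mf[1, 1] = 0.7
        q.q_mf[2, 0] = 0.7
        vals = mb_values(q, 0.8)
        assert vals[0] == vals[1] == pytest.approx(0.7)

    def test_deterministic_transitions(self):
        q = QState()
        q.q_mf[1, 0] = 0.9
        q.q_mf[2, 1] = 0.3
        np.testing.assert_allclose(mb_values(q, 1.0), [0.9, 0.3])


def test_hybrid_values_mixture():
    q_mb, q_mf = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    np.testing.assert_allclose(hybrid_values(q_mb, q_mf, 1.0), q_mb)
    np.testing.assert_allclose(hybrid_values(q_mb, q_mf, 0.0), q_mf)
    np.testing.assert_allclose(hybrid_values(q_mb, q_mf, 0.5), [0.5, 0.5])


class TestChoiceProbabilities:
    def test_uniform_at_zero_temperature(self):
        np.testing.assert_allclose(
            choice_probabilities(np.array([3.0, -1.0]), beta=0.0), [0.5, 0.5])

    def test_hand_evaluated_softmax(self):
        p = choice_probabilities(np.array([1.0, 0.0]), beta=1.0)
        e = np.e
        np.testing.assert_allclose(p, [e / (1 + e), 1 / (1 + e)], atol=1e-12)

    def test_stickiness_repetition_bias(self):
        # equal Q, pi=2, prev choice 0 -> P(0) = e^2 / (1 + e^2)
        p = choice_probabilities(np.zeros(2), beta=1.0, pi=2.0, prev_choice=0)
        np.testing.assert_allclose(p[0], np.exp(2) / (1 + np.exp(2)), atol=1e-12)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities(np.zeros(2), beta=-1.0)

    @settings(deadline=None, derandomize=True)
    @given(q0=st.floats(-50, 50), q1=st.floats(-50, 50),
           beta=st.floats(0, 100), shift=st.floats(-100, 100))
    def test_simplex_and_shift_invariance(self, q0, q1, beta, shift):
        q = np.array([q0, q1])
        p = choice_probabilities(q, beta)
        assert np.all(p >= 0) and p.sum() == pytest.approx(1.0)
        p2 = choice_probabilities(q + shift, beta)
        np.testing.assert_allclose(p, p2, atol=1e-9)


class TestSequenceLoglik:
    def test_uniform_policy_closed_form(self, cfg):
        b = make_behavior(random_trials(np.random.default_rng(0), 25))
        params = AgentParams(alpha=0.5, lam=0.5, beta=0.0, w=0.5)
        total, _ = sequence_loglik(params, b, cfg)
        assert total == pytest.approx(2 * 25 * np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("n_trials", [3, 20])
    @pytest.mark.parametrize("pseed", range(4))
    def test_matches_independent_trace_oracle(self, cfg, n_trials, pseed):
        rng = np.random.default_rng(pseed)
        pars = dict(alpha=rng.uniform(0.1, 0.9), lam=rng.uniform(0, 1),
                    beta=rng.uniform(0, 8), w=rng.uniform(0, 1),
                    pi=rng.normal(0, 0.5), rho=rng.normal(0, 0.5))
        trials = random_trials(rng, n_trials)
        b = make_behavior(trials)
        total, frame = sequence_loglik(AgentParams(**pars), b, cfg)
        ref_total, recs = trace_loglik(**pars, trials=trials,
                                       p_common=cfg.p_common, scale=cfg.scale)
        assert total == pytest.approx(ref_total, abs=1e-12)
        for col, key in [("loglik_stage1", "ll1"), ("loglik_stage2", "ll2"),
                         ("delta1", "delta1"), ("delta2", "delta2")]:
            np.testing.assert_allclose(frame[col], [r[key] for r in recs], atol=1e-12)

    def test_logliks_nonpositive_and_deterministic(self, cfg, simulated_subject):
        params = AgentParams(alpha=0.4, lam=0.3, beta=3.0, w=0.7, pi=0.1)
        t1, f1 = sequence_loglik(params, simulated_subject, cfg)
        t2, f2 = sequence_loglik(params, simulated_subject, cfg)
        assert t1 == t2 and (f1["loglik_stage1"] <= 0).all()
        assert f1.equals(f2)

    def test_delta2_is_reward_minus_preupdate_q(self, cfg):
        """Recompute the RPE series independently by replaying the updates."""
        rng = np.random.default_rng(3)
        trials = random_trials(rng, 50)
        params = AgentParams(alpha=0.7, lam=0.4, beta=2.0, w=0.3)
        _, frame = sequence_loglik(params, make_behavior(trials), cfg)
        q = np.zeros((3, 2))
        for i, (a1, s2, a2, pts) in enumerate(trials):
            r = pts * cfg.scale
            expected = r - q[s2, a2]
            assert frame["delta2"].iloc[i] == pytest.approx(expected, abs=1e-12)
            d1 = q[s2, a2] - q[0, a1]
            q[0, a1] += params.alpha * d1 + params.alpha * params.lam * expected
            q[s2, a2] += params.alpha * expected

    def test_stage2_likelihood_independent_of_w(self, cfg):
        """MF and MB values coincide at stage 2, so w cannot affect it."""
        trials = random_trials(np.random.default_rng(9), 40)
        b = make_behavior(trials)
        base = dict(alpha=0.5, lam=0.5, beta=4.0, pi=0.2)
        _, f0 = sequence_loglik(AgentParams(w=0.0, **base), b, cfg)
        _, f1 = sequence_loglik(AgentParams(w=1.0, **base), b, cfg)
        np.testing.assert_allclose(f0["loglik_stage2"], f1["loglik_stage2"], atol=1e-12)

    def test_missed_trials_skipped_and_sticky_reset(self, cfg):
        trials = random_trials(np.random.default_rng(5), 10)
        b = make_behavior(trials)
        b.trials.loc[4, ["a1", "a2"]] = -1
        params = AgentParams(alpha=0.5, lam=0.5, beta=3.0, w=0.5, pi=1.0)
        total, frame = sequence_loglik(params, b, cfg)
        assert np.isnan(frame.loc[4, "delta2"])
        assert np.isfinite(total)


def test_params_validated():
    with pytest.raises(ValueError):
        AgentParams(alpha=1.2, lam=0.5, beta=1.0, w=0.5)
    with pytest.raises(ValueError):
        AgentParams(alpha=0.5, lam=0.5, beta=-1.0, w=0.5)


def test_variant_fixes_enforced():
    from twostep_eeg.hybrid import MODEL_VARIANTS
    mf = MODEL_VARIANTS["mf_pure"]
    with pytest.raises(ValueError):
        mf.check_params(AgentParams(alpha=0.5, lam=0.5, beta=1.0, w=0.5))
    assert mf.k == 3 and MODEL_VARIANTS["hybrid_choice_resp"].k == 6
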