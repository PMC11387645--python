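"""First-level EEG tests: filters, rejection, Huber regression, group maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twostep_eeg import firstlevel as fl


def make_epochs(data, channels=("FCz", "Cz"), srate=500.0, t0=-200.0, meta=None):
    n = data.shape[0]
    if meta is None:
        meta = pd.DataFrame({"subject_id": "s000", "trial": np.arange(n),
                             "rt1_ms": 500.0, "rt2_ms": 450.0})
    return fl.EpochArray(data, list(channels), srate, t0, meta)


def test_epoch_array_zarr_roundtrip(tmp_path):
    import warnings
    rng = np.random.default_rng(0)
    meta = pd.DataFrame({"subject_id": "s000", "trial": np.arange(5),
                         "transition": ["common"] * 3 + ["rare"] * 2,
                         "rpe": rng.standard_normal(5),
                         "rt1_ms": 500.0, "rt2_ms": 450.0})
    ep = make_epochs(rng.standard_normal((5, 2, 30)), meta=meta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # zarr v3 string-dtype spec notices
        ep.save_zarr(tmp_path / "ep.zarr")
        back = fl.EpochArray.load_zarr(tmp_path / "ep.zarr")
    np.testing.assert_allclose(back.data, ep.data)
    assert back.channels == ep.channels and back.t0_ms == ep.t0_ms
    assert list(back.trial_metadata["transition"]) == list(meta["transition"])


class TestFastResponseFilter:
    def test_no_fast_trials_unchanged(self):
        ep = make_epochs(np.zeros((5, 2, 10)))
        out, n = fl.drop_fast_response_trials(ep)
        assert n == 0 and out.data.shape[0] == 5

    def test_single_fast_stage2_trial_removed(self):
        ep = make_epochs(np.arange(5)[:, None, None] * np.ones((5, 2, 10)))
        ep.trial_metadata.loc[2, "rt2_ms"] = 50.0
        out, n = fl.drop_fast_response_trials(ep)
        assert n == 1
        assert set(out.trial_metadata["trial"]) == {0, 1, 3, 4}

    def test_zero_threshold_vacuous(self):
        ep = make_epochs(np.zeros((4, 2, 10)))
        ep.trial_metadata.loc[1, "rt1_ms"] = 30.0
        out, n = fl.drop_fast_response_trials(ep, threshold_ms=0.0)
        assert n == 0 and out.data.shape[0] == 4


class TestBaselineCorrect:
    def test_constant_signal_zeroed(self):
        ep = make_epochs(np.full((3, 2, 100), 7.0))
        out = fl.baseline_correct(ep)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((3, 2, 100))
        a = fl.baseline_correct(make_epochs(sig)).data
        b = fl.baseline_correct(make_epochs(sig + 11.5)).data
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_hand_computed_four_sample_trace(self):
        # srate chosen so the first two samples lie in [-200, 0)
        data = np.array([[[2.0, 4.0, 10.0, 20.0]]])
        ep = make_epochs(data, channels=("FCz",), srate=10.0, t0=-200.0)
        out = fl.baseline_correct(ep, window=(-200.0, 0.0))
        np.testing.assert_allclose(out.data[0, 0], [-1.0, 1.0, 7.0, 17.0])

    def test_empty_window_rejected(self):
        ep = make_epochs(np.zeros((2, 2, 50)))
        with pytest.raises(ValueError):
            fl.baseline_correct(ep, window=(0.0, 0.0))

    def test_post_mean_zero(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((4, 2, 600)))
        out = fl.baseline_correct(ep)
        sel = (out.times >= -200) & (out.times < 0)
        assert np.abs(out.data[:, :, sel].mean(axis=2)).max() < 1e-10


class TestArtifactRejection:
    def test_planted_gross_artifact_removed_exactly(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((500, 2, 100))
        data[123] += 50.0
        ep = make_epochs(data)
        kept, removed, th = fl.adaptive_artifact_rejection(ep)
        assert list(removed) == [123]

    def test_homogeneous_data_forces_min_removal(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.standard_normal((200, 2, 50)))
        kept, removed, th = fl.adaptive_artifact_rejection(ep, min_remove=3)
        # threshold steps down 0.1 at a time until >= 3 trials cross it
        assert 3 <= len(removed) <= 10 and th < 4.0

    def test_many_artifacts_capped_at_5_percent(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((400, 2, 50))
        data[:40] += 30.0           # 10% planted artifacts
        kept, removed, th = fl.adaptive_artifact_rejection(make_epochs(data))
        assert len(removed) <= 20 and th > 4.0

    def test_unsatisfiable_constraints_rejected(self):
        ep = make_epochs(np.random.default_rng(5).standard_normal((40, 2, 20)))
        with pytest.raises(ValueError, match="cap"):
            fl.adaptive_artifact_rejection(ep, min_remove=5, max_frac=0.05)

    def test_too_few_trials_rejected(self):
        ep = make_epochs(np.zeros((10, 2, 20)))
        with pytest.raises(ValueError):
            fl.adaptive_artifact_rejection(ep)


def _planted_epochs(n=80, noise=0.0, outlier_frac=0.0, seed=0, betas=(1.0, -0.5, 2.0, 0.8)):
    """Epochs whose FCz signal follows the linear model exactly."""
    rng = np.random.default_rng(seed)
    trans = np.where(rng.random(n) < 0.75, 1.0, -1.0)
    rpe = rng.standard_normal(n)
    rpe_z = (rpe - rpe.mean()) / rpe.std()
    X = np.column_stack([np.ones(n), trans, rpe_z, trans * rpe_z])
    y = X @ np.array(betas)
    data = np.zeros((n, 2, 60))
    data[:, 0, :] = y[:, None]
    data += noise * rng.standard_normal(data.shape)
    if outlier_frac:
        bad = rng.random(n) < outlier_frac
        data[bad] += rng.normal(0, 40, (bad.sum(), 1, 1))
    meta = pd.DataFrame({"subject_id": "s000", "trial": np.arange(n),
                         "transition": np.where(trans > 0, "common", "rare"),
                         "rpe": rpe, "rt1_ms": 500.0, "rt2_ms": 450.0})
    return make_epochs(data, meta=meta), np.array(betas)


class TestRobustRegression:
    def test_noiseless_recovery_to_1e6(self):
        ep, betas = _planted_epochs()
        bm = fl.robust_regress_trials(ep)
        np.testing.assert_allclose(bm.b[:, 0, :], betas[:, None] * np.ones(60),
                                   atol=1e-6)

    def test_huber_inf_equals_ols(self):
        ep, _ = _planted_epochs(noise=1.0, outlier_frac=0.1, seed=3)
        bm_inf = fl.robust_regress_trials(ep, huber_c=np.inf)
        X, names, mask = fl.build_design(ep.trial_metadata)
        ref, *_ = np.linalg.lstsq(X, ep.data.reshape(len(ep.data), -1), rcond=None)
        np.testing.assert_allclose(bm_inf.b.reshape(4, -1), ref, atol=1e-8)

    def test_matches_statsmodels_rlm_at_single_point(self):
        import statsmodels.api as sm
        ep, _ = _planted_epochs(noise=1.0, outlier_frac=0.15, seed=4)
        bm = fl.robust_regress_trials(ep)
        X, _, _ = fl.build_design(ep.trial_metadata)
        y = ep.data[:, 0, 30]
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit(update_scale=False)
        np.testing.assert_allclose(bm.b[:, 0, 30], ref.params, atol=5e-3)

    def test_huber_beats_ols_under_gross_outliers(self):
        errs = {"huber": [], "ols": []}
        for seed in range(15):
            ep, betas = _planted_epochs(n=120, noise=1.0, outlier_frac=0.05,
                                        seed=seed)
            for name, c in [("huber", 1.345), ("ols", np.inf)]:
                bm = fl.robust_regress_trials(ep, huber_c=c)
                errs[name].append(np.sqrt(np.mean((bm.b[:, 0, :] - betas[:, None]) ** 2)))
        assert np.mean(errs["huber"]) < np.mean(errs["ols"])

    def test_single_transition_subset_drops_transition_columns(self):
        ep, _ = _planted_epochs(noise=0.5, seed=5)
        bm = fl.robust_regress_trials(ep, subset="common")
        assert bm.regressor_names == ("intercept", "rpe")

    def test_constant_transition_column_detected(self):
        ep, _ = _planted_epochs(seed=6)
        ep.trial_metadata["transition"] = "common"
        with pytest.raises(ValueError, match="transition"):
            fl.robust_regress_trials(ep)


def _maps_from_values(values_per_subject):
    """One-channel, one-timepoint beta maps holding given rpe values."""
    out = []
    for i, v in enumerate(np.atleast_2d(values_per_subject).T):
        b = np.zeros((2, 1, len(v)))
        b[1, 0, :] = v
        out.append(fl.BetaMap(b, ("intercept", "rpe"), ["FCz"], 500.0, 0.0, f"s{i}"))
    return out


class TestGroupTmap:
    def test_hand_benjamini_hochberg_rejections(self):
        """Four tests with p = .01, .02, .03, .5 at q = .05: BH rejects 3."""
        n = 10
        z = np.linspace(-1, 1, n)
        z = (z - z.mean()) / z.std(ddof=1)       # exact mean 0, sd 1
        targets = [0.01, 0.02, 0.03, 0.5]
        # subject values with mean t*/sqrt(n) and unit sd give exactly t = t*
        vals = np.column_stack([z + stats.t.ppf(1 - p / 2, n - 1) / np.sqrt(n)
                                for p in targets])
        maps = _maps_from_values(vals.T)
        gm = fl.group_tmap(maps, "rpe", q=0.05, family_channels=["FCz"])
        np.testing.assert_allclose(gm.p.ravel(), targets, atol=1e-10)
        assert gm.mask.ravel().tolist() == [True, True, True, False]

    def test_zero_variance_flagged(self):
        maps = _maps_from_values(np.array([[1.0, 1.0, 1.0, 1.0]]))
        gm = fl.group_tmap(maps, "rpe", family_channels=["FCz"])
        assert gm.zero_variance_points == 1 and gm.p.ravel()[0] == 0.0

    def test_minimum_subjects_enforced(self):
        maps = _maps_from_values(np.array([[1.0], [2.0]]).T)
        with pytest.raises(ValueError):
            fl.group_tmap(maps[:2], "rpe")


class TestComponentWindows:
    def _ga(self, frn_peak=294.0, p3_peak=370.0):
        times = -200.0 + 2.0 * np.arange(600)
        ga = np.zeros((2, 600))
        ga[0] -= 5.0 * np.exp(-0.5 * ((times - frn_peak) / 20) ** 2)
        ga[1] += 6.0 * np.exp(-0.5 * ((times - p3_peak) / 40) ** 2)
        return ga, ["FCz", "Cz"], times

    def test_planted_peaks_found_with_25ms_windows(self):
        ga, chans, times = self._ga()
        wins = fl.find_component_windows(ga, chans, times)
        assert wins["FRN"].peak_ms == 294.0 and wins["FRN"].window == (269.0, 319.0)
        assert wins["P3"].peak_ms == 370.0 and wins["P3"].window == (345.0, 395.0)

    def test_tie_breaks_to_earlier_latency(self):
        ga, chans, times = self._ga()
        sel = (times >= 250) & (times <= 350)
        ga[0, sel] = 0.0
        ga[0, np.flatnonzero(sel)[[10, 20]]] = -3.0   # two equal troughs
        wins = fl.find_component_windows(ga, chans, times)
        assert wins["FRN"].peak_ms == times[np.flatnonzero(sel)[10]]

    def test_boundary_peak_warns(self):
        ga, chans, times = self._ga(frn_peak=250.0)
        with pytest.warns(UserWarning, match="boundary"):
            fl.find_component_windows(ga, chans, times)


class TestMeanBInWindow:
    def _map(self, values):
        b = np.zeros((2, 1, len(values)))
        b[1, 0, :] = values
        return fl.BetaMap(b, ("intercept", "rpe"), ["Cz"], 500.0, 0.0)

    def test_constant_window(self):
        bm = self._map(np.full(50, 2.0))
        win = fl.ComponentWindow("P3", "Cz", 50.0, (25.0, 75.0))
        assert fl.mean_b_in_window(bm, win, "rpe") == 2.0

    def test_linear_ramp_gives_center_value(self):
        times = 2.0 * np.arange(50)
        bm = self._map(times)
        win = fl.ComponentWindow("P3", "Cz", 50.0, (26.0, 74.0))
        assert fl.mean_b_in_window(bm, win, "rpe") == pytest.approx(50.0)

    def test_five_sample_hand_mean(self):
        bm = self._map(np.array([9.0, 1.0, 2.0, 3.0, 4.0, 5.0, 9.0]))
        win = fl.ComponentWindow("P3", "Cz", 6.0, (2.0, 10.0))
        assert fl.mean_b_in_window(bm, win, "rpe") == 3.0

    def test_missing_channel_rejected(self):
        bm = self._map(np.zeros(5))
        win = fl.ComponentWindow("FRN", "FCz", 4.0, (2.0, 6.0))
        with pytest.raises(KeyError):
            fl.mean_b_in_window(bm, win, "rpe")
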