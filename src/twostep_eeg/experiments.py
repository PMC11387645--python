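"""Self-contained simulation experiments exercising the full pipeline.

Each function generates its own synthetic inputs from a seed, runs the
relevant analysis stages, and returns summary quantities.  They back both
the validation suite and the numbered analysis drivers.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import behavior as bh
from . import cohort as ch
from . import firstlevel as fl
from . import fitting as ft
from . import secondlevel as sl
from .hybrid import AgentParams, sequence_loglik
from .task import TaskConfig, simulate_subject


def common_transition_fraction(seed: int, n_trials: int = 10_000,
                               cfg: Optional[TaskConfig] = None) -> float:
    """Percentage of simulated trials whose realized stage matches the chosen
    action's preferred stage, at the default 80/20 transition structure."""
    cfg = cfg or TaskConfig(n_trials=n_trials)
    params = AgentParams(alpha=0.6, lam=0.6, beta=5.0, w=0.5, pi=0.25)
    b = simulate_subject(params, cfg, np.random.default_rng(seed))
    return 100.0 * (b.trials["transition"] == "common").mean()


def simulate_cohort_behavior(coh: pd.DataFrame, cfg: TaskConfig, seed: int):
    """Simulate a session for every cohort row; returns SubjectBehavior list."""
    root = np.random.SeedSequence(seed)
    out = []
    for (_, row), ss in zip(coh.iterrows(), root.spawn(len(coh))):
        out.append(simulate_subject(
            ch.agent_params_from_row(row), cfg, np.random.default_rng(ss),
            subject_id=row["subject_id"], bis_score=row["bis_score"],
            oci_score=row["oci_score"]))
    return out


def parameter_recovery(seed: int, n_subjects: int = 100, n_trials: int = 500,
                       n_restarts: int = 20) -> pd.DataFrame:
    """Fit the hybrid+choice-stickiness model to cohort-simulated agents.

    Returns per-subject true and fitted parameters; attrs carry the
    true-vs-fitted correlation of the model-based weight w.
    """
    spec = ch.CohortSpec(n_subjects=n_subjects)
    rng = np.random.default_rng(seed)
    coh = ch.generate_cohort(spec, rng)
    cfg = TaskConfig(n_trials=n_trials)
    behaviors = simulate_cohort_behavior(coh, cfg, seed + 1)
    fits = ft.fit_cohort(behaviors, cfg, "hybrid_choice",
                         n_restarts=n_restarts, seed=seed + 2)
    df = pd.DataFrame({
        "subject_id": coh["subject_id"],
        "w_true": coh["w"].to_numpy(),
        "w_fit": [f.params.w for f in fits],
        "alpha_true": coh["alpha"].to_numpy(),
        "alpha_fit": [f.params.alpha for f in fits],
        "beta_true": coh["beta"].to_numpy(),
        "beta_fit": [f.params.beta for f in fits],
    })
    df.attrs["w_correlation"] = float(np.corrcoef(df["w_true"], df["w_fit"])[0, 1])
    return df


def model_recovery(seed: int, n_subjects: int = 30, n_trials: int = 500,
                   n_restarts: int = 20) -> pd.DataFrame:
    """Model-comparison table for a hybrid+choice-stickiness generative cohort."""
    spec = ch.CohortSpec(n_subjects=n_subjects)
    coh = ch.generate_cohort(spec, np.random.default_rng(seed))
    cfg = TaskConfig(n_trials=n_trials)
    behaviors = simulate_cohort_behavior(coh, cfg, seed + 1)
    return ft.compare_models(behaviors, cfg, n_restarts=n_restarts, seed=seed + 2)


def pure_family_cohort(seed: int, w: float, n_subjects: int = 30,
                       n_trials: int = 500, beta: float = 5.0,
                       walk_mode: str = "probability"):
    """Cohort of pure-MF (w=0) or pure-MB (w=1) agents with trait scores."""
    rng = np.random.default_rng(seed)
    cfg = TaskConfig(n_trials=n_trials, walk_mode=walk_mode)
    out = []
    for i in range(n_subjects):
        params = AgentParams(alpha=rng.uniform(0.4, 0.8), lam=rng.uniform(0.4, 0.8),
                             beta=beta, w=w, pi=rng.normal(0.25, 0.1))
        out.append(simulate_subject(params, cfg, rng, subject_id=f"s{i:03d}",
                                    bis_score=rng.normal(65, 10),
                                    oci_score=rng.normal(12, 8)))
    return out, cfg


def behavioral_signature(seed: int, w: float, n_subjects: int = 30,
                         n_trials: int = 500) -> pd.DataFrame:
    """Stay-probability GLMM for a pure-MF or pure-MB cohort.

    Runs under the binary-reward (probability-walk) task reading, where the
    canonical MF/MB dissociation of the stay analysis is defined.
    """
    cohort, _ = pure_family_cohort(seed, w, n_subjects, n_trials)
    kept = [b for b in cohort if bh.screen_random_responder(b).keep]
    design, _ = bh.build_stay_design(kept)
    return bh.fit_stay_glmm(design)


def _null_spec(n_subjects, channels=("FCz", "Cz")) -> ch.CohortSpec:
    zero_links = {"frn": {"w": 0, "bis": 0, "oci": 0},
                  "p3": {"w": 0, "bis": 0, "oci": 0}}
    zero_gain = {"frn": {"common": 0.0, "rare": 0.0},
                 "p3": {"common": 0.0, "rare": 0.0}}
    return ch.CohortSpec(n_subjects=n_subjects, channels=tuple(channels),
                         frn_common_gain=0.0, p3_rarity_gain=0.0,
                         rpe_gain=zero_gain, gain_links=zero_links,
                         gain_noise_sd={"frn": 0.0, "p3": 0.0})


def _subject_beta_map(row, spec, cfg, rng, subset=None):
    b = simulate_subject(ch.agent_params_from_row(row), cfg, rng,
                         subject_id=row["subject_id"])
    _, frame = sequence_loglik(ch.agent_params_from_row(row), b, cfg)
    ep = ch.generate_eeg_epochs(b.trials, frame["delta2"].to_numpy(), row, spec, rng)
    ep, _ = fl.drop_fast_response_trials(ep)
    ep, _, _ = fl.adaptive_artifact_rejection(ep)
    ep = fl.baseline_correct(ep)
    return fl.robust_regress_trials(ep, subset=subset), ep


def null_fdr_calibration(seed: int, n_replicates: int = 200,
                         n_subjects: int = 8, n_trials: int = 100,
                         q: float = 0.05) -> pd.DataFrame:
    """Fraction of FDR-significant points per regressor on null EEG.

    All planted gains are zero, so any significant point is a false
    positive.  Returns one row per replicate with the significant fraction
    of each regressor's group map.
    """
    root = np.random.SeedSequence(seed)
    cfg = TaskConfig(n_trials=n_trials)
    rows = []
    for ss in root.spawn(n_replicates):
        rng = np.random.default_rng(ss)
        spec = _null_spec(n_subjects)
        coh = ch.generate_cohort(spec, rng)
        maps = [_subject_beta_map(row, spec, cfg, rng)[0]
                for _, row in coh.iterrows()]
        rec = {}
        for reg in ("transition", "rpe", "transition_x_rpe"):
            gm = fl.group_tmap(maps, reg, q=q)
            rec[reg] = gm.mask.mean()
        rows.append(rec)
    df = pd.DataFrame(rows)
    df.attrs["q"] = q
    return df


def planted_firstlevel_maps(seed: int, n_subjects: int = 12,
                            n_trials: int = 400) -> dict:
    """Group t maps for a cohort with the default planted effects.

    Returns the three group maps plus the component windows found on the
    grand average, for checks of effect sign and window coverage.
    """
    rng = np.random.default_rng(seed)
    spec = ch.CohortSpec(n_subjects=n_subjects, channels=("FCz", "Cz"))
    coh = ch.generate_cohort(spec, rng)
    cfg = TaskConfig(n_trials=n_trials)
    maps, eps = [], []
    for _, row in coh.iterrows():
        bm, ep = _subject_beta_map(row, spec, cfg, rng)
        maps.append(bm)
        eps.append(ep)
    ga, chans, times = fl.grand_average(eps)
    windows = fl.find_component_windows(ga, chans, times)
    return {"maps": {reg: fl.group_tmap(maps, reg)
                     for reg in ("transition", "rpe", "transition_x_rpe")},
            "windows": windows, "times": maps[0].times}


def outlier_robustness(seed: int, n_replicates: int = 30, n_trials: int = 120,
                       outlier_frac: float = 0.05) -> pd.DataFrame:
    """Paired Huber-vs-OLS coefficient RMSE with gross outlier trials.

    Plants a known linear model in one channel, contaminates a fraction of
    trials with large offsets, and fits both estimators on identical data.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for ss in root.spawn(n_replicates):
        rng = np.random.default_rng(ss)
        betas = np.array([1.0, -0.5, 2.0, 0.8])
        trans = np.where(rng.random(n_trials) < 0.8, 1.0, -1.0)
        rpe = rng.standard_normal(n_trials)
        rpe_z = (rpe - rpe.mean()) / rpe.std()
        X = np.column_stack([np.ones(n_trials), trans, rpe_z, trans * rpe_z])
        y = X @ betas
        data = np.zeros((n_trials, 2, 40)) + y[:, None, None]
        data += rng.standard_normal(data.shape)
        bad = rng.random(n_trials) < outlier_frac
        data[bad] += rng.normal(0, 40, (bad.sum(), 1, 1))
        meta = pd.DataFrame({"subject_id": "s000", "trial": np.arange(n_trials),
                             "transition": np.where(trans > 0, "common", "rare"),
                             "rpe": rpe, "rt1_ms": 500.0, "rt2_ms": 450.0})
        ep = fl.EpochArray(data, ["FCz", "Cz"], 500.0, -200.0, meta)
        rec = {}
        for name, c in [("huber", 1.345), ("ols", np.inf)]:
            bm = fl.robust_regress_trials(ep, huber_c=c)
            rec[f"rmse_{name}"] = float(np.sqrt(np.mean(
                (bm.b - betas[:, None, None]) ** 2)))
        rows.append(rec)
    return pd.DataFrame(rows)


def end_to_end_recovery(seed: int, n_subjects: int = 200,
                        n_trials: int = 500) -> dict:
    """One full synthetic study: behavior, EEG, first and second level.

    Epochs are generated and analyzed per subject at the two component
    channels; component windows are located on the grand average before
    window-mean extraction.  The second level uses the generator's true w
    (the fitting path is validated separately), across the four cells: RPE effect in the FRN window (common/rare) and P3 window
    (common/rare).

    Returns the four SecondLevelResults plus the cohort table and windows.
    """
    rng = np.random.default_rng(seed)
    spec = ch.CohortSpec(n_subjects=n_subjects, channels=("FCz", "Cz"))
    coh = ch.generate_cohort(spec, rng)
    cfg = TaskConfig(n_trials=n_trials)
    maps = {"common": [], "rare": []}
    ga_sum = None
    for _, row in coh.iterrows():
        params = ch.agent_params_from_row(row)
        b = simulate_subject(params, cfg, rng, subject_id=row["subject_id"])
        _, frame = sequence_loglik(params, b, cfg)
        ep = ch.generate_eeg_epochs(b.trials, frame["delta2"].to_numpy(),
                                    row, spec, rng)
        ep, _ = fl.drop_fast_response_trials(ep)
        ep, _, _ = fl.adaptive_artifact_rejection(ep)
        ep = fl.baseline_correct(ep)
        ga_sum = ep.data.mean(axis=0) if ga_sum is None else ga_sum + ep.data.mean(axis=0)
        for subset in ("common", "rare"):
            maps[subset].append(fl.robust_regress_trials(ep, subset=subset))
    ga = ga_sum / n_subjects
    windows = fl.find_component_windows(ga, list(spec.channels), maps["common"][0].times)
    results = {}
    for comp, win in windows.items():
        for subset in ("common", "rare"):
            mb = [fl.mean_b_in_window(bm, win, "rpe") for bm in maps[subset]]
            results[(comp, subset)] = sl.second_level_regression(
                mb, coh["bis_z"], coh["oci_z"], coh["w"], comp, subset)
    return {"results": results, "cohort": coh, "windows": windows, "spec": spec}
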