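"""Behavioral statistics for the two-step task.

Covers the random-responder screen, construction of the stay-probability
design with +/-1 coding of previous-trial reward and transition, the
generalized linear mixed model for stay behavior (solved by lme4 through
Rscript; a cluster-robust plain-logistic fallback is used when R is absent),
and the rare-minus-common reaction-time difference used as a behavioral
marker of model-based control.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

STAY_FORMULA = "stay ~ transition * reward * bis * oci"
STAY_RANDOM = "(transition * reward | subject_id)"


@dataclass
class ScreenDecision:
    subject_id: str
    keep: bool
    b_reward: float
    p_reward: float          # one-sided, H1: b > 0
    b_interaction: float
    p_interaction: float
    diagnostics: dict = field(default_factory=dict)


def _stay_terms(trials: pd.DataFrame):
    """Per-trial stay indicator and +/-1 coded previous-trial covariates."""
    t = trials.reset_index(drop=True)
    a1 = t["a1"].to_numpy()
    stay = (a1[1:] == a1[:-1]).astype(float)
    reward_prev = np.where(t["reward_points"].to_numpy()[:-1] > 0, 1.0, -1.0)
    trans_prev = np.where(t["transition"].to_numpy()[:-1] == "common", 1.0, -1.0)
    ok = (a1[1:] >= 0) & (a1[:-1] >= 0)
    return stay[ok], reward_prev[ok], trans_prev[ok], t.loc[1:, "trial"].to_numpy()[ok]


def _penalized_logit(X, y, ridge=1e-2):
    """Ridge-penalized logistic fit with Hessian-based SEs (separation fallback)."""
    from scipy import optimize, special

    def nll(b):
        eta = X @ b
        return -(y * eta - np.logaddexp(0, eta)).sum() + ridge * (b ** 2).sum()

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS")
    p = special.expit(X @ res.x)
    H = X.T @ (X * (p * (1 - p))[:, None]) + 2 * ridge * np.eye(X.shape[1])
    cov = np.linalg.inv(H)
    return res.x, np.sqrt(np.diag(cov))


def screen_random_responder(behavior, alpha: float = 0.05) -> ScreenDecision:
    """Exclude subjects whose staying is unrelated to reward history.

    Fits the per-subject logistic model ``stay ~ reward_prev +
    reward_prev:transition_prev``; the subject is kept when either
    coefficient is positive with one-sided p < ``alpha``.
    """
    from scipy import stats

    stay, rew, trans, _ = _stay_terms(behavior.trials)
    if len(stay) < 2:
        raise ValueError("need at least 2 usable trials")
    X = np.column_stack([np.ones_like(rew), rew, rew * trans])
    diagnostics = {}
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(stay, X).fit(disp=0, maxiter=100)
        b, se = fit.params, fit.bse
        if not np.all(np.isfinite(se)) or np.max(np.abs(b)) > 15:
            raise RuntimeError("separation suspected")
    except Exception:
        b, se = _penalized_logit(X, stay)
        diagnostics["penalized"] = True
    z = b / se
    p_one = stats.norm.sf(z)  # H1: coefficient > 0
    keep = bool((b[1] > 0 and p_one[1] < alpha) or (b[2] > 0 and p_one[2] < alpha))
    return ScreenDecision(behavior.subject_id, keep, b[1], p_one[1],
                          b[2], p_one[2], diagnostics)


def build_stay_design(behaviors: Sequence, traits: Optional[pd.DataFrame] = None):
    """Stack per-trial stay rows across subjects and z-score trait columns.

    Returns ``(design, descriptor)`` where the design has one row per trial
    from the second trial onward with columns subject_id, stay, reward
    (previous trial, +1 rewarded / -1 not), transition (previous trial,
    +1 common / -1 rare), bis, oci (z-scored across the included sample) and
    optional gender (+/-0.5); the descriptor records the fixed and random
    effect formulas.
    """
    if traits is None:
        traits = pd.DataFrame({
            "subject_id": [b.subject_id for b in behaviors],
            "bis_score": [b.bis_score for b in behaviors],
            "oci_score": [b.oci_score for b in behaviors],
            "gender": [b.gender for b in behaviors],
        })
    traits = traits.set_index("subject_id")
    rows = []
    dropped = []
    for b in behaviors:
        tr = traits.loc[b.subject_id]
        if not (np.isfinite(tr["bis_score"]) and np.isfinite(tr["oci_score"])):
            dropped.append(b.subject_id)
            continue
        stay, rew, trans, trial = _stay_terms(b.trials)
        rows.append(pd.DataFrame({
            "subject_id": b.subject_id, "trial": trial, "stay": stay,
            "reward": rew, "transition": trans,
            "bis_raw": tr["bis_score"], "oci_raw": tr["oci_score"],
            "gender": tr.get("gender", None),
        }))
    if dropped:
        import warnings
        warnings.warn(f"dropping subjects with missing traits: {dropped}")
    design = pd.concat(rows, ignore_index=True)
    for raw, z in (("bis_raw", "bis"), ("oci_raw", "oci")):
        per_subj = design.groupby("subject_id")[raw].first()
        mu, sd = per_subj.mean(), per_subj.std(ddof=1)
        design[z] = (design[raw] - mu) / sd
    if design["gender"].notna().any():
        design["gender_code"] = design["gender"].map(
            lambda g: 0.5 if g in ("f", "female") else (-0.5 if g in ("m", "male") else np.nan))
    descriptor = {"fixed": STAY_FORMULA, "random": STAY_RANDOM}
    return design, descriptor


_R_TEMPLATE = """
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
d <- read.csv("{csv}")
d$subject_id <- factor(d$subject_id)
fit_one <- function(form) {{
  glmer(form, data = d, family = binomial, nAGQ = {nagq},
        control = glmerControl(optimizer = "bobyqa", calc.derivs = FALSE))
}}
m <- fit_one({fixed} + {random})
msgs <- unlist(m@optinfo$conv$lme4$messages)
fallback <- FALSE
if (length(msgs) > 0) {{
  m2 <- tryCatch(fit_one({fixed} + (1 | subject_id)), error = function(e) NULL)
  if (!is.null(m2)) {{ m <- m2; fallback <- TRUE }}
}}
co <- summary(m)$coefficients
out <- list(term = rownames(co), estimate = co[, 1], se = co[, 2],
            t = co[, 3], p = co[, 4], fallback = fallback,
            messages = if (length(msgs)) msgs else list())
write(toJSON(out, digits = 12), "{out}")
"""


def fit_stay_glmm(design: pd.DataFrame, include_gender: bool = False,
                  nagq: int = 0) -> pd.DataFrame:
    """Fit the stay GLMM and report exponentiated fixed effects.

    Delegates to lme4's ``glmer`` (binomial family, bobyqa, adaptive
    quadrature order ``nagq``; 0 trades a little accuracy for a large
    speedup on full random-slope structures).  Returns a table with columns
    term, beta (exponentiated), estimate (log-odds), se, t, p plus attrs
    ``backend`` and ``fallback``.
    """
    fixed = "stay ~ transition * reward * bis * oci"
    if include_gender and "gender_code" in design:
        fixed += " + gender_code"
    cols = ["subject_id", "stay", "reward", "transition", "bis", "oci"]
    if include_gender and "gender_code" in design:
        cols.append("gender_code")
    if shutil.which("Rscript") is None:
        return _fit_stay_glm_fallback(design, fixed)
    with tempfile.TemporaryDirectory() as td:
        csv = Path(td) / "design.csv"
        out = Path(td) / "fit.json"
        design[cols].to_csv(csv, index=False)
        script = Path(td) / "fit.R"
        script.write_text(_R_TEMPLATE.format(csv=csv, out=out, nagq=nagq,
                                             fixed=fixed, random=STAY_RANDOM))
        proc = subprocess.run(["Rscript", "--vanilla", str(script)],
                              capture_output=True, text=True)
        if proc.returncode != 0 or not out.exists():
            raise RuntimeError(f"lme4 fit failed:\n{proc.stderr[-2000:]}")
        res = json.loads(out.read_text())
    table = pd.DataFrame({"term": res["term"], "estimate": res["estimate"],
                          "se": res["se"], "t": res["t"], "p": res["p"]})
    table.insert(1, "beta", np.exp(table["estimate"]))
    table.attrs["backend"] = "lme4/glmer"
    table.attrs["fallback"] = bool(np.ravel(res["fallback"])[0])
    table.attrs["messages"] = res.get("messages", [])
    return table


def _fit_stay_glm_fallback(design: pd.DataFrame, fixed: str) -> pd.DataFrame:
    """Plain logistic regression with subject-clustered SEs (no R available)."""
    import statsmodels.formula.api as smf

    fit = smf.glm(fixed, design, family=sm.families.Binomial()).fit(
        cov_type="cluster", cov_kwds={"groups": design["subject_id"]})
    table = pd.DataFrame({"term": fit.params.index, "estimate": fit.params.values,
                          "se": fit.bse.values, "t": fit.tvalues.values,
                          "p": fit.pvalues.values})
    table.insert(1, "beta", np.exp(table["estimate"]))
    table.attrs["backend"] = "glm_cluster_fallback"
    table.attrs["fallback"] = True
    return table


def rt_delta(behavior, stage: int = 2) -> float:
    """Median RT on rare minus median RT on common trials (milliseconds).

    Uses the stage-2 response by default (the orienting response to the
    realized transition); returns NaN when a transition type is absent.
    """
    col = "rt2_ms" if stage == 2 else "rt1_ms"
    t = behavior.trials
    ok = t["a1"] >= 0
    rare = t.loc[ok & (t["transition"] == "rare"), col].dropna()
    common = t.loc[ok & (t["transition"] == "common"), col].dropna()
    if len(rare) == 0 or len(common) == 0:
        return np.nan
    return float(rare.median() - common.median())


def rt_delta_regression(behaviors: Sequence, design: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level robust regression RT_delta ~ BIS * OCI.

    ``design`` supplies the z-scored trait columns (one value per subject);
    subjects lacking one of the transition types are dropped.
    """
    per_subj = design.groupby("subject_id")[["bis", "oci"]].first()
    rows = []
    for b in behaviors:
        if b.subject_id not in per_subj.index:
            continue
        d = rt_delta(b)
        if np.isfinite(d):
            tr = per_subj.loc[b.subject_id]
            rows.append({"subject_id": b.subject_id, "rt_delta": d,
                         "bis": tr["bis"], "oci": tr["oci"]})
    df = pd.DataFrame(rows)
    X = sm.add_constant(np.column_stack([df["bis"], df["oci"], df["bis"] * df["oci"]]))
    fit = sm.RLM(df["rt_delta"], X, M=sm.robust.norms.HuberT()).fit()
    out = pd.DataFrame({"term": ["intercept", "bis", "oci", "bis:oci"],
                        "beta": fit.params, "se": fit.bse,
                        "t": fit.tvalues, "p": fit.pvalues})
    out.attrs["n_subjects"] = len(df)
    return out.reset_index(drop=True)
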