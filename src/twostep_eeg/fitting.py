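"""Per-subject maximum-likelihood fitting and BIC model comparison.

Nine variants are compared: {model-free, model-based, hybrid} x {no
stickiness, +choice stickiness, +choice+response stickiness}.  Each subject
is fitted by multi-start quasi-Newton optimization in an unconstrained
transformed space (logit for unit-interval parameters, log for beta), and
variants are ranked by summed BIC across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .hybrid import MODEL_VARIANTS, AgentParams, ModelVariant, sequence_loglik

_EPS = 1e-9


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds and bijective transforms to unconstrained space.

    Unit-interval parameters use the logit, beta uses log, the stickiness
    parameters are unbounded and pass through untouched.
    """

    beta_max: float = 20.0
    sticky_abs_max: float = 10.0

    def bounds(self, name: str):
        if name in ("alpha", "lam", "w"):
            return 0.0, 1.0
        if name == "beta":
            return 0.0, self.beta_max
        return -self.sticky_abs_max, self.sticky_abs_max

    def to_unconstrained(self, name: str, value: float) -> float:
        lo, hi = self.bounds(name)
        if name in ("alpha", "lam", "w"):
            return special.logit(np.clip(value, _EPS, 1 - _EPS))
        if name == "beta":
            return np.log(max(value, _EPS))
        return float(value)

    def from_unconstrained(self, name: str, x: float) -> float:
        if name in ("alpha", "lam", "w"):
            return float(special.expit(x))
        if name == "beta":
            return float(min(np.exp(x), self.beta_max))
        lo, hi = self.bounds(name)
        return float(np.clip(x, lo, hi))


@dataclass
class FitResult:
    model_variant: str
    params: AgentParams
    loglik: float
    n_obs: int
    bic: float
    n_restarts_converged: int
    rpe_series: pd.Series
    diagnostics: dict = field(default_factory=dict)


def bic(loglik: float, k: int, n_obs: int) -> float:
    """Bayesian Information Criterion, k*ln(n) - 2*loglik."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return k * np.log(n_obs) - 2.0 * loglik


def _draw_start(variant: ModelVariant, bounds: ParameterBounds,
                rng: np.random.Generator) -> np.ndarray:
    vals = []
    for name in variant.free:
        if name in ("alpha", "lam", "w"):
            v = rng.uniform(0.05, 0.95)
        elif name == "beta":
            v = np.exp(rng.normal(np.log(3.0), 0.8))
        else:
            v = rng.normal(0.0, 0.5)
        vals.append(bounds.to_unconstrained(name, v))
    return np.array(vals)


def fit_subject(behavior, cfg, variant: ModelVariant | str = "hybrid_choice",
                bounds: Optional[ParameterBounds] = None, n_restarts: int = 20,
                rng: Optional[np.random.Generator] = None,
                min_trials: int = 50, tol: float = 1e-6) -> FitResult:
    """Multi-start MLE of one variant on one subject's choice sequence."""
    if isinstance(variant, str):
        variant = MODEL_VARIANTS[variant]
    bounds = bounds or ParameterBounds()
    rng = rng if rng is not None else np.random.default_rng(0)
    trials = behavior.trials if hasattr(behavior, "trials") else behavior
    n_valid = int(((trials["a1"] >= 0) & (trials["a2"] >= 0)).sum())
    if n_valid < min_trials:
        raise ValueError(f"only {n_valid} valid trials (< {min_trials})")

    from ._kernels import loglik_kernel
    from .task import behavior_arrays
    a1, s2, a2, points, valid = behavior_arrays(trials)
    r = (points * cfg.scale).astype(float)
    pos_map = np.zeros(len(a1), np.int64)

    def objective(x):
        params = variant.build_params(
            [bounds.from_unconstrained(n, v) for n, v in zip(variant.free, x)])
        total, *_ = loglik_kernel(a1, s2, a2, r, valid, pos_map, cfg.p_common,
                                  params.alpha, params.lam, params.beta,
                                  params.w, params.pi, params.rho)
        return -total

    best = None
    n_conv = 0
    fails = []
    for _ in range(n_restarts):
        x0 = _draw_start(variant, bounds, rng)
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"maxiter": 300, "ftol": tol})
        if not np.isfinite(res.fun):
            fails.append(res.message)
            continue
        if res.success:
            n_conv += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all restarts failed for {variant.name}: {fails}")
    params = variant.build_params(
        [bounds.from_unconstrained(n, v) for n, v in zip(variant.free, best.x)])
    total, frame = sequence_loglik(params, behavior, cfg)
    n_obs = 2 * n_valid  # two choice observations per complete trial
    diagnostics = {"n_restarts": n_restarts, "optimizer": "L-BFGS-B"}
    # flat-likelihood flag: uniform-policy likelihood within 2 units
    if total - n_obs * np.log(0.5) < 2.0:
        diagnostics["flat_likelihood"] = True
    return FitResult(variant.name, params, total, n_obs,
                     bic(total, variant.k, n_obs), n_conv,
                     frame.set_index("trial")["delta2"], diagnostics)


def fit_cohort(behaviors: Sequence, cfg, variant="hybrid_choice",
               n_restarts: int = 20, seed: int = 0, **kw) -> list[FitResult]:
    """Fit one variant to every subject, with per-subject child seeds."""
    root = np.random.SeedSequence(seed)
    return [fit_subject(b, cfg, variant, n_restarts=n_restarts,
                        rng=np.random.default_rng(s), **kw)
            for b, s in zip(behaviors, root.spawn(len(behaviors)))]


def compare_models(behaviors: Sequence, cfg,
                   variants: Optional[Sequence[str]] = None,
                   n_restarts: int = 20, seed: int = 0) -> pd.DataFrame:
    """Fit all variants to all subjects; rank by summed BIC.

    Returns a table with one row per variant (columns: variant, k,
    sum_bic, sum_loglik, n_subjects, winner) sorted by summed BIC; ties
    break toward fewer parameters.  All variants see identical trial sets.
    """
    variants = list(variants or MODEL_VARIANTS)
    n_valid = [int(((b.trials["a1"] >= 0) & (b.trials["a2"] >= 0)).sum())
               for b in behaviors]
    rows = []
    per_subject = {}
    for vname in variants:
        fits = fit_cohort(behaviors, cfg, vname, n_restarts=n_restarts, seed=seed)
        if [f.n_obs // 2 for f in fits] != n_valid:
            raise RuntimeError(f"variant {vname} fitted on mismatched trial sets")
        per_subject[vname] = fits
        rows.append({"variant": vname, "k": MODEL_VARIANTS[vname].k,
                     "sum_bic": sum(f.bic for f in fits),
                     "sum_loglik": sum(f.loglik for f in fits),
                     "n_subjects": len(fits)})
    table = pd.DataFrame(rows).sort_values(["sum_bic", "k"]).reset_index(drop=True)
    table["winner"] = False
    table.loc[0, "winner"] = True
    table.attrs["per_subject"] = per_subject
    return table


def fits_to_frame(fits: Sequence[FitResult], subject_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    for sid, f in zip(subject_ids, fits):
        rows.append({"subject_id": sid, "variant": f.model_variant,
                     **f.params.as_dict(), "loglik": f.loglik,
                     "n_obs": f.n_obs, "bic": f.bic})
    return pd.DataFrame(rows)
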