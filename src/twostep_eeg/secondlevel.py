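"""Trait moderation of windowed RPE effects (second-level analysis).

Per-subject window-mean RPE b values (FRN at FCz, P3 at Cz; computed within
common or rare trials) are regressed on z-scored impulsivity (BIS-11),
compulsivity (OCI-R) and the model-based weight w with all interactions,

    mean_b ~ BIS + OCI + w + BIS:OCI + BIS:w + OCI:w + BIS:OCI:w,

by Huber robust linear regression.  Interaction columns are products of the
z-scored mains and are not re-standardized.  Significant interactions are
followed up by single-predictor fits in median-split groups, and pairs of
coefficients are compared with z-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SECOND_LEVEL_TERMS = ("intercept", "bis", "oci", "w",
                      "bis_x_oci", "bis_x_w", "oci_x_w", "bis_x_oci_x_w")


@dataclass
class SecondLevelResult:
    component: str
    transition_type: str
    table: pd.DataFrame         # term, beta, se, t, p
    n_subjects: int = 0

    def coef(self, term: str) -> pd.Series:
        row = self.table.loc[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    return (x - x.mean()) / x.std(ddof=0)


def _robust_fit(X: np.ndarray, y: np.ndarray, huber_c: float = 1.345):
    fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=huber_c)).fit()
    return fit.params, fit.bse, fit.tvalues, fit.pvalues


def second_level_regression(mean_b: Sequence[float], bis: Sequence[float],
                            oci: Sequence[float], w: Sequence[float],
                            component: str = "", transition_type: str = "",
                            huber_c: float = 1.345,
                            min_subjects: int = 20,
                            condition_limit: float = 1e6) -> SecondLevelResult:
    """Eight-term robust trait-moderation regression of windowed b values.

    ``bis``, ``oci`` and ``w`` are z-scored across the entered subjects
    before forming products; raw questionnaire sums or already-standardized
    scores may both be passed.
    """
    y = np.asarray(mean_b, float)
    ok = np.isfinite(y)
    for v in (bis, oci, w):
        ok &= np.isfinite(np.asarray(v, float))
    if ok.sum() < min_subjects:
        raise ValueError(f"only {int(ok.sum())} complete subjects (< {min_subjects})")
    b_z, o_z, w_z = (_zscore(np.asarray(v, float)[ok]) for v in (bis, oci, w))
    y = y[ok]
    X = np.column_stack([np.ones_like(y), b_z, o_z, w_z, b_z * o_z,
                         b_z * w_z, o_z * w_z, b_z * o_z * w_z])
    cond = np.linalg.cond(X)
    if cond > condition_limit:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        i, j = divmod(int(np.nanargmax(np.abs(corr - np.eye(len(corr))))), len(corr))
        raise ValueError(
            f"design nearly collinear (cond={cond:.2g}); worst pair: "
            f"{SECOND_LEVEL_TERMS[i + 1]} ~ {SECOND_LEVEL_TERMS[j + 1]}")
    params, se, t, p = _robust_fit(X, y, huber_c)
    table = pd.DataFrame({"term": SECOND_LEVEL_TERMS, "beta": params,
                          "se": se, "t": t, "p": p})
    return SecondLevelResult(component, transition_type, table, int(ok.sum()))


def median_split_followup(mean_b: Sequence[float], split_values: Sequence[float],
                          predictor_values: Sequence[float],
                          split_on: str = "bis", predictor: str = "w",
                          huber_c: float = 1.345, min_group: int = 10) -> pd.DataFrame:
    """Single-predictor robust fits within median-split groups.

    Subjects at or below the median of ``split_values`` form the low group
    (ties deterministically to low).  Returns one row per group with the
    predictor's coefficient, SE, t, p and group size.
    """
    y = np.asarray(mean_b, float)
    s = np.asarray(split_values, float)
    x = np.asarray(predictor_values, float)
    low = s <= np.median(s)
    rows = []
    for name, grp in (("low", low), ("high", ~low)):
        if grp.sum() < min_group:
            raise ValueError(f"{name} {split_on} group has only {int(grp.sum())} subjects")
        X = np.column_stack([np.ones(grp.sum()), _zscore(x[grp])])
        params, se, t, p = _robust_fit(X, y[grp], huber_c)
        rows.append({"split_on": split_on, "group": name, "predictor": predictor,
                     "beta": params[1], "se": se[1], "t": t[1], "p": p[1],
                     "n": int(grp.sum())})
    return pd.DataFrame(rows)


def compare_coefficients_z(b1: float, se1: float, b2: float, se2: float):
    """z-test of two independent regression coefficients.

    z = (b1 - b2) / sqrt(se1^2 + se2^2), two-sided normal p.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def second_level_table(results: Sequence[SecondLevelResult]) -> pd.DataFrame:
    """Stack results into a (component x transition x term) long table."""
    frames = []
    for r in results:
        t = r.table.copy()
        t.insert(0, "component", r.component)
        t.insert(1, "transition", r.transition_type)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
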