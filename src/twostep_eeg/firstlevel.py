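"""Single-trial (first-level) EEG analysis over channel x time.

Feedback-locked epochs are filtered (fast-response removal, adaptive
artifact rejection, baseline correction) and regressed trial-by-trial on
transition type (+1 common / -1 rare), the z-scored signed reward prediction
error, and their interaction, with Huber-weighted iteratively reweighted
least squares at every (channel, time) point.  Per-subject b maps feed
group-level one-sample t maps with Benjamini-Hochberg FDR correction, and
scalar per-subject effects are extracted in +/-25 ms windows around the FRN
(negative peak at FCz, searched 250-350 ms) and P3 (positive peak at Cz,
searched 330-430 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REGRESSOR_NAMES = ("intercept", "transition", "rpe", "transition_x_rpe")


@dataclass
class EpochArray:
    """Feedback-locked EEG epochs (trial x channel x time) with metadata.

    ``trial_metadata`` carries one row per epoch (columns at least
    subject_id, trial; typically also transition, rpe, rt1_ms, rt2_ms).
    """

    data: np.ndarray
    channels: list
    srate: float = 500.0
    t0_ms: float = -200.0
    trial_metadata: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3 or self.data.shape[1] != len(self.channels):
            raise ValueError("data must be (trial, channel, time)")
        if self.trial_metadata is not None and len(self.trial_metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must match trial count")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to feedback onset."""
        return self.t0_ms + 1000.0 * np.arange(self.data.shape[2]) / self.srate

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present (have {self.channels})")

    def select(self, mask) -> "EpochArray":
        mask = np.asarray(mask)
        meta = None
        if self.trial_metadata is not None:
            meta = self.trial_metadata.iloc[mask] if mask.dtype.kind == "i" \
                else self.trial_metadata.loc[mask]
            meta = meta.reset_index(drop=True)
        return EpochArray(self.data[mask], self.channels, self.srate, self.t0_ms, meta)

    def to_xarray(self):
        import xarray as xr
        ds = xr.Dataset(
            {"eeg": (("trial", "channel", "time"), self.data)},
            coords={"trial": self.trial_metadata["trial"].to_numpy()
                    if self.trial_metadata is not None else np.arange(self.data.shape[0]),
                    "channel": list(self.channels), "time": self.times},
            attrs={"srate_hz": self.srate, "epoch_start_ms": self.t0_ms},
        )
        return ds

    def save_zarr(self, path) -> None:
        ds = self.to_xarray()
        if self.trial_metadata is not None:
            for c in self.trial_metadata.columns:
                if c == "trial":
                    continue
                ds = ds.assign_coords({f"meta_{c}": ("trial", self.trial_metadata[c].to_numpy())})
        ds.to_zarr(path, mode="w")

    @classmethod
    def load_zarr(cls, path) -> "EpochArray":
        import xarray as xr
        ds = xr.open_zarr(path)
        meta_cols = {c[5:]: ds[c].to_numpy() for c in ds.coords if str(c).startswith("meta_")}
        meta = pd.DataFrame({"trial": ds["trial"].to_numpy(), **meta_cols})
        return cls(ds["eeg"].to_numpy(), [str(c) for c in ds["channel"].to_numpy()],
                   float(ds.attrs["srate_hz"]), float(ds.attrs["epoch_start_ms"]), meta)


@dataclass
class BetaMap:
    """Per-subject regression weights over (regressor, channel, time)."""

    b: np.ndarray
    regressor_names: tuple
    channels: list
    srate: float
    t0_ms: float
    subject_id: str = ""
    n_trials: int = 0

    @property
    def times(self) -> np.ndarray:
        return self.t0_ms + 1000.0 * np.arange(self.b.shape[2]) / self.srate

    def regressor_index(self, name: str) -> int:
        return self.regressor_names.index(name)


@dataclass(frozen=True)
class ComponentWindow:
    """A +/-25 ms averaging window around a component peak."""

    name: str
    channel: str
    peak_ms: float
    window: tuple  # (start_ms, end_ms), inclusive


def drop_fast_response_trials(epochs: EpochArray, threshold_ms: float = 100.0):
    """Remove trials with a stage-1 or stage-2 RT below ``threshold_ms``.

    Returns ``(filtered_epochs, n_removed)``.
    """
    meta = epochs.trial_metadata
    if meta is None or not {"rt1_ms", "rt2_ms"}.issubset(meta.columns):
        raise ValueError("trial metadata with rt1_ms/rt2_ms required")
    fast = (meta["rt1_ms"].to_numpy() < threshold_ms) | \
           (meta["rt2_ms"].to_numpy() < threshold_ms)
    return epochs.select(~fast), int(fast.sum())


def baseline_correct(epochs: EpochArray, window=(-200.0, 0.0)) -> EpochArray:
    """Subtract the per-trial, per-channel mean over ``window`` (ms)."""
    t = epochs.times
    sel = (t >= window[0]) & (t < window[1]) if window[1] > window[0] else None
    if sel is None or not sel.any():
        raise ValueError("empty baseline window")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return EpochArray(epochs.data - base, epochs.channels, epochs.srate,
                      epochs.t0_ms, epochs.trial_metadata)


def adaptive_artifact_rejection(epochs: EpochArray, start_sd: float = 4.0,
                                step: float = 0.1, min_remove: int = 1,
                                max_frac: float = 0.05):
    """Reject extreme epochs with a self-adapting SD threshold.

    Each trial is summarized by its RMS amplitude over channels and time;
    the deviation score is that summary's z value within its
    across-trial distribution (robust location/scale, so artifact trials
    cannot mask themselves).  Starting at ``start_sd``, the threshold is
    lowered in ``step`` decrements until at least ``min_remove`` trials are
    rejected, or raised until no more than ``max_frac`` of trials are.

    Returns ``(kept_epochs, removed_indices, final_threshold)``.
    """
    n = epochs.data.shape[0]
    if n < 20:
        raise ValueError("need at least 20 trials for artifact statistics")
    cap = int(np.floor(max_frac * n))
    if min_remove > cap:
        raise ValueError(f"min_remove={min_remove} exceeds the {max_frac:.0%} cap ({cap} trials)")
    summary = np.sqrt((epochs.data ** 2).mean(axis=(1, 2)))
    med = np.median(summary)
    mad = 1.4826 * np.median(np.abs(summary - med))
    score = np.abs(summary - med) / max(mad, 1e-12)
    th = start_sd
    while (score > th).sum() < min_remove and th > step:
        th = round(th - step, 10)
    while (score > th).sum() > cap:
        th = round(th + step, 10)
    removed = np.flatnonzero(score > th)
    keep = np.setdiff1d(np.arange(n), removed)
    return epochs.select(keep), removed, th


def build_design(meta: pd.DataFrame, subset: Optional[str] = None):
    """First-level design matrix from epoch metadata.

    Full model: intercept, transition (+1 common / -1 rare), within-subject
    z-scored RPE, and their product.  With ``subset`` ("common"/"rare") the
    transition columns are dropped and only matching trials are used.

    Returns ``(X, regressor_names, row_mask)``.
    """
    trans = np.where(meta["transition"].to_numpy() == "common", 1.0, -1.0)
    mask = np.ones(len(meta), bool) if subset is None else \
        (meta["transition"].to_numpy() == subset)
    rpe = meta["rpe"].to_numpy(float)[mask]
    sd = rpe.std(ddof=0)
    if sd == 0:
        raise ValueError("RPE series is constant; regressor undefined")
    rpe_z = (rpe - rpe.mean()) / sd
    if subset is None:
        X = np.column_stack([np.ones(mask.sum()), trans[mask], rpe_z, trans[mask] * rpe_z])
        names = REGRESSOR_NAMES
        if len(np.unique(trans[mask])) < 2:
            raise ValueError("transition column is constant; collinear with intercept "
                             "(use subset= for single-transition data)")
    else:
        X = np.column_stack([np.ones(mask.sum()), rpe_z])
        names = ("intercept", "rpe")
    return X, names, mask


def huber_irls(X: np.ndarray, Y: np.ndarray, c: float = 1.345,
               max_iter: int = 50, tol: float = 1e-8) -> np.ndarray:
    """Vectorized Huber M-estimation of Y (n x p outcomes) on X (n x k).

    Runs iteratively reweighted least squares independently at every outcome
    column; the residual scale is the normalized MAD of the initial OLS
    residuals, held fixed while the coefficients iterate.  ``c = inf``
    reproduces ordinary least squares exactly.  Returns betas of shape
    (k, p) (or (k, *outcome_shape) for multi-dimensional Y).
    """
    n, k = X.shape
    Y2 = Y.reshape(n, -1)
    beta, *_ = np.linalg.lstsq(X, Y2, rcond=None)
    if not np.isfinite(c):
        return beta.reshape(k, *Y.shape[1:])
    # cross-product columns X_i * X_j so each IRLS step is two GEMMs
    iu, ju = np.triu_indices(k)
    xx = X[:, iu] * X[:, ju]                       # (n, k*(k+1)/2)
    xtwx = np.empty((Y2.shape[1], k, k))
    # MAD scale (uncentered, as in statsmodels.robust.scale.mad) from the
    # initial OLS residuals, held fixed while the coefficients iterate
    # (one-step scale M-estimation)
    r = Y2 - X @ beta
    scale = np.median(np.abs(r), axis=0) / 0.6745
    scale = np.maximum(scale, 1e-12)
    for _ in range(max_iter):
        r = Y2 - X @ beta
        a = np.abs(r) / (scale * c)
        w = np.minimum(1.0, 1.0 / np.maximum(a, 1e-300))
        # per-outcome weighted normal equations, solved in a batch
        flat = w.T @ xx                            # (p, n_pairs)
        xtwx[:, iu, ju] = flat
        xtwx[:, ju, iu] = flat
        xtwy = (w * Y2).T @ X                      # (p, k)
        new = np.linalg.solve(xtwx, xtwy[:, :, None])[:, :, 0].T
        if np.max(np.abs(new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new
    return beta.reshape(k, *Y.shape[1:])


def robust_regress_trials(epochs: EpochArray, subset: Optional[str] = None,
                          huber_c: float = 1.345, max_iter: int = 50,
                          tol: float = 1e-8, min_trials: int = 10) -> BetaMap:
    """Huber regression of every (channel, time) point on the trial design."""
    meta = epochs.trial_metadata
    if meta is None or "rpe" not in meta.columns:
        raise ValueError("epoch metadata must include an 'rpe' column")
    X, names, mask = build_design(meta, subset)
    if mask.sum() < min_trials:
        raise ValueError(f"only {int(mask.sum())} trials after subsetting (< {min_trials})")
    Y = epochs.data[mask]
    b = huber_irls(X, Y.reshape(mask.sum(), -1), c=huber_c,
                   max_iter=max_iter, tol=tol)
    b = b.reshape(len(names), *epochs.data.shape[1:])
    if not np.all(np.isfinite(b)):
        raise FloatingPointError("non-finite regression weights")
    sid = str(meta["subject_id"].iloc[0]) if "subject_id" in meta else ""
    return BetaMap(b, tuple(names), list(epochs.channels), epochs.srate,
                   epochs.t0_ms, sid, int(mask.sum()))


@dataclass
class GroupTMap:
    """One-sample group statistics of b maps against zero, FDR-corrected."""

    t: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    mask: np.ndarray
    channels: list
    times: np.ndarray
    regressor: str
    q: float
    zero_variance_points: int = 0


def group_tmap(beta_maps: Sequence[BetaMap], regressor: str, q: float = 0.05,
               family_channels: Optional[Sequence[str]] = ("FCz", "Cz")) -> GroupTMap:
    """Two-tailed one-sample t map of subject b values with BH-FDR.

    The FDR family defaults to all time points at FCz and Cz (the two
    component channels); pass ``family_channels=None`` for a whole-scalp family.
    """
    from statsmodels.stats.multitest import multipletests

    if len(beta_maps) < 3:
        raise ValueError("need at least 3 subjects")
    ri = beta_maps[0].regressor_index(regressor)
    chans = list(family_channels) if family_channels is not None else list(beta_maps[0].channels)
    ci = [beta_maps[0].channels.index(c) for c in chans]
    stackfull = np.stack([bm.b[ri] for bm in beta_maps])   # (subj, ch, time)
    stack = stackfull[:, ci, :]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(stack.shape[0]))
    p = 2.0 * stats.t.sf(np.abs(t), df=stack.shape[0] - 1)
    p[zero_var] = np.where(mean[zero_var] != 0, 0.0, 1.0)
    rej, p_fdr, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return GroupTMap(t, p, p_fdr.reshape(p.shape), rej.reshape(p.shape),
                     chans, beta_maps[0].times, regressor, q, int(zero_var.sum()))


def grand_average(epoch_arrays: Sequence[EpochArray]) -> tuple:
    """Mean over subjects of each subject's trial-mean, (channel x time)."""
    ga = np.mean([ep.data.mean(axis=0) for ep in epoch_arrays], axis=0)
    return ga, epoch_arrays[0].channels, epoch_arrays[0].times


COMPONENT_SEARCH = {
    "FRN": {"channel": "FCz", "range_ms": (250.0, 350.0), "polarity": -1},
    "P3": {"channel": "Cz", "range_ms": (330.0, 430.0), "polarity": +1},
}


def find_component_windows(ga: np.ndarray, channels: Sequence[str],
                           times: np.ndarray, half_ms: float = 25.0) -> dict:
    """Locate FRN/P3 peaks on the grand average and return +/-25 ms windows.

    FRN: most negative sample at FCz within 250-350 ms; P3: most positive at
    Cz within 330-430 ms.  Ties break toward the earlier latency (first
    extremum); a peak at a search boundary triggers a truncation warning.
    """
    out = {}
    for name, spec in COMPONENT_SEARCH.items():
        ci = list(channels).index(spec["channel"])
        lo, hi = spec["range_ms"]
        sel = np.flatnonzero((times >= lo) & (times <= hi))
        seg = ga[ci, sel] * spec["polarity"]
        peak_i = sel[int(np.argmax(seg))]
        peak_ms = float(times[peak_i])
        if peak_i in (sel[0], sel[-1]):
            warnings.warn(f"{name} peak at search boundary ({peak_ms:.0f} ms); "
                          "window may be truncated")
        out[name] = ComponentWindow(name, spec["channel"], peak_ms,
                                    (peak_ms - half_ms, peak_ms + half_ms))
    return out


def mean_b_in_window(beta_map: BetaMap, window: ComponentWindow, regressor: str) -> float:
    """Average the named regressor's b over the window at its channel."""
    if window.channel not in beta_map.channels:
        raise KeyError(f"channel {window.channel!r} missing from beta map")
    ci = beta_map.channels.index(window.channel)
    ri = beta_map.regressor_index(regressor)
    t = beta_map.times
    sel = (t >= window.window[0]) & (t <= window.window[1])
    if not sel.any():
        raise ValueError("window outside the epoch")
    return float(beta_map.b[ri, ci, sel].mean())
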