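"""Synthetic cohort generator: traits, trait-linked agents, and EEG epochs.

Emulates the statistical structure the analyses assume in a community
sample: impulsivity (BIS-11) and compulsivity (OCI-R) sum scores drawn from
a correlated bivariate normal; the model-based weight w linked negatively to
standardized compulsivity through a noisy logistic; and feedback-locked EEG
epochs in which Gaussian-windowed FRN (FCz, 294 ms) and P3 (Cz, 370 ms)
half-waves are modulated by feedback valence / signed RPE and by transition
rarity / RPE magnitude, with subject-level modulation gains linear in traits
and w.

Default gain values are chosen so that the recovered first- and second-level
coefficients match the magnitudes the analyses are designed to detect
(window-mean RPE effects of order 1-2 uV, trait links of order 0.3-0.5 uV
per z unit against a ~2 uV between-subject residual).  The mapping from a
planted peak-amplitude coefficient to the recovered window-mean b value is
exposed by :func:`expected_window_slope` so recovery tests can compare
against analytic expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal, stats

from .firstlevel import EpochArray
from .hybrid import AgentParams


# Empirical transfer constants of the default generative model: the slope of
# the recovered window-mean RPE b value on the planted per-subject peak
# coefficient, measured per (component, transition-subset) cell on a large
# calibration cohort under the default task/EEG conditions (subset z-scaling
# of the RPE regressor and the valence / |RPE| drive components make these
# smaller than 1 and cell-specific).  PIPELINE_NOISE_SD is the corresponding
# between-subject SD contributed by first-level estimation alone.
TRANSFER = {("frn", "common"): 0.652, ("frn", "rare"): 0.863,
            ("p3", "common"): 0.412, ("p3", "rare"): 0.690}
PIPELINE_NOISE_SD = {("frn", "common"): 0.37, ("frn", "rare"): 0.72,
                     ("p3", "common"): 0.39, ("p3", "rare"): 0.81}
# the cell each component's trait links are calibrated against
PRIMARY_CELL = {"frn": "common", "p3": "rare"}


def _default_gain_links():
    # planted peak-uV per z unit, calibrated so the *recovered* second-level
    # slopes land at ~(0.31 w, 0.23 BIS, -0.12 OCI) for the FRN and
    # ~(-0.45 OCI, 0.23 w, -0.10 BIS) for the P3 in their primary cells
    return {
        "frn": {"w": 0.475, "bis": 0.353, "oci": -0.184},
        "p3": {"w": 0.333, "bis": -0.145, "oci": -0.652},
    }


def _default_rpe_gain():
    # per-transition baseline RPE-modulation coefficient (uV at peak),
    # calibrated to recovered window intercepts of ~(2.09, 1.16) uV for the
    # FRN and ~(1.01, 0.06) uV for the P3; larger on common trials
    return {"frn": {"common": 3.21, "rare": 1.34},
            "p3": {"common": 2.45, "rare": 0.087}}


@dataclass(frozen=True)
class ErpTemplate:
    """Gaussian-windowed component waveform at a single channel."""

    component: str          # "FRN" | "P3"
    channel: str            # "FCz" | "Cz"
    peak_ms: float          # 294 | 370
    halfwidth_ms: float     # FWHM of the Gaussian window
    polarity: int           # -1 (FRN) | +1 (P3)

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        """Unit-peak window (polarity applied by the amplitude model)."""
        sigma = self.halfwidth_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((times_ms - self.peak_ms) / sigma) ** 2)


FRN_TEMPLATE = ErpTemplate("FRN", "FCz", 294.0, 60.0, -1)
P3_TEMPLATE = ErpTemplate("P3", "Cz", 370.0, 120.0, +1)
DEFAULT_CHANNELS = ["FCz", "Cz", "Pz", "F3", "F4"]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 238
    bis_mean: float = 65.0
    bis_sd: float = 10.0
    oci_mean: float = 12.0
    oci_sd: float = 9.0
    trait_correlation: float = 0.3
    # w = logistic(w_base + w_link * oci_z + noise); link negative: higher
    # compulsivity -> less model-based control
    w_link: float = -0.5
    w_base: float = 0.0
    w_noise_sd: float = 0.8
    # EEG amplitude model (uV at template peak)
    frn_base_amp: float = -3.5
    frn_common_gain: float = 1.44   # extra (negative) FRN amplitude on common trials
    p3_base_amp: float = 7.0
    p3_rarity_gain: float = 2.60    # extra P3 amplitude on rare trials
    rpe_gain: dict = field(default_factory=_default_rpe_gain)
    gain_links: dict = field(default_factory=_default_gain_links)
    # per-subject coefficient noise calibrated to a total second-level
    # residual SD of ~2.0 uV (FRN) and ~2.6 uV (P3), the regime the trait
    # moderation analysis is designed for
    gain_noise_sd: dict = field(default_factory=lambda: {"frn": 3.0, "p3": 3.6})
    # signed/valence composition of the RPE drives
    frn_signed_mix: float = 0.5     # weight of linear signed RPE vs valence step
    p3_signed_mix: float = 0.5      # weight of linear signed RPE vs |RPE|
    noise_sd: float = 10.0          # uV, band-limited background noise
    noise_lowpass_hz: float = 30.0
    srate: float = 500.0
    epoch_span_ms: tuple = (-200.0, 1000.0)
    channels: tuple = tuple(DEFAULT_CHANNELS)
    seed: Optional[int] = None

    def __post_init__(self):
        if abs(self.trait_correlation) >= 1:
            raise ValueError("|trait_correlation| must be < 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def generate_cohort(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw traits, trait-linked agent parameters, and planted EEG gains.

    Returns one row per subject with questionnaire scores, their cohort
    z-scores, the agent's generative parameters (true w included), and the
    planted per-subject RPE-modulation coefficients per component and
    transition type (full provenance for recovery tests).
    """
    n = spec.n_subjects
    cov = np.array([[spec.bis_sd ** 2,
                     spec.trait_correlation * spec.bis_sd * spec.oci_sd],
                    [spec.trait_correlation * spec.bis_sd * spec.oci_sd,
                     spec.oci_sd ** 2]])
    if np.linalg.det(cov) <= 0:
        raise ValueError("degenerate trait covariance")
    traits = rng.multivariate_normal([spec.bis_mean, spec.oci_mean], cov, size=n)
    bis, oci = traits[:, 0], traits[:, 1]

    def z(x):
        return (x - x.mean()) / x.std(ddof=0) if n > 1 else np.zeros_like(x)

    bis_z, oci_z = z(bis), z(oci)
    w = 1.0 / (1.0 + np.exp(-(spec.w_base + spec.w_link * oci_z
                              + rng.normal(0.0, spec.w_noise_sd, n))))
    df = pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in range(n)],
        "bis_score": bis, "oci_score": oci,
        "bis_z": bis_z, "oci_z": oci_z,
        "gender": rng.choice(["f", "m"], size=n),
        "alpha": rng.uniform(0.3, 0.8, n),
        "lam": rng.uniform(0.3, 0.9, n),
        "beta": np.minimum(np.exp(rng.normal(np.log(5.0), 0.3, n)), 15.0),
        "w": np.clip(w, 1e-4, 1 - 1e-4),
        "pi": rng.normal(0.25, 0.10, n),
        "rho": 0.0,
    })
    df["w_z"] = z(df["w"].to_numpy())
    for comp in ("frn", "p3"):
        links = spec.gain_links[comp]
        link_part = (links.get("w", 0) * df["w_z"]
                     + links.get("bis", 0) * df["bis_z"]
                     + links.get("oci", 0) * df["oci_z"])
        for trans in ("common", "rare"):
            eps = rng.normal(0.0, spec.gain_noise_sd[comp], n)
            df[f"a_{comp}_{trans}"] = spec.rpe_gain[comp][trans] + link_part + eps
    return df


def agent_params_from_row(row) -> AgentParams:
    return AgentParams(alpha=row["alpha"], lam=row["lam"], beta=row["beta"],
                       w=row["w"], pi=row["pi"], rho=row["rho"])


def _band_limited_noise(shape, sd, srate, cutoff_hz, rng):
    white = rng.standard_normal(shape)
    b, a = signal.butter(4, cutoff_hz / (srate / 2.0), btype="low")
    filt = signal.filtfilt(b, a, white, axis=-1)
    filt *= sd / filt.std()
    return filt


def generate_eeg_epochs(trials: pd.DataFrame, rpe_series: np.ndarray,
                        subject_row, spec: CohortSpec,
                        rng: np.random.Generator,
                        templates=(FRN_TEMPLATE, P3_TEMPLATE)) -> EpochArray:
    """Simulate feedback-locked epochs for one subject.

    Each epoch is band-limited Gaussian noise plus the FRN and P3 templates
    scaled by a per-trial amplitude:

    FRN (at FCz): ``polarity * |base| + common_gain`` on common trials, plus
    the subject's planted coefficient times a valence/signed-RPE drive
    (mixture ``frn_signed_mix``); the drive enters positively, so positive
    RPEs reduce the negative deflection.

    P3 (at Cz): base plus ``rarity_gain`` on rare trials, plus the subject's
    coefficient times a signed/|RPE| mixture drive (``p3_signed_mix``).

    ``rpe_series`` must align with ``trials`` row-for-row.
    """
    n = len(trials)
    rpe = np.asarray(rpe_series, float)
    if len(rpe) != n:
        raise ValueError(f"rpe series length {len(rpe)} != {n} trials")
    t0, t1 = spec.epoch_span_ms
    n_t = int(round((t1 - t0) * spec.srate / 1000.0))
    times = t0 + 1000.0 * np.arange(n_t) / spec.srate
    chans = list(spec.channels)
    data = _band_limited_noise((n, len(chans), n_t), spec.noise_sd,
                               spec.srate, spec.noise_lowpass_hz, rng)
    sd = rpe.std(ddof=0)
    rpe_z = (rpe - rpe.mean()) / sd if sd > 0 else np.zeros_like(rpe)
    valence = np.sign(rpe)
    common = (trials["transition"].to_numpy() == "common").astype(float)
    rare = 1.0 - common

    drive_frn = spec.frn_signed_mix * rpe_z + (1 - spec.frn_signed_mix) * valence
    drive_p3 = spec.p3_signed_mix * rpe_z + (1 - spec.p3_signed_mix) * np.abs(rpe_z)
    amp = {
        "FRN": (spec.frn_base_amp - spec.frn_common_gain * common
                + subject_row[["a_frn_common", "a_frn_rare"]].to_numpy(float)[
                    (1 - common).astype(int)] * drive_frn),
        "P3": (spec.p3_base_amp + spec.p3_rarity_gain * rare
               + subject_row[["a_p3_common", "a_p3_rare"]].to_numpy(float)[
                   (1 - common).astype(int)] * drive_p3),
    }
    for tmpl in templates:
        ci = chans.index(tmpl.channel)
        data[:, ci, :] += amp[tmpl.component][:, None] * tmpl.waveform(times)[None, :]
    meta = trials[["subject_id", "trial", "transition", "rt1_ms", "rt2_ms"]].copy()
    meta["rpe"] = rpe
    return EpochArray(data, chans, spec.srate, t0, meta.reset_index(drop=True))


def window_mean_factor(template: ErpTemplate, half_ms: float = 25.0) -> float:
    """Mean of the unit-peak template over the +/-25 ms peak window."""
    sigma = template.halfwidth_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return float(np.sqrt(2 * np.pi) * sigma
                 * (2 * stats.norm.cdf(half_ms / sigma) - 1) / (2 * half_ms))


def linear_rpe_attenuation(spec: CohortSpec, component: str) -> float:
    """Expected slope of the component's RPE drive on z-scored signed RPE.

    The valence step projects onto a standard-normal z with slope
    E|z| = sqrt(2/pi); |RPE| projects with slope ~0 (symmetry).  This is the
    factor by which the linear first-level RPE regressor attenuates the
    planted drive.
    """
    e_abs_z = np.sqrt(2.0 / np.pi)
    if component.lower() == "frn":
        return spec.frn_signed_mix + (1 - spec.frn_signed_mix) * e_abs_z
    return spec.p3_signed_mix


def expected_window_slope(spec: CohortSpec, component: str, predictor: str,
                          transition: Optional[str] = None) -> float:
    """Window-mean b expected for a planted coefficient.

    ``predictor`` in {"w", "bis", "oci"} gives the expected second-level
    slope; ``predictor="base"`` (with ``transition``) gives the expected
    per-transition intercept.  Both equal the planted peak coefficient times
    the calibrated cell transfer constant (valid for the default drive
    mixtures, templates and task conditions the constants were measured
    under).
    """
    comp = component.lower()
    if transition is None:
        transition = PRIMARY_CELL[comp]
    factor = TRANSFER[(comp, transition)]
    if predictor == "base":
        return spec.rpe_gain[comp][transition] * factor
    return spec.gain_links[comp][predictor] * factor
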