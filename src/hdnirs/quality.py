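"""Per-channel signal-quality metrics, the ROI-weighted session quality
score, poor-quality/minimum-viable-quality partitioning, and the
quality-versus-length sigmoid fit.

Conventions fixed here: the coefficient of variation uses the sample SD
(ddof=1); stimulus SNR powers are mean squares; the robust SNR is capped at
a configurable ceiling when the MAD is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .io import SessionRecording
from .montage import Montage
from .preprocessing import butterworth_bandpass, epoch_extract, intensity_to_od

SNR_CAP_DB = 60.0


def coefficient_of_variation(segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CV_c = sigma_c / mu_c per channel (sample SD, ddof=1).

    Returns (cv, valid); cv is NaN and valid False where mu <= 0.
    """
    x = np.atleast_2d(np.asarray(segment, float))
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    valid = mu > 0
    cv = np.where(valid, sd / np.where(valid, mu, 1.0), np.nan)
    return cv, valid


def robust_snr(segment: np.ndarray, cap_db: float = SNR_CAP_DB
               ) -> tuple[np.ndarray, np.ndarray]:
    """SNR_c = 10 log10( median(x) / median|x - median(x)| ) in dB.

    Returns (snr_db, capped); channels with zero MAD return the cap,
    flagged in ``capped``.
    """
    x = np.atleast_2d(np.asarray(segment, float))
    med = np.median(x, axis=1)
    mad = np.median(np.abs(x - med[:, None]), axis=1)
    capped = mad <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = 10.0 * np.log10(med / np.where(capped, 1.0, mad))
    snr = np.where(capped, cap_db, snr)
    return np.minimum(snr, cap_db), capped


def stimulus_snr(
    od: np.ndarray,
    fs: float,
    onsets_s,
    band=(0.01, 0.1),
    order: int = 4,
) -> np.ndarray:
    """Stimulus-dependent SNR in dB per channel.

    Signal power: 0.01-0.1 Hz bandpassed OD in the [0, 2) s task window
    minus that channel's [-2, 0) s baseline mean; noise power: unfiltered OD
    in [0, 2) s.  Powers are mean squares averaged over trials.
    """
    onsets = list(onsets_s)
    if not onsets:
        raise ValueError("stimulus SNR needs at least one trial onset")
    filt = butterworth_bandpass(od, fs, band, order=order, zero_phase=True)
    ep_f = epoch_extract(filt, fs, onsets, -2.0, 2.0)  # [trial x ch x 40]
    ep_r = epoch_extract(od, fs, onsets, 0.0, 2.0)
    nb = int(round(2.0 * fs))
    base = ep_f[..., :nb].mean(axis=-1, keepdims=True)
    sig = ep_f[..., nb:] - base
    p_sig = np.mean(sig**2, axis=(0, 2))
    p_noise = np.mean(ep_r**2, axis=(0, 2))
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(p_sig / p_noise)


# ---------------------------------------------------------------------------
# ROI quality score and partitioning
# ---------------------------------------------------------------------------

def roi_weights(channels: pd.DataFrame, montage: Montage,
                sigma_mm: float = 30.0) -> np.ndarray:
    """Gaussian falloff of channel midpoint distance to the nearer motor ROI
    center (summed over both ROIs); montage mirror-symmetric."""
    mids = channels[["mid_x", "mid_y", "mid_z"]].to_numpy()
    w = np.zeros(len(channels))
    for c in montage.roi_centers().values():
        d = np.linalg.norm(mids - c[None, :], axis=1)
        w += np.exp(-0.5 * (d / sigma_mm) ** 2)
    return w


def roi_quality_score(
    channel_cvs: np.ndarray,
    channels: pd.DataFrame,
    montage: Montage,
    sigma_mm: float = 30.0,
    v0: float = 0.5,
) -> float:
    """Session quality in [0, 1] (1 best): ROI-weighted mean of the
    per-channel quality map q(cv) = exp(-cv / v0); invalid CVs score 0."""
    cv = np.asarray(channel_cvs, float)
    q = np.where(np.isfinite(cv), np.exp(-cv / v0), 0.0)
    w = roi_weights(channels, montage, sigma_mm)
    return float(np.sum(w * q) / np.sum(w))


@dataclass
class QualityPartition:
    roi_quality: float
    t_qual: float
    label: str  # "PQ" | "MVQ"


def partition_sessions(
    scores, t_qual: float | None = None
) -> list[QualityPartition]:
    """Label sessions PQ/MVQ by ROI quality score.

    Manual mode applies the given threshold (MVQ iff score > t_qual).  Auto
    mode re-derives the threshold per cohort as the lowest upper bound of
    the lowest-quality cluster: the largest gap among sorted scores below
    the median separates the low cluster; the threshold is that cluster's
    maximum.  With no gap (all scores equal) everything is MVQ, with a
    warning.
    """
    s = np.asarray(list(scores), float)
    if t_qual is None:
        if len(s) < 2:
            raise ValueError("auto partitioning needs at least 2 sessions")
        order = np.sort(s)
        med = np.median(order)
        gaps = np.diff(order)
        below = np.where(order[:-1] < med)[0]
        if below.size == 0 or gaps[below].max() <= 0:
            warnings.warn("no quality gap found: all sessions labeled MVQ")
            t_qual = order[0] - 1.0
        else:
            i = below[np.argmax(gaps[below])]
            t_qual = float(order[i])
    return [QualityPartition(float(v), float(t_qual),
                             "MVQ" if v > t_qual else "PQ") for v in s]


def session_quality(
    rec: SessionRecording,
    montage: Montage,
    sigma_mm: float = 30.0,
    v0: float = 0.5,
    guard_s: float = 1.0,
) -> tuple[float, pd.DataFrame]:
    """CV-based quality report for one session (task spans only, breaks and
    baseline excluded with a 1-s guard band)."""
    mask = rec.task_span_mask(guard_s=guard_s)
    seg = rec.intensity[:, mask]
    cv, valid = coefficient_of_variation(seg)
    snr, capped = robust_snr(seg)
    report = montage.channels[["id", "length", "roi"]].copy()
    report["cv"] = cv
    report["cv_valid"] = valid
    report["snr_db"] = snr
    report["snr_capped"] = capped
    score = roi_quality_score(cv, montage.channels, montage, sigma_mm, v0)
    return score, report


# ---------------------------------------------------------------------------
# CoV vs length sigmoid
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    a: float       # lower asymptote (short-channel CoV)
    b: float       # upper asymptote (long-channel CoV)
    m: float       # midpoint length (mm)
    s: float       # slope scale (mm)
    rmse: float
    converged: bool
    degenerate: bool


def fit_cv_length_sigmoid(channel_cvs, lengths) -> SigmoidFit:
    """Least-squares 4-parameter logistic cv(L) = a + (b-a)/(1+e^-((L-m)/s))."""
    cv = np.asarray(channel_cvs, float)
    L = np.asarray(lengths, float)
    ok = np.isfinite(cv) & np.isfinite(L)
    cv, L = cv[ok], L[ok]
    if len(np.unique(L)) < 8:
        raise ValueError("sigmoid fit needs >= 8 distinct channel lengths")

    def f(x, a, b, m, s):
        return a + (b - a) / (1.0 + np.exp(-(x - m) / s))

    p0 = [float(cv.min()), float(cv.max()), float(np.median(L)), 10.0]
    try:
        popt, _ = optimize.curve_fit(f, L, cv, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    a, b, m, s = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((f(L, a, b, m, s) - cv) ** 2)))
    scale = max(abs(a), abs(b), 1e-12)
    return SigmoidFit(a, b, m, s, rmse, converged,
                      degenerate=abs(b - a) < 1e-3 * scale)
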