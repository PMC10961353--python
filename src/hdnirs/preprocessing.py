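"""Causal and block-level signal transforms shared by the quality,
block-average, and decoding stages.

Conventions
-----------
* Arrays are [n_channels x n_samples] unless stated otherwise.
* Optical density uses the natural log: OD = -ln(I / ref).
* Sample indexing is 0-based; epoch windows are half-open [t0, t1).
* Every transform flagged *causal* depends at sample t only on samples <= t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import Montage


class PreprocessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Extinction coefficients
# ---------------------------------------------------------------------------

#: Molar extinction coefficients at the montage wavelengths, from the
#: standard compiled hemoglobin spectra (base-10, cm^-1 / M), converted to
#: natural-log units of 1 / (uM * mm):  eps_ln = eps10 * ln(10) * 1e-7.
#: Keys: wavelength nm -> (HbO, HbR).
EXTINCTION_BASE10_CM_M = {
    735.0: (450.0, 1102.0),
    850.0: (1058.0, 691.0),
}
_LN10_SCALE = np.log(10.0) * 1e-7
EXTINCTION_LN_UM_MM = {
    wl: (e[0] * _LN10_SCALE, e[1] * _LN10_SCALE)
    for wl, e in EXTINCTION_BASE10_CM_M.items()
}


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------

def intensity_to_od(
    intensity: np.ndarray,
    fs: float,
    reference_mode: str = "whole_session",
    ema_forget: float = 0.01,
    clamp_rel: float = 1e-9,
) -> np.ndarray:
    """OD_c(t) = -ln( I_c(t) / ref_c(t) ).

    reference_mode:
      ``whole_session`` - per-channel whole-recording mean;
      ``first_60s``     - mean over the first 60 s;
      ``running_ema``   - causal exponential moving average (forget factor
      ``ema_forget``), i.e. delta-OD against a running baseline.

    Intensities are clamped below at ``clamp_rel`` x channel median; channels
    whose median is non-positive cannot be referenced and raise.
    """
    I = np.asarray(intensity, float)
    med = np.median(I, axis=1)
    bad = np.where(med <= 0)[0]
    if bad.size:
        raise PreprocessingError(
            f"non-positive median intensity in channels {bad.tolist()}"
        )
    floor = (clamp_rel * med)[:, None]
    I = np.maximum(I, floor)
    if reference_mode == "whole_session":
        ref = I.mean(axis=1, keepdims=True)
    elif reference_mode == "first_60s":
        n = max(1, min(I.shape[1], int(round(60.0 * fs))))
        ref = I[:, :n].mean(axis=1, keepdims=True)
    elif reference_mode == "running_ema":
        ref = _ema(I, ema_forget)
    else:
        raise PreprocessingError(f"unknown reference mode {reference_mode!r}")
    return -np.log(I / ref)


def _ema(x: np.ndarray, forget: float) -> np.ndarray:
    """Causal exponential moving average, initialized at the first sample."""
    b, a = [forget], [1.0, -(1.0 - forget)]
    zi = sps.lfilter_zi(b, a)
    x2 = np.atleast_2d(x)
    out = np.empty_like(x2)
    for i in range(x2.shape[0]):
        out[i], _ = sps.lfilter(b, a, x2[i], zi=zi * x2[i, 0])
    return out.reshape(np.shape(x))


# ---------------------------------------------------------------------------
# MACD-type causal bandpass
# ---------------------------------------------------------------------------

@dataclass
class FilterState:
    """Streaming state for :func:`macd_bandpass` (per-channel lfilter zi)."""

    forget: float = 0.01
    window_s: float = 2.0
    ema_zi: np.ndarray | None = None
    ma_zi: np.ndarray | None = None


def macd_bandpass(
    series: np.ndarray,
    fs: float,
    state: FilterState | None = None,
) -> tuple[np.ndarray, FilterState]:
    """Low-latency causal bandpass: y = movavg_2s( x - EMA_0.01(x) ).

    The EMA (forget factor 0.01 per sample) acts as the high-pass; the 2-s
    rectangular moving average is the low-pass.  The effective group delay
    is about half the moving-average window (~1 s at the defaults).
    """
    if state is None:
        state = FilterState()
    x = np.atleast_2d(np.asarray(series, float))
    ff = state.forget
    w = max(1, int(round(state.window_s * fs)))
    b_e, a_e = np.array([ff]), np.array([1.0, -(1.0 - ff)])
    b_m, a_m = np.ones(w) / w, np.array([1.0])
    if state.ema_zi is None:
        zi_e = sps.lfilter_zi(b_e, a_e)
        state.ema_zi = zi_e[None, :] * x[:, :1]
        state.ma_zi = np.zeros((x.shape[0], w - 1))
    ema, state.ema_zi = sps.lfilter(b_e, a_e, x, axis=1, zi=state.ema_zi)
    hp = x - ema
    y, state.ma_zi = sps.lfilter(b_m, a_m, hp, axis=1, zi=state.ma_zi)
    return y.reshape(np.shape(series)), state


def macd_frequency_response(freqs_hz, fs: float, forget: float = 0.01,
                            window_s: float = 2.0) -> np.ndarray:
    """Analytic transfer function magnitude of the MACD filter."""
    zinv = np.exp(-2j * np.pi * np.asarray(freqs_hz, float) / fs)
    ema = forget / (1.0 - (1.0 - forget) * zinv)
    w = max(1, int(round(window_s * fs)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ma = (1.0 / w) * (1.0 - zinv**w) / (1.0 - zinv)
    ma = np.where(np.isclose(zinv, 1.0), 1.0, ma)
    return np.abs((1.0 - ema) * ma)


# ---------------------------------------------------------------------------
# Butterworth bandpass
# ---------------------------------------------------------------------------

def butterworth_bandpass(
    series: np.ndarray,
    fs: float,
    band: tuple[float, float],
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Standard IIR bandpass; zero-phase (forward-backward) by default for
    the offline chains, causal when ``zero_phase=False``."""
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi):
        raise PreprocessingError(f"invalid band {band}")
    if hi >= nyq:
        raise PreprocessingError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = np.asarray(series, float)
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def butterworth_lowpass(series, fs, cutoff, order=3, zero_phase=True):
    nyq = fs / 2.0
    if cutoff >= nyq:
        raise PreprocessingError(f"cutoff {cutoff} Hz at or above Nyquist")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    x = np.asarray(series, float)
    return sps.sosfiltfilt(sos, x, axis=-1) if zero_phase else sps.sosfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# Temporal Derivative Distribution Repair
# ---------------------------------------------------------------------------

def tddr(series: np.ndarray, fs: float, max_iter: int = 50,
         return_info: bool = False):
    """Motion-artifact repair by robust reweighting of signal derivatives.

    The signal is split at 0.5 Hz into a low-frequency component (corrected)
    and a high-frequency residual (added back).  Derivatives of the
    low-frequency component are iteratively reweighted with the Tukey
    biweight (c = 4.685, robust sigma = 1.4826 * MAD) until the robust mean
    converges; the weighted, centered derivatives are re-integrated.

    Returns the corrected series; with ``return_info=True`` also a list of
    per-channel dicts with ``converged`` and ``n_iter``.
    """
    x = np.atleast_2d(np.asarray(series, float))
    out = np.empty_like(x)
    infos = []
    for i in range(x.shape[0]):
        out[i], info = _tddr_1d(x[i], fs, max_iter)
        infos.append(info)
        if not info["converged"]:
            warnings.warn(f"TDDR did not converge on channel {i}")
    out = out.reshape(np.shape(series))
    return (out, infos) if return_info else out


def _tddr_1d(sig: np.ndarray, fs: float, max_iter: int):
    tune = 4.685
    mean = sig.mean()
    sig = sig - mean
    if 0.5 * 2.0 / fs < 1.0 and len(sig) > 12:
        b, a = sps.butter(3, 0.5 * 2.0 / fs)
        low = sps.filtfilt(b, a, sig)
    else:
        low = sig
    high = sig - low
    deriv = np.diff(low)
    if deriv.size == 0:
        return sig + mean, {"converged": True, "n_iter": 0}
    w = np.ones_like(deriv)
    mu = np.inf
    converged = False
    it = 0
    eps = np.sqrt(np.finfo(float).eps)
    for it in range(1, max_iter + 1):
        mu0 = mu
        mu = np.sum(w * deriv) / np.sum(w)
        dev = deriv - mu
        sigma = 1.4826 * np.median(np.abs(dev - np.median(dev)))
        if sigma == 0:
            converged = True
            break
        r = dev / (sigma * tune)
        w = np.where(np.abs(r) < 1, (1 - r**2) ** 2, 0.0)
        if np.isfinite(mu0) and abs(mu - mu0) <= eps * max(abs(mu), abs(mu0), 1e-300):
            converged = True
            break
    new_deriv = w * (deriv - mu)
    low_corr = np.concatenate(([0.0], np.cumsum(new_deriv)))
    return low_corr + high + mean, {"converged": converged, "n_iter": it}


# ---------------------------------------------------------------------------
# GVTD epoch rejection
# ---------------------------------------------------------------------------

def gvtd(series: np.ndarray) -> np.ndarray:
    """Global variance of temporal derivatives:
    g(t) = sqrt( mean_c (x_c(t) - x_c(t-1))^2 ), g(0) = 0."""
    x = np.atleast_2d(np.asarray(series, float))
    d = np.diff(x, axis=1)
    g = np.sqrt(np.mean(d**2, axis=0))
    return np.concatenate(([0.0], g))


def gvtd_reject(epochs: np.ndarray, n_sd: float = 3.0):
    """Reject epochs whose max-GVTD statistic exceeds mean + n_sd * SD of the
    per-epoch statistics (computed over all epochs before any rejection).

    epochs: [n_trials x n_channels x n_samples].
    Returns (kept_epochs, keep_mask).
    """
    ep = np.asarray(epochs, float)
    n = ep.shape[0]
    if n < 3:
        warnings.warn("fewer than 3 epochs: GVTD rejection skipped")
        return ep, np.ones(n, bool)
    stats = np.array([gvtd(e).max() for e in ep])
    thresh = stats.mean() + n_sd * stats.std(ddof=1)
    keep = stats <= thresh
    return ep[keep], keep


# ---------------------------------------------------------------------------
# Within-tile averaging
# ---------------------------------------------------------------------------

def tile_average(
    series: np.ndarray,
    montage: Montage,
    include_intra_tile: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Average all channels between the same two tiles into one virtual
    channel per ordered (source tile, detector tile, wavelength) triple.

    Tile-pair length is the tile center-to-center distance; the midpoint is
    the mean of the two tile centers.  Returns (data, tile_channel_table)
    where the table carries the same columns used for optode-level channels
    so downstream steps (length filter, MBLL pairing) apply unchanged.
    """
    ch = montage.channels
    x = np.asarray(series, float)
    if x.shape[0] != len(ch):
        raise PreprocessingError(
            f"series has {x.shape[0]} rows, montage has {len(ch)} channels")
    rows = []
    data = []
    cid = 0
    roi_centers = montage.roi_centers()
    roi_radius = float(montage.geometry.get("roi_radius_mm", 30.0))
    grouped = ch.groupby(["source_tile", "detector_tile", "wavelength"]).indices
    for (st, dt, wl) in sorted(grouped):
        if not include_intra_tile and st == dt:
            continue
        idx = grouped[(st, dt, wl)]
        cs, cd = montage.tile_center(st), montage.tile_center(dt)
        length = float(np.linalg.norm(cs - cd))
        mid = (cs + cd) / 2.0
        roi = "none"
        for name, c in roi_centers.items():
            if np.linalg.norm(mid - c) <= roi_radius:
                roi = name
                break
        data.append(x[idx].mean(axis=0))
        rows.append(
            (cid, f"T{st}", f"T{dt}", wl, length, mid[0], mid[1], mid[2],
             length / 4.0, roi, st, dt)
        )
        cid += 1
    table = pd.DataFrame(
        rows,
        columns=["id", "source_id", "detector_id", "wavelength", "length",
                 "mid_x", "mid_y", "mid_z", "depth_proxy", "roi",
                 "source_tile", "detector_tile"],
    )
    return np.asarray(data), table


# ---------------------------------------------------------------------------
# Modified Beer-Lambert law
# ---------------------------------------------------------------------------

def extinction_matrix(wavelengths, table=None) -> np.ndarray:
    """2x2 matrix E with rows per wavelength, columns (HbO, HbR)."""
    table = table or EXTINCTION_LN_UM_MM
    return np.array([table[float(w)] for w in wavelengths], float)


def mbll(
    od: np.ndarray,
    channels: pd.DataFrame,
    dpf: float = 6.0,
    extinction_table: dict | None = None,
    det_tol: float = 1e-12,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Invert the modified Beer-Lambert law per source-detector pair:
    solve  E @ [dHbO; dHbR] = dOD_lambda / (L * DPF)  per sample.

    Returns (conc, pair_table): conc is [n_pairs x 2 x n_samples] in uM with
    chromophore axis (HbO, HbR); pair_table has one row per pair with the
    geometric columns of the first member channel.
    """
    od = np.asarray(od, float)
    groups = channels.groupby(["source_id", "detector_id"], sort=False).indices
    pairs, conc = [], []
    cid = 0
    for key in groups:
        idx = np.sort(groups[key])
        if len(idx) != 2:
            raise PreprocessingError(
                f"pair {key} has {len(idx)} wavelengths; MBLL needs exactly 2")
        sub = channels.iloc[idx]
        E = extinction_matrix(sub["wavelength"].tolist(), extinction_table)
        scale = np.linalg.norm(E, ord=np.inf)
        if abs(np.linalg.det(E / scale)) < det_tol:
            raise PreprocessingError("degenerate wavelength pair (singular E)")
        L = float(sub["length"].iloc[0])
        rhs = od[idx] / max(L * dpf, 1e-12)
        conc.append(np.linalg.solve(E, rhs))
        first = sub.iloc[0]
        pairs.append(
            (cid, first["source_id"], first["detector_id"], L,
             first["mid_x"], first["mid_y"], first["mid_z"],
             first["depth_proxy"], first["roi"])
        )
        cid += 1
    table = pd.DataFrame(
        pairs, columns=["id", "source_id", "detector_id", "length",
                        "mid_x", "mid_y", "mid_z", "depth_proxy", "roi"])
    return np.asarray(conc), table


def mbll_forward(
    conc: np.ndarray,
    lengths_mm: np.ndarray,
    wavelength: float,
    dpf: float = 6.0,
    extinction_table: dict | None = None,
) -> np.ndarray:
    """Forward MBLL: dOD at one wavelength from [n x 2 x t] concentrations."""
    table = extinction_table or EXTINCTION_LN_UM_MM
    eo, er = table[float(wavelength)]
    L = np.asarray(lengths_mm, float)[:, None]
    return (eo * conc[:, 0, :] + er * conc[:, 1, :]) * L * dpf


# ---------------------------------------------------------------------------
# Recursive ZCA
# ---------------------------------------------------------------------------

def recursive_zca(
    series: np.ndarray,
    fs: float,
    block_s: float = 5.0,
    shrinkage: float = 1e-6,
    half_life_s: float = 60.0,
) -> np.ndarray:
    """Causal adaptive spatial whitening in block updates.

    The running covariance (and mean) is updated once per ``block_s`` block
    with an exponential forgetting half-life of ``half_life_s``; each block
    is transformed with the symmetric inverse square root of the covariance
    known *before* that block (strictly causal), shrunk toward
    ``shrinkage * tr(S)/C * I`` so the shrinkage strength is unit-free.
    The very first block passes through unchanged (identity transform).
    """
    x = np.atleast_2d(np.asarray(series, float))
    C, n = x.shape
    blk = max(1, int(round(block_s * fs)))
    if n < blk:
        warnings.warn("fewer samples than one ZCA block: identity transform")
        return x.reshape(np.shape(series)).copy()
    rho = 0.5 ** (block_s / half_life_s)
    out = np.empty_like(x)
    S = None
    mu = None
    for start in range(0, n, blk):
        stop = min(start + blk, n)
        xb = x[:, start:stop]
        if S is None:
            out[:, start:stop] = xb
        else:
            lam = shrinkage * np.trace(S) / C
            evals, evecs = np.linalg.eigh(S + lam * np.eye(C))
            evals = np.maximum(evals, lam if lam > 0 else 1e-300)
            T = (evecs / np.sqrt(evals)) @ evecs.T
            out[:, start:stop] = T @ (xb - mu[:, None])
        bm = xb.mean(axis=1)
        xc = xb - bm[:, None]
        Sb = (xc @ xc.T) / max(xb.shape[1] - 1, 1)
        if S is None:
            S, mu = Sb, bm
        else:
            S = rho * S + (1 - rho) * Sb
            mu = rho * mu + (1 - rho) * bm
    return out.reshape(np.shape(series))


# ---------------------------------------------------------------------------
# Channel length filter & epoching
# ---------------------------------------------------------------------------

def channel_length_filter(
    series: np.ndarray,
    channels: pd.DataFrame,
    min_mm: float = 0.0,
    max_mm: float = np.inf,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep channels with min_mm <= length <= max_mm (inclusive)."""
    if min_mm > max_mm:
        raise PreprocessingError(f"min_mm {min_mm} > max_mm {max_mm}")
    mask = (channels["length"].to_numpy() >= min_mm) & (
        channels["length"].to_numpy() <= max_mm)
    if not mask.any():
        raise PreprocessingError(
            f"no channels in length range [{min_mm}, {max_mm}] mm")
    return np.asarray(series)[mask], channels.loc[mask].reset_index(drop=True)


def epoch_extract(
    data: np.ndarray,
    fs: float,
    onsets_s,
    t0: float,
    t1: float,
) -> np.ndarray:
    """Half-open epochs [onset+t0, onset+t1) -> [n_trials x ... x n_win].

    Trials whose window falls outside the recording are dropped.
    """
    x = np.asarray(data, float)
    nwin = int(round((t1 - t0) * fs))
    eps = []
    for on in onsets_s:
        i0 = int(round((on + t0) * fs))
        if i0 < 0 or i0 + nwin > x.shape[-1]:
            continue
        eps.append(x[..., i0:i0 + nwin])
    if not eps:
        raise PreprocessingError("no trials fit inside the recording")
    return np.asarray(eps)


def baseline_subtract(epochs: np.ndarray, fs: float, window_t0: float,
                      base_t0: float, base_t1: float) -> np.ndarray:
    """Subtract the per-trial mean over [base_t0, base_t1) (times relative to
    stimulus onset; window_t0 is the epoch start time, e.g. -5 s)."""
    i0 = int(round((base_t0 - window_t0) * fs))
    i1 = int(round((base_t1 - window_t0) * fs))
    base = epochs[..., i0:i1].mean(axis=-1, keepdims=True)
    return epochs - base
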