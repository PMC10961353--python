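"""Hemodynamic response estimation by single-trial block averaging, and
group statistics across sessions.

Per-session chain (offline, zero-phase filters): within-tile averaging of
raw intensity -> keep 15-60 mm tile pairs -> OD against the whole-session
mean -> 0.02-2 Hz bandpass -> TDDR -> GVTD outlier-trial rejection (3 SD,
statistics over all covert trials of the session) -> MBLL (DPF 6) ->
epochs [-5, 17) s around tapping onset -> [-2, 0) s baseline subtraction ->
mean per condition and chromophore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SessionRecording
from .montage import Montage
from .preprocessing import (
    baseline_subtract,
    butterworth_bandpass,
    channel_length_filter,
    epoch_extract,
    gvtd_reject,
    intensity_to_od,
    mbll,
    tddr,
    tile_average,
)

CONDITIONS = ("left", "right")
EPOCH_T0, EPOCH_T1 = -5.0, 17.0
BASELINE_T0, BASELINE_T1 = -2.0, 0.0


@dataclass
class BlockAverage:
    """Per-session HRF estimates: ``waveforms[cond]`` is
    [n_pairs x 2 chromophores x n_samples]."""

    waveforms: dict
    n_trials: dict
    pairs: pd.DataFrame
    times: np.ndarray
    keep_mask: np.ndarray


def run_block_average(
    rec: SessionRecording,
    montage: Montage,
    min_mm: float = 15.0,
    max_mm: float = 60.0,
    band=(0.02, 2.0),
    gvtd_sd: float = 3.0,
    dpf: float = 6.0,
) -> BlockAverage:
    fs = rec.fs
    x, table = tile_average(rec.intensity, montage)
    x, table = channel_length_filter(x, table, min_mm, max_mm)
    od = intensity_to_od(x, fs, "whole_session")
    od = butterworth_bandpass(od, fs, band, zero_phase=True)
    od = tddr(od, fs)

    trials = rec.trial_markers(covert_only=True)
    nwin = int(round((EPOCH_T1 - EPOCH_T0) * fs))
    onsets, labels = [], []
    for t, lab in trials:
        i0 = int(round((t + EPOCH_T0) * fs))
        if 0 <= i0 and i0 + nwin <= od.shape[1]:
            onsets.append(t)
            labels.append(lab)
    labels = np.array(labels)

    ep_od = epoch_extract(od, fs, onsets, EPOCH_T0, EPOCH_T1)
    _, keep = gvtd_reject(ep_od, gvtd_sd)

    conc, pairs = mbll(od, table, dpf=dpf)
    ep = epoch_extract(conc, fs, onsets, EPOCH_T0, EPOCH_T1)
    ep = baseline_subtract(ep, fs, EPOCH_T0, BASELINE_T0, BASELINE_T1)

    waveforms, n_trials = {}, {}
    for cond in CONDITIONS:
        sel = keep & (labels == cond)
        n_trials[cond] = int(sel.sum())
        waveforms[cond] = (ep[sel].mean(axis=0) if sel.any()
                           else np.full(ep.shape[1:], np.nan))
    times = EPOCH_T0 + np.arange(nwin) / fs
    return BlockAverage(waveforms, n_trials, pairs, times, keep)


@dataclass
class GroupHRF:
    mean: np.ndarray
    ci95: np.ndarray          # half-width
    t: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray   # p_fdr < alpha
    degenerate: np.ndarray    # zero-variance, nonzero-mean timepoints


def group_test(session_waveforms, alpha: float = 0.05) -> GroupHRF:
    """Two-sided 1-sample t across sessions vs 0 per timepoint, BH-FDR
    corrected along the last (time) axis independently for every other
    index (channel/chromophore).

    ``session_waveforms``: array-like [n_sessions x ... x n_samples].
    """
    X = np.asarray(session_waveforms, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("group test needs >= 3 sessions")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    degenerate = (sd == 0) & (mean != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t = np.where(degenerate, np.inf * np.sign(mean), t)
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((sd == 0) & (mean == 0), 1.0, p)

    flat = p.reshape(-1, p.shape[-1])
    p_fdr = np.empty_like(flat)
    for i in range(flat.shape[0]):
        p_fdr[i] = multipletests(flat[i], alpha=alpha, method="fdr_bh")[1]
    p_fdr = p_fdr.reshape(p.shape)
    ci95 = stats.t.ppf(0.975, df=n - 1) * se
    return GroupHRF(mean, ci95, t, p_fdr, p_fdr < alpha, degenerate)


def waveforms_to_frame(ba: BlockAverage) -> pd.DataFrame:
    """Tidy CSV-ready export of one session's block-average waveforms."""
    rows = []
    for cond, w in ba.waveforms.items():
        for pi, pair in ba.pairs.iterrows():
            for ci, chrom in enumerate(("HbO", "HbR")):
                for ti, tval in enumerate(ba.times):
                    rows.append((cond, pair["source_id"], pair["detector_id"],
                                 chrom, tval, w[pi, ci, ti]))
    return pd.DataFrame(
        rows, columns=["condition", "source", "detector", "chromophore",
                       "time_s", "concentration_uM"])
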