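"""Oracle and property tests for the shared signal transforms."""

import numpy as np
import pytest

from hdnirs.preprocessing import (
    EXTINCTION_LN_UM_MM,
    FilterState,
    PreprocessingError,
    baseline_subtract,
    butterworth_bandpass,
    channel_length_filter,
    epoch_extract,
    gvtd,
    gvtd_reject,
    intensity_to_od,
    macd_bandpass,
    macd_frequency_response,
    mbll,
    mbll_forward,
    recursive_zca,
    tddr,
    tile_average,
)

FS = 10.0
RNG = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------

def test_od_zero_when_equal_to_reference():
    I = np.full((3, 100), 7.5)
    od = intensity_to_od(I, FS, "whole_session")
    assert np.allclose(od, 0.0)


def test_od_analytic_point():
    I = np.full((1, 100), 2.0)
    I[0, 50] = 2.0 * np.exp(-1.0)
    od = intensity_to_od(I, FS, "first_60s")
    # reference is dominated by the constant value; OD at the dip ~ 1
    assert od[0, 50] == pytest.approx(1.0, abs=2e-2)


def test_od_whole_session_matches_direct_formula():
    I = RNG.lognormal(0, 0.3, size=(4, 500))
    od = intensity_to_od(I, FS, "whole_session")
    expected = -np.log(I / I.mean(axis=1, keepdims=True))
    assert np.allclose(od, expected)


def test_od_nonpositive_channel_named():
    I = np.ones((3, 50))
    I[1] = -1.0
    with pytest.raises(PreprocessingError, match=r"\[1\]"):
        intensity_to_od(I, FS)


# ---------------------------------------------------------------------------
# MACD filter
# ---------------------------------------------------------------------------

def _macd_oracle(x, fs, ff=0.01, window_s=2.0):
    """Direct recursion: EMA high-pass then rectangular moving average."""
    e = x[0]
    hp = np.empty_like(x)
    for t in range(len(x)):
        e = (1 - ff) * e + ff * x[t]
        hp[t] = x[t] - e
    w = int(round(window_s * fs))
    out = np.empty_like(x)
    for t in range(len(x)):
        lo = max(0, t - w + 1)
        out[t] = np.sum(hp[lo:t + 1]) / w
    return out


def test_macd_impulse_matches_direct_recursion():
    x = np.zeros(200)
    x[50] = 1.0
    y, _ = macd_bandpass(x, FS)
    assert np.allclose(y, _macd_oracle(x, FS), atol=1e-12)


def test_macd_constant_input_and_step_decay():
    # constant input: the EMA starts at the first sample, so output is 0
    y, _ = macd_bandpass(np.full(500, 5.0), FS)
    assert np.abs(y).max() < 1e-12
    # a DC step decays geometrically at (1 - forget) per sample
    x = np.zeros(3000)
    x[100:] = 5.0
    y, _ = macd_bandpass(x, FS)
    ratios = y[400:600] / y[399:599]
    assert np.allclose(ratios, 0.99, atol=1e-6)


def test_macd_sinusoid_matches_analytic_gain():
    f0 = 0.05
    t = np.arange(0, 2000, 1 / FS)
    x = np.sin(2 * np.pi * f0 * t)
    y, _ = macd_bandpass(x, FS)
    tail = y[len(y) // 2:]
    # amplitude via quadrature fit on the steady-state tail
    tt = t[len(t) // 2:]
    c = np.cos(2 * np.pi * f0 * tt)
    s = np.sin(2 * np.pi * f0 * tt)
    amp = np.hypot(2 * np.mean(tail * c), 2 * np.mean(tail * s))
    expected = macd_frequency_response([f0], FS)[0]
    assert amp == pytest.approx(expected, rel=0.01)


def test_macd_linear():
    a = RNG.standard_normal(500)
    b = RNG.standard_normal(500)
    ya, _ = macd_bandpass(a, FS)
    yb, _ = macd_bandpass(b, FS)
    yab, _ = macd_bandpass(a + b, FS)
    assert np.allclose(yab, ya + yb, atol=1e-10)


@pytest.mark.parametrize("transform", [
    lambda x: macd_bandpass(x, FS)[0],
    lambda x: intensity_to_od(np.abs(x) + 2.0, FS, "running_ema"),
    lambda x: butterworth_bandpass(x, FS, (0.02, 2.0), zero_phase=False),
    lambda x: recursive_zca(x, FS),
])
def test_causal_transforms_pass_truncation_test(transform):
    """Truncating the input at t and re-running yields identical output up
    to t, for every causal-flagged transform."""
    x = RNG.standard_normal((3, 400))
    cut = 217
    full = np.atleast_2d(transform(x))
    trunc = np.atleast_2d(transform(x[:, :cut]))
    assert np.allclose(full[:, :cut], trunc, atol=1e-10)


# ---------------------------------------------------------------------------
# Butterworth
# ---------------------------------------------------------------------------

def test_butter_dc_rejected():
    x = np.full(2000, 3.0)
    y = butterworth_bandpass(x, FS, (0.02, 2.0))
    assert np.abs(y[500:1500]).max() < 1e-3


def test_butter_passband_gain_unity():
    t = np.arange(0, 300, 1 / FS)
    x = np.sin(2 * np.pi * 1.0 * t)
    y = butterworth_bandpass(x, FS, (0.02, 2.0))
    mid = slice(len(x) // 4, 3 * len(x) // 4)
    amp = np.hypot(2 * np.mean(y[mid] * np.cos(2 * np.pi * t[mid])),
                   2 * np.mean(y[mid] * np.sin(2 * np.pi * t[mid])))
    assert amp == pytest.approx(1.0, rel=0.05)


def test_butter_band_above_nyquist_rejected():
    with pytest.raises(PreprocessingError):
        butterworth_bandpass(np.zeros(100), FS, (0.02, 6.0))


# ---------------------------------------------------------------------------
# TDDR
# ---------------------------------------------------------------------------

def test_tddr_constant_series_exact():
    x = np.full(500, 3.7)
    assert np.allclose(tddr(x, FS), x)
    assert np.allclose(tddr(np.zeros(500), FS), 0.0)


def test_tddr_clean_smooth_series_nearly_unchanged():
    t = np.arange(0, 120, 1 / FS)
    x = 0.5 * np.sin(2 * np.pi * 0.05 * t)
    y = tddr(x, FS)
    assert np.sqrt(np.mean((y - x) ** 2)) / x.std() < 0.1


def test_tddr_motion_spike_variance_reduced_10x():
    rng = np.random.default_rng(0)
    t = np.arange(0, 120, 1 / FS)
    clean = 0.5 * np.sin(2 * np.pi * 0.05 * t) + 0.02 * rng.standard_normal(len(t))
    sd = clean.std()
    x = clean + 20 * sd * np.exp(-0.5 * ((t - 60) / 1.0) ** 2)
    y = tddr(x, FS)
    seg = slice(570, 640)
    assert np.var(x[seg]) / np.var(y[seg]) >= 10.0


def test_tddr_near_idempotent_on_clean_data():
    """On artifact-free data the second application changes almost nothing
    (the first already leaves the motion band essentially untouched)."""
    t = np.arange(0, 120, 1 / FS)
    x = 0.5 * np.sin(2 * np.pi * 2.0 * t)  # energy above the trend split
    once = tddr(x, FS)
    twice = tddr(once, FS)
    d = np.sqrt(np.mean((twice - once) ** 2))
    assert d < 0.02 * x.std()
    assert d < 0.25 * np.sqrt(np.mean((once - x) ** 2))


# ---------------------------------------------------------------------------
# GVTD
# ---------------------------------------------------------------------------

def test_gvtd_constant_signal_zero():
    assert np.allclose(gvtd(np.full((4, 100), 2.0)), 0.0)


def test_gvtd_identical_epochs_none_rejected():
    ep = np.tile(RNG.standard_normal((1, 5, 50)), (10, 1, 1))
    kept, keep = gvtd_reject(ep)
    assert keep.all()
    assert kept.shape == ep.shape


def test_gvtd_planted_outlier_rejected_exactly():
    rng = np.random.default_rng(1)
    ep = 0.01 * rng.standard_normal((30, 5, 50))
    ep[17, :, 25] += 5.0  # large motion spike in epoch 17
    _, keep = gvtd_reject(ep)
    assert not keep[17]
    assert keep.sum() == 29


def test_gvtd_too_few_epochs_warns():
    with pytest.warns(UserWarning):
        _, keep = gvtd_reject(RNG.standard_normal((2, 3, 20)))
    assert keep.all()


# ---------------------------------------------------------------------------
# Tile averaging
# ---------------------------------------------------------------------------

def test_tile_average_identical_members(default_montage):
    m = default_montage
    x = np.ones((m.n_channels, 5)) * np.arange(5)
    d, t = tile_average(x, m)
    assert np.allclose(d, np.arange(5))


def test_tile_average_counts(default_montage):
    x = np.zeros((default_montage.n_channels, 2))
    _, t_all = tile_average(x, default_montage)
    assert len(t_all) == 12 * 12 * 2
    _, t_cross = tile_average(x, default_montage, include_intra_tile=False)
    assert len(t_cross) == 12 * 12 * 2 - 12 * 2


def test_tile_average_hemisphere_symmetry(default_montage):
    """Retaining 15-60 mm intra-hemisphere tile pairs gives identical
    channel counts on both hemispheres."""
    m = default_montage
    x = np.zeros((m.n_channels, 2))
    _, t = tile_average(x, m)
    hemi = {tid: tile.hemisphere for tid, tile in m.tiles.items()}
    sel = t[(t.length >= 15) & (t.length <= 60)]
    same = sel[[hemi[s] == hemi[d]
                for s, d in zip(sel.source_tile, sel.detector_tile)]]
    n_left = sum(hemi[s] == "left" for s in same.source_tile)
    assert n_left == len(same) - n_left > 0


# ---------------------------------------------------------------------------
# MBLL
# ---------------------------------------------------------------------------

def _toy_channels():
    import pandas as pd
    rows = []
    for cid, (s, d, L) in enumerate([("S1", "D1", 30.0), ("S1", "D2", 20.0)]):
        for wl in (735.0, 850.0):
            rows.append((cid, s, d, wl, L, 0.0, 0.0, 0.0, L / 4, "none", 1, 1))
    return pd.DataFrame(rows, columns=[
        "id", "source_id", "detector_id", "wavelength", "length",
        "mid_x", "mid_y", "mid_z", "depth_proxy", "roi",
        "source_tile", "detector_tile"])


def test_mbll_zero_od_zero_conc():
    ch = _toy_channels()
    conc, pairs = mbll(np.zeros((4, 10)), ch)
    assert np.allclose(conc, 0.0)
    assert len(pairs) == 2


def test_mbll_forward_inverse_round_trip():
    ch = _toy_channels()
    rng = np.random.default_rng(3)
    conc_true = rng.standard_normal((2, 2, 50))
    od = np.empty((4, 50))
    for wl in (735.0, 850.0):
        mask = (ch.wavelength == wl).to_numpy()
        od[mask] = mbll_forward(conc_true, ch.length[mask].to_numpy(), wl)
    conc, _ = mbll(od, ch)
    assert np.allclose(conc, conc_true, atol=1e-10)


def test_mbll_planted_hbo_step():
    ch = _toy_channels()
    conc_true = np.zeros((2, 2, 40))
    conc_true[:, 0, 20:] = 1.0  # +1 uM HbO step, HbR 0
    od = np.empty((4, 40))
    for wl in (735.0, 850.0):
        mask = (ch.wavelength == wl).to_numpy()
        od[mask] = mbll_forward(conc_true, ch.length[mask].to_numpy(), wl)
    conc, _ = mbll(od, ch)
    assert np.allclose(conc[:, 0, 20:], 1.0, atol=1e-10)
    assert np.allclose(conc[:, 1], 0.0, atol=1e-10)


def test_mbll_degenerate_wavelengths_rejected():
    ch = _toy_channels()
    table = {735.0: EXTINCTION_LN_UM_MM[850.0], 850.0: EXTINCTION_LN_UM_MM[850.0]}
    with pytest.raises(PreprocessingError, match="degenerate"):
        mbll(np.zeros((4, 5)), ch, extinction_table=table, det_tol=1e-6)


# ---------------------------------------------------------------------------
# Recursive ZCA
# ---------------------------------------------------------------------------

def test_zca_white_input_roughly_preserved():
    x = np.random.default_rng(5).standard_normal((4, 6000))
    y = recursive_zca(x, FS)
    tail = slice(3000, None)
    # output stays close to input and keeps ~unit variance after burn-in
    rel = np.linalg.norm(y[:, tail] - x[:, tail]) / np.linalg.norm(x[:, tail])
    assert rel < 0.35
    assert np.allclose(y[:, tail].var(axis=1), 1.0, atol=0.25)


def test_zca_decorrelates_stationary_input():
    rng = np.random.default_rng(6)
    C = 6
    A = np.eye(C) + 0.7 * np.ones((C, C)) / C + 0.1 * rng.standard_normal((C, C))
    x = A @ rng.standard_normal((C, 4000))
    y = recursive_zca(x, FS)
    tail = y[:, 1000:]
    rho = np.corrcoef(tail)
    off = rho[~np.eye(C, dtype=bool)]
    assert np.abs(off).max() < 0.1


def test_zca_duplicated_channels_stay_finite():
    rng = np.random.default_rng(7)
    base = rng.standard_normal((1, 900))
    x = np.vstack([base, base, rng.standard_normal((1, 900))])
    y = recursive_zca(x, FS, shrinkage=1e-6)
    assert np.all(np.isfinite(y))


def test_zca_short_input_identity_with_warning():
    x = RNG.standard_normal((3, 20))
    with pytest.warns(UserWarning):
        y = recursive_zca(x, FS, block_s=5.0)
    assert np.allclose(y, x)


# ---------------------------------------------------------------------------
# Length filter & epoching
# ---------------------------------------------------------------------------

def test_length_filter_identity_and_oracle(default_montage):
    m = default_montage
    x = RNG.standard_normal((m.n_channels, 3))
    full, _ = channel_length_filter(x, m.channels, 0.0, np.inf)
    assert full.shape == x.shape
    sub, table = channel_length_filter(x, m.channels, 0.0, 50.0)
    brute = [np.linalg.norm(
        np.array(m.optodes[r.source_id].position)
        - np.array(m.optodes[r.detector_id].position)) <= 50.0
        for r in m.channels.itertuples()]
    assert len(table) == sum(brute)
    with pytest.raises(PreprocessingError):
        channel_length_filter(x, m.channels, 60.0, 50.0)


def test_epoch_baseline_zero_mean():
    x = RNG.standard_normal((2, 500)) + 5.0
    ep = epoch_extract(x, FS, [20.0, 30.0], -5.0, 17.0)
    ep = baseline_subtract(ep, FS, -5.0, -2.0, 0.0)
    i0, i1 = int(3 * FS), int(5 * FS)
    assert np.allclose(ep[..., i0:i1].mean(axis=-1), 0.0, atol=1e-12)
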