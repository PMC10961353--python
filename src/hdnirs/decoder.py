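"""Subject-independent high-density decoder.

Single-trial features are spatio-temporal matrices X_i in R^{2*C_L x T}
(HbO rows then HbR rows, C_L source-detector pairs of length <= 50 mm,
T = 43 samples of the 0-8.5 s epoch at 5 Hz) obtained by a strictly causal
chain: length filter -> log-OD against a running EMA baseline (forget
0.01) -> recursive ZCA (5-s blocks, shrinkage 1e-6) -> MBLL (DPF 6) ->
epoch -> polyphase resample -> robust z-scoring with training-set medians
and MADs.

The decoder minimizes the jointly convex objective

    (1/N) sum_i log(1 + exp(-y_i (<W, X_i>_F + b)))
    + alpha * ||W||_*  + beta * ||Gamma_U vec W||^2 + gamma * ||Gamma_V vec W||^2

with y_i in {-1, +1}, nuclear norm ||.||_*, a spatial pairwise-difference
Tikhonov operator Gamma_U (Gaussian weights over channel pairs within an
anisotropic radius r = 15 mm, depth scaled by tau = 3/2) and a first-order
temporal difference operator Gamma_V.  It is solved with a monotone
accelerated proximal gradient method (FISTA with backtracking); the
nuclear-norm prox is singular-value soft-thresholding.

vec(W) is row-major (C order): index = row * T + t with rows ordered
channel-major inside chromophore blocks; Gamma_U = D_U kron I_T and
Gamma_V = I_rows kron D_V are built to match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import resample_poly

from .io import SessionRecording
from .montage import Montage
from .preprocessing import (
    channel_length_filter,
    epoch_extract,
    intensity_to_od,
    mbll,
    recursive_zca,
)

MAX_LENGTH_MM = 50.0
EPOCH_S = 8.5
TARGET_FS = 5.0
CHROMOPHORES = ("HbO", "HbR")


class DecoderError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass
class RobustScaler:
    """Per-feature median/MAD from the training set; MAD of constant
    features is floored to unit scale and flagged."""

    median_: np.ndarray
    scale_: np.ndarray
    flagged_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "RobustScaler":
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med[None]), axis=0)
        floor = 1e-12 * (np.abs(med) + 1.0)
        flagged = mad <= floor
        scale = np.where(flagged, 1.0, mad)
        return cls(med, scale, flagged)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.median_[None]) / self.scale_[None]


@dataclass
class TrialFeatures:
    """X: [n_trials x 2*C_L x T]; y in {-1, +1}; pairs: table of the C_L
    retained source-detector pairs (row order of the HbO block)."""

    X: np.ndarray
    y: np.ndarray
    pairs: pd.DataFrame
    fs: float = TARGET_FS
    trial_onsets: np.ndarray | None = None


def extract_trial_features(
    rec: SessionRecording,
    montage: Montage,
    scaler: RobustScaler | None = None,
    max_len_mm: float = MAX_LENGTH_MM,
    ema_forget: float = 0.01,
    zca: bool = True,
    zca_block_s: float = 5.0,
    zca_shrinkage: float = 1e-6,
    dpf: float = 6.0,
    scale: bool = True,
) -> tuple[TrialFeatures, RobustScaler | None]:
    """Causal feature chain for one session.

    A scaler fitted elsewhere (the training set) may be passed in; when
    ``scaler`` is None a new one is fitted on this session's trials.  The
    0-8.5 s epoch is taken as 86 samples at 10 Hz and polyphase-resampled
    by 1/2, giving T = 43 = floor(8.5 * 5) + 1 samples (pinned convention).
    """
    fs = rec.fs
    x, table = channel_length_filter(rec.intensity, montage.channels,
                                     0.0, max_len_mm)
    od = intensity_to_od(x, fs, "running_ema", ema_forget=ema_forget)
    if zca:
        od = recursive_zca(od, fs, block_s=zca_block_s, shrinkage=zca_shrinkage)
    conc, pairs = mbll(od, table, dpf=dpf)

    trials = rec.trial_markers(covert_only=True)
    onsets = [t for t, _ in trials]
    labels = np.array([+1 if lab == "right" else -1 for _, lab in trials])
    n_in = int(np.floor(EPOCH_S * fs)) + 1  # 86 samples at 10 Hz
    ep = epoch_extract(conc, fs, onsets, 0.0, n_in / fs)  # [N x C_L x 2 x 86]
    down = int(round(fs / TARGET_FS))
    ep = resample_poly(ep, 1, down, axis=-1)              # [N x C_L x 2 x 43]
    # rows: chromophore blocks (HbO block then HbR block), channel-major
    N, CL, _, T = ep.shape
    X = np.concatenate([ep[:, :, 0, :], ep[:, :, 1, :]], axis=1)  # [N x 2CL x T]
    if scale:
        if scaler is None:
            scaler = RobustScaler.fit(X)
        X = scaler.transform(X)
    feats = TrialFeatures(X=X, y=labels[: len(X)], pairs=pairs,
                          trial_onsets=np.asarray(onsets[: len(X)]))
    return feats, scaler


# ---------------------------------------------------------------------------
# Tikhonov operators
# ---------------------------------------------------------------------------

@dataclass
class TikhonovOperators:
    """D_U: [n_pairs x n_rows] spatial difference operator (acts on the row
    dimension of W); D_V: [T-1 x T] temporal first differences.  The full
    operators on vec(W) are ``Gamma_U = D_U kron I_T`` and
    ``Gamma_V = I_rows kron D_V``."""

    D_U: sp.csr_matrix
    D_V: sp.csr_matrix
    r_mm: float
    tau: float

    def gamma_u(self) -> sp.csr_matrix:
        T = self.D_V.shape[1]
        return sp.kron(self.D_U, sp.identity(T), format="csr")

    def gamma_v(self) -> sp.csr_matrix:
        n_rows = self.D_U.shape[1]
        return sp.kron(sp.identity(n_rows), self.D_V, format="csr")


def build_tikhonov_operators(
    pairs: pd.DataFrame,
    T: int,
    r_mm: float = 15.0,
    tau: float = 1.5,
    n_chrom: int = 2,
) -> TikhonovOperators:
    """Spatial and temporal smoothness operators for the decoder weights.

    For every channel pair (same chromophore block) whose anisotropic
    distance d = sqrt(d_lateral^2 + (tau * d_depth)^2) is within ``r_mm``,
    D_U gets one row  w * (e_i - e_j)  with Gaussian weight
    w = exp(-d^2 / (2 (r/2)^2)); d_lateral is the midpoint distance and
    d_depth the difference of the length/4 depth proxies.
    """
    C = len(pairs)
    mids = pairs[["mid_x", "mid_y", "mid_z"]].to_numpy()
    depth = pairs["depth_proxy"].to_numpy()
    rows, cols, vals = [], [], []
    k = 0
    for i in range(C):
        for j in range(i + 1, C):
            d_lat = np.linalg.norm(mids[i] - mids[j])
            d = np.hypot(d_lat, tau * (depth[i] - depth[j]))
            if d > r_mm:
                continue
            w = np.exp(-d**2 / (2.0 * (r_mm / 2.0) ** 2))
            for c in range(n_chrom):
                rows += [k, k]
                cols += [c * C + i, c * C + j]
                vals += [w, -w]
                k += 1
    if k == 0:
        warnings.warn("no channel pairs within the smoothing radius; "
                      "spatial operator is empty")
    D_U = sp.csr_matrix((vals, (rows, cols)), shape=(k, n_chrom * C))
    D_V = sp.diags([-np.ones(T - 1), np.ones(T - 1)], [0, 1],
                   shape=(T - 1, T)).tocsr()
    return TikhonovOperators(D_U, D_V, r_mm, tau)


# ---------------------------------------------------------------------------
# Proximal operator and solver
# ---------------------------------------------------------------------------

def svt_prox(M: np.ndarray, threshold: float) -> np.ndarray:
    """Prox of threshold * nuclear norm: singular-value soft-thresholding."""
    U, s, Vt = np.linalg.svd(np.asarray(M, float), full_matrices=False)
    return (U * np.maximum(s - threshold, 0.0)) @ Vt


def nuclear_norm(M: np.ndarray) -> float:
    return float(np.linalg.svd(M, compute_uv=False).sum())


@dataclass
class DecoderModel:
    W: np.ndarray
    b: float
    alpha: float
    beta: float
    gamma: float
    operators: TikhonovOperators
    scaler: RobustScaler | None = None
    trace: list = field(default_factory=list)
    pairs: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _objective_parts(W, b, X, y, alpha, beta, gamma, DU, DVt):
    z = np.tensordot(X, W, axes=([1, 2], [0, 1])) + b
    m = -y * z
    loss = float(np.mean(np.logaddexp(0.0, m)))
    pen_u = float(beta * np.sum((DU @ W) ** 2)) if DU.shape[0] else 0.0
    pen_v = float(gamma * np.sum((W @ DVt) ** 2))
    return loss + pen_u + pen_v, z


def _smooth_grad(W, b, X, y, beta, gamma, DUtDU, DVtDV):
    z = np.tensordot(X, W, axes=([1, 2], [0, 1])) + b
    m = -y * z
    # sigma(-y z) = 1/(1+exp(y z)); computed stably
    s = np.exp(m - np.logaddexp(0.0, m))
    coef = -(y * s) / len(y)
    gW = np.tensordot(coef, X, axes=(0, 0))
    if DUtDU is not None:
        gW = gW + 2.0 * beta * (DUtDU @ W)
    gW = gW + 2.0 * gamma * (W @ DVtDV)
    gb = float(coef.sum())
    f = float(np.mean(np.logaddexp(0.0, m)))
    if DUtDU is not None:
        f += float(beta * np.sum(W * (DUtDU @ W)))
    f += float(gamma * np.sum(W * (W @ DVtDV)))
    return f, gW, gb


def fit(
    features: np.ndarray,
    labels: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
    operators: TikhonovOperators | None = None,
    pairs: pd.DataFrame | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    scaler: RobustScaler | None = None,
) -> DecoderModel:
    """Fit the decoder by monotone FISTA with backtracking line search.

    ``features``: [N x n_rows x T]; ``labels``: +-1 (or {left,right}
    strings, mapped to -1/+1).  The bias is unpenalized.  Raises on a
    diverging objective; the per-iteration objective is kept in
    ``model.trace`` and is non-increasing.
    """
    X = np.asarray(features, float)
    y = np.asarray([
        (+1 if lab == "right" else -1) if isinstance(lab, str) else lab
        for lab in labels], float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise DecoderError("labels must be in {-1,+1} (or 'left'/'right')")
    if len(np.unique(y)) < 2:
        raise DecoderError("both classes must be present")
    if min(alpha, beta, gamma) < 0:
        raise DecoderError("regularization strengths must be >= 0")
    n_rows, T = X.shape[1], X.shape[2]
    if operators is None:
        if pairs is not None:
            operators = build_tikhonov_operators(pairs, T)
        else:
            operators = TikhonovOperators(
                sp.csr_matrix((0, n_rows)),
                sp.diags([-np.ones(T - 1), np.ones(T - 1)], [0, 1],
                         shape=(T - 1, T)).tocsr(),
                15.0, 1.5)
    DU = operators.D_U
    DUtDU = (DU.T @ DU).toarray() if DU.shape[0] else None
    DVt = operators.D_V.T.toarray()
    DVtDV = (operators.D_V.T @ operators.D_V).toarray()

    W = np.zeros((n_rows, T))
    b = 0.0
    Wz, bz = W.copy(), b  # extrapolation point
    tk = 1.0
    L = 1.0
    obj, _ = _objective_parts(W, b, X, y, alpha, beta, gamma, DU, DVt)
    obj += alpha * nuclear_norm(W)
    trace = [obj]
    stall = 0
    for _ in range(max_iter):
        fz, gW, gb = _smooth_grad(Wz, bz, X, y, beta, gamma, DUtDU, DVtDV)
        while True:
            W_new = svt_prox(Wz - gW / L, alpha / L)
            b_new = bz - gb / L
            f_new = _objective_parts(W_new, b_new, X, y, alpha, beta, gamma,
                                     DU, DVt)[0]
            dW, db = W_new - Wz, b_new - bz
            quad = fz + np.sum(gW * dW) + gb * db + \
                0.5 * L * (np.sum(dW**2) + db**2)
            if f_new <= quad + 1e-12 * max(1.0, abs(quad)):
                break
            L *= 2.0
            if L > 1e18:
                raise DecoderError("backtracking diverged (objective trace: "
                                   f"{trace[-5:]})")
        obj_new = f_new + alpha * nuclear_norm(W_new)
        # monotone FISTA: keep the better of the prox point and the incumbent
        if obj_new <= trace[-1]:
            W_next, b_next, obj_next = W_new, b_new, obj_new
        else:
            W_next, b_next, obj_next = W, b, trace[-1]
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk**2))
        Wz = W_next + (tk / t_next) * (W_new - W_next) + \
            ((tk - 1.0) / t_next) * (W_next - W)
        bz = b_next + (tk / t_next) * (b_new - b_next) + \
            ((tk - 1.0) / t_next) * (b_next - b)
        W, b = W_next, b_next
        tk = t_next
        trace.append(obj_next)
        stall = stall + 1 if abs(trace[-2] - trace[-1]) <= \
            tol * max(1.0, abs(trace[-2])) else 0
        if stall >= 3:
            break
        L = max(L / 2.0, 1e-8)
    return DecoderModel(W=W, b=float(b), alpha=alpha, beta=beta, gamma=gamma,
                        operators=operators, scaler=scaler, trace=trace,
                        pairs=pairs,
                        meta={"T": T, "n_rows": n_rows,
                              "epoch_s": EPOCH_S, "target_fs": TARGET_FS})


def objective(model: DecoderModel, X, y) -> float:
    f, _ = _objective_parts(model.W, model.b, np.asarray(X, float),
                            np.asarray(y, float), model.alpha, model.beta,
                            model.gamma, model.operators.D_U,
                            model.operators.D_V.T.toarray())
    return f + model.alpha * nuclear_norm(model.W)


def predict(model: DecoderModel, features: np.ndarray) -> np.ndarray:
    """Probability of class +1 ('right') per trial."""
    X = np.asarray(features, float)
    if X.shape[1:] != model.W.shape:
        raise DecoderError(
            f"feature shape {X.shape[1:]} does not match weights {model.W.shape}")
    z = np.tensordot(X, model.W, axes=([1, 2], [0, 1])) + model.b
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Weight-map export
# ---------------------------------------------------------------------------

DEFAULT_WINDOWS = ((0.0, 1.2), (1.2, 2.1), (2.1, 4.0), (4.0, 6.5), (6.5, 8.5))


def export_weight_maps(
    model: DecoderModel,
    pairs: pd.DataFrame | None = None,
    windows=DEFAULT_WINDOWS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hemispheric asymmetry curve and per-window spatial weight tables.

    Returns (asymmetry, spatial): asymmetry has one row per timepoint and
    chromophore with the left-minus-right mean signed weight; spatial has
    one row per channel, chromophore and window with the window-mean weight
    plus midpoint/depth columns for plotting.  Trial times are reported
    uncorrected for the ~1 s causal filter delay.
    """
    pairs = pairs if pairs is not None else model.pairs
    if pairs is None:
        raise DecoderError("a pair table is required to export weight maps")
    C = len(pairs)
    T = model.W.shape[1]
    times = np.arange(T) / TARGET_FS
    left = (pairs["mid_x"] < 0).to_numpy()
    right = ~left
    rows = []
    for ci, chrom in enumerate(CHROMOPHORES):
        block = model.W[ci * C:(ci + 1) * C]
        asym = block[left].mean(axis=0) - block[right].mean(axis=0)
        for t, a in zip(times, asym):
            rows.append((chrom, t, a))
    asymmetry = pd.DataFrame(rows, columns=["chromophore", "time_s",
                                            "left_minus_right"])
    srows = []
    for wi, (t0, t1) in enumerate(windows):
        m = (times >= t0) & (times < t1) if t1 < times[-1] else \
            (times >= t0) & (times <= t1)
        for ci, chrom in enumerate(CHROMOPHORES):
            block = model.W[ci * C:(ci + 1) * C]
            wmean = block[:, m].mean(axis=1)
            for k in range(C):
                p = pairs.iloc[k]
                srows.append((wi, t0, t1, chrom, p["source_id"],
                              p["detector_id"], p["mid_x"], p["mid_y"],
                              p["depth_proxy"], p["length"], wmean[k]))
    spatial = pd.DataFrame(
        srows, columns=["window", "t0_s", "t1_s", "chromophore", "source",
                        "detector", "mid_x", "mid_y", "depth_mm",
                        "length_mm", "weight"])
    return asymmetry, spatial
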