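"""Decoder: feature conventions, Tikhonov operators, the nuclear-norm prox,
the FISTA solver (against an independent ADMM oracle), prediction, and
weight-map export."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from hdnirs import decoder as dec
from hdnirs.synth import CouplingSpec, HemodynamicSpec, generate_schedule, \
    simulate_session


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def test_feature_shape_convention(make_session, reduced_montage):
    rec = make_session(seed=1)
    feats, scaler = dec.extract_trial_features(rec, reduced_montage)
    n_pairs_le50 = (reduced_montage.channels.length <= 50).sum() // 2
    assert feats.X.shape[1] == 2 * n_pairs_le50
    assert feats.X.shape[2] == 43  # floor(8.5 * 5) + 1 at 5 Hz
    assert set(np.unique(feats.y)) <= {-1, 1}
    assert np.isfinite(feats.X).all()


def test_constant_intensity_features_zero(make_session, reduced_montage):
    """All-constant intensity exercises the MAD-floor path: features come
    out (near) zero rather than NaN."""
    from hdnirs.synth import NoiseSpec
    quiet = NoiseSpec(cardiac_um=0, resp_um=0, mayer_um=0,
                      superficial_drift_um=0, od_drift_sigma=0,
                      white_sigma_rel=0, motion_spike_per_min=0,
                      motion_shift_per_min=0)
    rec = make_session(seed=2, noise=quiet,
                       hemo=HemodynamicSpec(amp_hbo_contra=0, amp_hbo_ipsi=0,
                                            superficial_systemic=0),
                       coupling=CouplingSpec(fixed_value=1.0))
    feats, scaler = dec.extract_trial_features(rec, reduced_montage)
    assert scaler.flagged_.all()
    assert np.allclose(feats.X, 0.0, atol=1e-9)


def test_scaler_train_only_semantics(make_session, reduced_montage):
    """A scaler fitted on one session is applied, not re-fit, on another."""
    rec_a = make_session(seed=3)
    rec_b = make_session(seed=4)
    _, scaler = dec.extract_trial_features(rec_a, reduced_montage)
    feats_b, scaler_b = dec.extract_trial_features(rec_b, reduced_montage,
                                                   scaler=scaler)
    assert scaler_b is scaler
    raw_b, _ = dec.extract_trial_features(rec_b, reduced_montage, scale=False)
    assert np.allclose(feats_b.X, scaler.transform(raw_b.X))


# ---------------------------------------------------------------------------
# Tikhonov operators
# ---------------------------------------------------------------------------

def _toy_pairs(n=10, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "mid_x": rng.uniform(-30, 30, n),
        "mid_y": rng.uniform(-20, 20, n),
        "mid_z": np.zeros(n),
        "depth_proxy": rng.uniform(2, 12, n),
    })


def test_gamma_v_kills_temporal_constants():
    ops = dec.build_tikhonov_operators(_toy_pairs(), T=7, r_mm=30)
    W = np.tile(np.random.default_rng(1).standard_normal((20, 1)), (1, 7))
    assert np.allclose(ops.gamma_v() @ W.ravel(), 0.0)


def test_gamma_u_kills_spatial_constants():
    ops = dec.build_tikhonov_operators(_toy_pairs(), T=7, r_mm=30)
    W = np.ones((20, 7)) * np.arange(7)  # constant across channels
    assert np.allclose(ops.gamma_u() @ W.ravel(), 0.0, atol=1e-12)


def test_gamma_u_matches_bruteforce_pairwise_sum():
    pairs = _toy_pairs(10)
    T, tau, r = 5, 1.5, 25.0
    ops = dec.build_tikhonov_operators(pairs, T, r_mm=r, tau=tau)
    rng = np.random.default_rng(2)
    W = rng.standard_normal((20, T))
    via_op = np.sum((ops.gamma_u() @ W.ravel()) ** 2)
    mids = pairs[["mid_x", "mid_y", "mid_z"]].to_numpy()
    depth = pairs["depth_proxy"].to_numpy()
    brute = 0.0
    for c in range(2):
        for i in range(10):
            for j in range(i + 1, 10):
                d_lat = np.linalg.norm(mids[i] - mids[j])
                d = np.hypot(d_lat, tau * (depth[i] - depth[j]))
                if d > r:
                    continue
                w = np.exp(-d**2 / (2 * (r / 2) ** 2))
                brute += np.sum((w * (W[c * 10 + i] - W[c * 10 + j])) ** 2)
    assert via_op == pytest.approx(brute, rel=1e-12)
    # and the matrix form used internally agrees with the vec form
    assert np.sum((ops.D_U @ W) ** 2) == pytest.approx(via_op, rel=1e-12)


def test_gamma_u_empty_radius_warns():
    with pytest.warns(UserWarning):
        ops = dec.build_tikhonov_operators(_toy_pairs(), T=4, r_mm=1e-6)
    assert ops.D_U.shape[0] == 0


# ---------------------------------------------------------------------------
# SVT prox
# ---------------------------------------------------------------------------

def test_svt_analytic_diag():
    out = dec.svt_prox(np.diag([3.0, 1.0]), 1.0)
    assert np.allclose(out, np.diag([2.0, 0.0]), atol=1e-12)


def test_svt_zero_threshold_identity():
    M = np.random.default_rng(3).standard_normal((4, 6))
    assert np.allclose(dec.svt_prox(M, 0.0), M, atol=1e-12)


def test_svt_satisfies_prox_optimality():
    """X = svt(M, t) solves min 1/2||X-M||^2 + t||X||_*: checked via the
    nuclear-norm subgradient optimality conditions."""
    rng = np.random.default_rng(4)
    M = rng.standard_normal((5, 7))
    t = 0.8
    X = dec.svt_prox(M, t)
    G = (M - X) / t          # must lie in the subdifferential of ||X||_*
    assert np.linalg.norm(G, 2) <= 1.0 + 1e-9
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for k in np.where(s > 1e-12)[0]:
        assert U[:, k] @ G @ Vt[k] == pytest.approx(1.0, abs=1e-9)
    # objective can't be improved by random perturbations
    def f(A):
        return 0.5 * np.sum((A - M) ** 2) + t * dec.nuclear_norm(A)
    for _ in range(20):
        assert f(X) <= f(X + 0.01 * rng.standard_normal(X.shape)) + 1e-12


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def test_unregularized_separable_toy():
    X = np.zeros((2, 1, 1))
    X[0, 0, 0], X[1, 0, 0] = -1.0, 1.0
    model = dec.fit(X, np.array([-1.0, 1.0]), 0.0, 0.0, 0.0, max_iter=3000,
                    tol=1e-12)
    p = dec.predict(model, X)
    assert ((p > 0.5) == np.array([False, True])).all()
    assert model.trace[-1] < 0.05  # objective driven toward 0


def test_huge_alpha_zeroes_weights():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((30, 4, 3))
    y = np.where(rng.standard_normal(30) > -0.4, 1.0, -1.0)  # majority +1
    model = dec.fit(X, y, 1e4, 0.0, 0.0, max_iter=300)
    assert np.allclose(model.W, 0.0, atol=1e-8)
    p = dec.predict(model, X)
    assert np.all((p > 0.5) == (np.mean(y > 0) > 0.5))


def _admm_oracle(X, y, alpha, beta, gamma, ops, iters=250, rho=1.0):
    """Independent solver: ADMM splitting W=Z with an L-BFGS smooth step and
    the closed-form nuclear prox on Z."""
    N, C, T = X.shape
    DUtDU = (ops.D_U.T @ ops.D_U).toarray()
    DVt = ops.D_V.T.toarray()
    DVtDV = (ops.D_V.T @ ops.D_V).toarray()

    def smooth(wb, Zu):
        W = wb[:-1].reshape(C, T)
        b = wb[-1]
        m = -y * (np.tensordot(X, W, axes=([1, 2], [0, 1])) + b)
        f = (np.mean(np.logaddexp(0, m)) + beta * np.sum(W * (DUtDU @ W))
             + gamma * np.sum((W @ DVt) ** 2) + 0.5 * rho * np.sum((W - Zu) ** 2))
        s = np.exp(m - np.logaddexp(0, m))
        coef = -(y * s) / N
        gW = (np.tensordot(coef, X, axes=(0, 0)) + 2 * beta * (DUtDU @ W)
              + 2 * gamma * (W @ DVtDV) + rho * (W - Zu))
        return f, np.concatenate([gW.ravel(), [coef.sum()]])

    W, b = np.zeros((C, T)), 0.0
    Z, U = np.zeros((C, T)), np.zeros((C, T))
    for _ in range(iters):
        res = minimize(smooth, np.concatenate([W.ravel(), [b]]), args=(Z - U,),
                       jac=True, method="L-BFGS-B",
                       options=dict(maxiter=200, ftol=1e-14, gtol=1e-10))
        W, b = res.x[:-1].reshape(C, T), res.x[-1]
        Z = dec.svt_prox(W + U, alpha / rho)
        U = U + W - Z
    m = -y * (np.tensordot(X, Z, axes=([1, 2], [0, 1])) + b)
    return (np.mean(np.logaddexp(0, m)) + beta * np.sum((ops.D_U @ Z) ** 2)
            + gamma * np.sum((Z @ DVt) ** 2) + alpha * dec.nuclear_norm(Z))


def test_solver_matches_admm_oracle_small_instance():
    """Final objective on a 6-channel x 5-timepoint x 40-trial problem
    matches an independent ADMM solver within 1e-4 relative."""
    rng = np.random.default_rng(0)
    N, C, T = 40, 6, 5
    X = rng.standard_normal((N, C, T))
    w_true = rng.standard_normal((C, T))
    z = np.tensordot(X, w_true, axes=([1, 2], [0, 1]))
    y = np.where(z + 0.5 * rng.standard_normal(N) > 0, 1.0, -1.0)
    pairs = _toy_pairs(C // 2, seed=6)
    ops = dec.build_tikhonov_operators(pairs, T, r_mm=30.0)
    alpha, beta, gamma = 0.1, 0.05, 0.05
    model = dec.fit(X, y, alpha, beta, gamma, operators=ops,
                    max_iter=3000, tol=1e-12)
    oracle = _admm_oracle(X, y, alpha, beta, gamma, ops)
    assert model.trace[-1] == pytest.approx(oracle, rel=1e-4)


def test_objective_trace_monotone():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((50, 8, 6))
    y = np.where(rng.standard_normal(50) > 0, 1.0, -1.0)
    model = dec.fit(X, y, 0.05, 0.0, 0.1, max_iter=300)
    tr = np.array(model.trace)
    assert np.all(np.diff(tr) <= 1e-10)


def test_fit_input_validation():
    X = np.zeros((4, 2, 2))
    with pytest.raises(dec.DecoderError):
        dec.fit(X, np.ones(4), 0.1, 0.0, 0.0)  # single class
    with pytest.raises(dec.DecoderError):
        dec.fit(X, np.array([1, -1, 1, -1]), -0.1, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def test_predict_contracts():
    ops = dec.build_tikhonov_operators(_toy_pairs(2), T=3, r_mm=50)
    model = dec.DecoderModel(W=np.zeros((4, 3)), b=0.0, alpha=0, beta=0,
                             gamma=0, operators=ops)
    X = np.random.default_rng(8).standard_normal((5, 4, 3))
    assert np.allclose(dec.predict(model, X), 0.5)
    model2 = dec.DecoderModel(W=np.ones((4, 3)), b=0.0, alpha=0, beta=0,
                              gamma=0, operators=ops)
    p = dec.predict(model2, X)
    assert np.allclose(dec.predict(model2, -X), 1.0 - p)
    with pytest.raises(dec.DecoderError):
        dec.predict(model2, np.zeros((2, 3, 3)))


# ---------------------------------------------------------------------------
# Weight maps
# ---------------------------------------------------------------------------

def test_weight_maps_symmetric_weights_zero_asymmetry():
    pairs = pd.DataFrame({
        "mid_x": [-20.0, 20.0, -10.0, 10.0],
        "mid_y": [0.0, 0.0, 5.0, 5.0],
        "mid_z": 0.0,
        "depth_proxy": [5.0, 5.0, 7.0, 7.0],
        "source_id": ["a", "b", "c", "d"],
        "detector_id": ["e", "f", "g", "h"],
        "length": 30.0,
    })
    ops = dec.build_tikhonov_operators(pairs, T=43, r_mm=15)
    rng = np.random.default_rng(9)
    half = rng.standard_normal((2, 43))
    W = np.empty((8, 43))
    for c in range(2):
        W[c * 4 + 0] = W[c * 4 + 1] = half[0]
        W[c * 4 + 2] = W[c * 4 + 3] = half[1]
    model = dec.DecoderModel(W=W, b=0.0, alpha=0, beta=0, gamma=0,
                             operators=ops, pairs=pairs)
    asym, spatial = dec.export_weight_maps(model)
    assert np.allclose(asym.left_minus_right, 0.0, atol=1e-12)
    # windows tile [0, 8.5] s without overlap and cover every timepoint
    covered = np.zeros(43, dtype=int)
    times = np.arange(43) / 5.0
    for t0, t1 in dec.DEFAULT_WINDOWS:
        covered += ((times >= t0) & (times < t1)) | \
            ((t1 == 8.5) & (times == 8.5))
    assert (covered == 1).all()
    assert len(spatial) == len(dec.DEFAULT_WINDOWS) * 2 * len(pairs)
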