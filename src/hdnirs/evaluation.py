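"""Cross-validation harnesses, significance testing against chance, and the
demographic/hair factor-analysis battery.

All harnesses carry a leakage audit: every array a fit function sees is
fingerprinted per trial, and ``LeakageAudit.verify`` asserts that no
held-out trial was ever part of a fit input.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import decoder as dec
from .io import SessionRecording
from .montage import Montage


# ---------------------------------------------------------------------------
# Leakage audit
# ---------------------------------------------------------------------------

def _trial_fingerprints(X: np.ndarray) -> set:
    return {hashlib.sha1(np.ascontiguousarray(xi).tobytes()).hexdigest()
            for xi in np.asarray(X)}


@dataclass
class LeakageAudit:
    """Fingerprints of fit inputs per fold, checked against test trials."""

    folds: list = field(default_factory=list)

    def record(self, fold_id, fit_X: np.ndarray, test_X: np.ndarray):
        self.folds.append(
            (fold_id, _trial_fingerprints(fit_X), _trial_fingerprints(test_X)))

    def verify(self) -> bool:
        for fold_id, fit_fp, test_fp in self.folds:
            if fit_fp & test_fp:
                raise AssertionError(
                    f"leakage: fold {fold_id} fitted on held-out trials")
        return True


# ---------------------------------------------------------------------------
# CV results
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    per_session: pd.DataFrame  # columns: subject_id, session_number, accuracy
    grouping: str = "All"
    audit: LeakageAudit | None = None

    @property
    def accuracies(self) -> np.ndarray:
        return self.per_session["accuracy"].to_numpy()

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        a = self.accuracies
        return float(a.std(ddof=1)) if len(a) > 1 else 0.0

    def t_vs_chance(self, chance: float = 0.5):
        """One-sided 1-sample t of per-session accuracies against chance."""
        res = stats.ttest_1samp(self.accuracies, chance, alternative="greater")
        return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# LOSO over the spatio-temporal decoder
# ---------------------------------------------------------------------------

DEFAULT_GRID = {"alpha": (0.025, 0.05, 0.075), "beta": (50.0, 62.5, 75.0)}
DEFAULT_HYPERPARAMS = {"alpha": 0.05, "beta": 62.5, "gamma": 5.0}


def session_feature_sets(recordings, montage: Montage, **kwargs):
    """Per-session *unscaled* causal features for the high-density decoder.

    Everything before robust scaling is per-session and fit-free, so it can
    be computed once; the scaler is re-fit inside each training fold.
    """
    sets = []
    for rec in recordings:
        feats, _ = dec.extract_trial_features(rec, montage, scale=False, **kwargs)
        sets.append({"subject_id": rec.subject_id,
                     "session_number": rec.session_number,
                     "X": feats.X, "y": feats.y, "pairs": feats.pairs})
    return sets


def _fit_decoder_on(sets, alpha, beta, gamma, operators, max_iter, tol):
    X = np.concatenate([s["X"] for s in sets])
    y = np.concatenate([s["y"] for s in sets])
    scaler = dec.RobustScaler.fit(X)
    model = dec.fit(scaler.transform(X), y, alpha, beta, gamma,
                    operators=operators, pairs=sets[0]["pairs"],
                    max_iter=max_iter, tol=tol, scaler=scaler)
    return model


def _score(model, s):
    p = dec.predict(model, model.scaler.transform(s["X"]))
    return float(np.mean((p > 0.5) == (s["y"] > 0)))


def loso_cv(
    feature_sets,
    hyperparams: dict | None = None,
    grid: dict | None = None,
    gamma: float = 5.0,
    grouping: str = "All",
    max_iter: int = 200,
    tol: float = 1e-5,
    operators: dec.TikhonovOperators | None = None,
) -> CVResult:
    """Leave-one-subject-out CV of the high-density decoder.

    For each session, a model is trained on all sessions of all *other*
    subjects and tested on that session.  With ``grid`` set, (alpha, beta)
    are selected per outer fold by a nested leave-one-subject-out search on
    the training subjects (gamma fixed); otherwise ``hyperparams`` (default
    alpha 0.05, beta 62.5, gamma 5) are used directly.
    """
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    subjects = sorted({s["subject_id"] for s in feature_sets})
    if len(subjects) < 3:
        raise ValueError("LOSO needs >= 3 subjects")
    if operators is None:
        T = feature_sets[0]["X"].shape[2]
        operators = dec.build_tikhonov_operators(feature_sets[0]["pairs"], T)
    audit = LeakageAudit()
    rows = []
    for subj in subjects:
        train = [s for s in feature_sets if s["subject_id"] != subj]
        tests = [s for s in feature_sets if s["subject_id"] == subj]
        if not tests:
            continue
        if grid is not None:
            a, b = _nested_select(train, grid, gamma, operators, max_iter, tol)
        else:
            a, b = hp["alpha"], hp["beta"]
        model = _fit_decoder_on(train, a, b, hp.get("gamma", gamma),
                                operators, max_iter, tol)
        for s in tests:
            audit.record(f"{subj}/{s['session_number']}",
                         np.concatenate([t["X"] for t in train]), s["X"])
            rows.append((s["subject_id"], s["session_number"],
                         _score(model, s), a, b))
    result = CVResult(pd.DataFrame(
        rows, columns=["subject_id", "session_number", "accuracy",
                       "alpha", "beta"]), grouping=grouping, audit=audit)
    audit.verify()
    return result


def _nested_select(train, grid, gamma, operators, max_iter, tol):
    inner_subjects = sorted({s["subject_id"] for s in train})
    best, best_acc = None, -1.0
    for a in grid["alpha"]:
        for b in grid["beta"]:
            accs = []
            for subj in inner_subjects:
                itrain = [s for s in train if s["subject_id"] != subj]
                itests = [s for s in train if s["subject_id"] == subj]
                model = _fit_decoder_on(itrain, a, b, gamma, operators,
                                        max_iter, tol)
                accs += [_score(model, s) for s in itests]
            acc = float(np.mean(accs))
            if acc > best_acc:
                best, best_acc = (a, b), acc
    return best


# ---------------------------------------------------------------------------
# Generic harnesses (used by the reference variants)
# ---------------------------------------------------------------------------

def loso_cv_generic(session_tables, fit_fn, predict_fn,
                    grouping: str = "All") -> CVResult:
    """LOSO over arbitrary per-session trial tables.

    ``session_tables``: list of dicts with subject_id, session_number,
    X [n_trials x n_feat], y; ``fit_fn(X, y) -> model``;
    ``predict_fn(model, X) -> labels``.
    """
    subjects = sorted({s["subject_id"] for s in session_tables})
    if len(subjects) < 3:
        raise ValueError("LOSO needs >= 3 subjects")
    audit = LeakageAudit()
    rows = []
    for subj in subjects:
        train = [s for s in session_tables if s["subject_id"] != subj]
        tests = [s for s in session_tables if s["subject_id"] == subj]
        Xtr = np.concatenate([s["X"] for s in train])
        ytr = np.concatenate([s["y"] for s in train])
        model = fit_fn(Xtr, ytr)
        for s in tests:
            audit.record(f"{subj}/{s['session_number']}", Xtr, s["X"])
            yhat = predict_fn(model, s["X"])
            rows.append((s["subject_id"], s["session_number"],
                         float(np.mean(yhat == s["y"]))))
    result = CVResult(pd.DataFrame(
        rows, columns=["subject_id", "session_number", "accuracy"]),
        grouping=grouping, audit=audit)
    audit.verify()
    return result


def blockwise_cv(X, y, blocks, fit_fn, predict_fn, k: int = 4) -> float:
    """k-fold within-session CV where folds are the task blocks (no trial
    shuffling across blocks).  Returns mean accuracy over folds."""
    blocks = np.asarray(blocks)
    uniq = np.unique(blocks)
    if len(uniq) < k:
        raise ValueError(f"session has {len(uniq)} blocks; need >= {k}")
    audit = LeakageAudit()
    accs = []
    for fold in uniq:
        test = blocks == fold
        Xtr, ytr = X[~test], y[~test]
        try:
            model = fit_fn(Xtr, ytr, np.where(~test)[0])
        except TypeError:
            model = fit_fn(Xtr, ytr)
        audit.record(int(fold), Xtr, X[test])
        yhat = predict_fn(model, X[test])
        accs.append(float(np.mean(yhat == y[test])))
    audit.verify()
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# Statistics helpers
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y):
    """Rank-sum test: exact enumeration for small samples (both n <= 20),
    normal approximation with tie correction otherwise.  Returns (|z|, p)
    two-sided."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    z, p_norm = stats.ranksums(x, y)
    if len(x) <= 20 and len(y) <= 20:
        method = "exact" if len(np.unique(np.concatenate([x, y]))) == len(x) + len(y) \
            else "asymptotic"
        p = stats.mannwhitneyu(x, y, alternative="two-sided",
                               method=method).pvalue
    else:
        p = p_norm
    return float(abs(z)), float(p)


@dataclass
class FactorResult:
    factor: str
    kind: str                      # "binary" | "ordinal"
    stats: dict                    # pearson_r, spearman_rho, kendall_tau, ...
    p_raw: float
    p_fdr: float | None = None


def factor_battery(values, factors: pd.DataFrame,
                   binary_factors=("sex",),
                   binarize_hair_length: bool = True) -> list[FactorResult]:
    """Correlation battery of a per-session outcome against subject factors.

    Binary factors get a Wilcoxon rank-sum test; ordinal/continuous ones get
    Pearson r, Spearman rho and Kendall tau (tau's p is the primary p-value)
    plus a Theil-Sen slope for visualization.  hair_length is binarized
    none/short vs medium/long.  BH-FDR is applied over the battery.
    """
    v = np.asarray(values, float)
    if np.allclose(v, v[0]):
        raise ValueError("constant outcome: factor statistics undefined")
    results = []
    for col in factors.columns:
        x = factors[col]
        ok = x.notna() & np.isfinite(v)
        if ok.sum() < 3 or x[ok].nunique() < 2:
            continue
        vv = v[ok.to_numpy()]
        if col in binary_factors or (col == "hair_length" and binarize_hair_length):
            if col == "hair_length":
                g = x[ok].isin(["medium", "long"])
            else:
                levels = sorted(x[ok].unique())
                g = x[ok] == levels[-1]
            a, b = vv[~g.to_numpy()], vv[g.to_numpy()]
            if len(a) < 2 or len(b) < 2:
                continue
            zstat, p = wilcoxon_rank_sum(a, b)
            results.append(FactorResult(col, "binary",
                                        {"wilcoxon_T": zstat}, p))
        else:
            xv = pd.to_numeric(x[ok], errors="coerce").to_numpy(float)
            if np.isnan(xv).any():
                continue
            r, _ = stats.pearsonr(xv, vv)
            rho, _ = stats.spearmanr(xv, vv)
            tau, p_tau = stats.kendalltau(xv, vv)
            slope = stats.theilslopes(vv, xv)[0] if len(np.unique(xv)) > 1 else 0.0
            results.append(FactorResult(col, "ordinal",
                                        {"pearson_r": float(r),
                                         "spearman_rho": float(rho),
                                         "kendall_tau": float(tau),
                                         "theil_sen_slope": float(slope)},
                                        float(p_tau)))
    if results:
        p_adj = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
        for r, pa in zip(results, p_adj):
            r.p_fdr = float(pa)
    return results


def anova_variance_explained(values, factors: pd.DataFrame,
                             factor_names) -> pd.DataFrame:
    """Mass-univariate one-way ANOVA per factor with BH-FDR.

    Variance explained is SS_between(factor) / SS_total; the residual row
    is the remainder so the table's percentages sum to 100.
    """
    v = np.asarray(values, float)
    ss_total = float(np.sum((v - v.mean()) ** 2))
    rows = []
    ss_sum = 0.0
    for name in factor_names:
        x = factors[name]
        groups = [v[(x == lev).to_numpy()] for lev in x.dropna().unique()]
        groups = [g for g in groups if len(g) > 0]
        ss_b = float(sum(len(g) * (g.mean() - v.mean()) ** 2 for g in groups))
        df_b = len(groups) - 1
        ss_w = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
        df_w = len(v) - len(groups)
        F = (ss_b / df_b) / (ss_w / df_w) if df_b > 0 and ss_w > 0 else np.inf
        p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
        ss_sum += ss_b
        rows.append((name, 100.0 * ss_b / ss_total, ss_b, F, p))
    p_adj = multipletests([r[4] for r in rows], method="fdr_bh")[1] if rows else []
    out = pd.DataFrame(rows, columns=["factor", "variance_explained_pct",
                                      "sum_squares", "F", "p_raw"])
    out["p_fdr"] = p_adj
    resid = pd.DataFrame([{
        "factor": "residual",
        "variance_explained_pct": 100.0 * (ss_total - ss_sum) / ss_total,
        "sum_squares": ss_total - ss_sum, "F": np.nan, "p_raw": np.nan,
        "p_fdr": np.nan}])
    return pd.concat([out, resid], ignore_index=True)


def ceiling_analysis(performance, alertness, top_frac: float = 0.2):
    """Top-performer trend across alertness bins (hypothesized ceiling).

    Bins are the distinct alertness values; in each bin the top
    ``top_frac`` quantile of performances is kept; Kendall tau and a
    Theil-Sen slope are computed on the pooled subset.
    """
    perf = np.asarray(performance, float)
    al = np.asarray(alertness, float)
    idx = []
    for lev in np.unique(al[np.isfinite(al)]):
        sel = np.where(al == lev)[0]
        if sel.size == 0:
            continue
        n_top = max(1, int(np.ceil(top_frac * sel.size)))
        idx.extend(sel[np.argsort(perf[sel])[-n_top:]])
    idx = np.asarray(sorted(idx))
    sub_p, sub_a = perf[idx], al[idx]
    tau, p = stats.kendalltau(sub_a, sub_p)
    slope = stats.theilslopes(sub_p, sub_a)[0] if len(np.unique(sub_a)) > 1 else 0.0
    return {"indices": idx, "kendall_tau": float(tau) if tau == tau else 0.0,
            "p": float(p) if p == p else 1.0, "theil_sen_slope": float(slope)}
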