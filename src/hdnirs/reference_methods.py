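"""The five adapted literature decoders, as configurable pipeline presets.

Every variant shares the causal front end (within-tile averaging where the
preset says so, log-OD against the first 60 s, the MACD-type causal
bandpass, MBLL with DPF 6) and the short-trial handcrafted time-window
averages (2-4 s "initial dip", 4.25-6.25 s first tap, 6.5-7.5 s second
tap); they differ in channel policy, feature selection and classifier:

cui          tile-average, 25-45 mm; mutual-information top-80 features;
             linear C-SVM with nested grid over C (subject-specific)
shin         optode-level channels in 10-20 and 25-35 mm bands; CoV
             rejection at 40%; shrinkage LDA (subject-specific)
schudlo      tile-average, 25-35 mm; CoV rejection at 40%; sequential
             forward selection of 4 features; plain LDA (subject-specific)
trambaiolli  tile-average, 25-34 mm; 4.5-8.5 s both-taps average plus the
             2-4 s initial-dip feature; F-score selection with nested CV
             over 2..100 features; shrinkage LDA (subject-independent)
shin_zca     shin's channels pooled across sessions with causal recursive
             ZCA; shrinkage LDA (subject-independent)

All stages with fit semantics (CoV rejection, selectors, classifier grids)
run inside the cross-validation folds of the evaluation harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .evaluation import blockwise_cv, loso_cv_generic
from .io import SessionRecording
from .montage import Montage
from .preprocessing import (
    FilterState,
    butterworth_lowpass,
    channel_length_filter,
    epoch_extract,
    intensity_to_od,
    macd_bandpass,
    mbll,
    recursive_zca,
    tile_average,
)

SHARED_WINDOWS = ((2.0, 4.0), (4.25, 6.25), (6.5, 7.5))
COV_THRESHOLD_PCT = 40.0


@dataclass(frozen=True)
class VariantSpec:
    name: str
    scope: str                      # subject_specific | subject_independent
    tile_averaging: bool
    length_bands: tuple             # ((lo, hi), ...)
    windows: tuple = SHARED_WINDOWS
    cov_reject: bool = False
    selector: str = "none"          # mutual_info | sfs | fscore_nested | none
    n_select: int = 0
    classifier: str = "lda"         # svm_grid | slda | lda
    zca: bool = False


PRESETS: dict[str, VariantSpec] = {
    "cui": VariantSpec("cui", "subject_specific", True, ((25.0, 45.0),),
                       selector="mutual_info", n_select=80,
                       classifier="svm_grid"),
    "shin": VariantSpec("shin", "subject_specific", False,
                        ((10.0, 20.0), (25.0, 35.0)), cov_reject=True,
                        classifier="slda"),
    "schudlo": VariantSpec("schudlo", "subject_specific", True,
                           ((25.0, 35.0),), cov_reject=True,
                           selector="sfs", n_select=4, classifier="lda"),
    "trambaiolli": VariantSpec("trambaiolli", "subject_independent", True,
                               ((25.0, 34.0),),
                               windows=((2.0, 4.0), (4.5, 8.5)),
                               selector="fscore_nested", classifier="slda"),
    "shin_zca": VariantSpec("shin_zca", "subject_independent", False,
                            ((10.0, 20.0), (25.0, 35.0)), cov_reject=True,
                            classifier="slda", zca=True),
}


def spec_to_config(spec: VariantSpec) -> dict:
    from dataclasses import asdict
    return asdict(spec)


def spec_from_config(cfg: dict) -> VariantSpec:
    return VariantSpec(**{**cfg, "length_bands": tuple(
        tuple(b) for b in cfg["length_bands"]),
        "windows": tuple(tuple(w) for w in cfg["windows"])})


# ---------------------------------------------------------------------------
# Causal feature extraction (fit-free)
# ---------------------------------------------------------------------------

def variant_channels(spec: VariantSpec, series: np.ndarray, montage: Montage):
    if spec.tile_averaging:
        x, table = tile_average(series, montage)
    else:
        x, table = np.asarray(series, float), montage.channels
    keep = np.zeros(len(table), bool)
    L = table["length"].to_numpy()
    for lo, hi in spec.length_bands:
        keep |= (L >= lo) & (L <= hi)
    if not keep.any():
        raise ValueError(f"{spec.name}: no channels in length bands")
    return x[keep], table.loc[keep].reset_index(drop=True)


def extract_variant_features(spec: VariantSpec, rec: SessionRecording,
                             montage: Montage, dpf: float = 6.0) -> dict:
    """Per-trial window-mean features for one session (strictly causal up to
    the feature stage; nothing here is fit on data)."""
    fs = rec.fs
    x, table = variant_channels(spec, rec.intensity, montage)
    od = intensity_to_od(x, fs, "first_60s")
    if spec.zca:
        od = recursive_zca(od, fs)
    filt, _ = macd_bandpass(od, fs, FilterState())
    conc, pairs = mbll(filt, table, dpf=dpf)

    trials = rec.trial_markers(covert_only=True)
    onsets = [t for t, _ in trials]
    y = np.array([+1 if lab == "right" else -1 for _, lab in trials])
    tmax = max(hi for _, hi in spec.windows)
    ep = epoch_extract(conc, fs, onsets, 0.0, tmax)  # [N x C x 2 x win]
    feats, meta = [], []
    for wi, (lo, hi) in enumerate(spec.windows):
        i0, i1 = int(round(lo * fs)), int(round(hi * fs))
        feats.append(ep[..., i0:i1].mean(axis=-1))  # [N x C x 2]
        for c in range(ep.shape[1]):
            for ch_i, chrom in enumerate(("HbO", "HbR")):
                meta.append((wi, c, chrom))
    N = ep.shape[0]
    X = np.stack(feats, axis=1).reshape(N, -1)  # windows x channel x chrom
    meta = pd.DataFrame(meta, columns=["window", "channel", "chromophore"])

    # per-trial channel CoV on 0.5 Hz lowpassed intensity (for rejection
    # thresholds fit on training trials only)
    low = butterworth_lowpass(x, fs, 0.5, order=3, zero_phase=False)
    ep_i = epoch_extract(low, fs, onsets, 0.0, tmax)
    mu = ep_i.mean(axis=-1)
    sd = ep_i.std(axis=-1, ddof=1)
    trial_cov = np.where(mu > 0, sd / np.where(mu > 0, mu, 1.0), np.inf)
    # reduce to one CoV per source-detector pair (mean over wavelengths),
    # in the same order as the MBLL pair table the features follow
    pair_cols = []
    for _, prow in pairs.iterrows():
        members = table.index[(table.source_id == prow.source_id)
                              & (table.detector_id == prow.detector_id)]
        pair_cols.append(trial_cov[:, members].mean(axis=1))
    trial_cov = np.column_stack(pair_cols)
    blocks = _trial_blocks(rec, onsets)
    return {"subject_id": rec.subject_id,
            "session_number": rec.session_number,
            "X": X[: len(y)], "y": y[: len(X)], "meta": meta,
            "pairs": pairs, "trial_cov": trial_cov[: len(y)],
            "blocks": blocks[: len(y)]}


def _trial_blocks(rec: SessionRecording, onsets) -> np.ndarray:
    starts = [t for t, lab in rec.markers if lab == "block_start"]
    ends = [t for t, lab in rec.markers if lab == "block_end"]
    blocks = np.full(len(onsets), -1)
    for bi, (t0, t1) in enumerate(zip(starts, ends)):
        for k, on in enumerate(onsets):
            if t0 <= on < t1:
                blocks[k] = bi
    return blocks


# ---------------------------------------------------------------------------
# Selectors and classifiers (fit inside folds)
# ---------------------------------------------------------------------------

def mutual_information(features: np.ndarray, labels: np.ndarray,
                       n_bins: int = 8) -> np.ndarray:
    """Histogram plug-in estimate of I(feature; class), seed-free.

    Features are discretized into equal-frequency bins.
    """
    y = labels > 0
    N, d = features.shape
    mi = np.zeros(d)
    py = np.array([np.mean(~y), np.mean(y)])
    for j in range(d):
        qs = np.quantile(features[:, j], np.linspace(0, 1, n_bins + 1)[1:-1])
        b = np.searchsorted(np.unique(qs), features[:, j])
        total = 0.0
        for bv in np.unique(b):
            sel = b == bv
            px = sel.mean()
            for cls in (0, 1):
                pxy = np.mean(sel & (y == bool(cls)))
                if pxy > 0:
                    total += pxy * np.log(pxy / (px * py[cls]))
        mi[j] = total
    return mi


def sfs_select(features: np.ndarray, labels: np.ndarray, k: int = 4,
               scorer=None) -> list[int]:
    """Greedy sequential forward selection maximizing inner-CV accuracy;
    ties broken by lowest feature index."""
    N, d = features.shape
    if k > d:
        raise ValueError(f"k={k} exceeds {d} features")
    if scorer is None:
        def scorer(Xs, y):
            # small fixed shrinkage keeps degenerate candidate sets solvable
            return _cv_accuracy(Xs, y, lambda A, b: LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage=0.01).fit(A, b))
    selected: list[int] = []
    remaining = list(range(d))
    for _ in range(k):
        best_j, best_score = None, -np.inf
        for j in remaining:
            score = scorer(features[:, selected + [j]], labels)
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def _cv_accuracy(X, y, fit_fn, k: int = 4) -> float:
    skf = StratifiedKFold(n_splits=min(k, np.bincount(y > 0).min(), len(y)),
                          shuffle=False)
    accs = []
    for tr, te in skf.split(X, y):
        model = fit_fn(X[tr], y[tr])
        accs.append(np.mean(model.predict(X[te]) == y[te]))
    return float(np.mean(accs))


def sldas_fit(features: np.ndarray, labels: np.ndarray):
    """Single-level shrinkage LDA (Ledoit-Wolf analytic shrinkage);
    well-defined for n_features > n_samples."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("sLDA needs two classes")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    clf.fit(features, y)
    clf.shrinkage_intensity_ = float(LedoitWolf().fit(features).shrinkage_)
    return clf


def fscore(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    y = labels > 0
    a, b = features[~y], features[y]
    num = (a.mean(0) - features.mean(0)) ** 2 + (b.mean(0) - features.mean(0)) ** 2
    den = (a.var(0, ddof=1) + b.var(0, ddof=1))
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def _fit_variant(spec: VariantSpec, X, y, trial_cov=None):
    """Fit channel rejection + selector + classifier on training data only;
    returns a predict closure."""
    keep_feat = np.ones(X.shape[1], bool)
    n_chan = trial_cov.shape[1] if trial_cov is not None else 0
    if spec.cov_reject and trial_cov is not None:
        chan_cov = np.nanmean(np.where(np.isfinite(trial_cov), trial_cov,
                                       np.nan), axis=0)
        bad = 100.0 * chan_cov >= COV_THRESHOLD_PCT
        if bad.all():
            raise ValueError(f"{spec.name}: CoV rejection removed all channels")
        n_win = X.shape[1] // (n_chan * 2)
        feat_chan = np.tile(np.repeat(np.arange(n_chan), 2), n_win)
        keep_feat &= ~bad[feat_chan]
    Xr = X[:, keep_feat]

    sel_idx = np.arange(Xr.shape[1])
    if spec.selector == "mutual_info":
        k = min(spec.n_select, Xr.shape[1])
        mi = mutual_information(Xr, y)
        sel_idx = np.sort(np.argsort(-mi, kind="stable")[:k])
    elif spec.selector == "sfs":
        sel_idx = np.asarray(sfs_select(Xr, y, k=min(spec.n_select, Xr.shape[1])))
    elif spec.selector == "fscore_nested":
        scores = fscore(Xr, y)
        order = np.argsort(-scores, kind="stable")
        best_k, best_acc = 2, -np.inf
        for k in _fscore_grid(Xr.shape[1]):
            acc = _cv_accuracy(Xr[:, order[:k]], y, lambda A, b: sldas_fit(A, b))
            if acc > best_acc + 1e-12:
                best_k, best_acc = k, acc
        sel_idx = np.sort(order[:best_k])
    Xs = Xr[:, sel_idx]

    if spec.classifier == "svm_grid":
        best_c, best_acc = 1.0, -np.inf
        for c in 2.0 ** np.arange(-5, 16, 2):
            acc = _cv_accuracy(Xs, y, lambda A, b, c=c: LinearSVC(C=c).fit(A, b))
            if acc > best_acc + 1e-12:
                best_c, best_acc = c, acc
        clf = LinearSVC(C=best_c).fit(Xs, y)
    elif spec.classifier == "slda":
        clf = sldas_fit(Xs, y)
    else:
        clf = LinearDiscriminantAnalysis().fit(Xs, y)

    def predict(Xnew):
        return clf.predict(Xnew[:, keep_feat][:, sel_idx])

    return predict


def _fscore_grid(d: int):
    ks = [2, 4, 8, 16, 32, 64, 100]
    return [k for k in ks if k <= d] or [min(2, d)]


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def run_variant(spec: VariantSpec | str, sessions, montage: Montage
                ) -> pd.DataFrame:
    """Score a preset on a list of sessions.

    Subject-specific presets use 4-fold blockwise within-session CV;
    subject-independent presets use leave-one-subject-out CV.  Returns a
    per-session accuracy table; sessions skipped (e.g. all channels CoV-
    rejected) are recorded with NaN accuracy.
    """
    if isinstance(spec, str):
        spec = PRESETS[spec]
    tables = [extract_variant_features(spec, rec, montage) for rec in sessions]
    rows = []
    if spec.scope == "subject_specific":
        for s in tables:
            try:
                def fit_fn(X, y, train_idx, s=s):
                    return _fit_variant(spec, X, y, s["trial_cov"][train_idx])
                acc = blockwise_cv(s["X"], s["y"], s["blocks"],
                                   fit_fn, lambda m, X: m(X), k=4)
            except ValueError as e:
                acc = np.nan
            rows.append((s["subject_id"], s["session_number"], acc))
    else:
        def fit_fn(X, y):
            return _fit_variant(spec, X, y, None)
        res = loso_cv_generic(tables, fit_fn, lambda m, X: m(X))
        rows = list(res.per_session.itertuples(index=False, name=None))
    return pd.DataFrame(rows, columns=["subject_id", "session_number",
                                       "accuracy"])


def benchmark(variants, sessions, montage: Montage) -> pd.DataFrame:
    """Table-shaped comparison: mean +/- SD accuracy and one-sided t vs
    50% per variant."""
    rows = []
    for name in variants:
        table = run_variant(name, sessions, montage)
        acc = table["accuracy"].dropna().to_numpy()
        t, p = stats.ttest_1samp(acc, 0.5, alternative="greater")
        rows.append((name, acc.mean(), acc.std(ddof=1) if len(acc) > 1 else 0.0,
                     float(t), float(p), len(acc)))
    return pd.DataFrame(rows, columns=["variant", "mean_accuracy",
                                       "sd_accuracy", "t_vs_chance",
                                       "p_one_sided", "n_sessions"])
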