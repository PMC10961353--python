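# Methods

This note documents the models, parameter choices and numerical
conventions behind `hdnirs`, and what the synthetic cohorts do and do not
establish about real recordings.

## Montage geometry

The headset model is a parameterized flat-surface layout: per hemisphere a
2 x 3 grid of rigid tiles (3 sources, 4 detectors each), tile column pitch
20 mm, row pitch 30 mm, and 90 mm between the innermost columns of the two
hemispheres. Within a tile, sources sit on an 8.5 mm triangle and
detectors on a center + 9–10.5 mm ring, giving intra-tile channel lengths
of 8.5–19 mm. These pitches were chosen so that (a) every inter-hemisphere
channel is longer than 60 mm (and is therefore noise-dominated and removed
by every length filter in the pipeline), (b) the within-tile-averaged
channel set retained at 15–60 mm is non-empty and hemisphere-symmetric,
and (c) exactly 9 unordered tile pairs per hemisphere fall in the 25–45 mm
band (36 ordered dual-wavelength tile-pair channels in total), the channel
budget the tile-averaging reference decoders expect. No claim of fidelity
to any vendor's coordinates is made; the geometry is explicit config and
is recorded in output metadata. The motor ROI centers are the innermost
bottom-row tiles of each hemisphere; channels whose midpoint lies within
30 mm are labeled `left_motor`/`right_motor`.

A reduced montage (one tile per hemisphere, 48 wavelength-resolved
channels after the decoder's ≤ 50 mm filter) is used for decoding
simulations; a 4-tile variant (two stacked tiles per hemisphere, with
cross-tile channels of 25–49 mm) is used wherever quality-vs-length
structure above 25 mm matters. Problem sizes in tests and scripts (session
counts, trials per session) are desk-scale choices: quality metrics
stabilize within a few minutes of signal and the decoder's planted-effect
recovery is already decisive at 10–20 subjects.

## Forward model

Concentration dynamics live in three compartments: two cortical motor
patches (Gaussian spatial footprint, sigma 25 mm, centered on the motor
ROIs) and one shared superficial layer. Each trial adds to the
contralateral patch an HbO response of peak amplitude 0.6 uM (ipsilateral
0.2 uM); the kernel is a double-gamma (peak 7 s, undershoot 16 s, ratio
1/6) convolved with the 2-s task boxcar and peak-normalized, which puts
the HbO peak ~8 s after task onset. HbR is −0.35 x the HbO kernel delayed
by 1 s. An optional initial dip (15% of peak, Gaussian at 3 +/- 0.8 s) is
on by default. The superficial layer carries cardiac (1.2 Hz, 0.3 uM),
respiratory (0.25 Hz, 0.2 uM), Mayer-wave (0.1 Hz, 0.25 uM) and
random-walk drift components; its HbR is +0.3 x its HbO, the sign of a
volume-driven (total-hemoglobin) scalp pulsation.

A channel of length L mixes compartments with smooth depth weights
w_sup = exp(−L/30 mm) and w_cort = 0.3 · clip((L−5)/20, 0, 1) — a
two-compartment stand-in for a photon-transport partial-path calculation.
Effective concentrations map to optical density through the forward
Beer–Lambert relation with DPF 6 and extinction coefficients pinned from
the standard compiled hemoglobin spectra (735 nm: 450/1102, 850 nm:
1058/691 cm⁻¹ M⁻¹ base-10, converted to natural-log uM⁻¹ mm⁻¹ units; OD is
natural-log throughout). Intensity is
I = I0 · c_src · c_det · 10^(−L/25 mm) · exp(−OD) plus white instrument
noise (sigma 0.0023 · I0), OD-domain random-walk drift, and montage-wide
motion artifacts (exponential spikes and baseline steps with random
per-channel gains). Per-optode coupling efficiencies c are drawn around
0.9 − 0.75 · h (jitter 0.05, floor 0.15), where h ∈ [0, 1] is the hair
severity index: the mean of the normalized hair length, density and
color-darkness ordinals. With these constants a coupling-floor subject
exceeds 15% CoV on every channel above 25 mm while a light-hair subject
stays below ~5% CoV at 30 mm, and a good-coupling cohort decodes in the
high-50s/low-60s percent range — modestly above chance, which is the
regime the method operates in.

What the generator does **not** emulate: realistic anatomy or photon
transport, session-to-session cap repositioning, nonstationary
physiological spectra, subject learning effects, and task-correlated
systemic responses. Passing tests therefore establish internal
consistency of the pipeline (planted structure in → recovered structure
out), not performance on real recordings.

## Preprocessing conventions

- OD references: whole-session mean, first-60-s mean, or a causal running
  EMA (forget 0.01). Intensities are clamped at 1e-9 x channel median
  before the log; channels with non-positive medians raise.
- The MACD bandpass is movavg_2s(x − EMA_0.01(x)); with the EMA
  initialized at the first sample, its group delay is ~1 s and a constant
  input maps to exactly zero. Offline chains (block averaging, the
  stimulus-SNR numerator) use zero-phase Butterworth filters instead.
- TDDR follows the published algorithm: the signal is split at 0.5 Hz,
  derivatives of the low-frequency part are iteratively reweighted with
  the Tukey biweight (c = 4.685, robust sigma = 1.4826 · MAD) until the
  robust mean converges, re-integrated, and the high-frequency residual is
  added back. On smooth oscillatory data the Tukey weights sit slightly
  below 1, so the output tracks the input to within a few percent rather
  than machine precision; constants and trends with constant derivative
  are reproduced exactly.
- GVTD: g(t) = sqrt(mean_c Δx_c(t)²); the per-epoch statistic is the max
  of g within the epoch, thresholded at mean + 3 SD of all epoch
  statistics of the session (computed before any rejection).
- Recursive ZCA: covariance and mean are updated once per 5-s block with
  an exponential forgetting half-life of 60 s (slow relative to trials,
  fast relative to cap drift); each block is transformed with the
  symmetric inverse square root of the covariance known before it, shrunk
  by λ · tr(S)/C · I with λ = 1e-6 so the shrinkage is unit-free. A
  sample-covariance recursion with memory N deviates from the identity by
  ~sqrt(C/N) even on white input, so "whitened" means decorrelated to
  |rho| < 0.1 and unit variance to ~20%, not exact identity.
- Epoch windows are half-open [t0, t1) with 0-based sample indexing;
  baselines are subtracted as the per-trial mean over [−2, 0) s.

## Quality score and partitioning

The session score is a weighted mean of q(cv) = exp(−cv / v0) (v0 = 0.5)
with Gaussian weights (scale 30 mm) around the two motor-ROI centers —
a reconstruction that preserves the defining properties (CoV-based,
ROI-emphasized, 0–1, higher is better) of the original montage-level
metric whose exact weights are not published. Consequently no fixed
numeric threshold transfers between datasets: the automatic partition
re-derives it per cohort as the lowest upper bound of the lowest-quality
cluster (largest gap among sorted scores below the median). Breaks and
baseline are excluded from the metrics with a 1-s guard band for filter
transients.

## Decoder

Features: ≤ 50 mm channels → log-OD against the running EMA baseline →
recursive ZCA → MBLL (DPF 6) → 0–8.5 s epochs (86 samples at 10 Hz) →
polyphase resampling by 1/2 to 5 Hz, giving T = 43 = floor(8.5·5) + 1
(pinned convention) → robust z-scoring with training-set medians and MADs
(MAD of constant features floored to unit scale and flagged). Rows are
chromophore blocks (HbO block then HbR block, channel-major); vec(W) is
row-major, index = row·T + t, and Γ_U = D_U ⊗ I_T, Γ_V = I ⊗ D_V are
built to match. Labels map {left, right} → {−1, +1} (the standard
logistic-loss coding). D_U has one row per same-chromophore channel pair
within anisotropic distance sqrt(Δlateral² + (1.5·Δdepth)²) ≤ 15 mm, with
Gaussian weight exp(−d²/(2·(r/2)²)) — a Gaussian-decay construction
honoring the radius and anisotropy; D_V is the first-order temporal
difference.

The solver is monotone FISTA: backtracking line search on the smooth part
(logistic loss + both quadratic penalties, gradients analytic), nuclear-
norm prox by singular-value soft-thresholding, the incumbent kept whenever
a prox step fails to improve the objective, stopping after three
consecutive relative changes below 1e-6 (default cap 500 iterations; the
cross-validation harnesses use 200 iterations and 1e-5, where the
objective is already flat). The bias is unpenalized. On toy problems the
final objective matches an independent ADMM solver to ~1e-6 relative.

Default hyperparameters α = 0.05, β = 62.5, γ = 5 are the centers of the
nested-search grid (α ∈ {0.025, 0.05, 0.075} × β ∈ {50, 62.5, 75}, γ
fixed at 5); the nested leave-one-subject-out search is available but the
defaults are used wherever a single setting is called for.

A structural note on weight maps: after ZCA whitening, the per-pair
HbO/HbR noise covariance is (E⁻¹)(E⁻¹)ᵀ for the extinction matrix E, so
the optimal weights are ~EᵀE·d for a discriminative pattern d. The
off-diagonal of EᵀE at 735/850 nm is comparable to its diagonal, which
mixes the chromophores into same-sign weights even when d itself has
opposite HbO/HbR polarity — as the planted physiology does, and as the
exported class-difference patterns show. Chromophore-polarity and
short-vs-long-channel sign structure in *weights* therefore reflect
residual (imperfectly whitened, nonstationary) noise structure in real
data and are not reproduced by this stationary generator; the functional
property — that a 3x superficial systemic component does not break
decoding — holds and is tested.

## Evaluation and statistics

Leave-one-subject-out CV excludes all sessions of the test subject from
training; the robust scaler is re-fit inside every training fold (the
rest of the feature chain is per-session and fit-free). Every harness
fingerprints (SHA-1 per trial) the arrays its fit functions see and
asserts no held-out trial ever entered a fit. Accuracy is compared to the
50% chance level with a one-sided t-test over per-session accuracies;
when several seeded cohorts are pooled, the sampling unit for the grand
mean is the cohort (sessions within a cohort share fitted models).
Subject-specific reference presets use 4-fold blockwise within-session CV
aligned to the task blocks.

Factor analyses: Wilcoxon rank-sum for binary factors (exact enumeration
when both groups have ≤ 20 untied observations, normal approximation with
tie correction otherwise; hair length binarized none/short vs
medium/long), Pearson + Spearman + Kendall with a Theil–Sen slope for
ordinal/continuous factors, BH-FDR over the battery. The ANOVA table
reports per-factor one-way between-group sums of squares over the total;
the residual row is the remainder, so percentages sum to 100 — with
strongly collinear factors (the synthetic hair ordinals all derive from
one severity index) individual factors overlap and the residual can be
negative, which the table reports as-is.

## Known limitations

- The geometry, ROI weighting and Γ_U weight profile are principled
  reconstructions of components whose exact published parameters are
  unavailable; absolute thresholds and weight values do not transfer to
  other implementations.
- The generator's noise is stationary and its compartments coarse; effect
  sizes were set to place good-coupling decoding modestly above chance,
  not to reproduce any specific accuracy figure.
- The recursive ZCA's forgetting scheme (EW, half-life 60 s) is a
  documented stand-in for an update rule that is not fully specified in
  the public literature.
- Mass-univariate ANOVA on collinear factors quantifies marginal, not
  partial, variance explained.
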