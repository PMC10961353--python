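"""Synthetic task schedules and multi-subject fNIRS cohorts.

The generator plants the statistical structure the downstream analyses
assume, so every stage of the pipeline is testable without access to a
recorded dataset:

* a session schedule of 4 blocks x 30 trials (17 s each: 5 s rest, 2 s
  imagined tapping, 8 s rest, 2 s feedback), a 2-min baseline, 30-s breaks,
  and, in session 1, two sub-blocks per block of 13 covert + 2 overt trials;
* lateralized double-gamma hemodynamic responses (HbO peaking ~8 s after
  the 2-s task onset, optional initial dip, smaller inverted HbR) in two
  cortical motor patches plus a shared superficial systemic compartment
  (cardiac, respiratory, Mayer waves, drift);
* a two-compartment forward model: effective channel concentration =
  depth-weighted superficial + cortical contributions, mapped to optical
  density by the forward Beer-Lambert relation and to intensity through
  per-optode coupling efficiencies that degrade with a hair-severity index.

All randomness flows through one seeded generator with per-session
substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as hio
from .montage import (
    HAIR_COLOR_LEVELS,
    HAIR_DENSITY_LEVELS,
    HAIR_LENGTH_LEVELS,
    Montage,
    build_default_montage,
    reduced_geometry_config,
)
from .preprocessing import EXTINCTION_LN_UM_MM, mbll_forward


class ScheduleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleSpec:
    n_blocks: int = 4
    trials_per_block: int = 30
    rest_pre_s: float = 5.0
    task_s: float = 2.0
    rest_post_s: float = 8.0
    feedback_s: float = 2.0
    baseline_s: float = 120.0
    break_s: float = 30.0
    covert_per_subblock: int = 13
    overt_per_subblock: int = 2

    @property
    def trial_s(self) -> float:
        return self.rest_pre_s + self.task_s + self.rest_post_s + self.feedback_s


def generate_schedule(
    spec: ScheduleSpec, session_number: int, seed: int
) -> list[tuple[float, str]]:
    """Markers for one session; task markers sit at the tapping onset.

    Session 1 interleaves overt (motor execution) sub-blocks: each block of
    ``trials_per_block`` is two sub-blocks of 13 covert + 2 overt trials.
    Left/right labels are balanced within covert and overt trials and
    pseudo-randomized deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_total = spec.n_blocks * spec.trials_per_block
    if session_number == 1:
        sub = spec.covert_per_subblock + spec.overt_per_subblock
        if spec.trials_per_block % sub:
            raise ScheduleError(
                f"trials_per_block {spec.trials_per_block} not divisible by "
                f"sub-block size {sub}")
        n_sub = spec.trials_per_block // sub
        n_overt = spec.n_blocks * n_sub * spec.overt_per_subblock
        n_covert = n_total - n_overt
    else:
        n_overt, n_covert = 0, n_total
    if n_covert % 2 or n_overt % 2:
        raise ScheduleError(
            "equal left/right counts require even covert and overt totals "
            f"(got {n_covert} covert, {n_overt} overt)")

    covert_labels = ["left"] * (n_covert // 2) + ["right"] * (n_covert // 2)
    overt_labels = ["overt_left"] * (n_overt // 2) + ["overt_right"] * (n_overt // 2)
    rng.shuffle(covert_labels)
    rng.shuffle(overt_labels)
    covert_iter, overt_iter = iter(covert_labels), iter(overt_labels)

    markers: list[tuple[float, str]] = [
        (0.0, "baseline_start"), (spec.baseline_s, "baseline_end")]
    t = spec.baseline_s
    for b in range(spec.n_blocks):
        markers.append((t, "block_start"))
        for k in range(spec.trials_per_block):
            if session_number == 1:
                pos = k % (spec.covert_per_subblock + spec.overt_per_subblock)
                overt = pos >= spec.covert_per_subblock
            else:
                overt = False
            label = next(overt_iter) if overt else next(covert_iter)
            markers.append((t + spec.rest_pre_s, label))
            t += spec.trial_s
        markers.append((t, "block_end"))
        if b < spec.n_blocks - 1:
            t += spec.break_s
    return markers


def schedule_duration(spec: ScheduleSpec) -> float:
    return (spec.baseline_s + spec.n_blocks * spec.trials_per_block * spec.trial_s
            + (spec.n_blocks - 1) * spec.break_s)


# ---------------------------------------------------------------------------
# Hemodynamics, noise, coupling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HemodynamicSpec:
    """Double-gamma HRF and response amplitudes (uM).

    The HRF kernel is the difference of two gamma densities (main lobe
    peaking at ``peak_s``, undershoot at ``undershoot_s``), convolved with
    the 2-s task boxcar and normalized to unit peak, so ``amp_*`` are peak
    concentrations.  With the defaults the HbO peak lands ~8 s after task
    onset.  ``dip_frac`` adds an optional negative HbO lobe at 2-4 s.
    """

    peak_s: float = 7.0
    undershoot_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    dispersion_s: float = 0.9
    amp_hbo_contra: float = 0.6
    amp_hbo_ipsi: float = 0.2
    hbr_ratio: float = -0.35
    hbr_delay_s: float = 1.0
    dip_frac: float = 0.15
    dip_center_s: float = 3.0
    dip_width_s: float = 0.8
    superficial_systemic: float = 1.0

    def kernel(self, fs: float, task_s: float = 2.0, tmax: float = 25.0):
        """(t, hbo_kernel, hbr_kernel), unit HbO peak."""
        t = np.arange(0.0, tmax, 1.0 / fs)
        b = self.dispersion_s

        def gamma_lobe(peak):
            a = peak / b + 1.0
            g = t ** (a - 1) * np.exp(-t / b)
            return g / g.max()

        h = gamma_lobe(self.peak_s) - self.undershoot_ratio * gamma_lobe(self.undershoot_s)
        box = np.ones(max(1, int(round(task_s * fs))))
        h = np.convolve(h, box)[: len(t)]
        h /= np.abs(h).max()
        if self.dip_frac:
            h = h - self.dip_frac * np.exp(
                -0.5 * ((t - self.dip_center_s) / self.dip_width_s) ** 2)
        hbo = h / np.abs(h).max()
        shift = int(round(self.hbr_delay_s * fs))
        hbr = self.hbr_ratio * np.concatenate([np.zeros(shift), hbo[: len(t) - shift]])
        return t, hbo, hbr

    def planted_peak_latency(self, fs: float, task_s: float = 2.0) -> float:
        t, hbo, _ = self.kernel(fs, task_s)
        return float(t[np.argmax(hbo)])


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument and physiological noise amplitudes.

    Physiological components (cardiac/respiration/Mayer/slow drift) live in
    the superficial compartment in uM; instrument terms act per channel
    (OD-domain random-walk drift, additive white intensity noise relative
    to the nominal source intensity) plus montage-wide motion artifacts
    (exponential spikes and baseline steps in OD with random per-channel
    gain).
    """

    cardiac_hz: float = 1.2
    cardiac_um: float = 0.30
    cardiac_jitter: float = 0.03
    resp_hz: float = 0.25
    resp_um: float = 0.20
    mayer_hz: float = 0.10
    mayer_um: float = 0.25
    superficial_drift_um: float = 0.4
    od_drift_sigma: float = 1e-4
    white_sigma_rel: float = 0.0023
    motion_spike_per_min: float = 0.5
    motion_spike_od: float = 0.15
    motion_shift_per_min: float = 0.2
    motion_shift_od: float = 0.05

    def validate(self):
        for f in ("cardiac_um", "resp_um", "mayer_um", "od_drift_sigma",
                  "white_sigma_rel", "motion_spike_od", "motion_shift_od",
                  "superficial_drift_um"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """Per-optode coupling efficiency as a function of hair severity.

    Efficiency is drawn around ``base - slope * severity`` with Gaussian
    jitter, clipped to [floor, 1].  Severity 0 (no/light hair) gives ~0.9;
    severity 1 (long, dense, dark hair) sits at the poor-quality floor.
    """

    base: float = 0.90
    slope: float = 0.75
    jitter_sd: float = 0.05
    floor: float = 0.15
    fixed_value: float | None = None  # force identical coupling (e.g. 1.0)

    def sample(self, severity: float, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.fixed_value is not None:
            return np.full(n, float(self.fixed_value))
        mean = self.base - self.slope * float(severity)
        vals = mean + self.jitter_sd * rng.standard_normal(n)
        return np.clip(vals, self.floor, 1.0)


def hair_severity(factors: hio.SubjectFactors) -> float:
    """Hair occlusion severity in [0, 1] from length, density and darkness."""
    parts = []
    if factors.hair_length is not None:
        parts.append(HAIR_LENGTH_LEVELS.index(factors.hair_length) / 3.0)
    if factors.hair_density is not None:
        parts.append(HAIR_DENSITY_LEVELS.index(factors.hair_density) / 2.0)
    if factors.hair_color is not None:
        parts.append(HAIR_COLOR_LEVELS.index(factors.hair_color) / 5.0)
    return float(np.mean(parts)) if parts else 0.5


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

#: Nominal source intensity (arbitrary units) and length attenuation scale:
#: detected intensity falls one decade per ATTEN_DECADE_MM of channel length.
I0 = 1.0e3
ATTEN_DECADE_MM = 25.0
PATCH_SIGMA_MM = 25.0


def depth_weights(lengths_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Superficial and cortical partial-path weights as smooth functions of
    channel length (two-compartment path model)."""
    L = np.asarray(lengths_mm, float)
    w_sup = np.exp(-L / 30.0)
    w_cort = 0.3 * np.clip((L - 5.0) / 20.0, 0.0, 1.0)
    return w_sup, w_cort


def _patch_gains(montage: Montage) -> np.ndarray:
    """[n_channels x 2] spatial gain of (left, right) motor patch per channel."""
    ch = montage.channels
    mids = ch[["mid_x", "mid_y", "mid_z"]].to_numpy()
    roi = montage.roi_centers()
    gains = np.empty((len(ch), 2))
    for j, name in enumerate(("left_motor", "right_motor")):
        d = np.linalg.norm(mids - roi[name][None, :], axis=1)
        gains[:, j] = np.exp(-0.5 * (d / PATCH_SIGMA_MM) ** 2)
    return gains


def effective_concentration(
    montage: Montage,
    cortical: np.ndarray,
    superficial: np.ndarray,
) -> np.ndarray:
    """Mix compartment concentrations into per-channel effective uM.

    cortical: [2 patches x 2 chromophores x n_samples]; superficial:
    [2 x n_samples].  Returns [n_channels x 2 x n_samples] (one row per
    wavelength-resolved channel; wavelength does not affect concentration).
    """
    ch = montage.channels
    w_sup, w_cort = depth_weights(ch["length"].to_numpy())
    gains = _patch_gains(montage)
    cort = np.tensordot(gains, cortical, axes=(1, 0))  # [n_ch x 2 x t]
    return (w_cort[:, None, None] * cort
            + w_sup[:, None, None] * superficial[None, :, :])


def simulate_session(
    montage: Montage,
    markers: list[tuple[float, str]],
    hemo: HemodynamicSpec | None = None,
    noise: NoiseSpec | None = None,
    coupling: CouplingSpec | None = None,
    seed: int = 0,
    fs: float = 10.0,
    subject_id: str = "sim01",
    session_number: int = 1,
    factors: hio.SubjectFactors | None = None,
    pad_s: float = 20.0,
) -> hio.SessionRecording:
    """Forward-simulate one session on the given montage.

    Pipeline: trial onsets -> compartment concentration time courses ->
    per-channel effective concentration (depth + patch weighting) ->
    forward MBLL (DPF 6) -> intensity
    I = I0 * c_src * c_det * 10^(-L/25mm) * exp(-OD) + white noise,
    with motion artifacts injected as correlated OD spikes/steps.
    """
    hemo = hemo or HemodynamicSpec()
    noise = noise or NoiseSpec()
    noise.validate()
    coupling = coupling or CouplingSpec()
    factors = factors or hio.SubjectFactors()
    rng = np.random.default_rng(seed)

    t_end = max(t for t, _ in markers) + pad_s
    n = int(round(t_end * fs))
    ch = montage.channels
    n_ch = len(ch)

    # --- cortical compartments -------------------------------------------
    _, k_hbo, k_hbr = hemo.kernel(fs, task_s=2.0)
    neural = np.zeros((2, n))  # left patch, right patch drive
    for t, lab in markers:
        if lab in ("left", "right", "overt_left", "overt_right"):
            i = int(round(t * fs))
            if i >= n:
                continue
            # left-hand trial drives the RIGHT (contralateral) hemisphere
            contra = 1 if lab.endswith("left") else 0
            ipsi = 1 - contra
            neural[contra, i] += hemo.amp_hbo_contra
            neural[ipsi, i] += hemo.amp_hbo_ipsi
    cortical = np.zeros((2, 2, n))  # patch x (HbO, HbR) x t
    for p in range(2):
        cortical[p, 0] = np.convolve(neural[p], k_hbo)[:n]
        cortical[p, 1] = np.convolve(neural[p], k_hbr)[:n]

    # --- superficial systemic compartment --------------------------------
    t_ax = np.arange(n) / fs
    sup_hbo = np.zeros(n)
    for f0, amp, jit in (
        (noise.cardiac_hz, noise.cardiac_um, noise.cardiac_jitter),
        (noise.resp_hz, noise.resp_um, noise.cardiac_jitter),
        (noise.mayer_hz, noise.mayer_um, noise.cardiac_jitter),
    ):
        if amp <= 0:
            continue
        freq = f0 * (1.0 + jit * np.cumsum(rng.standard_normal(n)) / np.sqrt(np.arange(1, n + 1)))
        phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
        sup_hbo += amp * np.sin(phase)
    if noise.superficial_drift_um > 0:
        walk = np.cumsum(rng.standard_normal(n)) / np.sqrt(n)
        sup_hbo += noise.superficial_drift_um * walk
    superficial = np.vstack([sup_hbo, 0.3 * sup_hbo]) * hemo.superficial_systemic

    conc = effective_concentration(montage, cortical, superficial)

    # --- forward MBLL per wavelength -------------------------------------
    lengths = ch["length"].to_numpy()
    od = np.empty((n_ch, n))
    for wl in np.unique(ch["wavelength"]):
        m = (ch["wavelength"] == wl).to_numpy()
        od[m] = mbll_forward(conc[m], lengths[m], float(wl))

    # --- instrument OD noise + motion artifacts --------------------------
    if noise.od_drift_sigma > 0:
        od += noise.od_drift_sigma * np.cumsum(rng.standard_normal((n_ch, n)), axis=1)
    task_minutes = t_end / 60.0
    for rate, make in (
        (noise.motion_spike_per_min, "spike"),
        (noise.motion_shift_per_min, "shift"),
    ):
        n_ev = rng.poisson(rate * task_minutes)
        for _ in range(n_ev):
            i = rng.integers(0, n)
            gain = np.abs(1.0 + 0.3 * rng.standard_normal(n_ch))
            if make == "spike":
                amp = noise.motion_spike_od * rng.standard_normal()
                tail = np.exp(-np.arange(n - i) / (0.5 * fs))
                od[:, i:] += gain[:, None] * amp * tail[None, :]
            else:
                amp = noise.motion_shift_od * rng.standard_normal()
                od[:, i:] += gain[:, None] * amp

    # --- coupling and intensity ------------------------------------------
    sev = hair_severity(factors)
    eff = {o.id: v for o, v in zip(
        montage.optodes.values(),
        coupling.sample(sev, len(montage.optodes), rng))}
    c_src = np.array([eff[s] for s in ch["source_id"]])
    c_det = np.array([eff[d] for d in ch["detector_id"]])
    atten = 10.0 ** (-lengths / ATTEN_DECADE_MM)
    base = I0 * c_src * c_det * atten
    intensity = base[:, None] * np.exp(-od)
    if noise.white_sigma_rel > 0:
        intensity = intensity + I0 * noise.white_sigma_rel * rng.standard_normal((n_ch, n))
    intensity = np.maximum(intensity, 0.0)

    return hio.SessionRecording(
        intensity=intensity,
        fs=fs,
        markers=list(markers),
        subject_id=subject_id,
        session_number=session_number,
        factors=factors,
        montage=montage,
    )


# ---------------------------------------------------------------------------
# Demographics and cohorts
# ---------------------------------------------------------------------------

#: Category frequencies emulating the study cohort (subject-level).
DEFAULT_DEMOGRAPHICS = {
    "sex": {"male": 0.5, "female": 0.5},
    "ethnicity": {"white": 0.48, "hispanic": 0.16, "asian": 0.23, "black": 0.13},
    "age_bins": {(18, 25): 0.44, (26, 40): 0.22, (41, 55): 0.12, (56, 75): 0.22},
    # hair severity tendency per ethnicity (mean of a clipped normal)
    "hair_severity_mean": {"white": 0.30, "asian": 0.50, "hispanic": 0.55, "black": 0.75},
    "hair_severity_sd": 0.18,
    # jitter when decomposing severity into the ordinal hair factors
    "hair_ordinal_spread": 0.8,
    # age lightens/thins hair: severity -= age_slope * (age - 30)/30 for age>30
    "age_slope": 0.25,
}


def _sample_factors(rng: np.random.Generator, cfg: dict) -> hio.SubjectFactors:
    sex = rng.choice(list(cfg["sex"]), p=list(cfg["sex"].values()))
    eth = rng.choice(list(cfg["ethnicity"]), p=list(cfg["ethnicity"].values()))
    bins = list(cfg["age_bins"])
    lo, hi = bins[rng.choice(len(bins), p=list(cfg["age_bins"].values()))]
    age = int(rng.integers(lo, hi + 1))
    sev = cfg["hair_severity_mean"][eth] + \
        cfg.get("hair_severity_sd", 0.18) * rng.standard_normal()
    if age > 30:
        sev -= cfg["age_slope"] * (age - 30) / 30.0
    sev = float(np.clip(sev, 0.0, 1.0))
    # decompose severity into correlated ordinal hair factors
    base_spread = cfg.get("hair_ordinal_spread", 0.8)

    def ordinal(levels, center, spread=base_spread):
        idx = center * (len(levels) - 1) + spread * rng.standard_normal()
        return levels[int(np.clip(round(idx), 0, len(levels) - 1))]
    hair_length = ordinal(HAIR_LENGTH_LEVELS, sev)
    hair_density = ordinal(HAIR_DENSITY_LEVELS, sev, spread=base_spread * 0.6)
    hair_color = ordinal(HAIR_COLOR_LEVELS[1:], sev)  # 'none' reserved for bald
    if hair_length == "none":
        hair_color = "none"
    alertness = int(np.clip(round(7 + 1.8 * rng.standard_normal()), 1, 10))
    return hio.SubjectFactors(
        age=age, sex=sex, ethnicity=eth, hair_length=hair_length,
        hair_color=hair_color, hair_density=hair_density, alertness=alertness)


def generate_cohort(
    n_subjects: int = 32,
    sessions_per_subject=(32, 15, 14),
    demographics_config: dict | None = None,
    seed: int = 0,
    montage: Montage | None = None,
    schedule_spec: ScheduleSpec | None = None,
    hemo: HemodynamicSpec | None = None,
    noise: NoiseSpec | None = None,
    coupling: CouplingSpec | None = None,
    out_dir=None,
):
    """Generate a synthetic cohort with subject-consistent factors.

    ``sessions_per_subject[k]`` is the number of subjects who recorded
    session k+1 (the first that many subjects return).  With ``out_dir``
    set, sessions are written as SNIRF files plus a factors CSV and a JSON
    manifest and the manifest path is returned; otherwise an in-memory list
    of SessionRecording objects is returned.
    """
    cfg = demographics_config or DEFAULT_DEMOGRAPHICS
    montage = montage or build_default_montage(reduced_geometry_config())
    spec = schedule_spec or ScheduleSpec()
    root = np.random.SeedSequence(seed)
    subj_ss, *sess_ss = root.spawn(1 + sum(
        min(k, n_subjects) for k in sessions_per_subject))
    subj_rng = np.random.default_rng(subj_ss)
    base_factors = [_sample_factors(subj_rng, cfg) for _ in range(n_subjects)]

    recordings, factor_rows, entries = [], [], []
    si = 0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for sess_num, n_k in enumerate(sessions_per_subject, start=1):
        for subj in range(min(n_k, n_subjects)):
            ss = sess_ss[si]
            si += 1
            rng = np.random.default_rng(ss)
            subject_id = f"sub{subj + 1:03d}"
            f = base_factors[subj]
            f = replace(f, alertness=int(np.clip(
                round((f.alertness or 7) + rng.normal(0, 1)), 1, 10)))
            sched_seed, sim_seed = rng.integers(0, 2**31 - 1, size=2)
            markers = generate_schedule(spec, sess_num, int(sched_seed))
            rec = simulate_session(
                montage, markers, hemo=hemo, noise=noise, coupling=coupling,
                seed=int(sim_seed), subject_id=subject_id,
                session_number=sess_num, factors=f)
            factor_rows.append({
                "subject_id": subject_id, "session_number": sess_num,
                "age": f.age, "sex": f.sex, "ethnicity": f.ethnicity,
                "hair_length": f.hair_length, "hair_color": f.hair_color,
                "hair_density": f.hair_density, "alertness": f.alertness,
            })
            if out_dir is None:
                recordings.append(rec)
            else:
                fname = f"{subject_id}_ses{sess_num}.snirf"
                hio.write_session(rec, out_dir / fname, montage=montage)
                entries.append({"path": fname, "subject_id": subject_id,
                                "session_number": sess_num,
                                "factors_csv": "factors.csv"})
    if out_dir is None:
        return recordings, factor_rows
    hio.write_factors_table(factor_rows, out_dir / "factors.csv")
    manifest = out_dir / "manifest.json"
    hio.write_manifest(entries, manifest, geometry=montage.geometry)
    return manifest
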