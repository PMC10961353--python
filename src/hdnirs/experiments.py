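"""Packaged study conditions: the canonical synthetic experiments that the
analysis scripts, the test suite and the acceptance script all share.

Each function builds a cohort at the condition it names (pure-noise
poor-quality, planted-effect minimum-viable-quality, hair-biased 61-session)
and runs the package's own pipeline on it.  Decoding experiments use the
reduced montage (one tile per hemisphere, 48 wavelength-resolved channels
after the <= 50 mm filter) at full 120-trial sessions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import decoder as dec
from .evaluation import CVResult, loso_cv, session_feature_sets
from .io import SubjectFactors
from .montage import Montage, build_default_montage, reduced_geometry_config
from .quality import partition_sessions, session_quality
from .synth import (
    DEFAULT_DEMOGRAPHICS,
    CouplingSpec,
    HemodynamicSpec,
    ScheduleSpec,
    generate_cohort,
    generate_schedule,
    hair_severity,
    simulate_session,
)

#: Factors of a light-hair subject (minimum-viable-quality profile).
MVQ_FACTORS = SubjectFactors(hair_length="short", hair_color="blond",
                             hair_density="low")

#: Demographics with a clearly separated severe-hair subgroup, for the
#: quality-bias cohort (the planted poor-quality sessions).
BIMODAL_DEMOGRAPHICS = dict(
    DEFAULT_DEMOGRAPHICS,
    ethnicity={"white": 0.40, "hispanic": 0.15, "asian": 0.15, "black": 0.30},
    hair_severity_mean={"white": 0.10, "asian": 0.20, "hispanic": 0.25,
                        "black": 1.20},
    hair_severity_sd=0.10,
    hair_ordinal_spread=0.35,
    age_slope=0.0,
)

#: Expected per-optode coupling below this marks a planted PQ session.
PQ_COUPLING_CUT = 0.30


def _montage(montage: Montage | None) -> Montage:
    return montage or build_default_montage(reduced_geometry_config())


def chance_floor_cohort(seed: int, n_subjects: int = 12,
                        montage: Montage | None = None,
                        schedule: ScheduleSpec | None = None):
    """Pure-noise poor-quality cohort: no neural response, per-optode
    coupling at the floor, one full session per subject."""
    montage = _montage(montage)
    schedule = schedule or ScheduleSpec()
    hemo = HemodynamicSpec(amp_hbo_contra=0.0, amp_hbo_ipsi=0.0)
    coupling = CouplingSpec(fixed_value=CouplingSpec().floor)
    rng = np.random.default_rng(seed)
    recs = []
    for s in range(n_subjects):
        sched_seed, sim_seed = rng.integers(0, 2**31 - 1, size=2)
        markers = generate_schedule(schedule, 2, int(sched_seed))
        recs.append(simulate_session(
            montage, markers, hemo=hemo, coupling=coupling,
            seed=int(sim_seed), subject_id=f"sub{s + 1:03d}",
            session_number=1))
    return recs


def planted_effect_cohort(seed: int, n_subjects: int = 20,
                          montage: Montage | None = None,
                          schedule: ScheduleSpec | None = None):
    """Minimum-viable-quality cohort with the default planted effect size
    and light-hair coupling."""
    montage = _montage(montage)
    schedule = schedule or ScheduleSpec()
    rng = np.random.default_rng(seed)
    recs = []
    for s in range(n_subjects):
        sched_seed, sim_seed = rng.integers(0, 2**31 - 1, size=2)
        markers = generate_schedule(schedule, 2, int(sched_seed))
        recs.append(simulate_session(
            montage, markers, seed=int(sim_seed), factors=MVQ_FACTORS,
            subject_id=f"sub{s + 1:03d}", session_number=1))
    return recs


def run_loso(recordings, montage: Montage | None = None,
             hyperparams: dict | None = None, grid: dict | None = None,
             max_iter: int = 200, tol: float = 1e-5,
             grouping: str = "All") -> CVResult:
    """Feature extraction + LOSO CV of the high-density decoder."""
    montage = _montage(montage)
    sets = session_feature_sets(recordings, montage)
    return loso_cv(sets, hyperparams=hyperparams, grid=grid,
                   max_iter=max_iter, tol=tol, grouping=grouping)


def chance_floor_accuracy(seed: int, n_seeds: int = 5, n_subjects: int = 12,
                          schedule: ScheduleSpec | None = None) -> dict:
    """Mean LOSO accuracy of the decoder on pure-noise PQ cohorts, averaged
    over ``n_seeds`` seeded cohorts."""
    montage = _montage(None)
    per_seed = []
    sessions = 0
    for k in range(n_seeds):
        recs = chance_floor_cohort(seed + k, n_subjects=n_subjects,
                                   montage=montage, schedule=schedule)
        res = run_loso(recs, montage, grouping="PQ")
        per_seed.append(res)
        sessions += len(res.per_session)
    accs = np.concatenate([r.accuracies for r in per_seed])
    return {
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)),
        "se_accuracy": float(accs.std(ddof=1) / np.sqrt(len(accs))),
        "n_sessions": sessions,
        "per_seed": per_seed,
    }


def fit_cohort_model(recordings, montage: Montage | None = None,
                     hyperparams: dict | None = None,
                     max_iter: int = 200, tol: float = 1e-5):
    """Fit one decoder on every session of a cohort (for weight maps)."""
    from .evaluation import DEFAULT_HYPERPARAMS, _fit_decoder_on
    montage = _montage(montage)
    sets = session_feature_sets(recordings, montage)
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    T = sets[0]["X"].shape[2]
    ops = dec.build_tikhonov_operators(sets[0]["pairs"], T)
    model = _fit_decoder_on(sets, hp["alpha"], hp["beta"], hp["gamma"],
                            ops, max_iter, tol)
    model.pairs = sets[0]["pairs"]
    return model


def quality_bias_cohort(seed: int, montage: Montage | None = None,
                        schedule: ScheduleSpec | None = None):
    """61-session cohort with the planted hair -> coupling dependence.

    Returns (recordings, factor_rows).
    """
    montage = _montage(montage)
    schedule = schedule or ScheduleSpec(n_blocks=2, trials_per_block=10,
                                        baseline_s=60.0,
                                        covert_per_subblock=4,
                                        overt_per_subblock=1)
    return generate_cohort(
        n_subjects=32, sessions_per_subject=(32, 15, 14),
        demographics_config=BIMODAL_DEMOGRAPHICS, seed=seed,
        montage=montage, schedule_spec=schedule)


def expected_coupling(factors: SubjectFactors,
                      spec: CouplingSpec | None = None) -> float:
    """Deterministic part of the planted coupling model for one session."""
    spec = spec or CouplingSpec()
    return float(np.clip(spec.base - spec.slope * hair_severity(factors),
                         spec.floor, 1.0))


def quality_bias_analysis(recordings, factor_rows,
                          montage: Montage | None = None) -> dict:
    """Quality scores, auto partition, and planted-ground-truth comparison
    for a hair-biased cohort."""
    montage = _montage(montage)
    scores = []
    for rec in recordings:
        scores.append(session_quality(rec, montage)[0])
    scores = np.asarray(scores)
    parts = partition_sessions(scores)
    labels = np.array([p.label for p in parts])
    factors = pd.DataFrame(factor_rows)
    planted_coupling = np.array([
        expected_coupling(rec.factors) for rec in recordings])
    planted_pq = planted_coupling <= PQ_COUPLING_CUT
    agreement = float(np.mean((labels == "PQ") == planted_pq))
    severity = np.array([hair_severity(rec.factors) for rec in recordings])
    return {
        "scores": scores,
        "labels": labels,
        "t_qual": parts[0].t_qual,
        "factors": factors,
        "planted_coupling": planted_coupling,
        "planted_pq": planted_pq,
        "agreement": agreement,
        "severity": severity,
    }
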