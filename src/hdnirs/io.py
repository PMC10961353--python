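"""Session containers and standard-format I/O.

Recordings are exchanged as SNIRF (HDF5) files restricted to the
continuous-wave amplitude case: one data block with a ``measurementLists``
group (SNIRF v1.1 array style), 3-D probe positions, and one stim group per
marker label.  The factors table travels as CSV with a fixed column
dictionary (see :data:`FACTOR_COLUMNS`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import (
    HAIR_COLOR_LEVELS,
    HAIR_DENSITY_LEVELS,
    HAIR_LENGTH_LEVELS,
    MARKER_LABELS,
    SEX_LEVELS,
    Montage,
    build_default_montage,
)


class FormatError(ValueError):
    """Malformed or unsupported on-disk data."""


@dataclass
class SubjectFactors:
    """Per-session questionnaire answers; any field may be None (missing)."""

    age: float | None = None
    sex: str | None = None
    ethnicity: str | None = None
    hair_length: str | None = None
    hair_color: str | None = None
    hair_density: str | None = None
    alertness: float | None = None

    def __post_init__(self):
        _check_level("sex", self.sex, SEX_LEVELS)
        _check_level("hair_length", self.hair_length, HAIR_LENGTH_LEVELS)
        _check_level("hair_color", self.hair_color, HAIR_COLOR_LEVELS)
        _check_level("hair_density", self.hair_density, HAIR_DENSITY_LEVELS)

    @property
    def hair_length_ordinal(self) -> int | None:
        return None if self.hair_length is None else HAIR_LENGTH_LEVELS.index(self.hair_length)

    @property
    def hair_color_ordinal(self) -> int | None:
        """Rank by lightness: 0 = none/lightest ... 5 = black."""
        return None if self.hair_color is None else HAIR_COLOR_LEVELS.index(self.hair_color)

    @property
    def hair_density_ordinal(self) -> int | None:
        return None if self.hair_density is None else HAIR_DENSITY_LEVELS.index(self.hair_density)


def _check_level(name, value, levels):
    if value is not None and value not in levels:
        raise FormatError(f"unknown {name} level {value!r}; allowed: {levels}")


@dataclass
class SessionRecording:
    """Continuous dual-wavelength intensity plus markers and metadata.

    intensity: [n_channels x n_samples], channel order follows
    ``montage.channels``; fs in Hz; markers: list of (time_s, label).
    """

    intensity: np.ndarray
    fs: float
    markers: list[tuple[float, str]]
    subject_id: str
    session_number: int
    factors: SubjectFactors = field(default_factory=SubjectFactors)
    montage: Montage | None = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, float)
        span = self.intensity.shape[1] / self.fs
        for t, lab in self.markers:
            if not (0.0 <= t <= span):
                raise FormatError(f"marker at {t} s outside recording span {span} s")
            if lab not in MARKER_LABELS:
                raise FormatError(f"unknown marker label {lab!r}")
        if np.any(self.intensity < 0):
            raise FormatError("negative intensity")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def trial_markers(self, covert_only: bool = True) -> list[tuple[float, str]]:
        """Task-onset markers; labels collapsed to left/right."""
        keep = ("left", "right") if covert_only else (
            "left", "right", "overt_left", "overt_right")
        out = []
        for t, lab in self.markers:
            if lab in keep:
                out.append((t, "left" if lab.endswith("left") else "right"))
        return out

    def task_span_mask(self, guard_s: float = 1.0) -> np.ndarray:
        """Sample mask for the task blocks, excluding baseline and breaks.

        Blocks are delimited by block_start/block_end markers with a
        guard band trimmed from each edge (filter transients).
        """
        mask = np.zeros(self.n_samples, bool)
        starts = [t for t, lab in self.markers if lab == "block_start"]
        ends = [t for t, lab in self.markers if lab == "block_end"]
        for t0, t1 in zip(starts, ends):
            i0 = int(round((t0 + guard_s) * self.fs))
            i1 = int(round((t1 - guard_s) * self.fs))
            mask[max(i0, 0):max(i1, 0)] = True
        if not mask.any():  # no block markers recorded: use everything
            mask[:] = True
        return mask


# ---------------------------------------------------------------------------
# SNIRF I/O (CW amplitude subset)
# ---------------------------------------------------------------------------

def write_session(rec: SessionRecording, path, montage: Montage | None = None) -> None:
    montage = montage or rec.montage
    if montage is None:
        raise ValueError("a montage is required to write SNIRF")
    ch = montage.channels
    src_ids = [o.id for o in montage.sources]
    det_ids = [o.id for o in montage.detectors]
    src_index = {s: i + 1 for i, s in enumerate(src_ids)}
    det_index = {d: i + 1 for i, d in enumerate(det_ids)}
    wls = sorted(ch["wavelength"].unique())
    wl_index = {w: i + 1 for i, w in enumerate(wls)}

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=str(rec.subject_id))
        meta.create_dataset("SessionNumber", data=str(rec.session_number))
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wls, float))
        probe.create_dataset(
            "sourcePos3D",
            data=np.asarray([montage.optodes[s].position for s in src_ids], float),
        )
        probe.create_dataset(
            "detectorPos3D",
            data=np.asarray([montage.optodes[d].position for d in det_ids], float),
        )
        probe.create_dataset("sourceLabels", data=np.array(src_ids, dtype="S"))
        probe.create_dataset("detectorLabels", data=np.array(det_ids, dtype="S"))

        data = nirs.create_group("data1")
        data.create_dataset(
            "dataTimeSeries", data=np.ascontiguousarray(rec.intensity.T)
        )
        data.create_dataset(
            "time", data=np.arange(rec.n_samples, dtype=float) / rec.fs
        )
        # v1.0 per-channel measurementList groups (widest reader support)
        for k, (_, row) in enumerate(ch.iterrows(), start=1):
            g = data.create_group(f"measurementList{k}")
            g.create_dataset("sourceIndex", data=np.int32(src_index[row["source_id"]]))
            g.create_dataset("detectorIndex", data=np.int32(det_index[row["detector_id"]]))
            g.create_dataset("wavelengthIndex", data=np.int32(wl_index[row["wavelength"]]))
            g.create_dataset("dataType", data=np.int32(1))  # CW amplitude
            g.create_dataset("dataTypeIndex", data=np.int32(1))

        labels = sorted({lab for _, lab in rec.markers})
        for k, lab in enumerate(labels, start=1):
            onsets = [t for t, l in rec.markers if l == lab]
            stim = nirs.create_group(f"stim{k}")
            stim.create_dataset("name", data=lab)
            stim.create_dataset(
                "data",
                data=np.column_stack(
                    [onsets, np.zeros(len(onsets)), np.ones(len(onsets))]
                ),
            )


def read_session(path, montage: Montage | None = None) -> SessionRecording:
    """Read a CW-amplitude SNIRF file written by :func:`write_session`.

    Raises :class:`FormatError` on missing wavelength metadata and on
    non-CW data types (only dataType 1 is supported).
    """
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        if "probe" not in nirs or "wavelengths" not in nirs["probe"]:
            raise FormatError("missing wavelength metadata in SNIRF probe group")
        data = nirs["data1"]
        if "measurementLists" in data:
            dtypes = np.asarray(data["measurementLists/dataType"])
        else:
            mlkeys = sorted((k for k in data.keys()
                             if k.startswith("measurementList")),
                            key=lambda k: int(k.removeprefix("measurementList")))
            dtypes = np.asarray([int(data[k]["dataType"][()]) for k in mlkeys])
        if not np.all(dtypes == 1):
            raise FormatError(
                "unsupported SNIRF data type(s) "
                f"{sorted(set(dtypes.tolist()) - {1})}; only CW amplitude (1) is supported"
            )
        ts = np.asarray(data["dataTimeSeries"])
        t = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        meta = nirs["metaDataTags"]
        subject = _str(meta["SubjectID"][()])
        sessnum = int(_str(meta["SessionNumber"][()])) if "SessionNumber" in meta else 1
        markers: list[tuple[float, str]] = []
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            lab = _str(nirs[key]["name"][()])
            for row in np.atleast_2d(np.asarray(nirs[key]["data"])):
                markers.append((float(row[0]), lab))
        markers.sort(key=lambda m: m[0])
    return SessionRecording(
        intensity=ts.T,
        fs=fs,
        markers=markers,
        subject_id=subject,
        session_number=sessnum,
        montage=montage,
    )


def _str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


# ---------------------------------------------------------------------------
# Factors CSV
# ---------------------------------------------------------------------------

FACTOR_COLUMNS = [
    "subject_id", "session_number", "age", "sex", "ethnicity",
    "hair_length", "hair_color", "hair_density", "alertness",
]


def write_factors_table(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=FACTOR_COLUMNS).to_csv(path, index=False)


def read_factors_table(path) -> dict[tuple[str, int], SubjectFactors]:
    """Parse the cohort factors CSV into a (subject, session) -> factors map.

    Missing cells stay missing (None); unknown category levels raise
    :class:`FormatError` listing the allowed levels.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(FACTOR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"factors CSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, int], SubjectFactors] = {}
    for _, row in df.iterrows():
        def _get(col):
            v = row[col]
            return None if pd.isna(v) else v
        out[(str(row["subject_id"]), int(row["session_number"]))] = SubjectFactors(
            age=_get("age"),
            sex=_get("sex"),
            ethnicity=_get("ethnicity"),
            hair_length=_get("hair_length"),
            hair_color=_get("hair_color"),
            hair_density=_get("hair_density"),
            alertness=_get("alertness"),
        )
    return out


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def write_manifest(entries: list[dict], path, geometry: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump({"geometry": geometry, "sessions": entries}, fh, indent=1)


def read_cohort(manifest_path, montage: Montage | None = None):
    """Yield SessionRecording objects for every session in a cohort manifest,
    with per-session factors joined from the factors CSV."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent
    factors = read_factors_table(root / manifest["sessions"][0]["factors_csv"]) if \
        manifest["sessions"] else {}
    if montage is None:
        montage = build_default_montage(manifest.get("geometry"))
    for entry in manifest["sessions"]:
        rec = read_session(root / entry["path"], montage=montage)
        key = (rec.subject_id, rec.session_number)
        if key in factors:
            rec.factors = factors[key]
        yield rec
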