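"""Montage geometry for a tiled high-density CW-NIRS headset.

The headset is modelled as 12 rigid tiles (6 per hemisphere, a 2x3 grid
each), every tile holding 3 dual-wavelength sources and 4 detectors.  All
source-detector pairs at both wavelengths are enumerated as channels, so the
default montage has 36 x 48 x 2 = 3456 wavelength-resolved channels.

Coordinates live in a flat head-surface approximation in mm:
x = left -> right, y = posterior -> anterior, z unused (0) by default.
Channel "length" is the Euclidean source-detector distance; a channel's
sampling depth is approximated as length/4 (the standard banana-path rule of
thumb used for plotting and for the decoder's anisotropic smoothing metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

WAVELENGTHS_NM = (735.0, 850.0)

#: Ordinal encodings for the subject-factors table (fixed, documented).
HAIR_LENGTH_LEVELS = ("none", "short", "medium", "long")
#: Ranked by approximate lightness, light -> dark.
HAIR_COLOR_LEVELS = ("none", "gray", "blond", "red", "brown", "black")
HAIR_DENSITY_LEVELS = ("low", "medium", "high")
SEX_LEVELS = ("male", "female")

MARKER_LABELS = (
    "left",
    "right",
    "overt_left",
    "overt_right",
    "block_start",
    "block_end",
    "baseline_start",
    "baseline_end",
)


class MontageError(ValueError):
    """Invalid montage/geometry configuration."""


@dataclass(frozen=True)
class Optode:
    id: str
    kind: str  # "source" | "detector"
    tile_id: int
    position: tuple[float, float, float]
    wavelengths: tuple[float, ...] = ()  # sources only

    def __post_init__(self):
        if self.kind not in ("source", "detector"):
            raise MontageError(f"bad optode kind {self.kind!r}")
        if not np.all(np.isfinite(self.position)):
            raise MontageError(f"non-finite position for optode {self.id}")
        if self.kind == "source" and len(self.wavelengths) == 0:
            raise MontageError(f"source {self.id} has no wavelengths")


@dataclass(frozen=True)
class Tile:
    id: int
    hemisphere: str  # "left" | "right"
    source_ids: tuple[str, ...]
    detector_ids: tuple[str, ...]
    center: tuple[float, float, float]

    def __post_init__(self):
        if len(self.source_ids) != 3 or len(self.detector_ids) != 4:
            raise MontageError(
                f"tile {self.id}: needs 3 sources and 4 detectors, got "
                f"{len(self.source_ids)}/{len(self.detector_ids)}"
            )
        if self.hemisphere not in ("left", "right"):
            raise MontageError(f"tile {self.id}: bad hemisphere")


@dataclass
class Montage:
    """Optode geometry plus the exhaustive wavelength-resolved channel table.

    ``channels`` columns: id, source_id, detector_id, wavelength, length,
    mid_x, mid_y, mid_z, depth_proxy, roi, source_tile, detector_tile.
    """

    optodes: dict[str, Optode]
    tiles: dict[int, Tile]
    channels: pd.DataFrame
    geometry: dict = field(default_factory=dict)

    @property
    def sources(self) -> list[Optode]:
        return [o for o in self.optodes.values() if o.kind == "source"]

    @property
    def detectors(self) -> list[Optode]:
        return [o for o in self.optodes.values() if o.kind == "detector"]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def tile_center(self, tile_id: int) -> np.ndarray:
        return np.asarray(self.tiles[tile_id].center, float)

    def tile_pair_length(self, src_tile: int, det_tile: int) -> float:
        """Center-to-center distance between two tiles (tile-pair length)."""
        return float(
            np.linalg.norm(self.tile_center(src_tile) - self.tile_center(det_tile))
        )

    def channel_mask(self, min_mm: float = 0.0, max_mm: float = np.inf) -> np.ndarray:
        """Boolean mask of channels with min_mm <= length <= max_mm."""
        L = self.channels["length"].to_numpy()
        return (L >= min_mm) & (L <= max_mm)

    def roi_centers(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v, float)
                for k, v in self.geometry["roi_centers"].items()}


# ---------------------------------------------------------------------------
# Default geometry
# ---------------------------------------------------------------------------

def default_geometry_config(n_tile_cols: int = 3, n_tile_rows: int = 2) -> dict:
    """Parameterized default geometry: a 2 x n_tile_cols tile grid per
    hemisphere.

    The shipped pitches (20 mm between tile columns, 30 mm between rows,
    90 mm between the innermost columns of the two hemispheres) were chosen
    so that (a) intra-hemisphere tile-pair lengths fall in 20-50 mm with
    exactly 9 unordered pairs per hemisphere inside 25-45 mm, and (b) all
    inter-hemisphere channels are longer than 60 mm.  The bottom tile row
    (y=0) sits over motor cortex; the innermost bottom tiles define the two
    motor ROIs.
    """
    return {
        "n_tile_cols": n_tile_cols,
        "n_tile_rows": n_tile_rows,
        "col_pitch_mm": 20.0,
        "row_pitch_mm": 30.0,
        "hemisphere_gap_mm": 90.0,
        "roi_radius_mm": 30.0,
        # within-tile optode offsets (mm, tile-local x/y)
        "source_offsets": [[0.0, 8.5], [-7.36, -4.25], [7.36, -4.25]],
        "detector_offsets": [[0.0, 0.0], [9.1, 5.25], [-9.1, 5.25], [0.0, -10.5]],
        "wavelengths_nm": list(WAVELENGTHS_NM),
    }


def reduced_geometry_config() -> dict:
    """One tile per hemisphere; the desk-scale montage used for decoding
    simulations (48 wavelength-resolved channels of <=50 mm length)."""
    return default_geometry_config(n_tile_cols=1, n_tile_rows=1)


def load_geometry_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def build_default_montage(geometry_config: dict | None = None) -> Montage:
    """Construct the montage from a geometry config (see
    :func:`default_geometry_config`).

    Raises :class:`MontageError` on duplicate optode ids or malformed tiles.
    """
    cfg = dict(geometry_config or default_geometry_config())
    ncols = int(cfg.get("n_tile_cols", 3))
    nrows = int(cfg.get("n_tile_rows", 2))
    a = float(cfg["col_pitch_mm"])
    b = float(cfg["row_pitch_mm"])
    gap = float(cfg["hemisphere_gap_mm"])
    wls = tuple(float(w) for w in cfg["wavelengths_nm"])
    src_off = np.asarray(cfg["source_offsets"], float)
    det_off = np.asarray(cfg["detector_offsets"], float)

    optodes: dict[str, Optode] = {}
    tiles: dict[int, Tile] = {}

    tile_id = 0
    tile_centers = {}
    hemis = [h for h in (("left", -1.0), ("right", +1.0))
             if h[0] in cfg.get("hemispheres", ("left", "right"))]
    for hemi, sign in hemis:
        for row in range(nrows):  # row 0 = bottom (motor), row 1 = top
            for col in range(ncols):
                tile_id += 1
                # column 0 is the innermost column of the hemisphere
                cx = sign * (gap / 2.0 + col * a)
                cy = row * b
                center = (cx, cy, 0.0)
                tile_centers[tile_id] = (hemi, row, col, center)
                sids, dids = [], []
                for k, (ox, oy) in enumerate(src_off):
                    oid = f"S{tile_id}_{k + 1}"
                    if oid in optodes:
                        raise MontageError(f"duplicate optode id {oid}")
                    optodes[oid] = Optode(
                        oid, "source", tile_id, (cx + ox, cy + oy, 0.0), wls
                    )
                    sids.append(oid)
                for k, (ox, oy) in enumerate(det_off):
                    oid = f"D{tile_id}_{k + 1}"
                    if oid in optodes:
                        raise MontageError(f"duplicate optode id {oid}")
                    optodes[oid] = Optode(
                        oid, "detector", tile_id, (cx + ox, cy + oy, 0.0)
                    )
                    dids.append(oid)
                tiles[tile_id] = Tile(tile_id, hemi, tuple(sids), tuple(dids), center)

    # Motor ROI centers: innermost bottom-row tile of each hemisphere.
    roi_centers = {}
    for hemi, _ in hemis:
        # the innermost bottom-row tiles (two where the grid has them)
        inner_bottom = [
            t for t, (h, row, col, _) in tile_centers.items()
            if h == hemi and row == 0 and col < min(2, ncols)
        ]
        c = np.mean([tile_centers[t][3] for t in inner_bottom], axis=0)
        roi_centers[f"{hemi}_motor"] = c.tolist()
    cfg["roi_centers"] = roi_centers
    roi_radius = float(cfg["roi_radius_mm"])

    # Exhaustive channel enumeration.
    srcs = [o for o in optodes.values() if o.kind == "source"]
    dets = [o for o in optodes.values() if o.kind == "detector"]
    rows = []
    cid = 0
    for s in srcs:
        ps = np.asarray(s.position)
        for d in dets:
            pd_ = np.asarray(d.position)
            length = float(np.linalg.norm(ps - pd_))
            mid = (ps + pd_) / 2.0
            roi = "none"
            for name, c in roi_centers.items():
                if np.linalg.norm(mid - np.asarray(c)) <= roi_radius:
                    roi = name
                    break
            for wl in wls:
                rows.append(
                    (
                        cid, s.id, d.id, wl, length,
                        mid[0], mid[1], mid[2], length / 4.0, roi,
                        s.tile_id, d.tile_id,
                    )
                )
                cid += 1
    channels = pd.DataFrame(
        rows,
        columns=[
            "id", "source_id", "detector_id", "wavelength", "length",
            "mid_x", "mid_y", "mid_z", "depth_proxy", "roi",
            "source_tile", "detector_tile",
        ],
    )
    return Montage(optodes=optodes, tiles=tiles, channels=channels, geometry=cfg)


def montage_to_json_dict(montage: Montage) -> dict:
    """JSON-serializable export of the montage (geometry + optodes)."""
    return {
        "geometry": montage.geometry,
        "optodes": [
            {
                "id": o.id,
                "kind": o.kind,
                "tile_id": o.tile_id,
                "position": list(o.position),
                "wavelengths": list(o.wavelengths),
            }
            for o in montage.optodes.values()
        ],
        "tiles": [
            {
                "id": t.id,
                "hemisphere": t.hemisphere,
                "source_ids": list(t.source_ids),
                "detector_ids": list(t.detector_ids),
                "center": list(t.center),
            }
            for t in montage.tiles.values()
        ],
    }
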