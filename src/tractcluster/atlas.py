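"""Parametric toy reference atlas of spinal-cord white-matter tracts.

The real study validates against a digitized version of a published rat
atlas; this module provides a synthetic stand-in with the same topology:
an elliptical cord outline, a gray-matter "butterfly", and nine tract
regions tiling the white matter — dorsal column (FG medial, PSdc deep to
FG, FC lateral), the dorsal corticospinal tract (dCST) at the base of the
dorsal column, lateral structures (LatC, LSp, RST), and the lateral and
ventral funiculi (LF, VF).  Geometry is mirror-symmetric about the
midline and modulated smoothly along the rostro-caudal axis (cervical and
lumbar enlargements, sacral taper).

Coordinates: row = dorsoventral (row 0 dorsal), column = left–right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import LabelAtlas, mirror_lr
from .levels import LevelScheme, full_scheme
from .signatures import TRACT_NAMES

#: tract name -> label id (1-based; 0 is background)
TRACT_IDS = {name: i + 1 for i, name in enumerate(TRACT_NAMES)}

#: label id used for the merged ventrolateral funiculus (LF+VF)
MERGED_LVF_ID = TRACT_IDS["LF"]


@dataclass(frozen=True)
class ToyAtlasSpec:
    """Geometric parameters of the synthetic cord and its tract regions.

    Linear dimensions are fractions of the grid half-extent, so one spec
    scales to any grid shape.  ``merge_lf_vf`` collapses the lateral and
    ventral funiculi into a single ventrolateral label, matching the
    8-tract convention of the reference atlas.
    """

    shape: tuple[int, int] = (64, 64)
    pixel_size_um: float = 50.0
    cord_semiaxes: tuple[float, float] = (0.82, 0.90)  # (row, col) × half-extent
    #: gray-matter butterfly: (center_u, center_v, semi_u, semi_v) per lobe,
    #: in cord-normalized coordinates (u dorsoventral in [-1, 1], v left-right)
    gm_central: tuple[float, float, float, float] = (0.0, 0.0, 0.20, 0.36)
    gm_dorsal_horn: tuple[float, float, float, float] = (-0.38, 0.34, 0.34, 0.15)
    gm_ventral_horn: tuple[float, float, float, float] = (0.38, 0.30, 0.36, 0.24)
    dorsal_column_halfwidth: float = 0.30
    dorsal_column_floor: float = -0.08   # u below which the dorsal column ends
    fg_halfwidth: float = 0.16           # medial strip: FG (shallow), PSdc (deep)
    dcst_depth: float = 0.62             # fractional depth where dCST begins
    psdc_depth: float = 0.40             # fractional depth where PSdc begins
    latc_center: tuple[float, float] = (-0.50, 0.64)
    latc_radius: float = 0.13
    lsp_center: tuple[float, float] = (-0.26, 0.76)
    lsp_radius: float = 0.12
    rst_center: tuple[float, float] = (0.02, 0.68)
    rst_radius: float = 0.17
    lf_vf_split: float = 0.28            # u separating lateral from ventral funiculus
    merge_lf_vf: bool = False
    symmetric: bool = True
    #: rostro-caudal modulation: overall taper plus two enlargement bumps
    #: (center level index, width, amplitude) — cervical and lumbar
    taper: float = 0.35
    enlargements: tuple[tuple[float, float, float], ...] = (
        (5.0, 3.0, 0.12),
        (23.0, 2.5, 0.10),
    )
    level_modulation: bool = True


def level_scale(spec: ToyAtlasSpec, level_index: int, n_levels: int) -> float:
    """Smooth cord-size scale factor for a level (1-ish rostral, smaller caudal)."""
    if not spec.level_modulation or n_levels <= 1:
        return 1.0
    # map the level index onto the canonical 31-level axis so reduced
    # schemes see the same profile
    x = level_index * (30.0 / max(n_levels - 1, 1))
    s = 1.0 - spec.taper * (x / 30.0)
    for center, width, amp in spec.enlargements:
        s += amp * np.exp(-(((x - center) / width) ** 2))
    return float(s)


def _ellipse(u, v, lobe):
    cu, cv, su, sv = lobe
    return ((u - cu) / su) ** 2 + ((v - cv) / sv) ** 2 <= 1.0


def cord_geometry(
    spec: ToyAtlasSpec, level: str, scheme: LevelScheme | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (cord, gray-matter, u, v): masks and normalized coordinates."""
    scheme = scheme or full_scheme()
    idx = scheme.index_of(level)  # raises KeyError for unknown levels
    scale = level_scale(spec, idx, scheme.n_levels)

    h, w = spec.shape
    ry = spec.cord_semiaxes[0] * (h - 1) / 2 * scale
    rx = spec.cord_semiaxes[1] * (w - 1) / 2 * scale
    if ry >= (h - 1) / 2 or rx >= (w - 1) / 2 or min(ry, rx) < 3:
        raise ValueError(
            f"cord geometry leaves the grid or degenerates at level {level}: "
            f"semi-axes ({ry:.1f}, {rx:.1f}) px on a {h}x{w} grid"
        )

    rows = np.arange(h, dtype=float)[:, None] - (h - 1) / 2
    cols = np.arange(w, dtype=float)[None, :] - (w - 1) / 2
    u = np.broadcast_to(rows / ry, (h, w))  # dorsal = negative
    v = np.broadcast_to(cols / rx, (h, w))
    if spec.symmetric:
        v_eff = np.abs(v)
    else:
        v_eff = v

    cord = u**2 + v**2 <= 1.0
    gm = _ellipse(u, v_eff, spec.gm_central)
    gm |= _ellipse(u, v_eff, spec.gm_dorsal_horn)
    gm |= _ellipse(u, v_eff, spec.gm_ventral_horn)
    gm &= cord
    return cord, gm, u, v


def build_reference_atlas(
    spec: ToyAtlasSpec, level: str, scheme: LevelScheme | None = None
) -> tuple[LabelAtlas, np.ndarray]:
    """Construct the tract label map and white-matter mask for one level.

    Every white-matter pixel is assigned to exactly one tract; the label
    map is mirror-symmetric when ``spec.symmetric`` is set.  Raises if any
    tract region ends up empty (geometry incompatible with the grid).
    """
    cord, gm, u, v = cord_geometry(spec, level, scheme)
    wm = cord & ~gm
    av = np.abs(v)

    labels = np.zeros(spec.shape, dtype=np.int32)

    # dorsal column: between the dorsal horns, above the central gray
    dc = wm & (u < spec.dorsal_column_floor) & (av <= spec.dorsal_column_halfwidth)
    # fractional depth within the column: 0 at the dorsal cord surface,
    # 1 at the column floor
    with np.errstate(invalid="ignore"):
        u_surf = -np.sqrt(np.clip(1.0 - v**2, 0.0, None))
    denom = spec.dorsal_column_floor - u_surf
    depth = np.where(denom > 1e-9, (u - u_surf) / np.maximum(denom, 1e-9), 0.0)

    dcst = dc & (depth > spec.dcst_depth)
    medial = av <= spec.fg_halfwidth
    psdc = dc & ~dcst & medial & (depth > spec.psdc_depth)
    fg = dc & ~dcst & medial & (depth <= spec.psdc_depth)
    fc = dc & ~dcst & ~medial

    labels[fg] = TRACT_IDS["FG"]
    labels[psdc] = TRACT_IDS["PSdc"]
    labels[fc] = TRACT_IDS["FC"]
    labels[dcst] = TRACT_IDS["dCST"]

    # lateral nuclei / tracts: small round regions at the lateral margin
    for name, center, radius in (
        ("LatC", spec.latc_center, spec.latc_radius),
        ("LSp", spec.lsp_center, spec.lsp_radius),
        ("RST", spec.rst_center, spec.rst_radius),
    ):
        cu, cv = center
        blob = wm & ~dc & ((u - cu) ** 2 + (av - cv) ** 2 <= radius**2)
        labels[blob & (labels == 0)] = TRACT_IDS[name]

    # lateral / ventral funiculi tile the remaining white matter
    rest = wm & (labels == 0)
    labels[rest & (u < spec.lf_vf_split)] = TRACT_IDS["LF"]
    labels[rest & (u >= spec.lf_vf_split)] = TRACT_IDS["VF"]

    names = {TRACT_IDS[n]: n for n in TRACT_NAMES}
    if spec.merge_lf_vf:
        labels[labels == TRACT_IDS["VF"]] = MERGED_LVF_ID
        names = {i: n for i, n in names.items() if n != "VF"}
        names[MERGED_LVF_ID] = "LVF"

    present = set(np.unique(labels)) - {0}
    if present != set(names):
        missing = sorted(set(names) - present)
        raise ValueError(
            f"tract regions {[names[i] for i in missing]} are empty at level "
            f"{level}; the grid is too coarse for this spec"
        )

    atlas = LabelAtlas(
        labels=labels, names=names, pixel_size_um=spec.pixel_size_um, level=level
    )
    if spec.symmetric:
        assert np.array_equal(atlas.labels, mirror_lr(atlas.labels))
    return atlas, wm
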