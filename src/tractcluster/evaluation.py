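"""Matching parcels to reference tracts: overlap, coloring, scores, figures.

Cluster-to-tract correspondence is driven by an overlap matrix (pixel
co-occurrence counts against discrete labels, or summed partial volume
against a soft atlas).  Each cluster inherits the hue of its
maximal-overlap tract; when several clusters share a tract their
intensities are spread over [0.2, 1] in proportion to their overlap
fraction, reproducing the hemi-section figure convention (clusters on the
left half, reference atlas on the right half, shared palette).

For synthetic data with known ground truth, the Adjusted Rand Index gives
the quantitative recovery score that visual inspection cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .images import LabelAtlas, Parcellation, SoftAtlas

#: distinguishable hues for up to 9 tracts (RGB in [0, 1]); order follows
#: tract ids so the same tract keeps its color across figures
DEFAULT_PALETTE = {
    1: (0.10, 0.10, 0.10),   # FG    black
    2: (0.00, 0.60, 0.20),   # PSdc  green
    3: (0.85, 0.10, 0.10),   # FC    red
    4: (0.00, 0.75, 0.85),   # dCST  cyan
    5: (0.95, 0.60, 0.10),   # LatC  orange
    6: (0.95, 0.90, 0.10),   # LSp   yellow
    7: (0.55, 0.10, 0.65),   # RST   purple
    8: (0.15, 0.25, 0.85),   # LF    blue
    9: (0.90, 0.40, 0.70),   # VF    pink
}


@dataclass
class OverlapMatrix:
    """Cluster × tract co-occurrence mass."""

    matrix: np.ndarray
    cluster_ids: tuple[int, ...]
    tract_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.cluster_ids), len(self.tract_ids)):
            raise ValueError("matrix shape does not match id lists")
        if m.size and m.min() < 0:
            raise ValueError("overlap mass must be non-negative")
        self.matrix = m

    def total_mass(self) -> float:
        return float(self.matrix.sum())


def overlap_matrix(
    parc: Parcellation, atlas: LabelAtlas | SoftAtlas
) -> OverlapMatrix:
    """Co-occurrence mass between clusters and reference tracts.

    Discrete atlas: entry (c, t) counts pixels labeled cluster c and tract
    t.  Soft atlas: entry (c, t) sums tract t's partial volume over the
    pixels of cluster c.
    """
    if parc.shape != atlas.shape:
        raise ValueError("parcellation and atlas grids differ")
    cluster_ids = tuple(int(c) for c in np.unique(parc.labels) if c != 0)
    if isinstance(atlas, SoftAtlas):
        tract_ids = atlas.tract_ids
        m = np.zeros((len(cluster_ids), len(tract_ids)))
        pv = np.nan_to_num(atlas.partial_volumes, nan=0.0)
        for i, c in enumerate(cluster_ids):
            sel = parc.labels == c
            m[i] = pv[:, sel].sum(axis=1)
    else:
        tract_ids = tuple(int(t) for t in sorted(atlas.names))
        m = np.zeros((len(cluster_ids), len(tract_ids)))
        for i, c in enumerate(cluster_ids):
            sel = parc.labels == c
            for j, t in enumerate(tract_ids):
                m[i, j] = np.count_nonzero(atlas.labels[sel] == t)
    return OverlapMatrix(matrix=m, cluster_ids=cluster_ids, tract_ids=tract_ids)


@dataclass
class ColorAssignment:
    """Per-cluster hue (from the best-matching tract) and intensity."""

    hues: dict[int, tuple[float, float, float]]
    intensities: dict[int, float]
    matched_tract: dict[int, int]

    def __post_init__(self) -> None:
        for c, level in self.intensities.items():
            if not 0.2 - 1e-9 <= level <= 1 + 1e-9:
                raise ValueError(f"cluster {c}: intensity {level} outside [0.2, 1]")

    def rgb(self, cluster: int) -> tuple[float, float, float]:
        r, g, b = self.hues[cluster]
        s = self.intensities[cluster]
        return (r * s, g * s, b * s)


def match_and_color(
    om: OverlapMatrix,
    tract_palette: dict[int, tuple[float, float, float]] | None = None,
) -> ColorAssignment:
    """Assign each cluster its argmax tract's hue and an overlap intensity.

    Clusters sharing a tract get intensities 0.2 + 0.8 · (f / f_max),
    where f is the fraction of the tract covered by the cluster and f_max
    the largest such fraction among the sharing clusters — the dominant
    cluster is shown at full intensity, minor ones dimmer but never below
    0.2.  Ties resolve toward the larger cluster, then the smaller id.
    """
    if om.matrix.size == 0 or om.total_mass() == 0:
        raise ValueError("overlap matrix has no mass")
    palette = tract_palette or DEFAULT_PALETTE
    hues: dict[int, tuple[float, float, float]] = {}
    matched: dict[int, int] = {}
    frac: dict[int, float] = {}
    sizes = om.matrix.sum(axis=1)
    tract_mass = om.matrix.sum(axis=0)
    for i, c in enumerate(om.cluster_ids):
        j = int(np.argmax(om.matrix[i]))
        t = om.tract_ids[j]
        matched[c] = t
        hues[c] = palette[t]
        frac[c] = float(om.matrix[i, j] / max(tract_mass[j], 1e-12))

    intensities: dict[int, float] = {}
    for t in set(matched.values()):
        sharing = [c for c in om.cluster_ids if matched[c] == t]
        # dominant cluster = largest overlap fraction; ties → larger
        # cluster, then smaller id
        order = sorted(
            sharing,
            key=lambda c: (-frac[c], -sizes[om.cluster_ids.index(c)], c),
        )
        f_max = frac[order[0]]
        for c in sharing:
            intensities[c] = 0.2 + 0.8 * (frac[c] / max(f_max, 1e-12))
        intensities[order[0]] = 1.0
    return ColorAssignment(hues=hues, intensities=intensities, matched_tract=matched)


def ari(parc: Parcellation, truth: LabelAtlas) -> float:
    """Adjusted Rand Index between a parcellation and ground-truth labels,
    over pixels covered by both."""
    if parc.shape != truth.shape:
        raise ValueError("grids differ")
    joint = parc.mask & (truth.labels > 0)
    if not joint.any():
        raise ValueError("no jointly labeled pixels")
    return float(adjusted_rand_score(truth.labels[joint], parc.labels[joint]))


def contiguous_truth(atlas: LabelAtlas, scheme: str = "axial4") -> LabelAtlas:
    """Relabel ground-truth tracts into spatially contiguous regions.

    Bilateral tracts occupy two disjoint blobs; a connectivity-constrained
    clustering can only ever recover contiguous parcels, so exact-recovery
    scores compare against the per-component relabeling.  Component ids are
    assigned in tract-id order; names become e.g. ``FC#1``, ``FC#2``.
    """
    from scipy import ndimage as ndi

    structure = (
        np.ones((3, 3), dtype=bool)
        if scheme == "axial8"
        else ndi.generate_binary_structure(2, 1)
    )
    out = np.zeros(atlas.shape, dtype=np.int32)
    names: dict[int, str] = {}
    next_id = 1
    for t in sorted(atlas.names):
        comp, n = ndi.label(atlas.labels == t, structure=structure)
        for k in range(1, n + 1):
            out[comp == k] = next_id
            suffix = f"#{k}" if n > 1 else ""
            names[next_id] = f"{atlas.names[t]}{suffix}"
            next_id += 1
    return LabelAtlas(
        labels=out, names=names, pixel_size_um=atlas.pixel_size_um, level=atlas.level
    )


def tract_recalls(parc: Parcellation, truth: LabelAtlas) -> dict[str, float]:
    """Per-tract recall of the best-matching cluster.

    For each tract, the cluster with the largest overlap is taken as its
    match; recall = matched overlap / tract size.  High recall means one
    cluster captures most of the tract.
    """
    om = overlap_matrix(parc, truth)
    recalls: dict[str, float] = {}
    for j, t in enumerate(om.tract_ids):
        size = om.matrix[:, j].sum()
        if size == 0:
            continue
        recalls[truth.names[t]] = float(om.matrix[:, j].max() / size)
    return recalls


def render_hemisection(
    parc: Parcellation,
    atlas: LabelAtlas,
    colors: ColorAssignment,
    out_path,
    tract_palette: dict[int, tuple[float, float, float]] | None = None,
    upscale: int = 4,
) -> np.ndarray:
    """Write a hemi-section figure: clusters left, reference atlas right.

    Both halves share the tract palette and the pixel grid (constant
    spatial scale).  The image is written deterministically (plain PNG via
    Pillow), so repeated renders are byte-identical.
    """
    from PIL import Image

    palette = tract_palette or DEFAULT_PALETTE
    h, w = parc.shape
    rgb = np.zeros((h, w, 3))
    mid = w // 2
    for c in np.unique(parc.labels):
        if c == 0:
            continue
        sel = parc.labels == int(c)
        sel[:, mid:] = False
        rgb[sel] = colors.rgb(int(c))
    for t in np.unique(atlas.labels):
        if t == 0:
            continue
        sel = atlas.labels == int(t)
        sel[:, :mid] = False
        rgb[sel] = palette[int(t)]
    img8 = (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    if upscale > 1:
        img8 = np.repeat(np.repeat(img8, upscale, axis=0), upscale, axis=1)
    Image.fromarray(img8).save(out_path, format="PNG")
    return rgb
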