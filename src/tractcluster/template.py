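"""Across-subject morphometric template and region-wise aggregation.

Template construction mirrors the histology workflow: per level, subjects'
white-matter masks are affinely aligned, the axon-density channel drives a
nonrigid refinement, metric maps are resampled into the common space,
averaged pixelwise over subjects, and right–left symmetry is imposed.
Region-wise aggregation then chains adjacent-slice registrations toward a
region's mid-slice, warps all metric channels and one-hot tract channels,
and averages along the superior–inferior axis, yielding one 2D stack and
one partial-volume (soft) atlas per region.
"""

from __future__ import annotations

import numpy as np

from .images import SENTINEL, LabelAtlas, MetricStack, SoftAtlas, mirror_lr
from .levels import LevelScheme
from .registration import (
    RegistrationConfig,
    apply_affine,
    apply_field,
    compose,
    estimate_affine,
    estimate_nonrigid,
    stepwise_chain,
)
from .synthetic import Cohort


def make_wm_mask(stack: MetricStack) -> np.ndarray:
    """White-matter mask = pixels where every metric channel is defined."""
    mask = np.ones(stack.shape, dtype=bool)
    for name in stack.metric_names:
        mask &= np.isfinite(stack.channels[name])
    if not mask.any():
        raise ValueError("white-matter mask is empty")
    return mask


def symmetrize(image: np.ndarray) -> np.ndarray:
    """Average an image with its left–right mirror (midline = center column).

    NaN-aware: a pixel defined on either side is defined in the output, so
    the result (including its defined-pixel set) is exactly mirror
    symmetric, and the operation is idempotent.
    """
    image = np.asarray(image, dtype=float)
    return _nanstack_mean([image, mirror_lr(image)])


def _nanstack_mean(layers: list[np.ndarray]) -> np.ndarray:
    """Pixelwise mean over defined values; all-undefined pixels stay NaN."""
    arr = np.stack(layers)
    defined = np.isfinite(arr)
    count = defined.sum(axis=0)
    total = np.where(defined, arr, 0.0).sum(axis=0)
    return np.where(count > 0, total / np.maximum(count, 1), SENTINEL)


def build_template(
    cohort: Cohort,
    level: str,
    cfg: RegistrationConfig | None = None,
    symmetric: bool = True,
) -> MetricStack:
    """Average co-registered subjects at one level into a template stack.

    The first subject's grid serves as the provisional common space; each
    other subject is aligned with an affine on the white-matter mask
    followed by a nonrigid refinement on the axon-density channel.
    """
    subjects = cohort.at_level(level)
    if not subjects:
        raise ValueError(f"no subjects at level {level!r}")
    cfg = cfg or RegistrationConfig()
    ref = subjects[0]
    ref_mask = ref.stack.mask.astype(float)
    ref_density = ref.stack.channels["axon_density"]

    warped: list[dict[str, np.ndarray]] = []
    for subj in subjects:
        if subj is ref:
            warped.append(dict(subj.stack.channels))
            continue
        mov_mask = subj.stack.mask.astype(float)
        tf = estimate_affine(ref_mask, mov_mask)
        density_aff = apply_affine(tf, subj.stack.channels["axon_density"])
        fld = estimate_nonrigid(ref_density, density_aff, cfg)
        total = compose(fld, tf.as_field(ref_mask.shape))
        warped.append(
            {m: apply_field(total, ch) for m, ch in subj.stack.channels.items()}
        )

    names = ref.stack.metric_names
    extra = [m for m in ref.stack.channels if m not in names]
    channels = {
        m: _nanstack_mean([w[m] for w in warped]) for m in (*names, *extra)
    }
    # template support = pixels covered by at least half the subjects
    # (evaluated after symmetrization so the mask stays mirror-symmetric);
    # the union rim would carry single-subject values
    coverage = np.sum(
        [np.isfinite(w["axon_density"]) for w in warped], axis=0
    ).astype(float)
    if symmetric:
        channels = {m: symmetrize(ch) for m, ch in channels.items()}
        coverage = symmetrize(coverage)
    keep = coverage >= len(warped) / 2
    for ch in channels.values():
        ch[~keep] = SENTINEL
    stack = MetricStack(
        channels=channels,
        mask=np.ones(ref.stack.shape, dtype=bool),
        pixel_size_um=ref.stack.pixel_size_um,
        level=level,
        metric_names=names,
    )
    stack.mask = make_wm_mask(stack)
    return stack


def build_template_stacks(
    cohort: Cohort, cfg: RegistrationConfig | None = None
) -> dict[str, MetricStack]:
    """Templates for every level of the cohort's scheme, keyed by level."""
    return {lv: build_template(cohort, lv, cfg) for lv in cohort.scheme.levels}


def mid_slice_index(n: int) -> int:
    """Reference slice within a region: the lower median index."""
    return (n - 1) // 2


def aggregate_region(
    template_slices: list[MetricStack],
    atlas_slices: list[LabelAtlas],
    region: str,
    cfg: RegistrationConfig | None = None,
) -> tuple[MetricStack, SoftAtlas]:
    """Register a region's slices to its mid-slice and average them.

    The stepwise chain is estimated on the axon-density channel only; the
    chained field of each slice is then applied to all metric channels
    (linear interpolation) and to the one-hot tract channels (also linear,
    so the superior–inferior average yields partial volumes in [0, 1]).
    """
    if not template_slices:
        raise ValueError(f"region {region!r} has no slices")
    if len(template_slices) != len(atlas_slices):
        raise ValueError("template and atlas slice lists differ in length")
    cfg = cfg or RegistrationConfig()
    ref = mid_slice_index(len(template_slices))
    chain = stepwise_chain(
        [s.channels["axon_density"] for s in template_slices], ref, cfg
    )

    names = template_slices[ref].metric_names
    metric_layers: dict[str, list[np.ndarray]] = {m: [] for m in names}
    tract_ids = sorted(atlas_slices[ref].names)
    tract_layers: dict[int, list[np.ndarray]] = {t: [] for t in tract_ids}
    for stack, atlas, fld in zip(template_slices, atlas_slices, chain.fields):
        for m in names:
            metric_layers[m].append(apply_field(fld, stack.channels[m]))
        one_hot = atlas.one_hot()
        for t, plane in zip(one_hot.tract_ids, one_hot.partial_volumes):
            tract_layers[t].append(apply_field(fld, plane, "linear", cval=0.0))

    channels = {m: _nanstack_mean(layers) for m, layers in metric_layers.items()}
    region_stack = MetricStack(
        channels=channels,
        mask=np.ones(template_slices[ref].shape, dtype=bool),
        pixel_size_um=template_slices[ref].pixel_size_um,
        level=region,
        metric_names=names,
    )
    region_stack.mask = make_wm_mask(region_stack)

    pv = np.stack(
        [np.clip(np.mean(tract_layers[t], axis=0), 0.0, 1.0) for t in tract_ids]
    )
    soft = SoftAtlas(
        partial_volumes=pv,
        tract_ids=tuple(tract_ids),
        names=dict(atlas_slices[ref].names),
        pixel_size_um=atlas_slices[ref].pixel_size_um,
    )
    return region_stack, soft


def aggregate_all_regions(
    templates: dict[str, MetricStack],
    atlases: dict[str, LabelAtlas],
    scheme: LevelScheme,
    cfg: RegistrationConfig | None = None,
) -> dict[str, tuple[MetricStack, SoftAtlas]]:
    """Aggregate every region of the scheme: region -> (stack, soft atlas)."""
    out = {}
    for region in scheme.regions:
        levels = scheme.levels_in(region)
        out[region] = aggregate_region(
            [templates[lv] for lv in levels],
            [atlases[lv] for lv in levels],
            region,
            cfg,
        )
    return out
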