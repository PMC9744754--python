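"""Synthetic subject-level morphometric maps with tract-wise structure.

Each synthetic subject is produced by (1) smoothly deforming the toy
reference atlas (emulating inter-subject anatomical variability), then
(2) drawing every pixel's metric value from a truncated normal around its
tract's signature mean.  Truncation keeps metrics physically bounded
(non-negative; fractions and the g-ratio capped at their upper bound).
Noise is white at the map resolution — the generator emulates the
downsampled 50 μm metric maps, not raw electron microscopy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .atlas import ToyAtlasSpec, build_reference_atlas
from .images import SENTINEL, LabelAtlas, MetricStack
from .levels import LevelScheme, full_scheme
from .registration import DisplacementField, apply_field
from .signatures import ALL_METRICS, METRICS, TractSignature, signatures_by_id


@dataclass
class SubjectSample:
    """One synthetic subject at one spinal level, with ground truth."""

    subject_id: int
    level: str
    stack: MetricStack
    truth: LabelAtlas
    deformation: DisplacementField
    seed: int

    def __post_init__(self) -> None:
        if self.stack.shape != self.truth.shape:
            raise ValueError("metric stack and ground-truth labels share no grid")


def smooth_displacement(
    shape: tuple[int, int],
    amplitude: float,
    rng: np.random.Generator,
    coarse: int = 6,
) -> DisplacementField:
    """Random smooth displacement with peak magnitude ``amplitude`` pixels.

    Gaussian noise on a coarse control grid is upsampled with cubic spline
    interpolation; the result is rescaled so its largest vector has the
    requested magnitude.  Small amplitudes relative to the coarse-grid
    spacing keep the map invertible (displacement gradients ≪ 1).
    """
    if amplitude < 0:
        raise ValueError("deformation amplitude must be non-negative")
    vec = np.zeros((*shape, 2))
    if amplitude > 0:
        coarse_field = rng.standard_normal((coarse, coarse, 2))
        zoom = (shape[0] / coarse, shape[1] / coarse)
        vec = np.stack(
            [
                ndimage.zoom(coarse_field[..., k], zoom, order=3, mode="nearest")
                for k in (0, 1)
            ],
            axis=-1,
        )[: shape[0], : shape[1]]
        peak = np.hypot(vec[..., 0], vec[..., 1]).max()
        if peak > 0:
            vec *= amplitude / peak
    return DisplacementField(vec)


def _draw_metric(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    bounds: tuple[float, float],
    size: int,
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    lo, hi = bounds
    a = (lo - mean) / sd
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_subject(
    atlas: LabelAtlas,
    signatures: dict[str, TractSignature],
    noise_scale: float = 1.0,
    deform_amplitude: float = 0.0,
    seed: int = 0,
    subject_id: int = 0,
    metrics: tuple[str, ...] = ALL_METRICS,
) -> SubjectSample:
    """Draw one subject's metric maps from a (deformed) tract atlas.

    Pixel values within tract ``t`` follow a truncated normal with mean
    ``signature(t).mean`` and standard deviation ``signature(t).sd ×
    noise_scale``.  The same smooth random deformation warps the label map
    (nearest-neighbor), so metrics and ground truth stay aligned.  The
    same seed reproduces the sample bit-for-bit.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    # a merged ventrolateral (LVF) label reuses LF's id and thus LF's signature
    by_id = signatures_by_id(signatures)
    present = set(atlas.present_labels().tolist())
    missing = present - set(by_id)
    if missing:
        raise ValueError(f"no signature for atlas labels {sorted(missing)}")

    rng = np.random.default_rng(seed)
    field = smooth_displacement(atlas.shape, deform_amplitude, rng)
    labels = apply_field(field, atlas.labels, "nearest")
    truth = LabelAtlas(
        labels=labels,
        names=dict(atlas.names),
        pixel_size_um=atlas.pixel_size_um,
        level=atlas.level,
    )
    mask = labels > 0

    channels: dict[str, np.ndarray] = {}
    for metric in metrics:
        ch = np.full(atlas.shape, SENTINEL)
        for tract_id in sorted(present):
            sig = by_id[tract_id]
            sel = labels == tract_id
            ch[sel] = _draw_metric(
                rng,
                sig.means[metric],
                sig.sds[metric] * noise_scale,
                sig.bounds(metric),
                int(sel.sum()),
            )
        channels[metric] = ch

    stack = MetricStack(
        channels=channels,
        mask=mask,
        pixel_size_um=atlas.pixel_size_um,
        level=atlas.level,
        metric_names=tuple(m for m in METRICS if m in metrics),
    )
    return SubjectSample(
        subject_id=subject_id,
        level=atlas.level or "?",
        stack=stack,
        truth=truth,
        deformation=field,
        seed=seed,
    )


@dataclass
class Cohort:
    """Samples indexed by (subject_id, level) plus the generation manifest."""

    samples: dict[tuple[int, str], SubjectSample]
    scheme: LevelScheme
    manifest: dict

    def at_level(self, level: str) -> list[SubjectSample]:
        return [s for (_, lv), s in sorted(self.samples.items()) if lv == level]

    def for_subject(self, subject_id: int) -> list[SubjectSample]:
        return [
            self.samples[(subject_id, lv)]
            for lv in self.scheme.levels
            if (subject_id, lv) in self.samples
        ]

    def __len__(self) -> int:
        return len(self.samples)


def generate_cohort(
    spec: ToyAtlasSpec,
    signatures: dict[str, TractSignature],
    n_subjects: int = 5,
    scheme: LevelScheme | None = None,
    seed: int = 0,
    noise_scale: float = 1.0,
    deform_amplitude: float = 1.5,
    metrics: tuple[str, ...] = ALL_METRICS,
) -> Cohort:
    """Generate a full subjects × levels cohort with a reproducible manifest.

    Per-sample seeds are derived deterministically from the master seed via
    ``numpy``'s seed-sequence spawning, so the whole cohort (and its
    manifest) is reproducible from one integer.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    scheme = scheme or full_scheme()
    samples: dict[tuple[int, str], SubjectSample] = {}
    sample_seeds: dict[str, int] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects * scheme.n_levels)
    k = 0
    for subject in range(n_subjects):
        for level in scheme.levels:
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            atlas, _ = build_reference_atlas(spec, level, scheme)
            samples[(subject, level)] = sample_subject(
                atlas,
                signatures,
                noise_scale=noise_scale,
                deform_amplitude=deform_amplitude,
                seed=child_seed,
                subject_id=subject,
                metrics=metrics,
            )
            sample_seeds[f"{subject}:{level}"] = child_seed
    manifest = {
        "master_seed": int(seed),
        "n_subjects": int(n_subjects),
        "levels": scheme.levels,
        "noise_scale": float(noise_scale),
        "deform_amplitude": float(deform_amplitude),
        "grid_shape": list(spec.shape),
        "pixel_size_um": float(spec.pixel_size_um),
        "metrics": list(metrics),
        "sample_seeds": sample_seeds,
    }
    return Cohort(samples=samples, scheme=scheme, manifest=manifest)
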