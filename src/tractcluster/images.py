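"""In-memory containers for morphometric maps, label atlases and parcellations.

Conventions used throughout the package:

* arrays are 2D ``(rows, cols)`` with pixel-center, 0-based indices;
  row = dorsoventral axis (row 0 is dorsal), column = left–right axis;
* pixels outside the white-matter mask carry ``NaN`` in metric channels
  (0 is a legal metric value, so it can never be the missing marker);
* label images use integer labels with 0 = background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signatures import METRICS

#: missing-value marker for metric channels outside the mask
SENTINEL = np.nan


def mirror_lr(image: np.ndarray) -> np.ndarray:
    """Mirror an image about the vertical midline (flip the column axis)."""
    return image[..., ::-1]


@dataclass
class MetricStack:
    """Aligned morphometric channels + white-matter mask on one axial grid.

    ``channels`` maps metric name -> 2D float array; ``metric_names`` fixes
    the order clustering consumes.  Values are finite inside ``mask`` and
    ``NaN`` outside.
    """

    channels: dict[str, np.ndarray]
    mask: np.ndarray
    pixel_size_um: float = 50.0
    level: str | None = None
    metric_names: tuple[str, ...] = METRICS

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for name in self.metric_names:
            if name not in self.channels:
                raise ValueError(f"missing metric channel {name!r}")
        for name, ch in self.channels.items():
            ch = np.asarray(ch, dtype=float)
            if ch.shape != self.mask.shape:
                raise ValueError(f"channel {name!r} grid differs from mask")
            self.channels[name] = ch

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def array(self, metrics: tuple[str, ...] | None = None) -> np.ndarray:
        """Stack the requested channels (default: canonical order) to (C, H, W)."""
        names = self.metric_names if metrics is None else metrics
        return np.stack([self.channels[m] for m in names], axis=0)

    def validate(self) -> None:
        """Raise if any channel is non-finite inside the mask."""
        for name in self.metric_names:
            if not np.all(np.isfinite(self.channels[name][self.mask])):
                raise ValueError(f"channel {name!r} has non-finite values inside mask")


@dataclass
class LabelAtlas:
    """Discrete tract labels on an axial grid (0 = background)."""

    labels: np.ndarray
    names: dict[int, str]
    pixel_size_um: float = 50.0
    level: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def present_labels(self) -> np.ndarray:
        """Distinct non-background labels present in the image."""
        vals = np.unique(self.labels)
        return vals[vals != 0]

    def one_hot(self) -> "SoftAtlas":
        """Expand to one partial-volume channel per tract (exact 0/1)."""
        ids = sorted(self.names)
        pv = np.stack([(self.labels == i).astype(float) for i in ids], axis=0)
        return SoftAtlas(
            partial_volumes=pv,
            tract_ids=tuple(ids),
            names=dict(self.names),
            pixel_size_um=self.pixel_size_um,
        )


@dataclass
class SoftAtlas:
    """Per-tract partial-volume channels in [0, 1], shape (T, H, W)."""

    partial_volumes: np.ndarray
    tract_ids: tuple[int, ...]
    names: dict[int, str]
    pixel_size_um: float = 50.0

    def __post_init__(self) -> None:
        pv = np.asarray(self.partial_volumes, dtype=float)
        if pv.ndim != 3 or pv.shape[0] != len(self.tract_ids):
            raise ValueError("partial_volumes must be (n_tracts, H, W)")
        if np.nanmin(pv) < -1e-9 or np.nanmax(pv) > 1 + 1e-6:
            raise ValueError("partial volumes must lie in [0, 1]")
        self.partial_volumes = pv

    @property
    def shape(self) -> tuple[int, int]:
        return self.partial_volumes.shape[1:]

    def validate_partition(self, mask: np.ndarray, tol: float = 1e-6) -> None:
        """Check the per-pixel sum over tracts stays ≤ 1 (+tol) inside ``mask``."""
        total = np.nansum(self.partial_volumes, axis=0)[mask]
        if total.size and total.max() > 1 + tol:
            raise ValueError("per-pixel partial volumes exceed 1")


@dataclass
class Parcellation:
    """Cluster labels over a mask (1..k inside, 0 outside) with provenance."""

    labels: np.ndarray
    n_clusters: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape
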