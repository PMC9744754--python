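"""Per-tract morphometric signatures.

A *signature* is the mean and standard deviation of each morphometric
metric within one white-matter tract; the synthetic generator draws pixel
values from these distributions.  Defaults live in
``data/default_signatures.yaml`` and are anchored to the published template
statistics (density 78,000–168,800 axons/mm², diameter 1.1–1.35 μm, myelin
thickness 0.35–0.5 μm, myelin volume fraction 15–30%, flat g-ratio ≈ 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

#: canonical clustering metrics, in the fixed channel order the pipeline uses
METRICS = (
    "axon_density",
    "axon_diameter",
    "axon_volume_fraction",
    "g_ratio",
    "myelin_thickness",
)

#: all metrics the generator can emulate (adds the myelin volume fraction,
#: reported as a template statistic but not part of the default feature set)
ALL_METRICS = METRICS + ("myelin_volume_fraction",)

#: tract short names in tract_id order (dorsal column, corticospinal,
#: lateral structures, lateral/ventral funiculi)
TRACT_NAMES = ("FG", "PSdc", "FC", "dCST", "LatC", "LSp", "RST", "LF", "VF")

#: tracts forming the dorsal column proper (excludes the dCST, which the
#: template statistics report separately)
DORSAL_COLUMN = ("FG", "PSdc", "FC")

#: metrics bounded above by 1 (fractions and ratios); truncation bounds for
#: the noise model.  myelin_volume_fraction is a percentage, bounded by 100.
_UPPER_BOUND = {
    "axon_volume_fraction": 1.0,
    "g_ratio": 1.0,
    "myelin_volume_fraction": 100.0,
}


@dataclass(frozen=True)
class TractSignature:
    """Morphometric signature of one tract: per-metric (mean, sd)."""

    tract_id: int
    name: str
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.name not in TRACT_NAMES:
            raise ValueError(f"unknown tract name {self.name!r}")
        for metric in ALL_METRICS:
            if metric not in self.means or metric not in self.sds:
                raise ValueError(f"signature {self.name}: missing metric {metric!r}")
        if any(m <= 0 for m in self.means.values()):
            raise ValueError(f"signature {self.name}: means must be strictly positive")
        if not 0 < self.means["g_ratio"] < 1:
            raise ValueError(f"signature {self.name}: g_ratio mean must lie in (0, 1)")
        if not 0 < self.means["axon_volume_fraction"] < 1:
            raise ValueError(
                f"signature {self.name}: axon_volume_fraction mean must lie in (0, 1)"
            )
        if any(s < 0 for s in self.sds.values()):
            raise ValueError(f"signature {self.name}: sds must be non-negative")

    def bounds(self, metric: str) -> tuple[float, float]:
        """Physical truncation bounds (low, high) for ``metric``."""
        return 0.0, _UPPER_BOUND.get(metric, float("inf"))


def default_signatures() -> dict[str, TractSignature]:
    """Load the default signature set, keyed by tract name."""
    text = resources.files("tractcluster.data").joinpath(
        "default_signatures.yaml"
    ).read_text()
    raw = yaml.safe_load(text)["tracts"]
    out: dict[str, TractSignature] = {}
    for name, entry in raw.items():
        means = {m: float(entry[m]["mean"]) for m in ALL_METRICS}
        sds = {m: float(entry[m]["sd"]) for m in ALL_METRICS}
        out[name] = TractSignature(
            tract_id=int(entry["tract_id"]), name=name, means=means, sds=sds
        )
    if tuple(sorted(out, key=lambda n: out[n].tract_id)) != TRACT_NAMES:
        raise ValueError("default signature file does not cover the 9 tracts")
    return out


def signatures_by_id(signatures: dict[str, TractSignature]) -> dict[int, TractSignature]:
    return {sig.tract_id: sig for sig in signatures.values()}
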