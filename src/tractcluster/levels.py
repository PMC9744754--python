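"""Spinal level scheme: 31 axial levels (C1–S4) grouped into 4 regions.

The rat spinal cord has 8 cervical, 13 thoracic, 6 lumbar and 4 sacral
segments.  Every slice-indexed structure in the pipeline is keyed by these
level labels, and region-wise aggregation groups them by region.
"""

from __future__ import annotations

from dataclasses import dataclass, field


REGION_NAMES = ("cervical", "thoracic", "lumbar", "sacral")

_DEFAULT_COUNTS = {"cervical": 8, "thoracic": 13, "lumbar": 6, "sacral": 4}
_PREFIX = {"cervical": "C", "thoracic": "T", "lumbar": "L", "sacral": "S"}


@dataclass(frozen=True)
class LevelScheme:
    """Ordered spinal levels grouped into named regions.

    ``counts`` maps region name -> number of levels; the default is the
    full rat scheme (8 + 13 + 6 + 4 = 31 levels, C1 ... S4).  Reduced
    schemes (e.g. a single region, or a few levels) are legal and used
    for small runs.
    """

    counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))

    def __post_init__(self) -> None:
        for region in self.counts:
            if region not in REGION_NAMES:
                raise ValueError(f"unknown region {region!r}")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("every region must have at least one level")

    @property
    def levels(self) -> list[str]:
        """Ordered level labels, rostral to caudal (C1 first)."""
        out: list[str] = []
        for region in REGION_NAMES:
            n = self.counts.get(region, 0)
            out.extend(f"{_PREFIX[region]}{i + 1}" for i in range(n))
        return out

    @property
    def n_levels(self) -> int:
        return sum(self.counts.values())

    @property
    def regions(self) -> list[str]:
        return [r for r in REGION_NAMES if self.counts.get(r, 0) > 0]

    def region_of(self, level: str) -> str:
        for region, prefix in _PREFIX.items():
            if level.startswith(prefix):
                if level not in self.levels:
                    break
                return region
        raise KeyError(f"unknown level label {level!r}")

    def levels_in(self, region: str) -> list[str]:
        if region not in REGION_NAMES:
            raise KeyError(f"unknown region {region!r}")
        prefix = _PREFIX[region]
        return [lv for lv in self.levels if lv.startswith(prefix)]

    def index_of(self, level: str) -> int:
        """Rostro-caudal index of ``level`` (0 = C1)."""
        try:
            return self.levels.index(level)
        except ValueError:
            raise KeyError(f"unknown level label {level!r}") from None


def full_scheme() -> LevelScheme:
    """The complete 31-level rat scheme (C1–S4)."""
    return LevelScheme()
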