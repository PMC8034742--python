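"""Run configuration: every threshold and constant the pipeline uses.

Nothing numeric is hard-coded in the stages; it all flows from here (or
from CLI flags that override fields here).  Defaults reproduce the
reference analysis where its constants are known: availability breaks
(22, 74, 225), three corridors named Eastern/Central/Western, chi-square
over routed species only, tau = 0 km^2 (any strictly positive overlap
counts) and epsilon = 0 km (no continuity gap-merging).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

#: Default sequence-availability breakpoints (closed integer intervals:
#: low = [1, 22], regular = [23, 74], intermediate = [75, 225], high = [226, inf)).
DEFAULT_AVAILABILITY_BREAKS = (22, 74, 225)

#: IUCN-style presence codes admitted by default when a presence attribute
#: exists: 1 "Extant" and 2 "Probably Extant".
DEFAULT_PRESENCE_FILTER = (1, 2)


@dataclass
class GridSpec:
    """Regular lon/lat grid: extent in degrees, resolution in degrees/pixel.

    Rows run north to south (row 0 is the northernmost), anchored exactly
    at (xmin, ymax); no snapping to a global graticule.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    resolution: float

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("grid extent must satisfy xmin < xmax and ymin < ymax")

    @property
    def ncols(self) -> int:
        import math

        return max(1, math.ceil((self.xmax - self.xmin) / self.resolution - 1e-12))

    @property
    def nrows(self) -> int:
        import math

        return max(1, math.ceil((self.ymax - self.ymin) / self.resolution - 1e-12))


@dataclass
class RunConfig:
    focal_region_names: tuple[str, str] = ("Amazonia", "AtlanticForest")
    #: route name -> {"ecoregions": [names...], "extra_geojson": [paths...]}
    corridor_definitions: dict[str, dict] = field(
        default_factory=lambda: {
            "Eastern": {"ecoregions": [], "extra_geojson": []},
            "Central": {"ecoregions": [], "extra_geojson": []},
            "Western": {"ecoregions": [], "extra_geojson": []},
        }
    )
    tau_km2: float = 0.0
    epsilon_km: float = 0.0
    availability_breaks: tuple[int, int, int] = DEFAULT_AVAILABILITY_BREAKS
    grid: Optional[GridSpec] = None
    rng_seed: int = 0
    presence_filter: Optional[tuple[int, ...]] = DEFAULT_PRESENCE_FILTER
    include_unrouted: bool = False
    mc_pvalue: bool = False
    mc_replicates: int = 2000

    def __post_init__(self):
        b1, b2, b3 = self.availability_breaks
        if not (0 < b1 < b2 < b3):
            raise ValueError("availability_breaks must be strictly increasing positive integers")
        if self.tau_km2 < 0 or self.epsilon_km < 0:
            raise ValueError("tau and epsilon must be non-negative")
        if len(self.focal_region_names) != 2:
            raise ValueError("exactly two focal regions are required")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "grid" in raw and raw["grid"] is not None:
            raw["grid"] = GridSpec(**raw["grid"])
        for key in ("focal_region_names", "availability_breaks", "presence_filter"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
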