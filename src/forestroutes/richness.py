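"""Species-richness rasters: per-pixel counts of overlapping ranges.

A pixel belongs to a range when the pixel *center* lies inside the
geometry, boundary included — the center-point convention changes counts
at range edges relative to any-overlap rasterization, so it is stated
here explicitly.  Richness is the cellwise sum of the binary per-species
grids, optionally restricted to the species of one route combination.

Grids are written as ESRI ASCII grids (plain text, georeferenced by the
six-line header), readable by any desktop GIS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .config import GridSpec
from .geometry import RouteAssignment, SpeciesRange

NODATA = -1


def default_grid(ranges: list[SpeciesRange], resolution: float = 0.5) -> GridSpec:
    """Bounding box of all ranges padded by one pixel, at the given resolution."""
    bounds = np.array([r.geometry.bounds for r in ranges])
    xmin, ymin = bounds[:, :2].min(axis=0) - resolution
    xmax, ymax = bounds[:, 2:].max(axis=0) + resolution
    return GridSpec(xmin=float(xmin), ymin=float(ymin), xmax=float(xmax),
                    ymax=float(ymax), resolution=resolution)


def pixel_centers(spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Center coordinates: x (ncols,) west->east, y (nrows,) north->south."""
    xs = spec.xmin + (np.arange(spec.ncols) + 0.5) * spec.resolution
    ys = spec.ymax - (np.arange(spec.nrows) + 0.5) * spec.resolution
    return xs, ys


def rasterize(geom: BaseGeometry, spec: GridSpec) -> np.ndarray:
    """Binary (nrows x ncols) uint8 grid of the center-in-geometry test."""
    xs, ys = pixel_centers(spec)
    xx, yy = np.meshgrid(xs, ys)
    # intersects == center inside or on the boundary
    mask = shapely.intersects_xy(geom, xx.ravel(), yy.ravel())
    return mask.reshape(spec.nrows, spec.ncols).astype(np.uint8)


@dataclass(frozen=True)
class RichnessGrid:
    spec: GridSpec
    values: np.ndarray  # int matrix, row 0 = northernmost

    def __post_init__(self):
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError("values shape does not match the grid spec")


def richness_sum(
    ranges: list[SpeciesRange],
    spec: GridSpec,
    assignments: dict[str, RouteAssignment] | None = None,
    subset_filter: frozenset[str] | None = None,
) -> RichnessGrid:
    """Sum the binary per-species grids into an integer richness grid.

    With ``subset_filter`` set, only species whose attributed route
    combination equals the filter exactly contribute (an empty frozenset
    selects the unrouted species); assignments must then cover all species.
    """
    total = np.zeros((spec.nrows, spec.ncols), dtype=np.int32)
    for rng in ranges:
        if subset_filter is not None:
            if assignments is None or rng.species_id not in assignments:
                raise ValueError(f"no route assignment for {rng.species_id}")
            if assignments[rng.species_id].routes != subset_filter:
                continue
        total += rasterize(rng.geometry, spec)
    return RichnessGrid(spec=spec, values=total)


def write_ascii_grid(grid: RichnessGrid, path: str | Path, nodata: int = NODATA) -> None:
    """Write an ESRI ASCII grid (.asc), cell-corner registered."""
    spec = grid.spec
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {spec.xmin:.10g}\n"
        f"yllcorner {spec.ymax - spec.nrows * spec.resolution:.10g}\n"
        f"cellsize {spec.resolution:.10g}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(str(int(v)) for v in row) for row in grid.values)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> RichnessGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    lines = Path(path).read_text().splitlines()
    head = {}
    for line in lines[:6]:
        key, val = line.split()
        head[key.lower()] = float(val)
    ncols, nrows = int(head["ncols"]), int(head["nrows"])
    res = head["cellsize"]
    spec = GridSpec(
        xmin=head["xllcorner"],
        ymin=head["yllcorner"],
        xmax=head["xllcorner"] + ncols * res,
        ymax=head["yllcorner"] + nrows * res,
        resolution=res,
    )
    values = np.array([[int(v) for v in line.split()] for line in lines[6:]], dtype=np.int32)
    return RichnessGrid(spec=spec, values=values)
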