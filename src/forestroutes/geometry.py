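"""Planar geometry primitives shared by every pipeline stage.

Coordinates are geographic decimal degrees on the WGS84 datum, longitude
first.  All areas and distances are evaluated on the world cylindrical
equal-area plane (Lambert, standard parallel at the equator):

    x = R * lambda_rad,   y = R * sin(phi)

with the WGS84 mean radius R = 6371.0088 km.  On that plane, planar area
equals spherical area exactly, which makes the overlap threshold tau a
reproducible quantity in km^2.  Antimeridian-crossing input is out of the
supported domain and rejected.

Geometries are plain shapely objects; validity is enforced once at ingest
by :func:`clean_geometry` rather than re-checked in every operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.geometry import MultiPolygon, Polygon

from .errors import AntimeridianError, EmptyGeometryError

#: WGS84 mean radius in kilometres.
EARTH_RADIUS_KM = 6371.0088

_DEG = math.pi / 180.0


def _to_equal_area(coords: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords, dtype=float)
    out[:, 0] = EARTH_RADIUS_KM * coords[:, 0] * _DEG
    out[:, 1] = EARTH_RADIUS_KM * np.sin(coords[:, 1] * _DEG)
    return out


def to_equal_area(geom: BaseGeometry) -> BaseGeometry:
    """Project a lon/lat geometry onto the cylindrical equal-area plane (km)."""
    return shapely.transform(geom, _to_equal_area)


def _check_domain(geom: BaseGeometry) -> None:
    if geom.is_empty:
        return
    xmin, ymin, xmax, ymax = geom.bounds
    if xmin < -180.0 or xmax > 180.0:
        raise AntimeridianError(
            f"longitudes [{xmin}, {xmax}] leave the supported [-180, 180] domain"
        )
    if ymin < -90.0 or ymax > 90.0:
        raise AntimeridianError(f"latitudes [{ymin}, {ymax}] leave [-90, 90]")


def _polygonal_parts(geom: BaseGeometry) -> list[Polygon]:
    """Non-degenerate Polygon parts, recursing through collections."""
    if isinstance(geom, Polygon):
        return [geom] if not geom.is_empty and geom.area > 0.0 else []
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        out: list[Polygon] = []
        for g in geom.geoms:
            out.extend(_polygonal_parts(g))
        return out
    return []


def clean_geometry(geom: BaseGeometry) -> BaseGeometry:
    """Repair a possibly-invalid polygon collection into a valid (Multi)Polygon.

    Self-intersecting rings are resolved with the even-odd make-valid
    strategy (a bow-tie becomes two triangles), orientation is normalized,
    and non-areal debris (points, lines) is discarded.  Valid input passes
    through with its area preserved.

    Raises
    ------
    EmptyGeometryError
        If nothing two-dimensional survives cleaning.
    AntimeridianError
        If coordinates leave the [-180, 180] x [-90, 90] domain.
    """
    _check_domain(geom)
    if not geom.is_valid:
        geom = shapely.make_valid(geom)
    polys = _polygonal_parts(geom)
    if not polys:
        raise EmptyGeometryError("no areal geometry left after cleaning")
    merged = shapely.unary_union(polys)
    merged = shapely.normalize(merged)
    if merged.is_empty or merged.area == 0.0:
        raise EmptyGeometryError("no areal geometry left after cleaning")
    return merged


def area_km2(geom: BaseGeometry) -> float:
    """Area of a lon/lat geometry in km^2 (equal-area plane; additive, >= 0)."""
    if geom.is_empty:
        return 0.0
    return to_equal_area(geom).area


def intersection_area(a: BaseGeometry, b: BaseGeometry) -> float:
    """Area of the geometric intersection of two lon/lat geometries, km^2."""
    inter = a.intersection(b)
    if inter.is_empty:
        return 0.0
    return area_km2(inter)


def gap_km(a: BaseGeometry, b: BaseGeometry) -> float:
    """Minimum separation between two geometries on the equal-area plane, km.

    Zero for touching or overlapping geometries.  The cylindrical plane
    compresses east-west distances away from the equator, so this is a
    low-latitude approximation — adequate for the tropical study domain
    and exact at the equator.
    """
    return float(to_equal_area(a).distance(to_equal_area(b)))


def components(geom: BaseGeometry) -> list[BaseGeometry]:
    """Connected polygonal components of a (Multi)Polygon."""
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    return [geom]


@dataclass(frozen=True)
class SpeciesRange:
    """One species' range: a cleaned multipolygon plus taxon metadata."""

    species_id: str
    order_name: str
    geometry: BaseGeometry
    presence_filter_applied: bool = False

    def __post_init__(self):
        if self.geometry.is_empty:
            raise EmptyGeometryError(f"{self.species_id}: empty range geometry")


@dataclass(frozen=True)
class RegionSet:
    """Named focal-region polygons; exactly two are designated per run."""

    regions: dict[str, BaseGeometry]
    focal: tuple[str, str]

    def __post_init__(self):
        a, b = self.focal
        for name in (a, b):
            if name not in self.regions:
                raise KeyError(f"focal region {name!r} not in region set")
        if a == b:
            raise ValueError("the two focal regions must be distinct")
        if intersection_area(self.regions[a], self.regions[b]) > 0.0:
            raise ValueError(f"focal regions {a!r} and {b!r} overlap")

    @property
    def focal_geometries(self) -> tuple[BaseGeometry, BaseGeometry]:
        return self.regions[self.focal[0]], self.regions[self.focal[1]]


#: Canonical reporting order for the three dispersal corridors.
ROUTE_ORDER = ("Eastern", "Central", "Western")


@dataclass(frozen=True)
class CorridorSet:
    """Ordered named corridor polygons (reported Eastern, Central, Western)."""

    corridors: dict[str, BaseGeometry]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def names(self) -> tuple[str, ...]:
        known = [r for r in ROUTE_ORDER if r in self.corridors]
        extra = [r for r in self.corridors if r not in ROUTE_ORDER]
        return tuple(known + extra)


@dataclass(frozen=True)
class RouteAssignment:
    """Per-species corridor membership, continuity flag and overlap areas."""

    species_id: str
    routes: frozenset[str]
    continuity: str  # "continuous" | "disjunct"
    overlap_areas: dict[str, float]

    def combo_label(self) -> str:
        """Table label: '+'-joined alphabetically sorted names, or 'none'."""
        if not self.routes:
            return "none"
        return "+".join(sorted(self.routes))
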