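"""Co-occurrence selection, continuity, corridor construction, route attribution.

This is the spatial heart of the pipeline: which species ranges reach both
focal rainforest blocks, whether they do so in one connected piece, and
which of the named dispersal corridors (Eastern / Central / Western bands
across the dry diagonal) each range overlaps.

Route membership is binary on thresholded overlap *area* (> tau km^2), not
on overlap fraction; corridors may overlap one another and a species
crossing several corridors is attributed to all of them — the Venn logic
downstream depends on multi-route attribution.  An empty route set is a
legal outcome (extremely disjunct species).
"""

from __future__ import annotations

import logging

import shapely

from .errors import UnknownEcoregionError
from .geometry import (
    CorridorSet,
    RegionSet,
    RouteAssignment,
    SpeciesRange,
    clean_geometry,
    components,
    gap_km,
    intersection_area,
)

log = logging.getLogger("forestroutes")


def select_cooccurring(
    ranges: list[SpeciesRange], regions: RegionSet, tau_km2: float = 0.0
) -> list[SpeciesRange]:
    """Keep species whose range overlaps BOTH focal regions by > tau km^2.

    Strictly positive overlap is required even at tau = 0, so a range that
    merely touches a region boundary (zero-area contact) is dropped.
    Input order is preserved; an empty result is valid.
    """
    geom_a, geom_b = regions.focal_geometries
    kept = [
        r
        for r in ranges
        if intersection_area(r.geometry, geom_a) > tau_km2
        and intersection_area(r.geometry, geom_b) > tau_km2
    ]
    log.info("select_cooccurring: %d of %d species occur in both focal regions",
             len(kept), len(ranges))
    return kept


def _merge_clusters(parts, epsilon_km: float) -> list[list[int]]:
    """Single-linkage clustering of geometry parts at gap <= epsilon_km."""
    n = len(parts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) != find(j) and gap_km(parts[i], parts[j]) <= epsilon_km:
                parent[find(j)] = find(i)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def classify_continuity(
    rng: SpeciesRange, regions: RegionSet, epsilon_km: float = 0.0, tau_km2: float = 0.0
) -> str:
    """'continuous' if one connected cluster of the range reaches both regions.

    Components separated by a gap <= epsilon_km are merged into a cluster
    first (epsilon = 0 keeps only truly touching components together; a
    positive epsilon absorbs the artificial fragmentation of digitized
    range maps).  A cluster "reaches" a region when its overlap area
    exceeds tau.
    """
    geom_a, geom_b = regions.focal_geometries
    parts = components(rng.geometry)
    for cluster in _merge_clusters(parts, epsilon_km):
        merged = shapely.unary_union([parts[i] for i in cluster])
        if (
            intersection_area(merged, geom_a) > tau_km2
            and intersection_area(merged, geom_b) > tau_km2
        ):
            return "continuous"
    return "disjunct"


def build_corridors(
    ecoregions: dict[str, "shapely.geometry.base.BaseGeometry"],
    corridor_definitions: dict[str, dict],
    extra_geometries: dict[str, list] | None = None,
) -> CorridorSet:
    """Union named ecoregion polygons (plus optional extra polygons) per route.

    ``corridor_definitions`` maps route name to ``{"ecoregions": [names]}``;
    ``extra_geometries`` supplies already-loaded supplementary polygons per
    route (the literature-derived corridor refinements are user-supplied
    data, not something this package derives).  Corridors may overlap each
    other.  Unknown ecoregion names raise, listing all of them at once.
    """
    unknown = set()
    for spec in corridor_definitions.values():
        unknown |= set(spec.get("ecoregions", ())) - set(ecoregions)
    if unknown:
        raise UnknownEcoregionError(unknown)
    corridors, provenance = {}, {}
    for route, spec in corridor_definitions.items():
        names = list(spec.get("ecoregions", ()))
        geoms = [ecoregions[n] for n in names]
        extras = list((extra_geometries or {}).get(route, ()))
        corridors[route] = clean_geometry(shapely.unary_union(geoms + extras))
        provenance[route] = names + [f"<extra {i}>" for i in range(len(extras))]
    return CorridorSet(corridors=corridors, provenance=provenance)


def attribute_routes(
    rng: SpeciesRange,
    corridors: CorridorSet,
    tau_km2: float = 0.0,
    continuity: str = "continuous",
) -> RouteAssignment:
    """Attribute a species to every corridor it overlaps by > tau km^2.

    Overlap areas are recorded for all corridors, members or not, so
    downstream users can apply their own fractions or thresholds.
    """
    overlaps = {
        name: intersection_area(rng.geometry, corridors.corridors[name])
        for name in corridors.names
    }
    routes = frozenset(name for name, a in overlaps.items() if a > tau_km2)
    return RouteAssignment(
        species_id=rng.species_id,
        routes=routes,
        continuity=continuity,
        overlap_areas=overlaps,
    )
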