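"""Synthetic worlds and species with known ground truth.

The generator emulates the structure of the real study system without any
of its data: two disjoint rainforest blocks (region A west, region B east)
separated by a dry gap, bridged by three disjoint corridor bands stacked
in latitude (Eastern on top, then Central, then Western), each crossing
the gap into both blocks.  Everything is an axis-aligned rectangle in
lon/lat so every overlap area has a closed form and every pipeline test
has an exact oracle.

Each synthetic species gets a route combination, a continuity flag, a
habitat class and a sequence count drawn from configurable distributions
whose defaults are the empirical frequencies of the reference mammal
compilation (see :mod:`forestroutes.reference_data`).  Its multipolygon is
then *constructed* to realize those labels:

* continuous + routed: one slab per member route, spanning from inside A
  to inside B through that corridor band, with the A- and B-side blobs
  welded to the first slab so a single connected component reaches both
  blocks;
* disjunct + routed: half-slabs that reach A and the corridor but stop in
  mid-gap, plus an isolated blob in B — no component touches both blocks;
* unrouted ("none"): isolated blobs in A and B only (the extremely
  disjunct case), or, when explicitly asked for a continuous unrouted
  species, a bridge through the neutral band above the corridors;

so clearance from non-member corridors holds by construction and route /
continuity recovery is exact, not statistical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from . import reference_data
from .config import RunConfig
from .errors import InfeasibleLayoutError
from .geometry import (
    CorridorSet,
    RegionSet,
    ROUTE_ORDER,
    SpeciesRange,
    gap_km,
)
from .io import write_geojson

_LABEL_TO_ROUTES = {
    "E": frozenset({"Eastern"}),
    "C": frozenset({"Central"}),
    "W": frozenset({"Western"}),
    "E+C": frozenset({"Eastern", "Central"}),
    "E+W": frozenset({"Eastern", "Western"}),
    "C+W": frozenset({"Central", "Western"}),
    "E+C+W": frozenset({"Eastern", "Central", "Western"}),
    "none": frozenset(),
}


@dataclass(frozen=True)
class WorldLayout:
    """Rectangle coordinates of the synthetic geography (degrees)."""

    region_a_lon: tuple[float, float] = (-70.0, -60.0)
    region_b_lon: tuple[float, float] = (-45.0, -35.0)
    region_lat: tuple[float, float] = (-20.0, 20.0)
    corridor_lon: tuple[float, float] = (-62.0, -43.0)
    corridor_lat: dict = field(
        default_factory=lambda: {
            "Eastern": (5.0, 10.0),
            "Central": (-2.5, 2.5),
            "Western": (-10.0, -5.0),
        }
    )
    #: latitude band free of corridors, for routeless bridges
    neutral_lat: tuple[float, float] = (14.0, 18.0)


@dataclass
class WorldTemplate:
    layout: WorldLayout
    regions: RegionSet
    corridors: CorridorSet
    ecoregions: dict
    #: ecoregion names per corridor, for corridor-building configs
    corridor_definitions: dict
    seed: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_geojson(
            [(g, {"region": name}) for name, g in self.regions.regions.items()],
            outdir / "regions.geojson",
        )
        write_geojson(
            [(g, {"region": name}) for name, g in self.ecoregions.items()],
            outdir / "ecoregions.geojson",
        )


def gen_world(seed: int = 0, c_min_km: float = 100.0, layout: WorldLayout | None = None) -> WorldTemplate:
    """Build the synthetic geography; deterministic given its arguments.

    ``c_min_km`` is the minimum clearance required between corridor bands
    (and between the corridors and the neutral band); a layout that cannot
    honour it raises :class:`InfeasibleLayoutError`.
    """
    layout = layout or WorldLayout()
    la, lb = layout.region_a_lon, layout.region_b_lon
    y0, y1 = layout.region_lat
    region_a = box(la[0], y0, la[1], y1)
    region_b = box(lb[0], y0, lb[1], y1)
    corridors = {
        name: box(layout.corridor_lon[0], lat[0], layout.corridor_lon[1], lat[1])
        for name, lat in layout.corridor_lat.items()
    }
    bands = list(corridors.items()) + [
        ("neutral", box(layout.corridor_lon[0], layout.neutral_lat[0],
                        layout.corridor_lon[1], layout.neutral_lat[1]))
    ]
    for i in range(len(bands)):
        for j in range(i + 1, len(bands)):
            sep = gap_km(bands[i][1], bands[j][1])
            if sep < c_min_km:
                raise InfeasibleLayoutError(
                    f"{bands[i][0]} and {bands[j][0]} are {sep:.1f} km apart; "
                    f"clearance c_min = {c_min_km} km is infeasible"
                )
    # tile each corridor into two named ecoregions (west / east halves)
    ecoregions, corridor_definitions = {}, {}
    xm = 0.5 * (layout.corridor_lon[0] + layout.corridor_lon[1])
    for name, lat in layout.corridor_lat.items():
        west = f"{name}DryForestWest"
        east = f"{name}DryForestEast"
        ecoregions[west] = box(layout.corridor_lon[0], lat[0], xm, lat[1])
        ecoregions[east] = box(xm, lat[0], layout.corridor_lon[1], lat[1])
        corridor_definitions[name] = {"ecoregions": [west, east], "extra_geojson": []}
    regions = RegionSet(
        regions={"Amazonia": region_a, "AtlanticForest": region_b},
        focal=("Amazonia", "AtlanticForest"),
    )
    return WorldTemplate(
        layout=layout,
        regions=regions,
        corridors=CorridorSet(corridors=corridors,
                              provenance={k: v["ecoregions"] for k, v in corridor_definitions.items()}),
        ecoregions=ecoregions,
        corridor_definitions=corridor_definitions,
        seed=seed,
    )


@dataclass(frozen=True)
class SpeciesSpec:
    """Ground truth for one synthetic species."""

    species_id: str
    order_name: str
    true_combo: frozenset[str]
    continuity_truth: str
    habitat_truth: str
    n_sequences: int
    geometry: shapely.geometry.base.BaseGeometry

    @property
    def combo_label(self) -> str:
        """Short fixed-order label ('E+C', ..., 'none')."""
        for label, routes in _LABEL_TO_ROUTES.items():
            if routes == self.true_combo:
                return label
        raise KeyError(self.true_combo)

    @property
    def routes_label(self) -> str:
        """Species-table encoding: '+'-joined sorted names, or 'none'."""
        return "+".join(sorted(self.true_combo)) if self.true_combo else "none"


def _default_order_model() -> dict:
    total = sum(reference_data.ORDER_COUNTS.values())
    return {
        order: {
            "p": n / total,
            "mean": reference_data.ORDER_MEAN_SEQUENCES[order],
            "dispersion": 0.5,
        }
        for order, n in reference_data.ORDER_COUNTS.items()
    }


def _species_geometry(
    world: WorldTemplate,
    combo: frozenset[str],
    continuity: str,
    rng: np.random.Generator,
):
    lay = world.layout
    # blob longitudes keep 0.5 deg clearance from the corridor columns that
    # protrude into the regions, so blobs never touch any corridor
    a_lon = (lay.region_a_lon[0] + 0.5, lay.corridor_lon[0] - 0.5)
    b_lon = (lay.corridor_lon[1] + 0.5, lay.region_b_lon[1] - 0.5)
    slab_w = lay.corridor_lon[0] - 4.0  # west end of a full slab, inside A
    slab_e = lay.corridor_lon[1] + 4.0  # east end, inside B
    margin = 0.5  # lat margin inside a corridor band

    def rand_blob(lon_range, lat_band=None):
        x0 = rng.uniform(lon_range[0], lon_range[1] - 2.0)
        if lat_band is None:
            y0 = rng.uniform(lay.region_lat[0] + 1.0, lay.region_lat[1] - 3.0)
            lat_band = (y0, y0 + 2.0)
        return box(x0, lat_band[0], x0 + 2.0, lat_band[1])

    members = [r for r in ROUTE_ORDER if r in combo]
    parts = []
    if continuity == "continuous":
        if members:
            for i, r in enumerate(members):
                lat = lay.corridor_lat[r]
                band = (lat[0] + margin, lat[1] - margin)
                parts.append(box(slab_w, band[0], slab_e, band[1]))
                if i == 0:
                    # weld the region blobs onto the first slab
                    parts.append(box(a_lon[0], band[0], slab_w + 1.0, band[1]))
                    parts.append(box(slab_e - 1.0, band[0], b_lon[1], band[1]))
        else:
            nb = lay.neutral_lat
            band = (nb[0] + margin, nb[1] - margin)
            parts.append(box(a_lon[0], band[0], b_lon[1], band[1]))
    else:
        if members:
            mid = 0.5 * (lay.corridor_lon[0] + lay.corridor_lon[1])
            for r in members:
                lat = lay.corridor_lat[r]
                band = (lat[0] + margin, lat[1] - margin)
                # reaches A and the corridor's west half, stops in mid-gap
                parts.append(box(slab_w, band[0], mid - 1.0, band[1]))
            parts.append(rand_blob(b_lon))
        else:
            parts.append(rand_blob(a_lon))
            parts.append(rand_blob(b_lon))
    return shapely.normalize(shapely.unary_union(parts))


def _habitat_records(species_id: str, habitat_class: str) -> list[dict]:
    forest = {"species": species_id, "habitat_code": "1.6",
              "suitability": "Suitable", "major_importance": "Yes"}
    savanna = {"species": species_id, "habitat_code": "2.1",
               "suitability": "Suitable", "major_importance": "No"}
    if habitat_class == "SF":
        return [forest]
    if habitat_class == "PF":
        return [forest, savanna]
    open_major = dict(savanna, major_importance="Yes")
    return [forest, open_major]


def gen_species(
    world: WorldTemplate,
    n: int,
    seed: int,
    combo_distribution: dict[str, float] | None = None,
    habitat_given_combo: dict[str, np.ndarray] | None = None,
    order_model: dict | None = None,
    p_disjunct_routed: float = 10.0 / 123.0,
) -> list[SpeciesSpec]:
    """Draw ``n`` synthetic species with geometries realizing their labels.

    ``combo_distribution`` maps the eight combination labels to
    probabilities summing to 1; ``habitat_given_combo`` maps each label to
    (P(SF), P(PF), P(G)); ``order_model`` maps order name to ``{"p",
    "mean", "dispersion"}`` for the negative-binomial sequence counts.
    Defaults are the reference compilation's empirical frequencies.
    Unrouted species are always disjunct (the extremely disjunct case);
    routed species are disjunct with probability ``p_disjunct_routed``.
    """
    rng = np.random.default_rng(seed)
    combo_distribution = combo_distribution or reference_data.combo_distribution()
    habitat_given_combo = habitat_given_combo or reference_data.habitat_given_combo()
    order_model = order_model or _default_order_model()
    labels = list(combo_distribution)
    probs = np.array([combo_distribution[l] for l in labels], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("combo_distribution must sum to 1")
    orders = list(order_model)
    order_p = np.array([order_model[o]["p"] for o in orders], dtype=float)
    order_p = order_p / order_p.sum()

    species = []
    for i in range(n):
        label = labels[rng.choice(len(labels), p=probs)]
        combo = _LABEL_TO_ROUTES[label]
        if not combo:
            continuity = "disjunct"
        else:
            continuity = "disjunct" if rng.random() < p_disjunct_routed else "continuous"
        hprobs = np.asarray(habitat_given_combo[label], dtype=float)
        habitat = ("SF", "PF", "G")[rng.choice(3, p=hprobs / hprobs.sum())]
        order = orders[rng.choice(len(orders), p=order_p)]
        m, k = order_model[order]["mean"], order_model[order]["dispersion"]
        n_seq = int(rng.negative_binomial(k, k / (k + m)))
        geom = _species_geometry(world, combo, continuity, rng)
        species.append(
            SpeciesSpec(
                species_id=f"Species_{i:04d}",
                order_name=order,
                true_combo=combo,
                continuity_truth=continuity,
                habitat_truth=habitat,
                n_sequences=n_seq,
                geometry=geom,
            )
        )
    return species


def species_ranges(species: list[SpeciesSpec]) -> list[SpeciesRange]:
    """Ground-truth species as the pipeline's SpeciesRange inputs."""
    return [
        SpeciesRange(species_id=s.species_id, order_name=s.order_name, geometry=s.geometry)
        for s in species
    ]


def write_dataset(
    world: WorldTemplate, species: list[SpeciesSpec], outdir: str | Path,
    config: RunConfig | None = None,
) -> None:
    """Emit the full ingest-format dataset plus ground_truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world.write(outdir)
    write_geojson(
        [(s.geometry, {"species": s.species_id, "order": s.order_name}) for s in species],
        outdir / "ranges.geojson",
    )
    habitat_rows = []
    for s in species:
        habitat_rows.extend(_habitat_records(s.species_id, s.habitat_truth))
    pd.DataFrame(habitat_rows).to_csv(outdir / "habitat.csv", index=False)
    pd.DataFrame(
        {
            "species": [s.species_id for s in species],
            "order": [s.order_name for s in species],
            "n_sequences": [s.n_sequences for s in species],
        }
    ).to_csv(outdir / "counts.csv", index=False)
    pd.DataFrame(
        {
            "species": [s.species_id for s in species],
            "order": [s.order_name for s in species],
            "true_combo": [s.routes_label for s in species],
            "true_combo_short": [s.combo_label for s in species],
            "continuity_truth": [s.continuity_truth for s in species],
            "habitat_truth": [s.habitat_truth for s in species],
            "n_sequences": [s.n_sequences for s in species],
        }
    ).to_csv(outdir / "ground_truth.csv", index=False)
    config = config or RunConfig(corridor_definitions=world.corridor_definitions)
    config.to_json(outdir / "config.json")
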