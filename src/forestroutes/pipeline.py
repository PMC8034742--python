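"""End-to-end orchestration: ingest -> co-occurrence -> routes -> traits ->
stats -> rasters -> report.

Species are excluded, with a logged reason, when they fail either study
criterion: (1) occurrence in both focal regions, (2) forest association.
Every input species appears exactly once in the species table or in the
exclusion table.  All randomness (the optional Monte-Carlo p-value) flows
from the configuration seed, so identical config and inputs give a
byte-identical report bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ForestRoutesError
from .geometry import RegionSet, RouteAssignment, SpeciesRange
from .io import (
    read_counts_table,
    read_habitat_table,
    read_named_geometries,
    read_overrides,
    read_ranges,
    write_report,
)
from .overlay import (
    attribute_routes,
    build_corridors,
    classify_continuity,
    select_cooccurring,
)
from .richness import default_grid, richness_sum, write_ascii_grid
from .stats import (
    ALL_COMBO_LABELS,
    make_contingency,
    pearson_chi_square,
    venn_counts,
)
from .traits import bin_availability, classify_habitat_table, per_order_mean

log = logging.getLogger("forestroutes")


@dataclass
class PipelineResult:
    species_table: pd.DataFrame
    exclusions: pd.DataFrame
    assignments: dict[str, RouteAssignment]
    contingency: "pd.DataFrame"
    venn: dict[str, int]
    stats: dict
    per_order_means: pd.Series
    grids: dict = field(default_factory=dict)

    def as_report(self) -> dict:
        return {
            "species_table": self.species_table,
            "contingency": self.contingency,
            "venn": self.venn,
            "stats": self.stats,
            "exclusions": self.exclusions,
        }


def run(
    config: RunConfig,
    ranges: list[SpeciesRange],
    regions: RegionSet,
    corridors,
    habitat: pd.DataFrame,
    counts: pd.DataFrame,
    overrides: dict[str, str] | None = None,
    compute_grids: bool = False,
) -> PipelineResult:
    """Run every analysis stage on in-memory inputs."""
    exclusions: list[dict] = []

    # stage 1: co-occurrence in both focal regions
    cooccurring = select_cooccurring(ranges, regions, config.tau_km2)
    kept_ids = {r.species_id for r in cooccurring}
    for r in ranges:
        if r.species_id not in kept_ids:
            exclusions.append(
                {"species": r.species_id, "stage": "cooccurrence",
                 "reason": "not present in both focal regions"}
            )

    # stage 2: forest association + habitat class
    habitat_class = classify_habitat_table(habitat, overrides)
    forest_kept = []
    for r in cooccurring:
        if r.species_id in habitat_class:
            forest_kept.append(r)
        else:
            exclusions.append(
                {"species": r.species_id, "stage": "habitat",
                 "reason": "no forest habitat record"}
            )
    log.info("habitat stage: %d of %d species forest-associated",
             len(forest_kept), len(cooccurring))

    # stage 3: continuity and route attribution
    assignments: dict[str, RouteAssignment] = {}
    for r in forest_kept:
        continuity = classify_continuity(r, regions, config.epsilon_km, config.tau_km2)
        assignments[r.species_id] = attribute_routes(
            r, corridors, config.tau_km2, continuity=continuity
        )

    # stage 4: availability
    counts_by_sp = dict(zip(counts["species"], counts["n_sequences"].astype(int)))
    order_by_sp = dict(zip(counts["species"], counts["order"]))
    availability = {
        sp: bin_availability(counts_by_sp.get(sp, 0), config.availability_breaks)
        for sp in assignments
    }

    # stage 5: tables and test
    assignment_list = [assignments[r.species_id] for r in forest_kept]
    table = make_contingency(assignment_list, habitat_class, config.include_unrouted)
    rng = np.random.default_rng(config.rng_seed)
    chisq = pearson_chi_square(
        table, mc_pvalue=config.mc_pvalue, mc_replicates=config.mc_replicates, rng=rng
    )
    venn = venn_counts(assignment_list)
    counts_df = pd.DataFrame(
        {
            "species": list(assignments),
            "order": [order_by_sp.get(sp, r.order_name)
                      for sp, r in zip(assignments, forest_kept)],
            "n_sequences": [counts_by_sp.get(sp, 0) for sp in assignments],
        }
    )
    order_means = per_order_mean(counts_df)

    species_table = pd.DataFrame(
        {
            "species": [r.species_id for r in forest_kept],
            "order": [r.order_name for r in forest_kept],
            "routes": [assignments[r.species_id].combo_label() for r in forest_kept],
            "continuity": [assignments[r.species_id].continuity for r in forest_kept],
            "habitat_class": [habitat_class[r.species_id] for r in forest_kept],
            "availability": [availability[r.species_id] for r in forest_kept],
            "n_sequences": [counts_by_sp.get(r.species_id, 0) for r in forest_kept],
        }
    )
    n_continuous = int((species_table["continuity"] == "continuous").sum())
    stats_out = {
        "n_input_species": len(ranges),
        "n_cooccurring": len(cooccurring),
        "n_analysed": len(forest_kept),
        "n_routed": int(sum(1 for a in assignment_list if a.routes)),
        "n_unrouted": int(sum(1 for a in assignment_list if not a.routes)),
        "n_continuous": n_continuous,
        "n_disjunct": len(forest_kept) - n_continuous,
        "venn": {k: int(venn[k]) for k in ALL_COMBO_LABELS},
        "availability_counts": {
            cls: int(sum(1 for v in availability.values() if v == cls))
            for cls in ("none", "low", "regular", "intermediate", "high")
        },
        "chi_square": {
            "statistic": round(chisq.statistic, 10),
            "df": chisq.df,
            "p_value": round(chisq.p_value, 10),
            "min_expected": round(chisq.min_expected, 10),
            "low_expected_warning": chisq.low_expected_warning,
            "mode": chisq.mode,
        },
        "per_order_mean_sequences": {k: round(float(v), 6) for k, v in order_means.items()},
    }

    result = PipelineResult(
        species_table=species_table,
        exclusions=pd.DataFrame(exclusions, columns=["species", "stage", "reason"]),
        assignments=assignments,
        contingency=table.to_frame(),
        venn=venn,
        stats=stats_out,
        per_order_means=order_means,
    )

    if compute_grids:
        spec = config.grid or default_grid(forest_kept)
        result.grids["all"] = richness_sum(forest_kept, spec)
    return result


def run_files(
    config: RunConfig,
    ranges_path: str | Path,
    regions_path: str | Path,
    ecoregions_path: str | Path,
    habitat_path: str | Path,
    counts_path: str | Path,
    overrides_path: str | Path | None = None,
    out_dir: str | Path | None = None,
    compute_grids: bool = False,
) -> PipelineResult:
    """File-based entry point: read inputs, run, optionally write the bundle."""
    ranges = read_ranges(ranges_path, config.presence_filter)
    named = read_named_geometries(regions_path, name_key="region")
    regions = RegionSet(regions=named, focal=tuple(config.focal_region_names))
    ecoregions = read_named_geometries(ecoregions_path, name_key="region")
    extra = {}
    for route, spec in config.corridor_definitions.items():
        geoms = []
        for p in spec.get("extra_geojson", ()):
            geoms.extend(read_named_geometries(p, name_key="region").values())
        if geoms:
            extra[route] = geoms
    corridors = build_corridors(ecoregions, config.corridor_definitions, extra)
    habitat = read_habitat_table(habitat_path)
    counts = read_counts_table(counts_path)
    overrides = read_overrides(overrides_path) if overrides_path else None
    result = run(config, ranges, regions, corridors, habitat, counts,
                 overrides, compute_grids=compute_grids)
    if out_dir is not None:
        write_report(result.as_report(), out_dir)
        for name, grid in result.grids.items():
            write_ascii_grid(grid, Path(out_dir) / f"richness_{name}.asc")
    return result


class StageError(ForestRoutesError):
    """A pipeline stage failed; carries the stage name for CLI reporting."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"[{stage}] {cause}")
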