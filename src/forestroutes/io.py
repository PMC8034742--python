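"""Readers and writers: GeoJSON, WKT-CSV, attribute tables, report bundle.

All geometry crossing the package boundary passes through
:func:`forestroutes.geometry.clean_geometry` on the way in, so downstream
stages can assume validity.  CSV dialect is fixed: comma-separated, UTF-8,
"." decimal separator, mandatory header row.  Report output is byte-stable
for identical inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import (
    DuplicateSpeciesError,
    EmptyGeometryError,
    MissingAttributeError,
    MissingColumnError,
)
from .geometry import SpeciesRange, clean_geometry

log = logging.getLogger("forestroutes")


# ---------------------------------------------------------------------------
# geometry input


def _iter_features(path: str | Path):
    """Yield (geometry, properties) pairs from GeoJSON or WKT-CSV."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        doc = json.loads(path.read_text())
        if doc.get("type") != "FeatureCollection":
            raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
        for feat in doc["features"]:
            yield shape(feat["geometry"]), dict(feat.get("properties") or {})
    else:
        df = pd.read_csv(path)
        if "wkt" not in df.columns:
            raise MissingColumnError(f"{path}: WKT-CSV input needs a 'wkt' column")
        for _, row in df.iterrows():
            props = row.drop(labels=["wkt"]).to_dict()
            yield shapely.from_wkt(row["wkt"]), props


def read_ranges(path: str | Path, presence_filter=None) -> list[SpeciesRange]:
    """Read species ranges; one cleaned, unioned SpeciesRange per species.

    Features carrying a ``presence`` attribute are kept only when its code
    is in ``presence_filter`` (features without the attribute are always
    kept; ``presence_filter=None`` disables filtering).  Input order of
    first appearance is preserved.
    """
    raw: dict[str, dict] = {}
    n_in = n_dropped = 0
    for geom, props in _iter_features(path):
        n_in += 1
        if "species" not in props or pd.isna(props["species"]):
            raise MissingAttributeError(f"{path}: feature lacks a 'species' attribute")
        filtered = False
        presence = props.get("presence")
        if presence is not None and not pd.isna(presence):
            filtered = True
            if presence_filter is not None and int(presence) not in presence_filter:
                n_dropped += 1
                continue
        sp = str(props["species"])
        entry = raw.setdefault(
            sp, {"order": str(props.get("order", "")), "geoms": [], "filtered": False}
        )
        entry["geoms"].append(geom)
        entry["filtered"] = entry["filtered"] or filtered
    ranges = []
    for sp, entry in raw.items():
        merged = clean_geometry(shapely.unary_union(entry["geoms"]))
        ranges.append(
            SpeciesRange(
                species_id=sp,
                order_name=entry["order"],
                geometry=merged,
                presence_filter_applied=entry["filtered"],
            )
        )
    log.info(
        "read_ranges: %d features in, %d dropped by presence filter, %d species out",
        n_in, n_dropped, len(ranges),
    )
    return ranges


def read_named_geometries(path: str | Path, name_key: str = "region") -> dict[str, BaseGeometry]:
    """Read named polygons (regions or ecoregions), unioning repeats per name."""
    groups: dict[str, list] = {}
    for geom, props in _iter_features(path):
        if name_key not in props or pd.isna(props[name_key]):
            raise MissingAttributeError(f"{path}: feature lacks a {name_key!r} attribute")
        groups.setdefault(str(props[name_key]), []).append(geom)
    return {
        name: clean_geometry(shapely.unary_union(geoms)) for name, geoms in groups.items()
    }


def write_geojson(features: list[tuple[BaseGeometry, dict]], path: str | Path) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# attribute tables

HABITAT_COLUMNS = ("species", "habitat_code", "suitability", "major_importance")
COUNTS_COLUMNS = ("species", "order", "n_sequences")


def read_attribute_table(
    path: str | Path, required_columns, unique_species: bool = False
) -> pd.DataFrame:
    """Read a CSV attribute table with schema checks.

    ``unique_species=True`` enforces one row per species (the sequence-count
    table); the habitat table legitimately repeats species.
    """
    df = pd.read_csv(path, dtype={"species": str})
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    if unique_species and df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"].unique())
        raise DuplicateSpeciesError(f"{path}: duplicate species rows: {dupes}")
    return df


def read_habitat_table(path: str | Path) -> pd.DataFrame:
    return read_attribute_table(path, HABITAT_COLUMNS, unique_species=False)


def read_counts_table(path: str | Path) -> pd.DataFrame:
    df = read_attribute_table(path, COUNTS_COLUMNS, unique_species=True)
    if (df["n_sequences"] < 0).any():
        raise ValueError(f"{path}: negative sequence counts are invalid")
    if (df["n_sequences"] != df["n_sequences"].astype(int)).any():
        raise ValueError(f"{path}: sequence counts must be integers")
    return df


def read_overrides(path: str | Path) -> dict[str, str]:
    """Per-species expert habitat-class overrides (species, habitat_class)."""
    df = read_attribute_table(path, ("species", "habitat_class"), unique_species=True)
    bad = set(df["habitat_class"]) - {"SF", "PF", "G"}
    if bad:
        raise ValueError(f"{path}: unknown habitat classes {sorted(bad)}")
    return dict(zip(df["species"], df["habitat_class"]))


# ---------------------------------------------------------------------------
# report bundle


def _stable_json(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n"


def write_report(results: dict, outdir: str | Path) -> None:
    """Write the report bundle: species_table.csv, contingency.csv, venn.csv,
    stats.json (plus exclusions.csv when species were excluded).

    ``results`` keys: ``species_table`` (DataFrame), ``contingency``
    (labelled DataFrame), ``venn`` (label -> count), ``stats`` (JSON-ready
    dict), optional ``exclusions`` (DataFrame).  Output is byte-stable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results["species_table"].to_csv(outdir / "species_table.csv", index=False)
    results["contingency"].to_csv(outdir / "contingency.csv")
    venn = results["venn"]
    pd.DataFrame(
        {"combination": list(venn.keys()), "n_species": list(venn.values())}
    ).to_csv(outdir / "venn.csv", index=False)
    (outdir / "stats.json").write_text(_stable_json(results["stats"]))
    if "exclusions" in results and results["exclusions"] is not None:
        results["exclusions"].to_csv(outdir / "exclusions.csv", index=False)
    log.info("write_report: bundle written to %s", outdir)
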