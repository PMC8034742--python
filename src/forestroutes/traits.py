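"""Habitat-preference classification and genetic-data availability binning.

Habitat preference uses three classes over IUCN-style habitat-use records:

* ``SF`` — strict forest specialist: every recorded habitat is forest;
* ``PF`` — prefers forest: uses non-forest habitat only marginally, or
  forest is the only habitat of major importance;
* ``G``  — generalist: uses forest and open environments alike.

The source analysis assigned these labels from free-text habitat accounts;
here the same trichotomy is computed by an auditable rule over structured
habitat codes (level-1 code 1 = Forest), with a per-species override table
for expert judgement.  Unknown suitability is treated as Suitable and
unknown major importance as No — both conservative toward G, the most
common class.

Availability of public nucleotide data is binned into none / low / regular
/ intermediate / high by closed integer intervals [1,b1], [b1+1,b2],
[b2+1,b3], [b3+1,inf); the shipped breaks are (22, 74, 225).  Breaks for a
new dataset come from the quartiles of the positive counts (linear
order-statistic interpolation, floored to integers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NotForestAssociatedError

HABITAT_CLASSES = ("SF", "PF", "G")
AVAILABILITY_CLASSES = ("none", "low", "regular", "intermediate", "high")

#: Level-1 prefix of IUCN Habitats Classification Scheme codes meaning Forest.
FOREST_LEVEL1 = 1


@dataclass(frozen=True)
class HabitatRecord:
    species_id: str
    habitat_code: str
    suitability: str = "Suitable"  # Suitable | Marginal | Unknown
    major_importance: str = "Unknown"  # Yes | No | Unknown

    @property
    def level1(self) -> int:
        return int(str(self.habitat_code).split(".")[0])

    @property
    def is_forest(self) -> bool:
        return self.level1 == FOREST_LEVEL1

    @property
    def effective_suitability(self) -> str:
        return "Suitable" if self.suitability in ("Suitable", "Unknown") else self.suitability

    @property
    def effective_major(self) -> str:
        return "Yes" if self.major_importance == "Yes" else "No"


def classify_habitat(records: list[HabitatRecord], override: str | None = None) -> str:
    """Classify one species' habitat records into SF, PF or G.

    Rules, applied in order: (i) all records forest -> SF; (ii) every
    non-forest record Marginal, or forest the sole habitat of major
    importance -> PF; (iii) otherwise G.  A species with no forest record
    fails the study inclusion criterion and raises
    :class:`NotForestAssociatedError`.
    """
    if override is not None:
        if override not in HABITAT_CLASSES:
            raise ValueError(f"unknown habitat class override {override!r}")
        return override
    if not records:
        raise ValueError("at least one habitat record is required")
    forest = [r for r in records if r.is_forest]
    nonforest = [r for r in records if not r.is_forest]
    if not forest:
        raise NotForestAssociatedError(records[0].species_id)
    if not nonforest:
        return "SF"
    all_nonforest_marginal = all(r.effective_suitability == "Marginal" for r in nonforest)
    forest_sole_major = any(r.effective_major == "Yes" for r in forest) and not any(
        r.effective_major == "Yes" for r in nonforest
    )
    if all_nonforest_marginal or forest_sole_major:
        return "PF"
    return "G"


def classify_habitat_table(
    habitat: pd.DataFrame, overrides: dict[str, str] | None = None
) -> dict[str, str]:
    """Vector version over a habitat CSV table; returns species -> class.

    Species whose records contain no forest habitat are *omitted* (they are
    excluded upstream by the pipeline, which logs them); overrides win.
    """
    overrides = overrides or {}
    out: dict[str, str] = {}
    for sp, grp in habitat.groupby("species", sort=False):
        records = [
            HabitatRecord(
                species_id=sp,
                habitat_code=str(row.habitat_code),
                suitability=str(row.suitability),
                major_importance=str(row.major_importance),
            )
            for row in grp.itertuples()
        ]
        try:
            out[sp] = classify_habitat(records, override=overrides.get(sp))
        except NotForestAssociatedError:
            continue
    return out


def bin_availability(n: int, breaks=(22, 74, 225)) -> str:
    """Bin a nucleotide-record count into an availability class.

    0 -> none; [1, b1] -> low; [b1+1, b2] -> regular; [b2+1, b3] ->
    intermediate; [b3+1, inf) -> high.
    """
    if n < 0 or int(n) != n:
        raise ValueError(f"count must be a non-negative integer, got {n!r}")
    b1, b2, b3 = breaks
    if n == 0:
        return "none"
    if n <= b1:
        return "low"
    if n <= b2:
        return "regular"
    if n <= b3:
        return "intermediate"
    return "high"


def quantile_breaks(counts, probs=(0.25, 0.50, 0.75)) -> tuple[int, ...]:
    """Quartile breakpoints of positive counts, floored to integers.

    Quantile p is taken at position 1 + p*(n-1) of the sorted counts with
    linear interpolation (the classic type-7 convention), then floored.
    Zeros must be filtered out upstream — species without data sit outside
    the availability scale.
    """
    counts = np.asarray(list(counts))
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if (counts < 1).any():
        raise ValueError("counts must all be >= 1 (filter zeros upstream)")
    qs = np.quantile(counts, probs, method="linear")
    return tuple(int(np.floor(q)) for q in qs)


def per_order_mean(counts: pd.DataFrame, include_zero: bool = True) -> pd.Series:
    """Mean sequences per species within each taxonomic order.

    Species with zero sequences are included by default (the availability
    figures cover the full species list); ``include_zero=False`` restricts
    to species with data.  Result is sorted by descending mean.
    """
    df = counts if include_zero else counts[counts["n_sequences"] > 0]
    if df.empty:
        return pd.Series(dtype=float, name="mean_sequences")
    means = df.groupby("order")["n_sequences"].mean()
    return means.sort_values(ascending=False).rename("mean_sequences")
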