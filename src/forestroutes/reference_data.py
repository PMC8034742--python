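"""Reference tallies from the motivating Amazonia–Atlantic Forest mammal compilation.

These constants are the printed summary numbers of the compilation of 127
mammal species occurring in both Amazonia and the Atlantic Forest — the
study system this package operationalizes.  They serve as worked-example
inputs: the raw range maps and sequence queries behind them are not
redistributable, but the summary tables are, and the package's arithmetic
(Venn totals, contingency construction, chi-square) can be run on them
directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import COMBO_LABELS, ContingencyTable
from .traits import HABITAT_CLASSES

#: Route-combination x habitat-class (SF, PF, G) species counts for the 123
#: species with at least one attributed route.  Rows follow the canonical
#: combination order E, C, W, E+C, E+W, C+W, E+C+W.
ROUTE_HABITAT_COUNTS = pd.DataFrame(
    [
        [7, 3, 9],    # Eastern only (19 species)
        [1, 2, 1],    # Central only (4)
        [0, 0, 3],    # Western only (3)
        [5, 8, 17],   # Eastern + Central (30)
        [0, 0, 4],    # Eastern + Western (4)
        [2, 6, 5],    # Central + Western (13)
        [1, 4, 45],   # all three routes (50)
    ],
    index=list(COMBO_LABELS),
    columns=list(HABITAT_CLASSES),
)

#: Species without any attributable route (extremely disjunct ranges).
N_UNROUTED = 4

#: Continuity split across the full compilation.
N_CONTINUOUS = 113
N_DISJUNCT = 14

#: Availability breakpoints used by the compilation (closed intervals).
AVAILABILITY_BREAKS = (22, 74, 225)

#: Species per taxonomic order in the compilation (sums to 127).
ORDER_COUNTS = {
    "Didelphimorphia": 7,
    "Pilosa": 4,
    "Cingulata": 5,
    "Perissodactyla": 1,
    "Cetartiodactyla": 3,
    "Primates": 2,
    "Carnivora": 12,
    "Chiroptera": 84,
    "Rodentia": 9,
}

#: Approximate mean nucleotide-record counts per species by order, as
#: reported by the compilation; drives the synthetic count generator.
ORDER_MEAN_SEQUENCES = {
    "Cingulata": 1000.0,
    "Chiroptera": 590.0,
    "Pilosa": 330.0,
    "Primates": 300.0,
    "Cetartiodactyla": 220.0,
    "Perissodactyla": 200.0,
    "Carnivora": 190.0,
    "Didelphimorphia": 115.0,
    "Rodentia": 93.0,
}


def reference_contingency() -> ContingencyTable:
    """The published route x habitat counts as a ContingencyTable."""
    return ContingencyTable(
        row_labels=tuple(ROUTE_HABITAT_COUNTS.index),
        col_labels=tuple(ROUTE_HABITAT_COUNTS.columns),
        counts=ROUTE_HABITAT_COUNTS.to_numpy(),
    )


def combo_distribution() -> dict[str, float]:
    """Empirical route-combination frequencies over all 127 species."""
    totals = ROUTE_HABITAT_COUNTS.sum(axis=1)
    n = float(totals.sum() + N_UNROUTED)
    dist = {label: totals[label] / n for label in ROUTE_HABITAT_COUNTS.index}
    dist["none"] = N_UNROUTED / n
    return dist


def habitat_given_combo() -> dict[str, np.ndarray]:
    """Habitat-class probabilities conditional on each route combination.

    Unrouted species get the compilation-wide marginal.
    """
    out = {}
    for label, row in ROUTE_HABITAT_COUNTS.iterrows():
        out[label] = (row / row.sum()).to_numpy(dtype=float)
    marginal = ROUTE_HABITAT_COUNTS.sum(axis=0)
    out["none"] = (marginal / marginal.sum()).to_numpy(dtype=float)
    return out
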