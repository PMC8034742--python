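"""Contingency tables, the Pearson chi-square test, and Venn-style counts.

The chi-square of independence is implemented from first principles
(expected matrix, statistic, df, upper-tail p through the regularized
upper incomplete gamma function) rather than delegated to a stats
routine: the behaviour at this analysis' table shapes — no continuity
correction at any size, zero-marginal rows/columns dropped before
testing, a small-expected-count warning — is part of the method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaincc

from .errors import DegenerateTableError, MissingHabitatError
from .geometry import ROUTE_ORDER, RouteAssignment
from .traits import HABITAT_CLASSES

log = logging.getLogger("forestroutes")

_ABBREV = {"Eastern": "E", "Central": "C", "Western": "W"}

#: The seven non-empty route combinations in fixed reporting order
#: (singletons, pairs, then the triple).
COMBO_ORDER = (
    frozenset({"Eastern"}),
    frozenset({"Central"}),
    frozenset({"Western"}),
    frozenset({"Eastern", "Central"}),
    frozenset({"Eastern", "Western"}),
    frozenset({"Central", "Western"}),
    frozenset({"Eastern", "Central", "Western"}),
)


def combo_key(routes: frozenset[str]) -> str:
    """Short fixed-order label for a route combination ('E+C', ..., 'none')."""
    if not routes:
        return "none"
    parts = [_ABBREV.get(r, r) for r in ROUTE_ORDER if r in routes]
    parts += sorted(_ABBREV.get(r, r) for r in routes if r not in ROUTE_ORDER)
    return "+".join(parts)


COMBO_LABELS = tuple(combo_key(c) for c in COMBO_ORDER)
ALL_COMBO_LABELS = COMBO_LABELS + ("none",)


@dataclass
class ContingencyTable:
    """Route-combination x habitat-class counts with fixed label ordering.

    ``counts`` is the full matrix over ``row_labels`` x ``col_labels``;
    ``tested()`` returns the submatrix with zero-marginal rows and columns
    removed (those labels are recorded in ``dropped_rows``/``dropped_cols``).
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray
    dropped_rows: tuple[str, ...] = field(default=())
    dropped_cols: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("contingency counts must be non-negative")
        keep_r = self.counts.sum(axis=1) > 0
        keep_c = self.counts.sum(axis=0) > 0
        self.dropped_rows = tuple(l for l, k in zip(self.row_labels, keep_r) if not k)
        self.dropped_cols = tuple(l for l, k in zip(self.col_labels, keep_c) if not k)
        self._keep_r, self._keep_c = keep_r, keep_c
        if self.dropped_rows or self.dropped_cols:
            log.info(
                "contingency: dropped zero-marginal rows %s cols %s",
                self.dropped_rows, self.dropped_cols,
            )

    def tested(self) -> pd.DataFrame:
        """Labelled submatrix entering the test (zero marginals removed)."""
        sub = self.counts[np.ix_(self._keep_r, self._keep_c)]
        return pd.DataFrame(
            sub,
            index=[l for l, k in zip(self.row_labels, self._keep_r) if k],
            columns=[l for l, k in zip(self.col_labels, self._keep_c) if k],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    min_expected: float
    low_expected_warning: bool
    mode: str = "asymptotic"


def make_contingency(
    assignments: list[RouteAssignment],
    habitat: dict[str, str],
    include_unrouted: bool = False,
) -> ContingencyTable:
    """Cross-tabulate route combination against habitat class.

    Each species contributes one count to the cell of its full route
    combination and habitat class.  Species with an empty route set are
    excluded unless ``include_unrouted`` adds a 'none' row.  Raises
    :class:`MissingHabitatError` listing every species without a class.
    """
    missing = [a.species_id for a in assignments if a.species_id not in habitat]
    if missing:
        raise MissingHabitatError(missing)
    row_labels = ALL_COMBO_LABELS if include_unrouted else COMBO_LABELS
    col_labels = HABITAT_CLASSES
    ri = {l: i for i, l in enumerate(row_labels)}
    ci = {l: i for i, l in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for a in assignments:
        key = combo_key(a.routes)
        if key == "none" and not include_unrouted:
            continue
        counts[ri[key], ci[habitat[a.species_id]]] += 1
    return ContingencyTable(row_labels=row_labels, col_labels=col_labels, counts=counts)


def chi_square_upper_tail(statistic: float, df: int) -> float:
    """Upper tail of the chi-square distribution: Q(df/2, statistic/2)."""
    return float(gammaincc(df / 2.0, statistic / 2.0))


def pearson_chi_square(
    table: ContingencyTable,
    mc_pvalue: bool = False,
    mc_replicates: int = 2000,
    rng: np.random.Generator | None = None,
) -> ChiSquareResult:
    """Pearson chi-square test of independence on the tested matrix.

    E_ij = (row_i total)(col_j total)/N; X^2 = sum (O-E)^2/E with no
    continuity correction at any table size; df = (r-1)(c-1); p is the
    chi-square upper tail.  ``min_expected`` is reported and a warning
    flagged below 5, where the asymptotic p is unreliable; the optional
    Monte-Carlo mode replaces it with a permutation p under fixed margins.
    """
    obs = table.tested().to_numpy(dtype=float)
    r, c = obs.shape
    if r < 2 or c < 2:
        raise DegenerateTableError(
            f"tested matrix is {r}x{c}; need at least 2x2 after zero-marginal drops"
        )
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    min_expected = float(expected.min())
    warning = min_expected < 5.0
    if warning:
        log.warning("pearson_chi_square: min expected count %.3f < 5", min_expected)
    if mc_pvalue:
        rng = rng if rng is not None else np.random.default_rng(0)
        p = _permutation_pvalue(obs, statistic, mc_replicates, rng)
        mode = "monte-carlo"
    else:
        p = chi_square_upper_tail(statistic, df)
        mode = "asymptotic"
    return ChiSquareResult(
        statistic=statistic, df=df, p_value=p, expected=expected,
        min_expected=min_expected, low_expected_warning=warning, mode=mode,
    )


def _permutation_pvalue(
    obs: np.ndarray, statistic: float, replicates: int, rng: np.random.Generator
) -> float:
    """Permutation p-value under fixed margins.

    Reconstructs per-individual row/column labels from the counts, shuffles
    the column labels, and re-tabulates; p uses the add-one estimator so it
    is never exactly zero.
    """
    r, c = obs.shape
    rows = np.repeat(np.arange(r), obs.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(c), obs.sum(axis=0).astype(int))
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    hits = 0
    for _ in range(replicates):
        perm = rng.permutation(cols)
        sim = np.zeros((r, c))
        np.add.at(sim, (rows, perm), 1.0)
        stat = ((sim - expected) ** 2 / expected).sum()
        if stat >= statistic - 1e-12:
            hits += 1
    return (hits + 1) / (replicates + 1)


def venn_counts(assignments: list[RouteAssignment]) -> dict[str, int]:
    """Species tallies over the 8 route combinations (including 'none').

    The values always sum to the number of assignments — the Venn counts
    are a partition of the assessed species.
    """
    out = {label: 0 for label in ALL_COMBO_LABELS}
    for a in assignments:
        out[combo_key(a.routes)] += 1
    return out
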