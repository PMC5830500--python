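"""Contamination-risk accounting for germ-free husbandry ledgers.

The unit of exposure is the mouse-day (one mouse maintained for one day) or
the cage-day; contamination risk is assessed per cage-opening, the episode
every ``T`` days at which a sealed cage is opened for bedding replacement.
The derived quantities follow the ledger identities

    cage_days  = n_cages * days_observed
    mouse_days = (n_adults + n_pups) * days_observed
    mouse_days_per_cage = mouse_days / n_cages
    cage_openings = cage_days / replacement_interval

Exact Fisher tests on 2x2 opening-by-housing-system tables compare the
contamination risk of housing systems; the two-sided p-value uses the
probability-mass convention (sum over all margin-preserving tables whose
probability does not exceed the observed one).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DegenerateTableError, InvalidParameterError, UndefinedStatisticError

__all__ = [
    "HusbandryLedger",
    "RiskSummary",
    "Table2x2",
    "summarize",
    "per_opening_risk",
    "one_in_n_risk",
    "cage_years",
    "auc_growth_estimate",
    "fisher_exact",
    "load_table1",
]


@dataclass(frozen=True)
class HusbandryLedger:
    """One housing unit's census row: counts, observation window, events."""

    unit: str
    n_cages: int
    n_adults: int
    n_pups: int = 0
    days_observed: float = 730.0
    replacement_interval: float = 10.0
    contamination_events: int = 0
    contaminated_mouse_days: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_cages", "n_adults", "n_pups", "contamination_events"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.days_observed < 0 or self.contaminated_mouse_days < 0:
            raise InvalidParameterError("day counts must be >= 0")
        if not (self.replacement_interval > 0):
            raise InvalidParameterError("replacement_interval must be > 0")


@dataclass(frozen=True)
class RiskSummary:
    """Derived exposure denominators and risks for one ledger row.

    ``mouse_days_per_cage`` is exact; ``mouse_days_per_cage_trunc`` and
    ``..._round`` are the two integer reporting conventions (truncation vs
    round-half-up), with ``truncation_ambiguous`` set when they differ.
    """

    unit: str
    cage_days: float
    mouse_days: float
    mouse_days_per_cage: float
    mouse_days_per_cage_trunc: int
    mouse_days_per_cage_round: int
    truncation_ambiguous: bool
    cage_openings: float
    per_opening_risk_pct: float | None
    one_in_n_mouse_days: int | None

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "cage_days": self.cage_days,
            "mouse_days": self.mouse_days,
            "mouse_days_per_cage": self.mouse_days_per_cage,
            "mouse_days_per_cage_trunc": self.mouse_days_per_cage_trunc,
            "mouse_days_per_cage_round": self.mouse_days_per_cage_round,
            "truncation_ambiguous": self.truncation_ambiguous,
            "cage_openings": self.cage_openings,
            "per_opening_risk_pct": self.per_opening_risk_pct,
            "one_in_n_mouse_days": self.one_in_n_mouse_days,
        }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize(ledger: HusbandryLedger) -> RiskSummary:
    """Apply the ledger identities to one row."""
    n_mice = ledger.n_adults + ledger.n_pups
    if ledger.n_cages == 0 and n_mice > 0:
        raise InvalidParameterError(
            f"{ledger.unit!r}: mice recorded but no cages; ledger row is inconsistent"
        )
    cage_days = ledger.n_cages * ledger.days_observed
    mouse_days = n_mice * ledger.days_observed
    if ledger.n_cages > 0:
        mdpc = mouse_days / ledger.n_cages
    else:
        mdpc = 0.0
    trunc = int(mdpc)
    rnd = _round_half_up(mdpc)
    openings = cage_days / ledger.replacement_interval
    risk = (
        per_opening_risk(ledger.contamination_events, openings) if openings > 0 else None
    )
    one_in_n = (
        one_in_n_risk(ledger.contaminated_mouse_days, mouse_days)
        if ledger.contaminated_mouse_days > 0
        else None
    )
    return RiskSummary(
        unit=ledger.unit,
        cage_days=cage_days,
        mouse_days=mouse_days,
        mouse_days_per_cage=mdpc,
        mouse_days_per_cage_trunc=trunc,
        mouse_days_per_cage_round=rnd,
        truncation_ambiguous=trunc != rnd,
        cage_openings=openings,
        per_opening_risk_pct=risk,
        one_in_n_mouse_days=one_in_n,
    )


def per_opening_risk(events: float, openings: float) -> float:
    """Contamination risk per cage-opening, percent, two decimals."""
    if openings <= 0:
        raise UndefinedStatisticError("per-opening risk undefined with zero openings")
    if events < 0:
        raise InvalidParameterError("event count must be >= 0")
    return round(100.0 * events / openings, 2)


def one_in_n_risk(contaminated_mouse_days: float, total_mouse_days: float) -> int | None:
    """'One contaminated day in every N' housing days; ``None`` with no events."""
    if contaminated_mouse_days < 0 or total_mouse_days <= 0:
        raise InvalidParameterError("mouse-day counts must be positive")
    if contaminated_mouse_days == 0:
        return None  # no events: a ratio would be misleading
    return _round_half_up(total_mouse_days / contaminated_mouse_days)


def cage_years(cage_days: float) -> int:
    """Cage-days expressed as whole cage-years (365-day years)."""
    if cage_days < 0:
        raise InvalidParameterError("cage_days must be >= 0")
    return _round_half_up(cage_days / 365.0)


def auc_growth_estimate(final_cages: float, mean_density: float, days: float) -> int:
    """Mouse-days of a colony growing linearly from zero to ``final_cages``.

    Geometric (area-under-the-triangle) estimate:
    ``final_cages * mean_density * days * 0.5``, truncated to an integer.
    """
    if final_cages <= 0 or mean_density <= 0 or days <= 0:
        raise InvalidParameterError("all inputs must be positive")
    return int(final_cages * mean_density * days * 0.5)


@dataclass(frozen=True)
class Table2x2:
    """2x2 count table; rows are housing systems, columns contaminated/clean."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise InvalidParameterError("table counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def swapped(self) -> "Table2x2":
        """Both rows and both columns swapped (Fisher p is invariant)."""
        return Table2x2(self.d, self.c, self.b, self.a)


#: Relative tolerance for probability ties in the two-sided Fisher sum.
_FISHER_TIE_RTOL = 1e-7


def fisher_exact(table: Table2x2, sided: str = "two_sided") -> float:
    """Exact Fisher p-value with fixed margins.

    ``sided="two_sided"`` sums the hypergeometric probabilities of every
    margin-preserving table whose probability is at most the observed
    table's (ties tolerated to a relative 1e-7).  ``sided=
    "one_sided_row2_low"`` is the cumulative probability that the second
    row's first-column count is at most its observed value (e.g. the
    isolators having as few or fewer contaminated openings as seen).

    A table with an empty margin carries no information; by convention its
    p-value is 1, and a warning flags the degenerate input.
    """
    if sided not in ("two_sided", "one_sided_row2_low"):
        raise InvalidParameterError(f"unknown sidedness {sided!r}")
    row1 = table.a + table.b
    row2 = table.c + table.d
    col1 = table.a + table.c
    col2 = table.b + table.d
    n = table.n
    if row1 == 0 or row2 == 0 or col1 == 0 or col2 == 0:
        warnings.warn(
            "degenerate 2x2 table (empty margin): p = 1 by convention",
            category=UserWarning,
            stacklevel=2,
        )
        if n == 0:
            raise DegenerateTableError("empty table")
        return 1.0
    # a ~ Hypergeom(n, col1, row1), support intersected with margins.
    dist = hypergeom(n, col1, row1)
    a_min = max(0, col1 - row2)
    a_max = min(col1, row1)
    support = np.arange(a_min, a_max + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(table.a)
    if sided == "two_sided":
        p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_RTOL)].sum())
    else:
        # row2 count in column 1 is c = col1 - a; c <= c_obs  <=>  a >= a_obs
        p = float(pmf[support >= table.a].sum())
    return min(p, 1.0)


def load_table1() -> pd.DataFrame:
    """The packaged two-year husbandry census fixture.

    Each row carries the raw ledger inputs, the values as printed in the
    source census table, and per-cell ``consistent_*`` flags: a printed cell
    is flagged consistent iff it equals the ledger-identity value under
    either integer reporting convention (truncation or round-half-up).  Two
    printed opening counts and the NesTiso total's mouse-day figures
    contradict the identities and are flagged 0.
    """
    with resources.files("cybed").joinpath("data/table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def ledgers_from_table1(df: pd.DataFrame | None = None) -> list[HusbandryLedger]:
    """Convert fixture rows (including totals) to ledger records."""
    if df is None:
        df = load_table1()
    return [
        HusbandryLedger(
            unit=row.unit,
            n_cages=int(row.n_cages),
            n_adults=int(row.n_adults),
            n_pups=int(row.n_pups),
            days_observed=float(row.days),
            replacement_interval=float(row.interval),
            contamination_events=int(row.events),
            contaminated_mouse_days=float(row.contaminated_mouse_days),
        )
        for row in df.itertuples()
    ]
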