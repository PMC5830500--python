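"""Agreement statistics for germ-free screening tests.

Paired screening methods (e.g. aerobic vs anaerobic fecal culture across a
set of cages) yield a 2x2 concordance table.  Agreement is summarized by
the raw percent agreement and by Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

where ``p_o`` is the observed agreement and ``p_e`` the agreement expected
from the marginals alone.  Two standard-error conventions exist and answer
different questions: the null-hypothesis SE (kappa = 0) underlies the Z
statistic, while the unconditional asymptotic SE is the one reported as a
"plus/minus" on the estimate — both are returned explicitly.

The module also implements the two ways of combining technical replicates
when scoring taxon presence: "in series" sums reads across replicates
(present if detected in any), "in parallel" requires detection in every
replicate.  The parallel presence set is always contained in the series
set, so "in series" is the more sensitive interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import DegenerateTableError, InvalidParameterError, UndefinedStatisticError
from .husbandry import Table2x2

__all__ = [
    "KappaResult",
    "cohen_kappa",
    "percent_agreement",
    "combine_in_series",
    "combine_in_parallel",
    "probability_of_recovery",
]


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with both SE conventions.

    ``se_null`` is the standard error under the kappa = 0 null (used for
    ``z = kappa / se_null``); ``se_asymptotic`` is the unconditional
    large-sample SE appropriate for confidence intervals around the
    estimate.
    """

    kappa: float
    se_null: float
    se_asymptotic: float
    z: float
    agreement_pct: float
    po: float
    pe: float


def percent_agreement(table: Table2x2) -> float:
    """Percent of concordant pairs, one decimal."""
    if table.n == 0:
        raise UndefinedStatisticError("empty table")
    return round(100.0 * (table.a + table.d) / table.n, 1)


def cohen_kappa(table: Table2x2) -> KappaResult:
    """Cohen's kappa for a 2x2 concordance table.

    Raises :class:`DegenerateTableError` when the marginals force
    ``p_e = 1`` (all mass in one concordant cell), where kappa is undefined.
    """
    n = table.n
    if n == 0:
        raise UndefinedStatisticError("empty table")
    a, b, c, d = (v / n for v in (table.a, table.b, table.c, table.d))
    p = [[a, b], [c, d]]
    row = [a + b, c + d]
    col = [a + c, b + d]
    po = a + d
    pe = row[0] * col[0] + row[1] * col[1]
    if math.isclose(pe, 1.0):
        raise DegenerateTableError("degenerate marginals: chance agreement is 1")
    kappa = (po - pe) / (1.0 - pe)

    # SE under H0 (kappa = 0), Fleiss/Cohen:
    s0 = sum(row[i] * col[i] * (row[i] + col[i]) for i in range(2))
    se_null = math.sqrt(max(pe + pe**2 - s0, 0.0)) / ((1.0 - pe) * math.sqrt(n))

    # Unconditional asymptotic SE (Fleiss, Cohen & Everitt):
    t1 = sum(
        p[i][i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2 for i in range(2)
    )
    t2 = (1.0 - kappa) ** 2 * sum(
        p[i][j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    t3 = (kappa - pe * (1.0 - kappa)) ** 2
    var = (t1 + t2 - t3) / (n * (1.0 - pe) ** 2)
    se_asym = math.sqrt(max(var, 0.0))

    z = kappa / se_null if se_null > 0 else math.inf * (1 if kappa > 0 else -1)
    return KappaResult(
        kappa=kappa,
        se_null=se_null,
        se_asymptotic=se_asym,
        z=z,
        agreement_pct=percent_agreement(table),
        po=po,
        pe=pe,
    )


def _check_replicates(reps: Sequence[Mapping[str, int]]) -> list[str]:
    if len(reps) < 2:
        raise InvalidParameterError("need at least two replicates to combine")
    universe = set(reps[0])
    for rep in reps[1:]:
        if set(rep) != universe:
            raise InvalidParameterError("replicates must share the same taxon universe")
    for rep in reps:
        for taxon, count in rep.items():
            if count < 0 or int(count) != count:
                raise InvalidParameterError(
                    f"read count for {taxon!r} must be a non-negative integer"
                )
    return sorted(universe)


def combine_in_series(reps: Sequence[Mapping[str, int]]) -> dict[str, int]:
    """Sum reads across replicates; a taxon is present if the sum is > 0."""
    taxa = _check_replicates(reps)
    return {t: sum(int(rep[t]) for rep in reps) for t in taxa}


def combine_in_parallel(reps: Sequence[Mapping[str, int]]) -> dict[str, bool]:
    """Presence per taxon requiring a positive count in *every* replicate."""
    taxa = _check_replicates(reps)
    return {t: all(rep[t] > 0 for rep in reps) for t in taxa}


def series_presence(reps: Sequence[Mapping[str, int]]) -> dict[str, bool]:
    """Presence under the in-series interpretation."""
    return {t: c > 0 for t, c in combine_in_series(reps).items()}


def probability_of_recovery(
    donor_presence: Mapping[str, bool],
    recipients: Iterable[Mapping[str, bool]],
) -> dict[str, float]:
    """Percent of recipients presenting each donor-present taxon."""
    recipients = list(recipients)
    if not recipients:
        raise UndefinedStatisticError("no recipients: recovery probability undefined")
    donor_taxa = [t for t, present in donor_presence.items() if present]
    for rec in recipients:
        missing = [t for t in donor_taxa if t not in rec]
        if missing:
            raise InvalidParameterError(
                f"recipient profile missing taxa {missing!r} from the shared universe"
            )
    return {
        t: 100.0 * sum(bool(rec[t]) for rec in recipients) / len(recipients)
        for t in donor_taxa
    }
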