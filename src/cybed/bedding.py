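"""Bedding soiledness accumulation and substrate-dependent growth.

Soiledness — the accumulated feces, spilled diet and moisture mixed into the
bedding substrate — builds up linearly in both animal density and bedding
age: a cage with ``m`` mice accumulates ``phi * m * t`` grams of feces and
``delta * m * t`` grams of spilled diet per gram of clean substrate over
``t`` days.  The shipped default rates are calibrated to the single
quantified composition datum for a 5-mouse cage at day 10 (6.9% feces,
43.6% diet by mass).

Soiledness also reshapes which taxa can grow in the bedding: each taxon
carries a substrate-response curve mapping the soiled-bedding mass fraction
``s`` to effective growth parameters (r_eff, K_eff).  The shipped defaults
for the three-taxon aerobic cocktail (Enterococcus faecalis, Escherichia
coli, Lactobacillus murinus) encode the observed orderings: E. faecalis is
resilient to soiledness and grows even on plain diet, E. coli is fast on
clean substrate but the least adapted to the cage environment, and
L. murinus peaks on intermediate (≈5-day) soiledness before E. faecalis
overgrows it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import CommunityState, TaxonParams, integrate_community
from .errors import CalibrationError, ConfigurationError, InvalidParameterError

__all__ = [
    "BeddingComposition",
    "AccumulationRates",
    "SoilednessScenario",
    "ResponseCurve",
    "accumulate",
    "calibrate",
    "growth_modifier",
    "simulate_cocktail",
    "default_rates",
    "default_cocktail",
    "DEFAULT_SCENARIOS",
    "CALIBRATION_DATUM",
]

#: The quantified bedding composition the default rates reproduce:
#: by day 10, a 5-mouse bedding contains 6.9% feces and 43.6% diet by mass.
CALIBRATION_DATUM = {"feces_frac": 0.069, "diet_frac": 0.436, "m": 5, "t": 10.0}


@dataclass(frozen=True)
class AccumulationRates:
    """Linear soiling rates, mass per mouse-day per unit clean-substrate mass."""

    phi: float  # feces deposition
    delta: float  # diet spillage
    omega: float = 0.0  # water/moisture (excluded from the default calibration)

    def __post_init__(self) -> None:
        if self.phi < 0 or self.delta < 0 or self.omega < 0:
            raise InvalidParameterError("accumulation rates must be non-negative")


@dataclass(frozen=True)
class BeddingComposition:
    """Masses of the bedding constituents after ``t`` days with ``m`` mice."""

    B0: float
    feces: float
    diet: float
    water: float
    t: float
    m: int

    @property
    def total(self) -> float:
        return self.B0 + self.feces + self.diet + self.water

    @property
    def feces_fraction(self) -> float:
        return self.feces / self.total

    @property
    def diet_fraction(self) -> float:
        return self.diet / self.total

    @property
    def water_fraction(self) -> float:
        return self.water / self.total

    @property
    def substrate_fraction(self) -> float:
        return self.B0 / self.total

    @property
    def soiled_fraction(self) -> float:
        """Total non-substrate mass fraction (the soiledness state s)."""
        return (self.feces + self.diet + self.water) / self.total

    def fractions(self) -> dict[str, float]:
        return {
            "substrate": self.substrate_fraction,
            "feces": self.feces_fraction,
            "diet": self.diet_fraction,
            "water": self.water_fraction,
        }


def accumulate(
    rates: AccumulationRates, m: int, t: float, B0: float = 1.0
) -> BeddingComposition:
    """Bedding composition after ``t`` days of soiling by ``m`` mice.

    Deposition is linear in mouse-days: ``feces = phi m t`` etc., with
    fractions taken over the grand total ``B0 + feces + diet + water``.
    """
    if m < 0 or t < 0:
        raise InvalidParameterError("mouse count and bedding age must be non-negative")
    if not (B0 > 0):
        raise InvalidParameterError("clean substrate mass must be positive")
    mt = m * t
    return BeddingComposition(
        B0=B0,
        feces=rates.phi * mt * B0,
        diet=rates.delta * mt * B0,
        water=rates.omega * mt * B0,
        t=t,
        m=m,
    )


def calibrate(
    feces_frac: float, diet_frac: float, m: int, t: float
) -> AccumulationRates:
    """Invert the accumulation model from one observed composition.

    Solves for the unique ``(phi, delta)`` (with ``B0`` normalized to 1 and
    ``omega = 0``) whose forward evaluation at ``(m, t)`` reproduces the given
    mass fractions exactly: ``accumulate(calibrate(f, g, m, t), m, t)`` is an
    algebraic round trip.
    """
    if feces_frac < 0 or diet_frac < 0:
        raise InvalidParameterError("fractions must be non-negative")
    if feces_frac + diet_frac >= 1:
        raise CalibrationError(
            "feces and diet fractions must sum to < 1 (the substrate has mass)"
        )
    if m * t <= 0 and (feces_frac > 0 or diet_frac > 0):
        raise InvalidParameterError("need m*t > 0 to calibrate nonzero fractions")
    if feces_frac == 0 and diet_frac == 0:
        return AccumulationRates(0.0, 0.0)
    # With B0 = 1: frac_i = rate_i*mt / (1 + (phi+delta)*mt).  The ratio
    # fixes phi/delta and the sum fixes (phi+delta)*mt.
    s = feces_frac + diet_frac
    total_rate_mt = s / (1.0 - s)
    phi = feces_frac / s * total_rate_mt / (m * t)
    delta = diet_frac / s * total_rate_mt / (m * t)
    return AccumulationRates(phi, delta)


def default_rates() -> AccumulationRates:
    """Accumulation rates calibrated to the packaged day-10, 5-mouse datum."""
    d = CALIBRATION_DATUM
    return calibrate(d["feces_frac"], d["diet_frac"], d["m"], d["t"])


@dataclass(frozen=True)
class SoilednessScenario:
    """A growth substrate for the in-vitro cocktail experiment.

    ``s`` is the soiled-bedding mass fraction mixed into clean bedding;
    ``s = 0.10`` and ``s = 0.50`` are the surrogates for 1-day- and
    5-day-soiled bedding under the accumulation model.  ``diet_only`` marks
    the plain ground-diet substrate, which is handled as its own response
    point rather than via ``s``.
    """

    label: str
    s: float
    diet_only: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise InvalidParameterError("soiled fraction s must be in [0, 1]")


DEFAULT_SCENARIOS: dict[str, SoilednessScenario] = {
    "clean": SoilednessScenario("clean", 0.0),
    "soiled_10pct": SoilednessScenario("soiled_10pct", 0.10),
    "soiled_50pct": SoilednessScenario("soiled_50pct", 0.50),
    "soiled_100pct": SoilednessScenario("soiled_100pct", 1.0),
    "diet_only": SoilednessScenario("diet_only", 0.0, diet_only=True),
}


@dataclass(frozen=True)
class ResponseCurve:
    """Piecewise-linear substrate response of one taxon.

    ``r_knots`` / ``k_knots`` are ``(s, multiplier)`` pairs interpolated
    linearly in the soiled fraction ``s``; multipliers scale the taxon's
    base ``r`` and ``K``.  ``diet_only_r`` / ``diet_only_k`` override the
    curve on the plain-diet substrate (a growth-rate multiplier may be
    negative: some taxa decline on plain diet).
    """

    r_knots: tuple[tuple[float, float], ...] = ((0.0, 1.0), (1.0, 1.0))
    k_knots: tuple[tuple[float, float], ...] = ((0.0, 1.0), (1.0, 1.0))
    diet_only_r: float = 1.0
    diet_only_k: float = 1.0

    def _interp(self, knots, s: float) -> float:
        xs = [k[0] for k in knots]
        ys = [k[1] for k in knots]
        if sorted(xs) != list(xs):
            raise ConfigurationError("response-curve knots must be sorted in s")
        return float(np.interp(s, xs, ys))

    def modifiers(self, scenario: SoilednessScenario) -> tuple[float, float]:
        if scenario.diet_only:
            return self.diet_only_r, self.diet_only_k
        return self._interp(self.r_knots, scenario.s), self._interp(self.k_knots, scenario.s)


#: Shared capacity response: clean sterile substrate supports little growth,
#: nutrient (soiled or diet) substrates approach the full capacity.
_K_KNOTS = ((0.0, 0.1), (0.1, 0.3), (0.5, 0.8), (1.0, 1.0))

DEFAULT_RESPONSES: dict[str, ResponseCurve] = {
    # Resilient to soiledness; readily grows on plain diet.
    "E. faecalis": ResponseCurve(
        r_knots=((0.0, 1.0), (0.1, 1.1), (0.5, 1.25), (1.0, 1.3)),
        k_knots=_K_KNOTS,
        diet_only_r=0.6,
        diet_only_k=1.0,
    ),
    # Fast grower on clean substrate, least adapted to the cage environment;
    # plain diet disfavors survival (negative net rate).
    "E. coli": ResponseCurve(
        r_knots=((0.0, 1.0), (0.1, 0.8), (0.5, 0.4), (1.0, 0.15)),
        k_knots=_K_KNOTS,
        diet_only_r=-0.4,
        diet_only_k=1.0,
    ),
    # Non-monotone optimum at intermediate (≈5-day) soiledness.
    "L. murinus": ResponseCurve(
        r_knots=((0.0, 1.0), (0.1, 1.05), (0.5, 1.4), (1.0, 0.9)),
        k_knots=_K_KNOTS,
        diet_only_r=-0.1,
        diet_only_k=1.0,
    ),
}


def default_cocktail() -> list[TaxonParams]:
    """The three-taxon aerobic cocktail with its default interactions.

    E. faecalis inhibits L. murinus when in close proximity (a = 2.0); all
    other pairwise competition is weak (a = 0.5), keeping coexistence
    possible at low density.
    """
    inhibition = 2.0
    weak = 0.5
    return [
        TaxonParams(
            "E. faecalis",
            r=0.9,
            K=1e8,
            interactions={"E. coli": weak, "L. murinus": weak},
            substrate_response=DEFAULT_RESPONSES["E. faecalis"],
        ),
        TaxonParams(
            "E. coli",
            r=1.2,
            K=1e8,
            interactions={"E. faecalis": weak, "L. murinus": weak},
            substrate_response=DEFAULT_RESPONSES["E. coli"],
        ),
        TaxonParams(
            "L. murinus",
            r=0.7,
            K=1e8,
            interactions={"E. faecalis": inhibition, "E. coli": weak},
            substrate_response=DEFAULT_RESPONSES["L. murinus"],
        ),
    ]


def growth_modifier(
    taxon: TaxonParams, scenario: SoilednessScenario
) -> tuple[float, float]:
    """Effective ``(r_eff, K_eff)`` of ``taxon`` on the given substrate."""
    curve = taxon.substrate_response
    if curve is None:
        curve = DEFAULT_RESPONSES.get(taxon.name)
    if curve is None:
        raise ConfigurationError(
            f"no substrate response curve configured for taxon {taxon.name!r}"
        )
    r_mult, k_mult = curve.modifiers(scenario)
    return taxon.r * r_mult, taxon.K * k_mult


def simulate_cocktail(
    inoculum_ratio: dict[str, float] | None = None,
    scenarios: list[SoilednessScenario] | None = None,
    duration: float = 9.0,
    *,
    taxa: list[TaxonParams] | None = None,
    total_inoculum: float = 3e5,
    n_points: int = 46,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Grow the cocktail on each substrate and rank taxa at the endpoint.

    Each scenario substitutes substrate-modified ``(r_eff, K_eff)`` into the
    community model (interactions unchanged) and integrates for ``duration``
    days from the inoculum.  Returns a long-format CFU trajectory table
    (``scenario``, ``time_days``, ``taxon``, ``abundance_cfu_per_g``) and the
    final abundance ranking per scenario (most abundant first).
    """
    if taxa is None:
        taxa = default_cocktail()
    names = [p.name for p in taxa]
    if inoculum_ratio is None:
        inoculum_ratio = {n: 1.0 for n in names}
    total_ratio = sum(inoculum_ratio.values())
    if total_ratio <= 0:
        raise InvalidParameterError("inoculum fractions must sum to a positive total")
    if not (duration > 0):
        raise InvalidParameterError("duration must be positive")
    if scenarios is None:
        scenarios = list(DEFAULT_SCENARIOS.values())

    N0 = np.array([inoculum_ratio.get(n, 0.0) / total_ratio * total_inoculum for n in names])
    frames = []
    rankings: dict[str, list[str]] = {}
    for sc in scenarios:
        eff = [p.with_effective(*growth_modifier(p, sc)) for p in taxa]
        state = CommunityState(0.0, tuple(names), N0.copy())
        t_eval = np.linspace(0.0, duration, n_points)
        times, N_traj, _ = integrate_community(state, eff, duration, t_eval=t_eval)
        df = pd.DataFrame(
            {
                "scenario": sc.label,
                "time_days": np.repeat(times, len(names)),
                "taxon": np.tile(names, len(times)),
                "abundance_cfu_per_g": N_traj.ravel(),
            }
        )
        frames.append(df)
        final = N_traj[-1]
        rankings[sc.label] = [names[i] for i in np.argsort(-final, kind="stable")]
    return pd.concat(frames, ignore_index=True), rankings
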