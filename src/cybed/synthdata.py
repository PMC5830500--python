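"""Seeded generators of synthetic study inputs.

The centerpiece emulates the "co-streaking" experiment: cohoused mice with
individually distinct cultivable fecal profiles are observed over repeated
bedding cycles.  Each mouse carries a latent colony-type composition pulled
toward a host-specific attractor (individuality); the cage bedding hosts
its own community in which colony types grow at different rates, so the
bedding is progressively taken over by fast growers as it soils.
Mouse-bedding exchange strengthens with the current feces fraction of the
bedding, so late in a cycle every mouse converges toward the same
bedding-selected profile, and a cage change (dilution event) resets the
bedding and lets individuality re-emerge.  Observed profiles are reduced to
ranked colony-type signatures, whose count of distinct values per timepoint
oscillates with the bedding cycle.

Colony types are abstract labels (plate morphotypes, not sequenced taxa).
All randomness flows from one top-level seed through named substreams, so
adding a generator never perturbs the output of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping
from zlib import crc32

import numpy as np
import pandas as pd

from .bedding import AccumulationRates, accumulate, default_rates
from .dynamics import CycleSchedule
from .errors import InvalidParameterError
from .husbandry import Table2x2

__all__ = [
    "ExperimentConfig",
    "CostreakProfile",
    "simulate_costreak_experiment",
    "profile_signature",
    "diversity",
    "diversity_by_day",
    "gen_plate_counts",
    "choose_dilution",
    "gen_agreement_tables",
    "AgreementSample",
    "analytic_kappa",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of a top-level seed.

    The stream key is a CRC32 of the name (stable across processes, unlike
    built-in string hashing), so each generator owns an independent stream.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), crc32(name.encode())]))


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the synthetic co-streaking experiment.

    The defaults mirror the emulated study: 9 mice in 3 cages observed on
    days 3 and 10 of three 10-day bedding cycles.  ``kappa0`` is the
    mouse-bedding exchange rate per day per unit feces fraction;
    ``host_rate`` the relaxation rate toward each mouse's own attractor;
    ``bedding_mix_rate`` the rate at which fresh fecal deposits mix into the
    bedding community.  Type growth rates in the bedding span
    ``type_r_range`` (per day), creating the fast-grower selection that
    drives late-cycle convergence.
    """

    n_mice: int = 3
    n_cages: int = 3
    n_types: int = 6
    schedule: CycleSchedule = field(
        default_factory=lambda: CycleSchedule(T=10.0, d=0.01, n_cycles=3)
    )
    kappa0: float = 60.0
    host_rate: float = 0.5
    bedding_mix_rate: float = 2.0
    type_r_range: tuple[float, float] = (0.1, 1.0)
    individuality: float = 0.5  # Dirichlet concentration of host attractors
    observation_days: tuple[float, ...] = (3.0, 10.0)
    signature_k: int = 3
    detection: float = 0.01
    dt: float = 0.25
    rates: AccumulationRates = field(default_factory=default_rates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.n_cages < 1 or self.n_types < 2:
            raise InvalidParameterError("need >= 1 mouse/cage and >= 2 colony types")
        if self.kappa0 < 0 or self.host_rate < 0 or self.bedding_mix_rate < 0:
            raise InvalidParameterError("rates must be non-negative")
        if any(d <= 0 or d > self.schedule.T for d in self.observation_days):
            raise InvalidParameterError("observation days must lie within a cycle")

    def type_labels(self) -> list[str]:
        return [f"type_{chr(ord('A') + i)}" for i in range(self.n_types)]


@dataclass(frozen=True)
class CostreakProfile:
    """One mouse's observed composition and ranked signature on one day."""

    cage: int
    mouse: int
    day: float
    composition: Mapping[str, float]
    signature: tuple[str, ...]


def profile_signature(
    composition: Mapping[str, float], k: int, detection: float = 0.01
) -> tuple[str, ...]:
    """Ranked labels of the ``k`` most abundant colony types.

    Types below the ``detection`` fraction (semi-quantitative plate reading
    cannot resolve them) are excluded; ties are broken by label order.
    """
    if k < 1:
        raise InvalidParameterError("signature length k must be >= 1")
    ranked = sorted(composition.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(label for label, frac in ranked[:k] if frac >= detection)


def diversity(profiles: Iterable[CostreakProfile | tuple]) -> int:
    """Number of distinct signatures among profiles at one timepoint."""
    sigs = [
        p.signature if isinstance(p, CostreakProfile) else tuple(p) for p in profiles
    ]
    if not sigs:
        raise InvalidParameterError("need at least one profile")
    return len(set(sigs))


def simulate_costreak_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate per-mouse colony-type profiles over repeated bedding cycles.

    Returns a long-format table with one row per (cage, mouse, day, type):
    columns ``cage``, ``mouse``, ``day``, ``type``, ``fraction`` and the
    mouse's ranked ``signature`` (joined with ``|``).  Bit-reproducible for
    a fixed ``config.seed``.
    """
    rng = substream(config.seed, "costreak")
    labels = config.type_labels()
    r_types = np.linspace(*config.type_r_range, config.n_types)
    T, n_cycles, dt = config.schedule.T, config.schedule.n_cycles, config.dt
    n_steps = int(round(T / dt))
    rows: list[tuple] = []

    for cage in range(config.n_cages):
        # Host attractors: spiky Dirichlet draws encode individuality.
        h = rng.dirichlet(np.full(config.n_types, config.individuality), size=config.n_mice)
        x = h.copy()
        for cyc in range(n_cycles):
            # Cage change: fresh substrate, bedding community re-seeded by deposits.
            b = x.mean(axis=0).copy()
            t_local = 0.0
            for _ in range(n_steps):
                s = accumulate(config.rates, config.n_mice, t_local).feces_fraction
                lam = config.kappa0 * s
                # Bedding: differential growth of types, then fresh deposits mix in.
                b = b * np.exp(r_types * dt)
                b /= b.sum()
                b = (1.0 - config.bedding_mix_rate * dt) * b + (
                    config.bedding_mix_rate * dt
                ) * x.mean(axis=0)
                # Mice: relax to host attractor, exchange with bedding.
                x = x + dt * (config.host_rate * (h - x) + lam * (b[None, :] - x))
                x = np.clip(x, 0.0, None)
                x /= x.sum(axis=1, keepdims=True)
                t_local += dt
                for obs_day in config.observation_days:
                    if abs(t_local - obs_day) < dt / 2:
                        day = cyc * T + obs_day
                        for mouse in range(config.n_mice):
                            comp = dict(zip(labels, x[mouse]))
                            sig = profile_signature(
                                comp, config.signature_k, config.detection
                            )
                            for label, frac in comp.items():
                                rows.append(
                                    (cage, mouse, day, label, frac, "|".join(sig))
                                )
    return pd.DataFrame(
        rows, columns=["cage", "mouse", "day", "type", "fraction", "signature"]
    )


def diversity_by_day(profiles: pd.DataFrame, within_cage: bool = False) -> pd.Series:
    """Distinct-signature count per observation day.

    With ``within_cage=True`` the count is averaged over cages (distinct
    profiles among cage-mates); otherwise signatures are pooled across all
    mice, as when co-streaking every mouse on one plate.
    """
    per_mouse = profiles.drop_duplicates(["cage", "mouse", "day"])[
        ["cage", "mouse", "day", "signature"]
    ]
    if within_cage:
        return per_mouse.groupby(["day", "cage"]).signature.nunique().groupby("day").mean()
    return per_mouse.groupby("day").signature.nunique()


def gen_plate_counts(
    true_cfu: float,
    dilution_exponent: int,
    seed: int | np.random.Generator,
    *,
    volume: float = 1.0,
) -> int:
    """Poisson colony count from plating a 10-fold serial dilution.

    The expected count is ``true_cfu * 10**-dilution_exponent * volume``.
    """
    if true_cfu < 0:
        raise InvalidParameterError("true CFU density must be non-negative")
    if volume <= 0:
        raise InvalidParameterError("plated volume must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "plate")
    mean = true_cfu * 10.0 ** (-dilution_exponent) * volume
    if mean == 0.0:
        return 0
    return int(rng.poisson(mean))


def choose_dilution(true_cfu: float, *, volume: float = 1.0) -> int:
    """Dilution exponent whose expected colony count falls in 30-300.

    Picks the smallest exponent with expectation <= 300 (and hence >= 30
    when such an exponent exists); 0 when the sample is countable neat.
    """
    if true_cfu <= 0:
        return 0
    exponent = max(0, math.ceil(math.log10(true_cfu * volume / 300.0)))
    return exponent


@dataclass(frozen=True)
class AgreementSample:
    """A simulated paired-test dataset with its latent truth."""

    table: Table2x2
    truth: np.ndarray  # latent contamination status per cage
    test_a: np.ndarray
    test_b: np.ndarray


def gen_agreement_tables(
    n_cages: int,
    sens_a: float,
    spec_a: float,
    sens_b: float,
    spec_b: float,
    prevalence: float,
    seed: int | np.random.Generator,
) -> AgreementSample:
    """Paired screening outcomes on ``n_cages`` cages.

    Each cage is contaminated with probability ``prevalence``; tests A and B
    fire independently given the truth with the stated sensitivity and
    specificity.  The 2x2 table cells are (a: both positive, b: A+/B-,
    c: A-/B+, d: both negative).
    """
    for name, p in (
        ("sens_a", sens_a),
        ("spec_a", spec_a),
        ("sens_b", sens_b),
        ("spec_b", spec_b),
        ("prevalence", prevalence),
    ):
        if not (0.0 <= p <= 1.0):
            raise InvalidParameterError(f"{name} must be a probability")
    if n_cages < 1:
        raise InvalidParameterError("need at least one cage")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "agreement")
    truth = rng.random(n_cages) < prevalence
    p_a = np.where(truth, sens_a, 1.0 - spec_a)
    p_b = np.where(truth, sens_b, 1.0 - spec_b)
    test_a = rng.random(n_cages) < p_a
    test_b = rng.random(n_cages) < p_b
    table = Table2x2(
        a=int(np.sum(test_a & test_b)),
        b=int(np.sum(test_a & ~test_b)),
        c=int(np.sum(~test_a & test_b)),
        d=int(np.sum(~test_a & ~test_b)),
    )
    return AgreementSample(table=table, truth=truth, test_a=test_a, test_b=test_b)


def analytic_kappa(
    sens_a: float, spec_a: float, sens_b: float, spec_b: float, prevalence: float
) -> float:
    """Population kappa of the paired-test generating process.

    Cell probabilities follow from conditional independence of the two tests
    given the latent contamination status.
    """
    pi = prevalence
    p11 = pi * sens_a * sens_b + (1 - pi) * (1 - spec_a) * (1 - spec_b)
    p10 = pi * sens_a * (1 - sens_b) + (1 - pi) * (1 - spec_a) * spec_b
    p01 = pi * (1 - sens_a) * sens_b + (1 - pi) * spec_a * (1 - spec_b)
    p00 = pi * (1 - sens_a) * (1 - sens_b) + (1 - pi) * spec_a * spec_b
    po = p11 + p00
    row1, col1 = p11 + p10, p11 + p01
    pe = row1 * col1 + (1 - row1) * (1 - col1)
    return (po - pe) / (1 - pe)
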