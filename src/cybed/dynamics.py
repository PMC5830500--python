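"""Logistic growth with periodic dilution events.

Microbial populations in cage bedding grow continuously between husbandry
events and are diluted abruptly whenever the cage (and hence the bedding
substrate) is replaced.  Between events a taxon follows logistic growth

    dN/dt = r N (1 - N / K),

and at each replacement, every ``T`` days, only a fraction ``d`` of the
population carries over (residual transfer on the mice themselves).  The
composition of the cage community over many cycles is then governed by the
low-density per-cycle multiplier

    mu = d * exp(r T),

which splits taxa into persisters (mu > 1, converging to a periodic orbit
with pre-event abundance ``N_star``) and taxa driven to extinction
(mu < 1).  The critical growth rate separating the two regimes is
``r_crit = ln(1/d) / T``: persistence in the bedding depends on the speed
of growth relative to the dilution schedule, not on the starting abundance.

Multi-taxon communities extend the single-taxon model with Lotka-Volterra
competition,

    dN_i/dt = r_i N_i (1 - sum_j a_ij N_j / K_i),   a_ii = 1,

which reduces exactly to the logistic model when a single taxon is present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidParameterError

__all__ = [
    "TaxonParams",
    "CommunityState",
    "CycleSchedule",
    "TaxonOutcome",
    "CycleOutcome",
    "logistic_solution",
    "integrate_community",
    "apply_dilution",
    "run_cycles",
    "persistence_multiplier",
    "cycle_map_fixed_point",
    "critical_rate",
    "cycle_map",
    "iterate_cycle_map",
    "persistence_diagram",
]

#: Default integrator relative tolerance between events.
DEFAULT_RTOL = 1e-8


@dataclass(frozen=True)
class TaxonParams:
    """Growth parameters of one taxon.

    Parameters
    ----------
    name : str
        Taxon label.
    r : float
        Intrinsic growth rate in the bedding, per day.  May be negative to
        model net decline on a hostile substrate.
    K : float
        Carrying capacity, CFU per gram of bedding.  Must be positive.
    interactions : mapping of str to float
        Competition coefficients ``a_ij`` against *other* taxa (the self
        coefficient is fixed at 1).  Missing entries default to 0
        (no interaction).
    substrate_response : object, optional
        Growth-modifier curve mapping bedding soiledness to effective
        (r, K); see :mod:`cybed.bedding`.
    """

    name: str
    r: float
    K: float
    interactions: Mapping[str, float] = field(default_factory=dict)
    substrate_response: object | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.r):
            raise InvalidParameterError(f"growth rate of {self.name!r} must be finite")
        if not (self.K > 0) or not math.isfinite(self.K):
            raise InvalidParameterError(f"carrying capacity of {self.name!r} must be > 0")
        for other, a in self.interactions.items():
            if a < 0:
                raise InvalidParameterError(
                    f"interaction a({self.name} <- {other}) must be >= 0, got {a}"
                )

    def with_effective(self, r_eff: float, K_eff: float) -> "TaxonParams":
        """Copy of these parameters with substrate-modified (r, K)."""
        return replace(self, r=r_eff, K=K_eff)


@dataclass
class CommunityState:
    """Abundances of a community at one instant.

    ``N`` is in CFU per gram of bedding; ``extinct`` marks taxa whose
    abundance fell below the extinction threshold at a dilution event
    (absorbing: extinct taxa have abundance exactly 0 thereafter).
    """

    t: float
    names: tuple[str, ...]
    N: np.ndarray
    extinct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        if self.N.ndim != 1 or len(self.N) != len(self.names):
            raise InvalidParameterError("N must be a vector with one entry per taxon")
        if np.any(self.N < 0):
            raise InvalidParameterError("abundances must be non-negative")
        if self.extinct is None:
            self.extinct = np.zeros(len(self.names), dtype=bool)
        else:
            self.extinct = np.asarray(self.extinct, dtype=bool)
        if np.any(self.N[self.extinct] != 0):
            raise InvalidParameterError("extinct taxa must have abundance 0")

    def copy(self) -> "CommunityState":
        return CommunityState(self.t, self.names, self.N.copy(), self.extinct.copy())


@dataclass(frozen=True)
class CycleSchedule:
    """Periodic cage-replacement schedule.

    Parameters
    ----------
    T : float
        Replacement interval in days (default 10, the routine husbandry
        interval for static cages).
    d : float
        Carry-over fraction per event, in (0, 1].  ``d = 1`` means no
        dilution at all.
    n_cycles : int
        Number of dilution events to simulate.
    N_min : float
        Extinction threshold in CFU per gram, applied immediately after
        each dilution: sub-threshold populations are unphysical in a
        deterministic model and are set to zero.
    """

    T: float = 10.0
    d: float = 0.01
    n_cycles: int = 20
    N_min: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise InvalidParameterError("replacement interval T must be > 0")
        if not (0 < self.d <= 1):
            raise InvalidParameterError("carry-over fraction d must be in (0, 1]")
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")
        if not (self.N_min > 0):
            raise InvalidParameterError("extinction threshold N_min must be > 0")


@dataclass(frozen=True)
class TaxonOutcome:
    """Fate of one taxon after repeated dilution cycles."""

    status: str  # "persistent" | "extinct"
    mu: float
    N_star: float | None
    cycles_to_extinction: int | None


@dataclass(frozen=True)
class CycleOutcome:
    """Per-taxon persistence classification for a completed simulation."""

    taxa: Mapping[str, TaxonOutcome]

    def __getitem__(self, name: str) -> TaxonOutcome:
        return self.taxa[name]

    def to_dict(self) -> dict:
        return {
            name: {
                "status": o.status,
                "mu": o.mu,
                "N_star": o.N_star,
                "cycles_to_extinction": o.cycles_to_extinction,
            }
            for name, o in self.taxa.items()
        }


def logistic_solution(N0: float, r: float, K: float, t: float) -> float:
    """Closed-form logistic growth from ``N0`` over ``t`` days.

    Returns ``K N0 e^{rt} / (K + N0 (e^{rt} - 1))``, the exact solution of
    ``dN/dt = r N (1 - N/K)``; no numerical integration is involved.
    """
    if N0 < 0:
        raise InvalidParameterError("initial abundance must be non-negative")
    if not (K > 0):
        raise InvalidParameterError("carrying capacity must be > 0")
    if t < 0:
        raise InvalidParameterError("duration must be non-negative")
    if N0 == 0.0 or t == 0.0:
        return float(N0)
    # Rearranged to stay stable for large r*t: divide through by e^{rt}.
    ert = math.exp(r * t)
    if math.isinf(ert):
        return float(K)
    return K * N0 * ert / (K + N0 * (ert - 1.0))


def _competition_matrix(params: Sequence[TaxonParams]) -> np.ndarray:
    names = [p.name for p in params]
    A = np.zeros((len(params), len(params)))
    for i, p in enumerate(params):
        A[i, i] = 1.0
        for other, a in p.interactions.items():
            if other == p.name:
                continue
            if other in names:
                A[i, names.index(other)] = a
    return A


def integrate_community(
    state: CommunityState,
    params: Sequence[TaxonParams],
    t_span: float,
    *,
    t_eval: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
) -> tuple[np.ndarray, np.ndarray, CommunityState]:
    """Integrate Lotka-Volterra competition over ``t_span`` days.

    Returns ``(times, N, final_state)`` where ``times`` are absolute times
    (``state.t`` offset included), ``N`` has shape ``(len(times), n_taxa)``
    and ``final_state`` is the community at ``state.t + t_span``.  A
    single-taxon community follows the closed-form logistic solution to
    within the integrator tolerance.
    """
    if t_span < 0:
        raise InvalidParameterError("t_span must be non-negative")
    names = tuple(p.name for p in params)
    if names != state.names:
        raise InvalidParameterError("state and params must list the same taxa in order")
    n = len(params)
    r = np.array([p.r for p in params])
    K = np.array([p.K for p in params])
    A = _competition_matrix(params)
    alive = ~state.extinct

    if t_eval is None:
        t_local = np.array([0.0, t_span]) if t_span > 0 else np.array([0.0])
    else:
        t_local = np.asarray(t_eval, dtype=float) - state.t
        if np.any(t_local < -1e-12) or np.any(t_local > t_span + 1e-12):
            raise InvalidParameterError("t_eval outside integration span")
        t_local = np.clip(t_local, 0.0, t_span)

    if t_span == 0 or not np.any(state.N > 0):
        N_out = np.tile(state.N, (len(t_local), 1))
        return t_local + state.t, N_out, state.copy()

    def rhs(_t: float, N: np.ndarray) -> np.ndarray:
        N = np.maximum(N, 0.0)
        dN = r * N * (1.0 - (A @ N) / K)
        dN[~alive] = 0.0
        return dN

    sol = solve_ivp(
        rhs,
        (0.0, t_span),
        state.N,
        method="LSODA",
        t_eval=t_local if t_eval is not None else None,
        rtol=rtol,
        # essentially pure relative control: decaying populations span many
        # decades and must keep relative accuracy all the way down
        atol=1e-290,
        dense_output=t_eval is None,
    )
    if not sol.success:
        raise IntegrationError(
            f"integrator failed: {sol.message}", t_fail=float(sol.t[-1]) + state.t
        )
    if t_eval is None:
        N_out = sol.sol(t_local).T if n else np.empty((len(t_local), 0))
    else:
        N_out = sol.y.T
    N_out = np.maximum(N_out, 0.0)
    final = CommunityState(state.t + t_span, names, N_out[-1], state.extinct.copy())
    return t_local + state.t, N_out, final


def apply_dilution(state: CommunityState, d: float, N_min: float) -> CommunityState:
    """Dilution event: multiply abundances by ``d``, zero out sub-threshold taxa.

    A taxon whose diluted abundance falls below ``N_min`` is flagged extinct;
    extinction is absorbing.
    """
    if not (0 < d <= 1):
        raise InvalidParameterError("carry-over fraction d must be in (0, 1]")
    N = state.N * d
    extinct = state.extinct | (N < N_min)
    N[extinct] = 0.0
    return CommunityState(state.t, state.names, N, extinct)


def run_cycles(
    state0: CommunityState,
    params: Sequence[TaxonParams],
    schedule: CycleSchedule,
    *,
    points_per_cycle: int = 21,
    rtol: float = DEFAULT_RTOL,
) -> tuple[pd.DataFrame, CycleOutcome]:
    """Alternate growth over ``T`` with dilution at ``t = kT``.

    Events occur exactly at multiples of ``T``; both the pre-event and
    post-event states are recorded at the event timestamp (ordered
    ``pre_event`` then ``post_event``) so trajectories are unambiguous.

    Returns a long-format trajectory (columns ``time_days``, ``taxon``,
    ``abundance_cfu_per_g``, ``phase``) and the per-taxon
    :class:`CycleOutcome`.
    """
    names = state0.names
    state = state0.copy()
    rows: list[tuple[float, str, float, str]] = []
    cycles_to_ext: dict[str, int | None] = {n: None for n in names}

    def record(t: float, N: np.ndarray, phase: str) -> None:
        for j, name in enumerate(names):
            rows.append((t, name, float(N[j]), phase))

    record(state.t, state.N, "interior")
    for k in range(1, schedule.n_cycles + 1):
        t_eval = state.t + np.linspace(0.0, schedule.T, points_per_cycle)
        times, N_traj, state = integrate_community(
            state, params, schedule.T, t_eval=t_eval, rtol=rtol
        )
        for ti, Ni in zip(times[1:-1], N_traj[1:-1]):
            record(ti, Ni, "interior")
        record(state.t, state.N, "pre_event")
        newly_alive = ~state.extinct
        state = apply_dilution(state, schedule.d, schedule.N_min)
        record(state.t, state.N, "post_event")
        for j, name in enumerate(names):
            if newly_alive[j] and state.extinct[j]:
                cycles_to_ext[name] = k

    outcome = {}
    for j, p in enumerate(params):
        mu = persistence_multiplier(p.r, schedule.T, schedule.d)
        n_star = cycle_map_fixed_point(p.r, p.K, schedule.T, schedule.d)
        status = "extinct" if state.extinct[j] or state.N[j] == 0 else "persistent"
        outcome[p.name] = TaxonOutcome(
            status=status,
            mu=mu,
            N_star=n_star if status == "persistent" else None,
            cycles_to_extinction=cycles_to_ext[p.name],
        )
    traj = pd.DataFrame(rows, columns=["time_days", "taxon", "abundance_cfu_per_g", "phase"])
    return traj, CycleOutcome(outcome)


def persistence_multiplier(r: float, T: float, d: float) -> float:
    """Low-density per-cycle multiplier ``mu = d e^{rT}``.

    Over one cycle a rare population grows by ``e^{rT}`` and is then diluted
    by ``d``; it invades (persists) iff ``mu > 1``.
    """
    if not (T > 0) or not (0 < d <= 1):
        raise InvalidParameterError("require T > 0 and 0 < d <= 1")
    return d * math.exp(r * T)


def cycle_map_fixed_point(r: float, K: float, T: float, d: float) -> float | None:
    """Pre-event fixed point of the cycle map, or ``None`` below threshold.

    The map ``N -> logistic_solution(d N, r, K, T)`` (dilute, then regrow for
    ``T`` days) has the unique positive fixed point

        N_star = K (d e^{rT} - 1) / (d (e^{rT} - 1))

    whenever ``mu = d e^{rT} > 1``; otherwise every positive orbit decays to
    extinction and ``None`` is returned.  With ``d = 1`` this reduces to the
    plain logistic fixed point ``K``.
    """
    if not (K > 0):
        raise InvalidParameterError("carrying capacity must be > 0")
    mu = persistence_multiplier(r, T, d)
    if mu <= 1.0:  # at mu = 1 the only fixed point is the degenerate N = 0
        return None
    ert = math.exp(r * T)
    return float(K * (d * ert - 1.0) / (d * (ert - 1.0)))


def critical_rate(T: float, d: float) -> float:
    """Critical growth rate ``r_crit = ln(1/d) / T``.

    Starting from low density, single taxa with ``r > r_crit`` persist under
    the schedule and taxa with ``r < r_crit`` go extinct.
    """
    if not (T > 0) or not (0 < d <= 1):
        raise InvalidParameterError("require T > 0 and 0 < d <= 1")
    return math.log(1.0 / d) / T


def cycle_map(N: float, r: float, K: float, T: float, d: float) -> float:
    """One application of the pre-event cycle map: dilute by ``d``, grow ``T`` days."""
    return logistic_solution(d * N, r, K, T)


def iterate_cycle_map(
    N0: float, r: float, K: float, T: float, d: float, n_cycles: int
) -> np.ndarray:
    """Pre-event abundances after each of ``n_cycles`` dilution-growth cycles.

    Closed-form companion to :func:`run_cycles` for single taxa (no
    extinction threshold applied); used as the analytic oracle for the ODE
    trajectory.
    """
    out = np.empty(n_cycles)
    N = N0
    for k in range(n_cycles):
        N = cycle_map(N, r, K, T, d)
        out[k] = N
    return out


def persistence_diagram(
    r_values: Sequence[float],
    schedule: CycleSchedule,
    *,
    K: float = 1e8,
    N0: float = 1e4,
    rtol: float = DEFAULT_RTOL,
) -> pd.DataFrame:
    """Persistence/extinction classification across growth rates.

    Simulates a single taxon for each rate in ``r_values`` under
    ``schedule`` and tabulates the per-cycle multiplier, analytic threshold
    and fixed point, simulated fate, and final pre-event abundance.  This is
    the model's persistence diagram: fast growers settle on a periodic orbit,
    slow growers are washed out by cumulative dilution events.
    """
    r_crit = critical_rate(schedule.T, schedule.d)
    rows = []
    for r in r_values:
        p = TaxonParams(name="taxon", r=r, K=K)
        s0 = CommunityState(0.0, ("taxon",), np.array([N0]))
        traj, outcome = run_cycles(s0, [p], schedule, points_per_cycle=2, rtol=rtol)
        pre = traj[traj.phase == "pre_event"].abundance_cfu_per_g.to_numpy()
        o = outcome["taxon"]
        rows.append(
            {
                "r": r,
                "r_crit": r_crit,
                "mu": o.mu,
                "status": o.status,
                "N_star": o.N_star,
                "final_pre_event": pre[-1] if len(pre) else float("nan"),
                "cycles_to_extinction": o.cycles_to_extinction,
            }
        )
    return pd.DataFrame(rows)
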