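"""Growth-dilution dynamics: closed forms, ODE agreement, cycle-map algebra."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cybed.dynamics import (
    CommunityState,
    CycleSchedule,
    TaxonParams,
    apply_dilution,
    critical_rate,
    cycle_map,
    cycle_map_fixed_point,
    integrate_community,
    iterate_cycle_map,
    logistic_solution,
    persistence_diagram,
    persistence_multiplier,
    run_cycles,
)
from cybed.errors import InvalidParameterError


def single_state(N0: float) -> CommunityState:
    return CommunityState(0.0, ("x",), np.array([N0]))


class TestLogisticSolution:
    @pytest.mark.parametrize(
        "N0,r,K,t,expected",
        [
            (1e8, 0.5, 1e8, 10.0, 1e8),  # equilibrium is fixed
            (1e4, 0.0, 1e8, 10.0, 1e4),  # zero growth
            (0.0, 0.9, 1e8, 10.0, 0.0),  # absorbing zero
            (1e4, 0.5, 1e8, 0.0, 1e4),  # zero time
        ],
    )
    def test_fixed_and_degenerate_points(self, N0, r, K, t, expected):
        assert logistic_solution(N0, r, K, t) == pytest.approx(expected, rel=1e-12)

    def test_matches_numerical_ode_integration(self):
        # Frozen from an independent ODE integration of dN/dt = rN(1 - N/K).
        assert logistic_solution(1e4, 0.5, 1e8, 10.0) == pytest.approx(1.46257e6, rel=1e-3)
        sol = solve_ivp(
            lambda _t, N: 0.5 * N * (1 - N / 1e8), (0, 10), [1e4], rtol=1e-10, atol=1e-4
        )
        assert logistic_solution(1e4, 0.5, 1e8, 10.0) == pytest.approx(
            sol.y[0, -1], rel=1e-6
        )

    def test_negative_rate_decays(self):
        assert logistic_solution(1e6, -0.3, 1e8, 5.0) < 1e6

    @pytest.mark.parametrize("bad", [dict(N0=-1.0), dict(K=0.0), dict(K=-5.0), dict(t=-1.0)])
    def test_invalid_parameters_raise(self, bad):
        kwargs = dict(N0=1e4, r=0.5, K=1e8, t=10.0)
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            logistic_solution(**kwargs)


class TestIntegrateCommunity:
    def test_single_taxon_matches_closed_form(self):
        state = single_state(1e4)
        _, N, final = integrate_community(state, [TaxonParams("x", 0.5, 1e8)], 10.0)
        assert final.N[0] == pytest.approx(logistic_solution(1e4, 0.5, 1e8, 10.0), rel=1e-6)
        assert N[-1, 0] == final.N[0]

    def test_identical_taxa_stay_symmetric(self):
        params = [
            TaxonParams("a", 0.6, 1e8, interactions={"b": 1.0}),
            TaxonParams("b", 0.6, 1e8, interactions={"a": 1.0}),
        ]
        state = CommunityState(0.0, ("a", "b"), np.array([1e4, 1e4]))
        t, N, _ = integrate_community(state, params, 15.0, t_eval=np.linspace(0, 15, 31))
        np.testing.assert_allclose(N[:, 0], N[:, 1], rtol=1e-9)

    def test_zero_abundance_is_absorbing(self):
        params = [
            TaxonParams("a", 0.6, 1e8, interactions={"b": 0.5}),
            TaxonParams("b", 0.9, 1e8, interactions={"a": 0.5}),
        ]
        state = CommunityState(0.0, ("a", "b"), np.array([0.0, 1e4]))
        _, N, final = integrate_community(state, params, 10.0)
        assert final.N[0] == 0.0
        assert np.all(N[:, 0] == 0.0)
        assert final.N[1] > 1e4

    def test_trajectory_non_negative(self):
        params = [TaxonParams("x", -1.5, 1e8)]
        _, N, _ = integrate_community(
            single_state(10.0), params, 30.0, t_eval=np.linspace(0, 30, 61)
        )
        assert np.all(N >= 0)


class TestApplyDilution:
    def test_multiplies_by_carry_over(self):
        out = apply_dilution(single_state(1e6), 0.01, 1.0)
        assert out.N[0] == pytest.approx(1e4)
        assert not out.extinct[0]

    def test_below_threshold_goes_extinct(self):
        out = apply_dilution(single_state(50.0), 0.01, 1.0)
        assert out.N[0] == 0.0
        assert out.extinct[0]

    def test_identity_event(self):
        out = apply_dilution(single_state(1e6), 1.0, 1.0)
        assert out.N[0] == 1e6

    @pytest.mark.parametrize("d", [0.0, -0.5, 1.5])
    def test_invalid_carry_over_raises(self, d):
        with pytest.raises(InvalidParameterError):
            apply_dilution(single_state(1e6), d, 1.0)


class TestCycleMapAlgebra:
    @pytest.mark.parametrize(
        "r,T,d,expected",
        [
            (0.5, 10.0, 0.01, 1.48413),
            (0.0, 10.0, 0.5, 0.5),
        ],
    )
    def test_persistence_multiplier(self, r, T, d, expected):
        assert persistence_multiplier(r, T, d) == pytest.approx(expected, rel=1e-5)

    def test_threshold_identity(self):
        d, T = 0.02, 8.0
        assert persistence_multiplier(math.log(1 / d) / T, T, d) == pytest.approx(1.0)

    def test_multiplier_is_low_density_per_cycle_growth(self):
        # A simulated near-zero-density population grows by mu per cycle.
        r, T, d, K = 0.5, 10.0, 0.01, 1e8
        N0 = 1e-3
        grown = logistic_solution(N0 * d, r, K, T)
        assert grown / N0 == pytest.approx(persistence_multiplier(r, T, d), rel=1e-4)

    def test_fixed_point_matches_iterated_map(self):
        r, K, T, d = 0.5, 1e8, 10.0, 0.01
        n_star = cycle_map_fixed_point(r, K, T, d)
        iterated = iterate_cycle_map(1.0, r, K, T, d, 200)[-1]
        assert n_star == pytest.approx(3.2841e7, rel=1e-4)  # frozen from iteration
        assert n_star == pytest.approx(iterated, rel=1e-9)
        # and it is actually fixed:
        assert cycle_map(n_star, r, K, T, d) == pytest.approx(n_star, rel=1e-12)

    def test_subcritical_has_no_fixed_point(self):
        assert cycle_map_fixed_point(0.4, 1e8, 10.0, 0.01) is None

    def test_no_dilution_recovers_carrying_capacity(self):
        assert cycle_map_fixed_point(0.5, 1e8, 10.0, 1.0) == pytest.approx(1e8)

    @pytest.mark.parametrize(
        "T,d,expected", [(10.0, 0.01, 0.460517), (10.0, 1.0, 0.0)]
    )
    def test_critical_rate(self, T, d, expected):
        assert critical_rate(T, d) == pytest.approx(expected, abs=1e-6)


class TestRunCycles:
    schedule = CycleSchedule(T=10.0, d=0.01, n_cycles=20, N_min=1.0)

    def run_single(self, r, N0=1e4, schedule=None, **kw):
        schedule = schedule or self.schedule
        return run_cycles(single_state(N0), [TaxonParams("x", r, 1e8)], schedule, **kw)

    def test_supercritical_persists_toward_fixed_point(self):
        traj, outcome = self.run_single(0.5, schedule=CycleSchedule(10.0, 0.01, 60, 1.0))
        o = outcome["x"]
        assert o.status == "persistent"
        pre = traj[traj.phase == "pre_event"].abundance_cfu_per_g.to_numpy()
        assert pre[-1] == pytest.approx(o.N_star, rel=1e-6)

    def test_subcritical_goes_extinct_with_mu_below_one(self):
        _, outcome = self.run_single(0.4)
        o = outcome["x"]
        assert o.status == "extinct"
        assert o.mu == pytest.approx(0.01 * math.exp(4.0), rel=1e-9)
        assert o.mu < 1
        assert o.N_star is None
        assert o.cycles_to_extinction is not None

    def test_extinction_within_analytic_cycle_bound(self):
        r, N0 = 0.35, 1e4
        _, outcome = self.run_single(r, N0=N0)
        mu = persistence_multiplier(r, 10.0, 0.01)
        bound = math.ceil(math.log(N0 / 1.0) / math.log(1.0 / mu)) + 1
        assert outcome["x"].cycles_to_extinction <= bound

    def test_pre_event_abundances_match_iterated_cycle_map(self):
        # ODE-with-events vs the closed-form map, across a (r, T, d) grid.
        for r in (0.3, 0.5, 0.8):
            for T in (5.0, 10.0):
                for d in (0.05, 0.2):
                    sched = CycleSchedule(T=T, d=d, n_cycles=10, N_min=1e-12)
                    traj, _ = self.run_single(r, schedule=sched, points_per_cycle=2)
                    pre = traj[traj.phase == "pre_event"].abundance_cfu_per_g.to_numpy()
                    expected = [logistic_solution(1e4, r, 1e8, T)]
                    for _k in range(9):
                        expected.append(cycle_map(expected[-1], r, 1e8, T, d))
                    np.testing.assert_allclose(pre, expected, rtol=1e-6)

    def test_no_dilution_equals_uninterrupted_logistic(self):
        sched = CycleSchedule(T=10.0, d=1.0, n_cycles=3, N_min=1.0)
        traj, _ = self.run_single(0.5, schedule=sched)
        interior = traj[traj.taxon == "x"]
        for row in interior.itertuples():
            assert row.abundance_cfu_per_g == pytest.approx(
                logistic_solution(1e4, 0.5, 1e8, row.time_days), rel=1e-6
            )

    def test_event_timestamps_record_pre_then_post(self):
        traj, _ = self.run_single(0.5, schedule=CycleSchedule(10.0, 0.01, 2, 1.0))
        events = traj[traj.phase != "interior"]
        assert list(events.phase) == ["pre_event", "post_event"] * 2
        assert list(events.time_days) == [10.0, 10.0, 20.0, 20.0]

    def test_classification_flips_at_critical_rate(self):
        # mu at 5% off threshold is close to 1, so give the slow decay
        # enough cycles to cross the extinction threshold
        sched = CycleSchedule(T=10.0, d=0.01, n_cycles=45, N_min=1.0)
        r_crit = critical_rate(10.0, 0.01)
        _, above = self.run_single(r_crit * 1.05, schedule=sched)
        _, below = self.run_single(r_crit * 0.95, schedule=sched)
        assert above["x"].status == "persistent"
        assert below["x"].status == "extinct"


class TestProperties:
    @given(
        r=st.floats(0.05, 1.2),
        d=st.floats(0.01, 1.0),
        N0=st.floats(10.0, 1e7),
    )
    def test_non_negative_and_absorbing(self, r, d, N0):
        sched = CycleSchedule(T=6.0, d=d, n_cycles=6, N_min=1.0)
        traj, _ = run_cycles(
            single_state(N0), [TaxonParams("x", r, 1e8)], sched, points_per_cycle=3
        )
        ab = traj.abundance_cfu_per_g.to_numpy()
        assert np.all(ab >= 0)
        # once zero, always zero
        zero_seen = False
        for v in traj.sort_values("time_days").abundance_cfu_per_g:
            if zero_seen:
                assert v == 0.0
            if v == 0.0:
                zero_seen = True

    @given(r=st.floats(0.2, 1.0), d=st.floats(0.02, 0.5), N0=st.floats(10.0, 9e7))
    def test_supercritical_converges_to_fixed_point(self, r, d, N0):
        T = 10.0
        mu = persistence_multiplier(r, T, d)
        if mu <= 1.05:
            return  # only test comfortably supercritical cases
        n_star = cycle_map_fixed_point(r, 1e8, T, d)
        orbit = iterate_cycle_map(N0, r, 1e8, T, d, 400)
        assert orbit[-1] == pytest.approx(n_star, rel=1e-8)
        # monotone approach after at most one overshoot
        err = np.abs(orbit - n_star)[1:]
        assert np.all(np.diff(err) <= err[:-1] * 1e-9 + 1e-6)

    @given(d=st.floats(0.05, 0.95), N0=st.floats(100.0, 1e6))
    def test_zero_rate_decays_geometrically(self, d, N0):
        orbit = iterate_cycle_map(N0, 0.0, 1e8, 10.0, d, 5)
        np.testing.assert_allclose(orbit, N0 * d ** np.arange(1, 6), rtol=1e-12)


def test_persistence_diagram_splits_at_threshold():
    sched = CycleSchedule(T=10.0, d=0.01, n_cycles=30, N_min=1.0)
    r_crit = critical_rate(sched.T, sched.d)
    df = persistence_diagram(np.linspace(0.1, 1.0, 10), sched)
    fast = df[df.r > r_crit]
    slow = df[df.r < r_crit]
    assert (fast.status == "persistent").all()
    assert (slow.status == "extinct").all()
    assert (fast.mu > 1).all() and (slow.mu < 1).all()
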