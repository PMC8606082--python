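"""Unit and property tests for the mass-action exchange model."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm
from scipy.optimize import fsolve

from ordflux import (
    ExchangeState,
    RateConstants,
    SimulationConfig,
    acceleration_factor,
    build_rhs,
    exchange_state,
    find_rate_maximum,
    initial_transfer_rate,
    log_grid,
    nonexchange_state,
    simulate,
    sweep,
)
from ordflux.kinetics import SPECIES, BoundaryMaximumWarning, SweepResult

# ---------------------------------------------------------------------------
# independent stoichiometry oracle: species x reactions incidence matrix and
# mass-action flux vector written out by hand, separately from build_rhs
# ---------------------------------------------------------------------------

# rows ordered as SPECIES; columns = net fluxes of the six reversible reactions
STOICH = np.array(
    #  r1  r2  r3  r4  r5  r6
    [[-1, -1,  0,  0,  0,  0],   # o_free
     [ 1,  0, -1,  0, -1,  0],   # o_ma
     [ 0,  1,  0, -1,  0, -1],   # o_mb
     [ 0,  0,  1,  1,  0,  0],   # o_ps
     [ 0,  0,  0,  0,  1,  1],   # o_pi4p
     [ 0,  0, -1,  0,  0,  0],   # ps_a
     [ 0,  0,  0, -1,  0,  0],   # ps_b
     [ 0,  0,  0,  0, -1,  0],   # pi4p_a
     [ 0,  0,  0,  0,  0, -1]],  # pi4p_b
    dtype=float,
)


def net_fluxes(r: RateConstants, s: ExchangeState) -> np.ndarray:
    return np.array([
        r.k_on_mb * s.o_free * s.m_a - r.k_off_mb * s.o_ma,
        r.k_on_mb * s.o_free * s.m_b - r.k_off_mb * s.o_mb,
        r.k_on_ps * s.o_ma * s.ps_a - r.k_off_ps * s.o_ps,
        r.k_on_ps * s.o_mb * s.ps_b - r.k_off_ps * s.o_ps,
        r.k_on_pi4p * s.o_ma * s.pi4p_a - r.k_off_pi4p * s.o_pi4p,
        r.k_on_pi4p * s.o_mb * s.pi4p_b - r.k_off_pi4p * s.o_pi4p,
    ])


class TestBuildRhs:
    def test_matches_stoichiometry_table_on_random_states(self, rng):
        """The RHS equals N @ v for the hand-written incidence matrix and
        flux vector, on arbitrary strictly positive states."""
        rates = RateConstants(k_on_mb=3.0, k_off_mb=0.7, k_on_ps=2.0,
                              k_off_ps=0.9, k_on_pi4p=5.0, k_off_pi4p=1.3)
        for _ in range(20):
            vals = rng.uniform(0.01, 5.0, size=11)
            state = ExchangeState(**dict(zip(SPECIES + ("m_a", "m_b"), vals)))
            rhs = build_rhs(rates, state.m_a, state.m_b)
            got = np.array(rhs(0.0, state.to_array()))
            expected = STOICH @ net_fluxes(rates, state)
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_protein_flux_audit_sums_to_zero(self):
        """Sum of the derivatives over the five protein-containing species
        vanishes exactly: every protein row pair in the stoichiometry
        cancels (closed-form check, default condition)."""
        assert np.all(STOICH[:5].sum(axis=0) == 0)
        state = nonexchange_state()
        rhs = build_rhs(RateConstants(), state.m_a, state.m_b)
        d = rhs(0.0, state.to_array())
        assert sum(d[:5]) == pytest.approx(0.0, abs=1e-15)

    def test_no_extraction_pathway_when_kon_ps_zero(self):
        state = nonexchange_state()
        rhs = build_rhs(RateConstants(k_on_ps=0.0), state.m_a, state.m_b)
        d = rhs(0.0, state.to_array())
        assert d[SPECIES.index("ps_b")] == 0.0

    def test_all_static_without_protein(self):
        state = ExchangeState(ps_a=5.0, pi4p_b=5.0, m_a=100.0, m_b=100.0)
        rhs = build_rhs(RateConstants(), state.m_a, state.m_b)
        assert np.all(np.array(rhs(0.0, state.to_array())) == 0.0)

    def test_negative_rate_constant_rejected(self):
        with pytest.raises(ValueError, match="k_on_ps"):
            RateConstants(k_on_ps=-1.0)


class TestSimulate:
    def test_lipid_conservation_along_trajectory(self, default_config):
        traj = simulate(default_config)
        totals = traj.y[:, [3]].ravel() + traj.y[:, 5] + traj.y[:, 6]
        np.testing.assert_allclose(totals, 5.0, atol=1e-6)

    def test_zero_duration_returns_initial_state(self, default_config):
        cfg = replace(default_config, t_end=0.0)
        traj = simulate(cfg)
        assert traj.time_s.tolist() == [0.0]
        np.testing.assert_array_equal(
            traj.y[0], default_config.initial_state.to_array())

    def test_symmetric_pools_stay_symmetric(self, symmetric_config):
        traj = simulate(symmetric_config)
        np.testing.assert_allclose(traj.species("ps_a"), traj.species("ps_b"),
                                   rtol=1e-7, atol=1e-9)

    def test_long_time_pools_match_algebraic_equilibrium(self, default_config):
        """Independent oracle: solve the detailed-balance conditions of the
        single-ligand scheme algebraically and compare with the simulated
        long-time state."""
        r = default_config.rates
        state = default_config.initial_state
        m, p_tot, s_tot = state.m_a, state.total_protein, state.total_ps
        c = r.k_on_mb * m / r.k_off_mb          # o_ma/o_free at equilibrium
        b = r.k_on_ps / r.k_off_ps              # o_ps/(o_ma * ps) at equilibrium

        def equations(z):
            o, ps = z
            return (o * (1 + 2 * c) + b * c * o * ps - p_tot,
                    2 * ps + b * c * o * ps - s_tot)

        o_eq, ps_eq = fsolve(equations, (p_tot / 10, s_tot / 2), xtol=1e-13)
        cfg = replace(default_config, t_end=1.0e5, t_step=1000.0,
                      rate_window=1000.0)
        traj = simulate(cfg)
        assert traj.species("ps_a")[-1] == pytest.approx(ps_eq, rel=1e-5)
        assert traj.species("ps_b")[-1] == pytest.approx(ps_eq, rel=1e-5)
        assert traj.species("o_free")[-1] == pytest.approx(o_eq, rel=1e-5)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        kon_ps=st.floats(0.01, 1000.0),
        koff_ps=st.floats(0.1, 10.0),
        ps_a=st.floats(0.5, 10.0),
        pi4p_b=st.floats(0.0, 10.0),
    )
    def test_conservation_property(self, kon_ps, koff_ps, ps_a, pi4p_b):
        """Total protein and each total lipid drift by < 1e-6 uM over any
        trajectory at default tolerances."""
        cfg = SimulationConfig(
            rates=RateConstants(k_on_ps=kon_ps, k_off_ps=koff_ps),
            initial_state=exchange_state(0.2, ps_a, pi4p_b),
            t_end=120.0, t_step=2.0, rate_window=2.0,
        )
        traj = simulate(cfg)
        for i in range(traj.time_s.size):
            s = traj.state_at(i)
            assert abs(s.total_protein - 0.2) < 1e-6
            assert abs(s.total_ps - ps_a) < 1e-6
            assert abs(s.total_pi4p - pi4p_b) < 1e-6

    def test_ligand_label_swap_symmetry(self):
        """Swapping the PS and PI(4)P labels (rates and pools) exactly
        swaps the corresponding trajectories."""
        rates = RateConstants(k_on_ps=3.0, k_off_ps=0.5, k_on_pi4p=40.0,
                              k_off_pi4p=2.0)
        state = exchange_state(0.2, 5.0, 4.0)
        cfg = SimulationConfig(rates=rates, initial_state=state,
                               t_end=30.0, t_step=0.6)
        swapped = SimulationConfig(rates=rates.swapped_ligands(),
                                   initial_state=state.swapped_ligands(),
                                   t_end=30.0, t_step=0.6)
        a, b = simulate(cfg), simulate(swapped)
        for lhs, rhs_name in (("ps_a", "pi4p_a"), ("ps_b", "pi4p_b"),
                              ("o_ps", "o_pi4p"), ("o_free", "o_free")):
            np.testing.assert_allclose(a.species(lhs), b.species(rhs_name),
                                       rtol=1e-6, atol=1e-8)

    def test_reduced_two_compartment_limit_matches_matrix_exponential(self):
        """With membrane binding frozen and the docked protein pools in
        vast excess over the ligand, the scheme reduces to a linear
        three-species system whose closed form is the matrix exponential."""
        om = 1.0e4     # docked protein per membrane, uM (effectively constant)
        ps0 = 1.0e-3   # trace ligand so docked pools stay unperturbed
        kon, koff = 1.0e-4, 1.0
        a = kon * om
        state = ExchangeState(o_ma=om, o_mb=om, ps_a=ps0, m_a=1.0, m_b=1.0)
        cfg = SimulationConfig(
            rates=RateConstants(k_on_mb=0.0, k_off_mb=0.0, k_on_ps=kon),
            initial_state=state, t_end=10.0, t_step=0.5,
            solver_rel_tol=1e-12, solver_abs_tol=1e-16,
        )
        traj = simulate(cfg)
        L = np.array([[-a, koff, 0.0],
                      [a, -2.0 * koff, a],
                      [0.0, koff, -a]])
        x0 = np.array([ps0, 0.0, 0.0])
        exact = np.stack([expm(L * t) @ x0 for t in traj.time_s])
        sim = np.stack([traj.species("ps_a"), traj.species("o_ps"),
                        traj.species("ps_b")], axis=1)
        assert np.max(np.abs(sim - exact)) / ps0 < 1e-6


class TestInitialRate:
    def test_linear_destination_pool_arithmetic(self, default_config):
        t = np.arange(0.0, 4.1, 0.5)
        y = np.zeros((t.size, 9))
        y[:, SPECIES.index("ps_b")] = 0.1 * t
        from ordflux.kinetics import Trajectory

        traj = Trajectory(t, y, 100.0, 100.0, default_config)
        rate = initial_transfer_rate(traj, "ps_b", protein_total=0.2, window=4.0)
        assert rate == pytest.approx(30.0)

    def test_flat_pool_gives_zero(self, default_config):
        t = np.arange(0.0, 4.1, 0.5)
        y = np.full((t.size, 9), 0.3)
        from ordflux.kinetics import Trajectory

        traj = Trajectory(t, y, 100.0, 100.0, default_config)
        assert initial_transfer_rate(traj, "ps_b", 0.2, 4.0) == pytest.approx(0.0)

    def test_window_beyond_span_rejected(self, default_config):
        traj = simulate(replace(default_config, t_end=2.4))
        with pytest.raises(ValueError, match="window"):
            initial_transfer_rate(traj, "ps_b", 0.2, window=10.0)

    def test_high_affinity_ligand_transfers_more_slowly(self):
        """Raising k_on_ps from 10 to 100 lowers the initial transfer rate:
        tighter binding slows simple transfer."""
        def rate_at(k):
            cfg = SimulationConfig(rates=RateConstants(k_on_ps=k))
            return initial_transfer_rate(simulate(replace(cfg, t_end=0.6)))

        assert rate_at(10.0) > rate_at(100.0)


class TestAccelerationFactor:
    @pytest.mark.parametrize(
        "ex, non, expected",
        [(5.0, 5.0, 0.0), (2.2, 1.0, np.log10(2.2)), (10.0, 1.0, 1.0)],
    )
    def test_log_ratio(self, ex, non, expected):
        assert acceleration_factor(ex, non) == pytest.approx(expected)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            acceleration_factor(0.0, 1.0)


class TestSweep:
    def test_single_point_matches_manual_composition(self, default_config):
        result = sweep(default_config, "k_on_ps", [10.0])
        cfg = replace(default_config, t_end=default_config.rate_window)
        manual = initial_transfer_rate(simulate(cfg))
        assert result.rate_ps_nonexchange[0] == pytest.approx(manual, rel=1e-12)

    def test_bell_shape_with_near_zero_extremes(self, default_config):
        result = sweep(default_config, "k_on_ps", log_grid(per_decade=4))
        rates = result.rate_ps_nonexchange
        peak = np.nanmax(rates)
        imax = int(np.nanargmax(rates))
        assert 0 < imax < rates.size - 1
        assert rates[0] < 0.05 * peak and rates[-1] < 0.05 * peak
        # monotone decline beyond the interior maximum
        tail = rates[imax:]
        assert np.all(np.diff(tail) < 1e-9)

    def test_pi4p_always_accelerated_by_ps(self, default_config):
        result = sweep(default_config, "k_on_ps", log_grid(per_decade=4))
        assert np.all(result.accel_pi4p >= 0.0)

    def test_nonexchange_pi4p_rate_constant_across_ps_sweep(self, default_config):
        result = sweep(default_config, "k_on_ps", log_grid(per_decade=3))
        ref = result.rate_pi4p_nonexchange
        np.testing.assert_allclose(ref, ref[0], rtol=1e-6)

    def test_invalid_grids_rejected(self, default_config):
        with pytest.raises(ValueError):
            sweep(default_config, "k_on_ps", [])
        with pytest.raises(ValueError):
            sweep(default_config, "k_on_ps", [2.0, 1.0])
        with pytest.raises(ValueError):
            sweep(default_config, "not_a_rate", [1.0])


class TestFindRateMaximum:
    def test_planted_parabola_recovers_exact_vertex(self):
        """Rates following a concave parabola in log-parameter have a
        closed-form vertex the locator must hit exactly."""
        grid = np.logspace(-2, 4, 61)
        vertex = np.log10(3.7)
        rates = 10.0 - (np.log10(grid) - vertex) ** 2
        result = SweepResult(
            swept_parameter="k_on_ps", grid=grid,
            rate_ps_nonexchange=rates, rate_ps_exchange=rates,
            rate_pi4p_nonexchange=rates, rate_pi4p_exchange=rates,
            accel_ps=np.zeros_like(rates), accel_pi4p=np.zeros_like(rates),
            base_config=None,
        )
        assert find_rate_maximum(result) == pytest.approx(3.7, rel=1e-9)

    def test_boundary_maximum_warns_without_refinement(self):
        grid = np.array([1.0, 2.0, 4.0])
        rates = np.array([3.0, 2.0, 1.0])
        result = SweepResult(
            swept_parameter="k_on_ps", grid=grid,
            rate_ps_nonexchange=rates, rate_ps_exchange=rates,
            rate_pi4p_nonexchange=rates, rate_pi4p_exchange=rates,
            accel_ps=np.zeros(3), accel_pi4p=np.zeros(3), base_config=None,
        )
        with pytest.warns(BoundaryMaximumWarning):
            assert find_rate_maximum(result) == 1.0

    def test_too_few_finite_rates_rejected(self):
        grid = np.array([1.0, 2.0, 4.0])
        rates = np.array([np.nan, 2.0, np.nan])
        result = SweepResult(
            swept_parameter="k_on_ps", grid=grid,
            rate_ps_nonexchange=rates, rate_ps_exchange=rates,
            rate_pi4p_nonexchange=rates, rate_pi4p_exchange=rates,
            accel_ps=np.zeros(3), accel_pi4p=np.zeros(3), base_config=None,
        )
        with pytest.raises(ValueError, match="finite"):
            find_rate_maximum(result)


class TestParametricCurve:
    def test_symmetric_ligands_give_equal_accelerations(self):
        """At k_on_pi4p = k_on_ps with otherwise identical ligand
        parameters, exchanging ligand labels is a symmetry, so the two
        acceleration factors coincide."""
        from ordflux import parametric_acceleration_curve

        cfg = SimulationConfig()
        curve = parametric_acceleration_curve(cfg, [10.0], kon_pi4p=10.0)
        assert curve["accel_ps"][0] == pytest.approx(curve["accel_pi4p"][0],
                                                     abs=1e-6)

    def test_ps_acceleration_vanishes_at_low_kon_ps(self):
        from ordflux import parametric_acceleration_curve

        cfg = SimulationConfig()
        curve = parametric_acceleration_curve(cfg, [0.01, 1.0], kon_pi4p=75.0)
        assert abs(curve["accel_ps"][0]) < 0.05
        assert curve["accel_ps"][0] < curve["accel_ps"][1]

    def test_higher_kon_pi4p_curve_dominates_pi4p_acceleration(self):
        """Brute-force comparison at shared k_on_ps points: the
        k_on_pi4p = 75 curve lies at higher PI(4)P acceleration than the
        40 curve."""
        from ordflux import parametric_acceleration_curve

        cfg = SimulationConfig()
        shared = np.logspace(0, 3, 5)
        c75 = parametric_acceleration_curve(cfg, shared, kon_pi4p=75.0)
        c40 = parametric_acceleration_curve(cfg, shared, kon_pi4p=40.0)
        assert np.all(c75["accel_pi4p"].to_numpy()
                      > c40["accel_pi4p"].to_numpy())
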