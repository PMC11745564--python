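"""Unit and property tests of the 3-state electronic model."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from flowtrast.photophysics import (
    DyeParams,
    StateVector,
    analytic_solution,
    coupling_matrix,
    excitation_rate,
    photon_energy,
    propagate_states,
    singlet_population,
    solve_derived_rates,
    steady_state,
)

HC = 6.62607015e-34 * 2.99792458e8  # J·m


class TestPhotonEnergy:
    def test_488nm_matches_planck_relation(self):
        assert photon_energy(488.0) == pytest.approx(HC / 488e-9, rel=1e-12)
        assert photon_energy(488.0) == pytest.approx(4.071e-19, rel=1e-3)

    def test_inverse_proportionality(self):
        assert photon_energy(976.0) == pytest.approx(photon_energy(488.0) / 2)
        assert photon_energy(244.0) == pytest.approx(2 * photon_energy(488.0))

    @pytest.mark.parametrize("bad", [0.0, -488.0])
    def test_rejects_nonpositive_wavelength(self, bad):
        with pytest.raises(ValueError):
            photon_energy(bad)


class TestExcitationRate:
    def test_cfl4br_at_peak_irradiance(self):
        # independent oracle: k01 = sigma * I / (hc/lambda), in 1/us
        sigma, I = 1.65e-16, 3.62e3
        expected = sigma * I / (HC / 488e-9) * 1e-6
        k01 = excitation_rate(sigma, I, 488.0)
        assert k01 == pytest.approx(expected, rel=1e-12)
        assert k01 == pytest.approx(1.47, rel=5e-3)

    def test_zero_irradiance_gives_zero(self):
        assert excitation_rate(1e-16, 0.0, 488.0) == 0.0

    def test_linearity_in_irradiance(self):
        base = excitation_rate(3e-16, 1000.0, 488.0)
        assert excitation_rate(3e-16, 2000.0, 488.0) == pytest.approx(2 * base)

    def test_negative_irradiance_rejected(self):
        with pytest.raises(ValueError):
            excitation_rate(3e-16, -1.0, 488.0)


class TestDerivedRates:
    def test_zero_excitation_limit(self, dyes):
        for dye in dyes:
            r = solve_derived_rates(dye, 0.0)
            assert r.k_isc_eff == 0.0
            assert r.k10 == pytest.approx(dye.inv_tau_f - dye.k_ox, rel=1e-12)

    def test_cfl4br_self_consistent_pair(self, catalog):
        dye = catalog["CFl-4Br"]
        r = solve_derived_rates(dye, 1.47)
        assert r.k10 == pytest.approx(891.5, rel=1e-3)
        assert r.k_isc_eff == pytest.approx(1.47, rel=1e-2)

    @pytest.mark.parametrize("k01", [0.01, 0.1, 0.5, 1.47, 3.0])
    def test_residual_invariants(self, dyes, k01):
        for dye in dyes:
            r = solve_derived_rates(dye, k01)
            inv_tau = dye.inv_tau_f
            # lifetime budget: kisc' + kox + k10 = 1/tau_f
            assert (r.k_isc_eff + dye.k_ox + r.k10) == pytest.approx(
                inv_tau, rel=1e-9
            )
            # effective ISC definition
            assert r.k_isc_eff == pytest.approx(
                dye.k_isc * k01 / (k01 + r.k10), rel=1e-9
            )

    def test_matches_root_finder_oracle(self, dyes):
        # independent closure of the two defining relations by bisection
        for dye in dyes:
            k01 = 1.0
            a = dye.inv_tau_f - dye.k_ox

            def residual(k10):
                return k10 - (a - dye.k_isc * k01 / (k01 + k10))

            # bracket around the physical root near a = 1/tau_f - k_ox (the
            # quadratic's second root is the spurious near-zero one)
            k10_oracle = brentq(residual, a / 2, a, xtol=1e-12, rtol=1e-14)
            r = solve_derived_rates(dye, k01)
            assert r.k10 == pytest.approx(k10_oracle, rel=1e-9)

    def test_naive_subtraction_would_fail_for_cfl4br(self, catalog):
        # the self-consistent solve is mandatory: kisc exceeds 1/tau_f
        dye = catalog["CFl-4Br"]
        assert dye.inv_tau_f - dye.k_isc - dye.k_ox < 0
        assert solve_derived_rates(dye, 1.47).k10 > 0


class TestCouplingMatrix:
    def test_columns_conserve_probability(self, dyes):
        for dye in dyes:
            M = coupling_matrix(dye, solve_derived_rates(dye, 1.0)).M
            assert np.allclose(M.sum(axis=0), 0.0, atol=1e-12)
            assert np.all(M[~np.eye(3, dtype=bool)] >= 0)
            assert np.all(np.diag(M) <= 0)

    def test_zero_excitation_first_column_vanishes(self, catalog):
        dye = catalog["CFl"]
        M = coupling_matrix(dye, solve_derived_rates(dye, 0.0)).M
        assert np.all(M[:, 0] == 0)

    def test_steady_state_is_null_vector(self, dyes):
        for dye in dyes:
            rates = solve_derived_rates(dye, 1.47)
            M = coupling_matrix(dye, rates).M
            ss = steady_state(dye, rates).as_array()
            # null-space oracle: svd null vector normalized to the simplex
            _, _, vt = np.linalg.svd(M)
            null = vt[-1] / vt[-1].sum()
            assert np.allclose(ss, null, atol=1e-10)
            assert np.allclose(M @ ss, 0.0, atol=1e-12)


class TestAnalyticSolution:
    def test_amplitudes_sum_to_one(self, dyes, irradiance_grid):
        for dye in dyes:
            for I0 in irradiance_grid:
                k01 = excitation_rate(dye.sigma_exc, I0, 488.0)
                sol = analytic_solution(dye, solve_derived_rates(dye, k01))
                assert sol.A1 + sol.A2 + sol.A3 == pytest.approx(1.0, abs=1e-12)
                assert sol.lam1 == 0.0
                assert sol.lam2 < 0 and sol.lam3 < 0
                assert abs(sol.lam2) > abs(sol.lam3)

    def test_eigenvalues_match_exact_spectrum(self, dyes, irradiance_grid):
        """Closed-form relaxation rates vs dense eigensolver, <=1% relative."""
        for dye in dyes:
            for I0 in irradiance_grid:
                k01 = excitation_rate(dye.sigma_exc, I0, 488.0)
                rates = solve_derived_rates(dye, k01)
                sol = analytic_solution(dye, rates)
                vals = coupling_matrix(dye, rates).eigenvalues()
                assert vals[0] == pytest.approx(0.0, abs=1e-9)
                exact = np.sort(vals[1:])
                approx = np.sort([sol.lam2, sol.lam3])
                assert np.all(np.abs((exact - approx) / exact) < 0.01)

    def test_requires_positive_excitation(self, catalog):
        dye = catalog["CFl"]
        with pytest.raises(ValueError):
            analytic_solution(dye, solve_derived_rates(dye, 0.0))


class TestSingletPopulation:
    def test_initial_condition_and_long_time_limit(self, catalog):
        dye = catalog["CFl-2Br"]
        sol = analytic_solution(dye, solve_derived_rates(dye, 1.0))
        assert singlet_population(0.0, sol) == pytest.approx(1.0, abs=1e-12)
        t_inf = 100.0 / abs(sol.lam3)
        assert singlet_population(t_inf, sol) == pytest.approx(sol.A1, abs=1e-12)

    def test_negative_time_rejected(self, catalog):
        dye = catalog["CFl"]
        sol = analytic_solution(dye, solve_derived_rates(dye, 1.0))
        with pytest.raises(ValueError):
            singlet_population(-0.1, sol)

    def test_matches_ode_integration(self, dyes):
        """Closed forms vs adaptive ODE solution of dP/dt = M P, <=1e-3."""
        for dye in dyes:
            k01 = excitation_rate(dye.sigma_exc, 3.63e3, 488.0)
            rates = solve_derived_rates(dye, k01)
            M = coupling_matrix(dye, rates).M
            sol = analytic_solution(dye, rates)
            t_end = 10.0 / abs(sol.lam3)
            ts = np.linspace(0.0, t_end, 50)
            ode = solve_ivp(
                lambda _, p: M @ p, (0, t_end), [1.0, 0.0, 0.0],
                t_eval=ts, rtol=1e-10, atol=1e-12, method="LSODA",
            )
            assert np.max(np.abs(singlet_population(ts, sol) - ode.y[0])) < 1e-3


class TestPropagateStates:
    def test_constant_segment_matches_analytic(self, catalog):
        dye = catalog["CFl-1Br"]
        k01 = 1.0
        sol = analytic_solution(dye, solve_derived_rates(dye, k01))
        dts = np.full(100, 0.05)
        traj = propagate_states(dye, StateVector.ground(),
                                [(k01, dt) for dt in dts])
        ts = np.concatenate([[0.0], np.cumsum(dts)])
        assert np.max(np.abs(traj[:, 0] - singlet_population(ts, sol))) < 1e-3

    def test_zero_excitation_is_stationary(self, catalog):
        dye = catalog["CFl"]
        traj = propagate_states(dye, StateVector.ground(), [(0.0, 1.0)] * 20)
        assert np.allclose(traj, np.tile([1.0, 0.0, 0.0], (21, 1)), atol=1e-15)

    def test_probability_conserved_over_many_segments(self, catalog):
        dye = catalog["CFl-4Br"]
        segments = [(1.47 * (0.5 + 0.5 * np.sin(i / 7.0)), 0.01)
                    for i in range(10_000)]
        traj = propagate_states(dye, StateVector.ground(), segments)
        assert np.max(np.abs(traj.sum(axis=1) - 1.0)) < 1e-9
        assert traj.min() >= -1e-12

    def test_invalid_duration_rejected(self, catalog):
        with pytest.raises(ValueError):
            propagate_states(catalog["CFl"], StateVector.ground(), [(1.0, 0.0)])


class TestModelProperties:
    def test_steady_singlet_nonincreasing_in_excitation(self, dyes):
        for dye in dyes:
            k01s = np.linspace(0.0, 3.0, 25)
            ss = [steady_state(dye, solve_derived_rates(dye, k)).S for k in k01s]
            assert np.all(np.diff(ss) <= 1e-12)

    def test_heavy_atom_triplet_ordering(self, dyes):
        """At fixed k01 the steady triplet fraction grows with bromination."""
        fractions = [steady_state(d, solve_derived_rates(d, 1.0)).T for d in dyes]
        assert np.all(np.diff(fractions) > 0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    tau_f=st.floats(0.5, 10.0),
    k_isc=st.floats(0.1, 1000.0),
    k_T=st.floats(0.1, 5.0),
    k_red=st.floats(1e-6, 0.1),
    k_ox=st.floats(1e-6, 0.1),
    k01=st.floats(1e-3, 5.0),
)
def test_random_dyes_satisfy_rate_closure(tau_f, k_isc, k_T, k_red, k_ox, k01):
    """The self-consistent rate pair satisfies both defining relations and
    yields a conservative coupling matrix for any physical parameter set."""
    dye = DyeParams("rnd", tau_f, 1e-16, k_isc, k_T, k_red, k_ox)
    # restrict to parameter sets where a physical de-excitation rate exists
    a = dye.inv_tau_f - k_ox
    assume((k01 - a) ** 2 >= 4 * k01 * (k_isc - a))
    rates = solve_derived_rates(dye, k01)
    assert rates.k10 > 0
    assert rates.k_isc_eff + dye.k_ox + rates.k10 == pytest.approx(
        dye.inv_tau_f, rel=1e-9
    )
    M = coupling_matrix(dye, rates).M
    assert np.allclose(M.sum(axis=0), 0.0, atol=1e-9 * abs(M).max())
    traj = propagate_states(dye, StateVector.ground(), [(k01, 0.1)] * 10)
    assert np.max(np.abs(traj.sum(axis=1) - 1.0)) < 1e-9
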