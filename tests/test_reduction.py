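"""Inter-patch water profiles, the pulse-location ODE and patch budgets."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_bvp

from drypatch import (
    PulseConfiguration,
    integrate_pulse_ode,
    patch_water_and_biomass,
    pulse_velocities,
    random_pattern,
    regular_pattern,
    solve_interpatch,
)
from drypatch.params import pulse_ode_prefactor
from drypatch.reduction import (
    DegeneratePatchError,
    SeparationError,
    solve_wall_gap,
)


def bvp_boundary_slopes(g: float, a: float, s: float = 0.0) -> tuple[float, float]:
    """Brute-force oracle: two-point BVP solve of 0 = w'' + s w' + a - w
    with w = 0 at both ends of the gap."""

    def rhs(x, y):
        return np.vstack([y[1], -s * y[1] - a + y[0]])

    def bc(ya, yb):
        return np.array([ya[0], yb[0]])

    x = np.linspace(0.0, g, 400)
    y0 = np.zeros((2, x.size))
    sol = solve_bvp(rhs, bc, x, y0, tol=1e-10, max_nodes=100_000)
    assert sol.success
    return float(sol.sol(0.0)[1]), float(sol.sol(g)[1])


class TestInterpatchProfile:
    @pytest.mark.parametrize("a,g", [(0.5, 4.0), (0.2, 1.5), (1.0, 8.0), (0.7, 2.5)])
    def test_matches_bvp_oracle(self, a, g):
        prof = solve_interpatch(0.0, g, a)
        d0, d1 = bvp_boundary_slopes(g, a)
        assert prof.deriv_left == pytest.approx(d0, abs=1e-8)
        assert prof.deriv_right == pytest.approx(d1, abs=1e-8)

    def test_symmetric_closed_form(self):
        prof = solve_interpatch(0.0, 4.0, 0.5)
        assert prof.deriv_left == pytest.approx(0.5 * math.tanh(2.0), rel=1e-12)
        assert prof.deriv_right == pytest.approx(-0.5 * math.tanh(2.0), rel=1e-12)
        # midpoint symmetry
        xs = np.linspace(0.1, 3.9, 101)
        w = prof.evaluate(xs)
        assert np.allclose(w, w[::-1], atol=1e-12)

    def test_no_rain_no_water(self):
        prof = solve_interpatch(0.0, 3.0, 0.0)
        assert np.all(prof.evaluate(np.linspace(0, 3, 17)) == 0.0)
        assert prof.deriv_left == 0.0 and prof.deriv_right == 0.0

    def test_wide_gap_asymptotics(self):
        prof = solve_interpatch(0.0, 40.0, 1.0)
        assert prof.evaluate(20.0) == pytest.approx(1.0, abs=1e-8)
        assert prof.deriv_left == pytest.approx(1.0, abs=1e-8)
        assert prof.deriv_right == pytest.approx(-1.0, abs=1e-8)

    def test_advective_profile_against_bvp(self):
        a, g, s = 0.5, 3.0, 0.4
        prof = solve_interpatch(0.0, g, a, s)
        d0, d1 = bvp_boundary_slopes(g, a, s)
        assert prof.deriv_left == pytest.approx(d0, abs=1e-8)
        assert prof.deriv_right == pytest.approx(d1, abs=1e-8)

    def test_gap_ordering_enforced(self):
        with pytest.raises(SeparationError):
            solve_interpatch(3.0, 1.0, 0.5)

    def test_nonnegative_on_gap(self):
        prof = solve_interpatch(0.0, 6.0, 0.8, s=0.3)
        assert prof.evaluate(np.linspace(0, 6, 301)).min() >= -1e-12

    def test_wall_gap_no_flux_condition(self):
        prof = solve_wall_gap(0.0, 2.5, 0.5)
        x = np.array([1e-7])
        assert prof.derivative(x)[0] == pytest.approx(0.0, abs=1e-6)
        assert prof.evaluate(np.array([2.5]))[0] == pytest.approx(0.0, abs=1e-12)


class TestPulseVelocities:
    def test_regular_configuration_is_stationary(self, p_ref):
        for n in (2, 5, 9):
            vel = pulse_velocities(regular_pattern(n, 2.0 * n), p_ref)
            assert np.all(vel.velocities == 0.0)

    def test_two_patch_direction_and_magnitude(self, p_ref):
        cfg = PulseConfiguration(domain_length=8.0, positions=np.array([2.0, 4.0]))
        vel = pulse_velocities(cfg, p_ref).velocities
        # patch at 4 has right gap 6, left gap 2: moves right (toward water)
        assert vel[1] > 0 and vel[0] < 0
        assert vel[1] == pytest.approx(-vel[0], rel=1e-12)
        kappa = pulse_ode_prefactor(p_ref)
        expected = kappa * p_ref.a ** 2 * abs(math.tanh(3.0) ** 2 - math.tanh(1.0) ** 2)
        assert abs(vel[1]) == pytest.approx(expected, rel=1e-12)

    def test_velocities_sum_to_zero_periodic(self, p_ref):
        for seed in range(6):
            cfg = random_pattern(8, 16.0, seed=seed)
            vel = pulse_velocities(cfg, p_ref).velocities
            assert abs(vel.sum()) < 1e-18

    def test_reflection_negates_velocities(self, p_ref):
        cfg = random_pattern(6, 12.0, seed=9)
        mirrored = PulseConfiguration(
            domain_length=12.0, positions=np.sort(12.0 - cfg.positions)
        )
        v = pulse_velocities(cfg, p_ref).velocities
        vm = pulse_velocities(mirrored, p_ref).velocities
        assert np.allclose(np.sort(v), np.sort(-vm), rtol=1e-10)

    def test_empty_configuration(self, p_ref):
        cfg = PulseConfiguration(domain_length=5.0, positions=np.empty(0))
        assert pulse_velocities(cfg, p_ref).velocities.size == 0


class TestPatchBudget:
    def test_regular_biomass_closed_form(self, p_ref):
        g = 2.0
        cfg = regular_pattern(5, 5 * g)
        budget = patch_water_and_biomass(cfg, p_ref)
        expected = 2.0 * p_ref.a / p_ref.m * math.tanh(g / 2.0)
        assert np.allclose(budget.biomass, expected, rtol=1e-12)
        # flux balance consistency: B_j = F_j / m and w_j B_j m = F_j w_j
        assert np.allclose(budget.biomass * p_ref.m, budget.flux, rtol=1e-14)

    def test_total_biomass_increases_with_n(self, p_ref):
        l = 24.0
        totals = [
            patch_water_and_biomass(regular_pattern(n, l), p_ref).total_biomass
            for n in range(2, 13)
        ]
        assert np.all(np.diff(totals) > 0)

    def test_weakest_patch_has_smallest_gap_sum(self, p_ref):
        cfg = random_pattern(7, 14.0, seed=21)
        budget = patch_water_and_biomass(cfg, p_ref)
        left, right = cfg.adjacent_gaps()
        assert np.argmin(budget.biomass) == np.argmin(left + right)

    def test_zero_rain_is_degenerate(self, p_ref):
        with pytest.raises(DegeneratePatchError, match="index 0"):
            patch_water_and_biomass(regular_pattern(3, 6.0), p_ref, a=0.0)

    def test_water_budget_closes(self, p_ref):
        # absorbed flux + evaporation over the gaps balances rainfall a*l
        cfg = random_pattern(6, 12.0, seed=4)
        budget = patch_water_and_biomass(cfg, p_ref)
        evap = 0.0
        pos = cfg.positions
        for j in range(cfg.n):
            left = pos[j]
            right = pos[(j + 1) % cfg.n] if j < cfg.n - 1 else pos[0] + cfg.domain_length
            prof = solve_interpatch(left, right, p_ref.a)
            xs = np.linspace(left, right, 2001)
            evap += np.trapezoid(prof.evaluate(xs), xs)
        total_in = p_ref.a * cfg.domain_length
        assert budget.flux.sum() + evap == pytest.approx(total_in, rel=0.01)


class TestIntegration:
    def test_regularization_to_equilibrium(self, p_ref):
        from drypatch import gap_statistics

        cfg = random_pattern(10, 20.0, seed=7)
        traj = integrate_pulse_ode(cfg, p_ref, t_end=1.5e5)
        final = traj.final_configuration()
        assert gap_statistics(final).cv < 1e-6
        vel = pulse_velocities(final, p_ref).velocities
        assert np.max(np.abs(vel)) < 1e-10

    def test_gap_variance_decreases(self, p_ref):
        cfg = random_pattern(8, 16.0, seed=13)
        traj = integrate_pulse_ode(cfg, p_ref, t_end=2e4, n_samples=60)
        cvs = traj.gap_cv()
        assert np.all(np.diff(cvs) <= 1e-10)

    def test_smallest_gap_never_shrinks(self, p_ref):
        # discrete maximum principle of the gap dynamics: the minimum gap
        # grows, so pulse collisions cannot occur on constant slopes
        cfg = random_pattern(9, 18.0, seed=2)
        traj = integrate_pulse_ode(cfg, p_ref, t_end=5e3, n_samples=40)
        min_gaps = [traj.configuration_at(i).min_gap() for i in range(len(traj.ts))]
        assert not traj.collided
        assert np.all(np.diff(min_gaps) >= -1e-9)

    def test_single_patch_is_stationary_periodic(self, p_ref):
        cfg = regular_pattern(1, 10.0)
        traj = integrate_pulse_ode(cfg, p_ref, t_end=1e3)
        assert np.max(np.abs(traj.positions - cfg.positions[0])) < 1e-9

    def test_single_patch_centres_under_neumann(self, p_ref):
        # domain short enough that the wall fluxes are not tanh-saturated,
        # otherwise the drive to the centre is exponentially weak
        cfg = PulseConfiguration(domain_length=4.0, positions=np.array([1.2]), bc="neumann")
        traj = integrate_pulse_ode(cfg, p_ref, t_end=5e4)
        assert traj.final_configuration().positions[0] == pytest.approx(2.0, abs=1e-3)

    def test_ramped_rainfall_scales_velocities(self, p_ref):
        from drypatch import ClimateRamp

        cfg = random_pattern(5, 10.0, seed=6)
        slow = integrate_pulse_ode(cfg, p_ref, ramp=ClimateRamp(0.5, 0.5, 100.0), t_end=100.0)
        const = integrate_pulse_ode(cfg, p_ref, t_end=100.0)
        assert np.allclose(slow.positions[-1], const.positions[-1], atol=1e-8)
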