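"""Feasibility analysis: quasi-steady states, spectra, critical rainfall,
transition prediction and resilience metrics."""

import numpy as np
import pytest

from drypatch import (
    FieldState,
    PulseConfiguration,
    field_from_pulses,
    predict_transition,
    random_pattern,
    regular_pattern,
    resilience_metrics,
    simulate,
)
from drypatch.stability import (
    critical_rainfall,
    is_feasible,
    linear_stability,
    quasi_steady_state,
)


class TestQuasiSteadyState:
    def test_regular_state_converges(self, p_ref):
        qs = quasi_steady_state(regular_pattern(4, 8.0), p_ref)
        assert qs.feasible_relaxation
        assert qs.residual < 1e-6

    def test_empty_configuration_is_desert(self, p_ref):
        cfg = PulseConfiguration(domain_length=6.0, positions=np.empty(0))
        qs = quasi_steady_state(cfg, p_ref)
        assert np.allclose(qs.field.w, p_ref.a)
        assert np.all(qs.field.v == 0)
        assert qs.residual == 0.0

    def test_no_rain_signals_infeasibility(self, p_ref):
        qs = quasi_steady_state(regular_pattern(3, 6.0), p_ref, a=0.0)
        assert not qs.feasible_relaxation
        assert qs.n_surviving == 0
        assert qs.lost_during_relaxation == (0, 1, 2)

    def test_patch_death_during_relaxation_identified(self, p_ref):
        # far below the feasibility boundary the weakest patches die while
        # relaxing; the signal is returned, not raised
        cfg = random_pattern(4, 8.0, seed=3)
        qs = quasi_steady_state(cfg, p_ref, a=0.30)
        assert not qs.feasible_relaxation
        assert len(qs.lost_during_relaxation) >= 1


class TestLinearStability:
    def test_desert_spectrum(self, p_ref):
        f = FieldState.desert(6.0, p_ref)
        fr = linear_stability(f, p_ref)
        assert fr.feasible
        assert fr.n_translation == 0
        assert np.all(fr.eigenvalues.real <= -min(1.0, p_ref.m) + 1e-6)

    def test_healthy_pattern_feasible_with_n_translations(self, p_ref):
        qs = quasi_steady_state(regular_pattern(4, 8.0), p_ref)
        fr = linear_stability(qs.field, p_ref)
        assert fr.feasible
        assert fr.margin > 0.1
        assert fr.n_translation == 4
        # loss eigenvalues live on the mortality scale O(m)
        assert 0.1 * p_ref.m < fr.margin < 2.0 * p_ref.m

    def test_feasible_state_survives_long_simulation(self, p_ref):
        cfg = regular_pattern(4, 8.0)
        f = field_from_pulses(cfg, p_ref)
        res = simulate(f, p_ref, t_end=500.0)
        assert not res.events
        assert res.series.n_patches.iloc[-1] == 4

    def test_period_doubling_mode_below_threshold(self, p_ref, ac_cache):
        # just below a_c the leading amplitude mode alternates sign from
        # patch to patch: the spatial signature of wavelength doubling
        crit = ac_cache(4, 8.0)
        a = crit.a_c - 0.005
        cfg = regular_pattern(4, 8.0)
        qs = quasi_steady_state(cfg, p_ref, a=a)
        fr = linear_stability(qs.field, p_ref, a=a)
        assert not fr.feasible
        from scipy.sparse.linalg import eigs

        from drypatch.pde import jacobian

        J = jacobian(qs.field, p_ref, a)
        vals, vecs = eigs(J, k=6, sigma=0.1 * p_ref.m, which="LM")
        lead = vecs[:, np.argmax(vals.real)].real
        n = qs.field.n_nodes
        v_part = lead[n:]
        samples = np.array([
            v_part[np.argmin(np.abs(qs.field.x - pj))] for pj in cfg.positions
        ])
        signs = np.sign(samples)
        assert np.all(signs[::2] == signs[0]) and np.all(signs[1::2] == -signs[0])


class TestCriticalRainfall:
    def test_bisection_contract(self, p_ref, ac_cache):
        crit = ac_cache(3, 6.0)
        assert crit.bracket[1] - crit.bracket[0] <= 1e-3 + 1e-12
        delta = 1e-3
        assert is_feasible(regular_pattern(3, 6.0), p_ref, a=crit.a_c + 10 * delta)[0]
        assert not is_feasible(regular_pattern(3, 6.0), p_ref, a=crit.a_c - 10 * delta)[0]

    def test_refinement_stability(self, p_ref):
        from drypatch.pde import resolve_dx

        base = critical_rainfall(3, p_ref, domain_length=6.0)
        fine = critical_rainfall(3, p_ref, domain_length=6.0, dx=resolve_dx(p_ref, None) / 2)
        assert abs(base.a_c - fine.a_c) <= 2e-3

    def test_never_feasible_sentinel(self, p_ref):
        # gaps far below the pulse-interaction range: no rainfall helps
        crit = critical_rainfall(8, p_ref, domain_length=1.6, a_max=1.5)
        assert crit.never_feasible


class TestPredictTransition:
    def test_regular_even_halving(self, p_ref):
        pred = predict_transition(regular_pattern(8, 16.0), p_ref)
        assert pred.predicted_type == "halving"
        assert len(pred.predicted_lost) == 4

    def test_regular_odd_halving(self, p_ref):
        pred = predict_transition(regular_pattern(5, 10.0), p_ref)
        assert pred.predicted_type == "halving"
        assert len(pred.predicted_lost) in (2, 3)

    def test_halving_set_alternates(self, p_ref):
        pred = predict_transition(regular_pattern(8, 16.0), p_ref)
        lost = np.array(pred.predicted_lost)
        assert np.all(np.diff(lost) == 2)

    def test_irregular_single_weakest(self, p_ref):
        from drypatch.reduction import patch_water_and_biomass

        cfg = random_pattern(5, 10.0, seed=3)
        pred = predict_transition(cfg, p_ref)
        assert pred.predicted_type == "single"
        budget = patch_water_and_biomass(cfg, p_ref)
        assert pred.predicted_lost == (int(np.argmin(budget.biomass)),)

    def test_requires_two_patches(self, p_ref):
        with pytest.raises(ValueError):
            predict_transition(regular_pattern(1, 2.0), p_ref)


class TestResilienceMetrics:
    def test_ecological_margin_vanishes_at_threshold(self, p_ref, ac_cache):
        crit = ac_cache(3, 6.0)
        met = resilience_metrics(regular_pattern(3, 6.0), p_ref, a=crit.a_c, a_c=crit.a_c)
        assert met.ecological == pytest.approx(0.0, abs=1e-12)

    def test_ecological_margin_tracks_rainfall(self, p_ref, ac_cache):
        crit = ac_cache(3, 6.0)
        margins = [
            resilience_metrics(regular_pattern(3, 6.0), p_ref, a=a, a_c=crit.a_c).ecological
            for a in (0.5, 0.4, 0.3)
        ]
        assert np.all(np.diff(margins) < 0)

    def test_irregular_restores_slower_than_regular(self, p_ref, ac_cache):
        # the engineering margin of an irregular state lies below the
        # regular state's at the same N and rainfall
        crit = ac_cache(4, 8.0)
        reg = resilience_metrics(regular_pattern(4, 8.0), p_ref, a=0.45, a_c=crit.a_c)
        irr = resilience_metrics(random_pattern(4, 8.0, seed=3), p_ref, a=0.45, a_c=crit.a_c)
        assert irr.engineering < reg.engineering


class TestFeasibilityConsistency:
    def test_flag_matches_direct_simulation(self, p_ref, rng):
        # the eigenvalue verdict agrees with "does the PDE lose a patch
        # at frozen rainfall" on random probes, except inside the
        # bisection-scale boundary layer
        agree = 0
        probes = 0
        while probes < 8:
            n = int(rng.integers(2, 7))
            a = float(rng.uniform(0.2, 0.6))
            cfg = random_pattern(n, 2.0 * n, seed=int(rng.integers(0, 1000)))
            flag, qs = is_feasible(cfg, p_ref, a=a)
            if flag:
                res = simulate(qs.field, p_ref.with_a(a), t_end=400.0)
                lost = res.series.n_patches.iloc[-1] < n
                agree += not lost
            else:
                agree += True  # infeasible verdicts already witnessed a death
            probes += 1
        assert agree >= 7
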