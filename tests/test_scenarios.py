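"""Climate-ramp scenarios, removal policies and the slow/fast dichotomy."""

import numpy as np
import pytest

from drypatch import (
    ClimateRamp,
    RemovalPolicy,
    ScenarioSpec,
    apply_removal,
    compare_strategies,
    dichotomy_report,
    gap_statistics,
    random_pattern,
    regular_pattern,
    run_scenario,
    strategy_every_kth,
)
from drypatch.params import ConstantRainfall
from drypatch.scenarios import PolicyError, apply_removal_field


@pytest.fixture(scope="module")
def slow_fast(p_ref):
    """Matched irregular 8-patch start under slow and fast drying."""
    init = random_pattern(8, 16.0, seed=5)
    slow = run_scenario(ScenarioSpec(init, p_ref, ClimateRamp(0.5, 0.0, 1e5), engine="hybrid"))
    fast = run_scenario(ScenarioSpec(init, p_ref, ClimateRamp(0.5, 0.0, 2e3), engine="hybrid"))
    return slow, fast


class TestHybridEngine:
    def test_static_feasible_climate_is_uneventful(self, p_ref):
        init = regular_pattern(6, 12.0)
        res = run_scenario(
            ScenarioSpec(init, p_ref, ConstantRainfall(0.5), engine="hybrid", t_end=200.0)
        )
        assert not res.events
        b = res.series.biomass
        assert abs(b.iloc[-1] - b.iloc[0]) / b.iloc[0] < 0.01

    def test_matches_pulse_ode_between_events(self, p_ref):
        # between events the hybrid engine is the pulse-location ODE: a
        # chunked hybrid run lands on the same positions as one direct
        # integration (up to solver restart noise at the shared rtol)
        from drypatch.reduction import integrate_pulse_ode

        init = random_pattern(6, 12.0, seed=8)
        res = run_scenario(
            ScenarioSpec(init, p_ref, ConstantRainfall(0.5), engine="hybrid", t_end=500.0)
        )
        assert not res.events
        direct = integrate_pulse_ode(init, p_ref, t_end=500.0).final_configuration().positions
        hybrid = res.final_cfg.positions
        assert np.max(np.abs(np.sort(direct) - np.sort(hybrid))) < 1e-6

    def test_patch_count_never_increases(self, slow_fast):
        for res in slow_fast:
            counts = res.series.n_patches.values
            assert np.all(np.diff(counts) <= 0)

    def test_cascade_ends_in_desert(self, slow_fast):
        for res in slow_fast:
            assert res.final_n == 0
            assert res.series.biomass.iloc[-1] == 0.0


class TestDichotomy:
    def test_fast_ramp_loses_one_by_one(self, slow_fast):
        _, fast = slow_fast
        sizes = [e.n_before - e.n_after for e in fast.loss_events()]
        assert sizes
        assert np.mean(np.array(sizes) == 1) >= 0.75

    def test_slow_ramp_first_event_is_halving_after_regularisation(self, slow_fast):
        slow, _ = slow_fast
        first = slow.loss_events()[0]
        assert first.type == "halving"
        pre_cv = slow.series[slow.series.t < first.t_event].gap_cv.iloc[-1]
        assert pre_cv < 0.05

    def test_slow_survives_to_lower_rainfall(self, slow_fast):
        slow, fast = slow_fast
        assert slow.loss_events()[0].a_event < fast.loss_events()[0].a_event

    def test_report_structure_and_crossings(self, slow_fast):
        slow, fast = slow_fast
        rep = dichotomy_report(slow, fast)
        assert rep["fast"]["frac_single"] >= 0.75
        assert rep["biomass_crossings"] >= 1

    def test_identical_ramps_identical_histograms(self, p_ref):
        init = random_pattern(8, 16.0, seed=5)
        spec = ScenarioSpec(init, p_ref, ClimateRamp(0.5, 0.0, 2e3), engine="hybrid")
        r1, r2 = run_scenario(spec), run_scenario(spec)
        assert r1.transition_histogram() == r2.transition_histogram()
        assert np.array_equal(r1.series.biomass.values, r2.series.biomass.values)

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_single_loss_fraction_ordering_across_seeds(self, p_ref, seed):
        # the central dichotomy holds for matched irregular starts: fast
        # ramps lose patches singly at least as often as slow ramps
        init = random_pattern(8, 16.0, seed=seed)
        slow = run_scenario(ScenarioSpec(init, p_ref, ClimateRamp(0.5, 0.0, 1e5), engine="hybrid"))
        fast = run_scenario(ScenarioSpec(init, p_ref, ClimateRamp(0.5, 0.0, 2e3), engine="hybrid"))
        frac = lambda r: np.mean([e.n_before - e.n_after == 1 for e in r.loss_events()])
        assert frac(fast) >= frac(slow)
        # regularised slow runs persist to lower rainfall before first loss
        assert slow.loss_events()[0].a_event <= fast.loss_events()[0].a_event + 1e-9


class TestRemovals:
    def test_remove_all_gives_desert(self, p_ref):
        cfg = regular_pattern(4, 8.0)
        out = apply_removal(cfg, range(4))
        assert out.n == 0

    def test_out_of_range_index(self, p_ref):
        with pytest.raises(IndexError):
            apply_removal(regular_pattern(3, 6.0), [5])

    def test_survivors_reregularise(self, p_ref):
        from drypatch.reduction import integrate_pulse_ode

        cfg = apply_removal(regular_pattern(6, 12.0), [2])
        traj = integrate_pulse_ode(cfg, p_ref, t_end=2e5)
        assert gap_statistics(traj.final_configuration()).cv < 1e-6

    def test_field_removal_idempotent(self, p_ref):
        from drypatch import field_from_pulses

        cfg = regular_pattern(3, 6.0)
        f = field_from_pulses(cfg, p_ref)
        once = apply_removal_field(f, [cfg.positions[1]], p_ref)
        twice = apply_removal_field(once, [cfg.positions[1]], p_ref)
        assert np.array_equal(once.v, twice.v)
        assert np.array_equal(once.w, f.w)


class TestEveryKth:
    def test_nine_over_three(self, p_ref):
        thinned, removed = strategy_every_kth(regular_pattern(9, 18.0), 3)
        assert len(removed) == 3
        assert thinned.n == 6
        gaps = np.round(np.sort(np.unique(np.round(thinned.gaps(), 9))), 6)
        assert len(gaps) == 2  # two gap sizes: the near-regular thinning

    def test_eight_over_two_emulates_halving(self, p_ref):
        thinned, removed = strategy_every_kth(regular_pattern(8, 16.0), 2)
        assert len(removed) == 4 and thinned.n == 4
        assert gap_statistics(thinned).cv == pytest.approx(0.0, abs=1e-12)

    def test_large_k_rounds_to_nearest(self, p_ref):
        thinned, removed = strategy_every_kth(regular_pattern(3, 6.0), 5)
        assert len(removed) == int(3 / 5 + 0.5)

    def test_irregular_input_rejected(self, p_ref):
        with pytest.raises(PolicyError, match="regular"):
            strategy_every_kth(random_pattern(9, 18.0, seed=1), 3)


class TestStrategies:
    def test_every_third_softens_first_drop(self, p_ref):
        base = ScenarioSpec(regular_pattern(9, 18.0), p_ref, ClimateRamp(0.5, 0.0, 1e5), engine="hybrid")
        table, results = compare_strategies(
            base,
            {
                "none": RemovalPolicy("none"),
                "every3": RemovalPolicy("every_kth", k=3, trigger=("at_margin", 0.02)),
            },
        )
        assert table.loc["every3", "biomass_drop_first"] < table.loc["none", "biomass_drop_first"]
        # the deliberate thinning brings the next destabilisation earlier
        # in the drying sequence (at higher rainfall)
        assert table.loc["every3", "a_first_event"] > table.loc["none", "a_second_event"]

    def test_determinism(self, p_ref):
        base = ScenarioSpec(regular_pattern(9, 18.0), p_ref, ClimateRamp(0.5, 0.0, 1e5), engine="hybrid")
        pols = {"every3": RemovalPolicy("every_kth", k=3, trigger=("at_margin", 0.02))}
        t1, _ = compare_strategies(base, pols)
        t2, _ = compare_strategies(base, pols)
        assert t1.equals(t2)

    def test_early_removal_at_rainfall_value(self, p_ref):
        spec = ScenarioSpec(
            regular_pattern(5, 10.0), p_ref, ClimateRamp(0.5, 0.0, 1e5),
            engine="hybrid",
            policy=RemovalPolicy("early_one", trigger=("at_a_value", 0.35)),
        )
        res = run_scenario(spec)
        manual = [e for e in res.events if e.manual]
        assert len(manual) == 1
        assert manual[0].a_event == pytest.approx(0.35, abs=0.01)
        assert manual[0].n_before - manual[0].n_after == 1
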