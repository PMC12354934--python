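import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_params, random_plan
from smartscan import (
    AcquisitionParams,
    RescanPlan,
    TileSpec,
    ValidationError,
    breakdown,
    breakeven_alpha,
    compare_modes,
    derive_tile_time,
    parallel_smart_runtime,
    serial_smart_runtime,
    traditional_runtime,
)
from smartscan.runtime_model import (
    SMART_PARALLEL_GLOBAL,
    SMART_SERIAL,
    TRADITIONAL,
)

# Analytic inversion of the default logistic curve at Q = 0.8
# (solves 1/(1+e^(-4a)) = 0.8 - e^-4/(1+e^-4)).
_T = math.exp(-4.0)
ALPHA_Q08 = -math.log(1.0 / (0.8 - _T / (1.0 + _T)) - 1.0) / 4.0


class TestDeriveTileTime:
    def test_reference_fast_tile(self):
        assert derive_tile_time(TileSpec(12000, 12000, 100.0)) == 14.4

    def test_reference_slow_tile(self):
        assert derive_tile_time(TileSpec(12000, 12000, 1000.0)) == 144.0

    def test_unit_conversion_identity(self):
        assert derive_tile_time(TileSpec(1, 1, 1e9)) == 1.0

    @pytest.mark.parametrize(
        "w,h,dwell", [(0, 10, 1.0), (10, -1, 1.0), (10, 10, 0.0), (10, 10, -5.0)]
    )
    def test_invalid_geometry_rejected(self, w, h, dwell):
        with pytest.raises(ValidationError):
            TileSpec(w, h, dwell)


class TestTraditionalRuntime:
    def test_defaults(self, defaults):
        # 30 * (20 + 24 * (4 + 144))
        assert traditional_runtime(defaults) == 107160.0

    def test_all_times_zero(self):
        p = AcquisitionParams(
            t_trad_s=0, t_fast_s=0, t_slow_s=0, t_compute_s=0, t_tile_s=0, t_section_s=0
        )
        assert traditional_runtime(p) == 0.0

    def test_single_tile_degenerate(self):
        p = AcquisitionParams(
            n_sections=1, n_tiles=1, t_section_s=0, t_tile_s=0, t_trad_s=10.0
        )
        assert traditional_runtime(p) == 10.0


class TestSerialSmartRuntime:
    def test_defaults_alpha_zero(self, defaults):
        # 30 * (20 + 24 * (4 + 14.4 + 28.8))
        assert serial_smart_runtime(defaults, RescanPlan(0.0)) == pytest.approx(
            34584.0, rel=1e-12
        )

    def test_defaults_alpha_one(self, defaults):
        assert serial_smart_runtime(defaults, RescanPlan(1.0)) == pytest.approx(
            138264.0, rel=1e-12
        )

    def test_all_times_zero(self):
        p = AcquisitionParams(
            t_trad_s=0, t_fast_s=0, t_slow_s=0, t_compute_s=0, t_tile_s=0, t_section_s=0
        )
        assert serial_smart_runtime(p, RescanPlan(0.5)) == 0.0

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            RescanPlan(1.5)
        with pytest.raises(ValidationError):
            RescanPlan(-0.1)


class TestParallelSmartRuntime:
    def test_defaults_at_operating_point(self, defaults):
        # hand evaluation: 38.4 + max{580 + 719*18.4, 719*28.8} + 28.8
        #                  + 30*(20 + 24*(4 + 0.31936*144)) = 57365.6448
        got = parallel_smart_runtime(defaults, RescanPlan(0.31936))
        assert got == pytest.approx(57365.6448, rel=1e-12)

    def test_operating_point_from_inversion(self, defaults):
        # 20774.4 + 30*(20 + 24*(4 + ALPHA_Q08*144)), evaluated independently
        expected = 20774.4 + 30 * (20 + 24 * (4 + ALPHA_Q08 * 144))
        got = parallel_smart_runtime(defaults, RescanPlan(ALPHA_Q08))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(57365.6596, abs=1e-3)

    def test_toy_hand_evaluation(self, toy_pipeline_params):
        # 110 + max{130, 150} + 50 + 200 = 510
        assert parallel_smart_runtime(toy_pipeline_params, RescanPlan(0.0)) == 510.0

    def test_single_tile_no_transitions(self):
        p = AcquisitionParams(
            n_sections=1, n_tiles=1, t_section_s=0, t_tile_s=0,
            t_fast_s=7.0, t_compute_s=3.0,
        )
        assert parallel_smart_runtime(p, RescanPlan(0.0)) == 10.0


class TestCompareModes:
    def test_defaults_parallel_wins(self, defaults):
        verdict = compare_modes(defaults, RescanPlan(ALPHA_Q08))
        assert verdict.fastest_mode == SMART_PARALLEL_GLOBAL
        assert verdict.per_mode_totals[TRADITIONAL] == 107160.0
        assert verdict.per_mode_totals[SMART_SERIAL] == pytest.approx(
            67695.2596, abs=1e-3
        )
        assert verdict.margin_s == pytest.approx(10329.6, abs=1e-6)

    def test_huge_compute_time_favors_traditional(self, defaults):
        p = defaults.replace(t_compute_s=1e6)
        verdict = compare_modes(p, RescanPlan(ALPHA_Q08))
        assert verdict.fastest_mode == TRADITIONAL

    def test_tie_reports_traditional(self, defaults):
        p = defaults.replace(t_fast_s=144.0, t_compute_s=0.0, t_slow_s=0.0)
        verdict = compare_modes(p, RescanPlan(1.0))
        assert verdict.per_mode_totals[TRADITIONAL] == verdict.per_mode_totals[
            SMART_SERIAL
        ]
        assert verdict.fastest_mode == TRADITIONAL

    def test_margin_nonnegative_and_fastest_is_minimum(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p, plan = random_params(rng), random_plan(rng)
            v = compare_modes(p, plan)
            assert v.margin_s >= 0.0
            assert v.per_mode_totals[v.fastest_mode] == min(v.per_mode_totals.values())


class TestBreakevenAlpha:
    def test_defaults_serial_closed_form(self, defaults):
        # (144 - 14.4 - 28.8) / 144 = 0.7
        assert breakeven_alpha(defaults, SMART_SERIAL) == pytest.approx(0.7, rel=1e-12)

    def test_serial_never_faster(self, defaults):
        p = defaults.replace(t_fast_s=120.0, t_compute_s=30.0)  # exceeds t_trad
        assert breakeven_alpha(p, SMART_SERIAL) is None

    def test_zero_slow_time_always_faster(self, defaults):
        p = defaults.replace(t_slow_s=0.0)
        assert breakeven_alpha(p, SMART_SERIAL) is None

    def test_crossing_actually_crosses(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = random_params(rng)
            for mode in (SMART_SERIAL, SMART_PARALLEL_GLOBAL):
                a = breakeven_alpha(p, mode)
                if a is not None:
                    f = (
                        serial_smart_runtime
                        if mode == SMART_SERIAL
                        else parallel_smart_runtime
                    )
                    assert f(p, RescanPlan(a)) == pytest.approx(
                        traditional_runtime(p), rel=1e-9, abs=1e-6
                    )


_params_strategy = st.builds(
    AcquisitionParams,
    quality_standard=st.floats(0, 1),
    n_tiles=st.integers(1, 8),
    n_sections=st.integers(1, 6),
    t_trad_s=st.floats(0, 100),
    t_fast_s=st.floats(0, 100),
    t_slow_s=st.floats(0, 100),
    t_compute_s=st.floats(0, 100),
    t_tile_s=st.floats(0, 100),
    t_section_s=st.floats(0, 100),
)


class TestProperties:
    @settings(max_examples=60, deadline=None)
    @given(p=_params_strategy, alpha=st.floats(0, 1))
    def test_monotone_in_every_time_parameter(self, p, alpha):
        plan = RescanPlan(alpha)
        for name in (
            "t_trad_s", "t_fast_s", "t_slow_s", "t_compute_s", "t_tile_s", "t_section_s"
        ):
            bumped = p.replace(**{name: getattr(p, name) + 5.0})
            assert traditional_runtime(bumped) >= traditional_runtime(p)
            assert serial_smart_runtime(bumped, plan) >= serial_smart_runtime(p, plan)
            assert parallel_smart_runtime(bumped, plan) >= parallel_smart_runtime(p, plan)

    @settings(max_examples=60, deadline=None)
    @given(p=_params_strategy, a1=st.floats(0, 1), a2=st.floats(0, 1))
    def test_affine_in_alpha(self, p, a1, a2):
        mid = RescanPlan(0.5 * (a1 + a2))
        for f in (serial_smart_runtime, parallel_smart_runtime):
            lin = 0.5 * (f(p, RescanPlan(a1)) + f(p, RescanPlan(a2)))
            assert f(p, mid) == pytest.approx(lin, rel=1e-9, abs=1e-9)
            assert f(p, RescanPlan(max(a1, a2))) >= f(p, RescanPlan(min(a1, a2)))

    @settings(max_examples=60, deadline=None)
    @given(p=_params_strategy)
    def test_serial_alpha_zero_is_traditional_with_fast_plus_compute(self, p):
        swapped = p.replace(t_trad_s=p.t_fast_s + p.t_compute_s)
        assert serial_smart_runtime(p, RescanPlan(0.0)) == pytest.approx(
            traditional_runtime(swapped), rel=1e-12, abs=1e-12
        )

    @settings(max_examples=60, deadline=None)
    @given(p=_params_strategy)
    def test_parallel_no_compute_is_fast_pass_plus_transition_pass(self, p):
        p0 = p.replace(t_compute_s=0.0)
        fast_pass = p0.n_sections * (
            p0.t_section_s + p0.n_tiles * (p0.t_tile_s + p0.t_fast_s)
        )
        empty_rescan = p0.n_sections * (p0.t_section_s + p0.n_tiles * p0.t_tile_s)
        assert parallel_smart_runtime(p0, RescanPlan(0.0)) == pytest.approx(
            fast_pass + empty_rescan, rel=1e-12, abs=1e-12
        )

    @settings(max_examples=60, deadline=None)
    @given(p=_params_strategy, alpha=st.floats(0, 1))
    def test_doubling_sections_doubles_serial_modes(self, p, alpha):
        doubled = p.replace(n_sections=2 * p.n_sections)
        assert traditional_runtime(doubled) == pytest.approx(
            2 * traditional_runtime(p), rel=1e-12, abs=1e-12
        )
        plan = RescanPlan(alpha)
        assert serial_smart_runtime(doubled, plan) == pytest.approx(
            2 * serial_smart_runtime(p, plan), rel=1e-12, abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(p=_params_strategy, alpha=st.floats(0, 1))
    def test_parallel_equals_max_form_identity(self, p, alpha):
        # T_par = max{A_n + T_c, a_1 + n*T_c} + rescan pass, where a_1 is the
        # pipeline start-up span and A_n the total fast-imaging span.
        n = p.n_sections * p.n_tiles
        a1 = p.t_section_s + p.t_tile_s + p.t_fast_s
        fast_span = p.n_sections * (
            p.t_section_s + p.n_tiles * (p.t_tile_s + p.t_fast_s)
        )
        rescan = p.n_sections * (
            p.t_section_s + p.n_tiles * (p.t_tile_s + alpha * p.t_slow_s)
        )
        expected = max(fast_span + p.t_compute_s, a1 + n * p.t_compute_s) + rescan
        assert parallel_smart_runtime(p, RescanPlan(alpha)) == pytest.approx(
            expected, rel=1e-9, abs=1e-9
        )


class TestBreakdown:
    def test_serial_components_sum_to_total(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p, plan = random_params(rng), random_plan(rng)
            for mode in (TRADITIONAL, SMART_SERIAL):
                b = breakdown(p, plan, mode)
                assert sum(b.components.values()) == pytest.approx(
                    b.total_s, rel=1e-9, abs=1e-9
                )

    def test_parallel_components_sum_at_least_total(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p, plan = random_params(rng), random_plan(rng)
            b = breakdown(p, plan, SMART_PARALLEL_GLOBAL)
            assert sum(b.components.values()) >= b.total_s - 1e-9

    def test_unknown_mode_rejected(self, defaults):
        with pytest.raises(ValidationError):
            breakdown(defaults, RescanPlan(0.0), "warp_speed")


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"quality_standard": 1.5},
            {"quality_standard": -0.1},
            {"n_tiles": 0},
            {"n_sections": -2},
            {"t_fast_s": -1.0},
            {"t_slow_s": float("nan")},
            {"t_compute_s": float("inf")},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            AcquisitionParams(**kwargs)
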