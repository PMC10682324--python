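"""Break-even arithmetic: C = S*dt, W = P/(S*dt), CI propagation, grid."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cad_breakeven import (
    breakeven_curve,
    evaluate_grid,
    min_workload,
    per_case_cost,
    propagate_ci,
)
from cad_breakeven.economics import SavedTimeRow
from cad_breakeven.report import round_half_up

ROWS = [
    SavedTimeRow(label="concurrent_reader", saved_time_s=77, saved_time_ci=(47, 107)),
    SavedTimeRow(label="prescreen_best_case", saved_time_s=100, saved_time_ci=(69, 131)),
    SavedTimeRow(label="prescreen_worst_case", saved_time_s=64, saved_time_ci=(43, 83)),
]


class TestPerCaseCost:
    def test_published_points(self):
        assert round_half_up(per_case_cost(196, 77)) == 4.2
        assert round_half_up(per_case_cost(45, 77)) == 1.0  # 0.9625 rounds half-up

    def test_unit_conversion_identity(self):
        assert per_case_cost(1, 3600) == 1.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            per_case_cost(-1, 10)

    @given(s=st.floats(1, 500), dt=st.floats(1, 500), a=st.floats(0.1, 10))
    def test_linear_in_salary_and_time(self, s, dt, a):
        assert per_case_cost(a * s, dt) == pytest.approx(a * per_case_cost(s, dt))
        assert per_case_cost(s, a * dt) == pytest.approx(a * per_case_cost(s, dt))


class TestMinWorkload:
    def test_published_points(self):
        assert round_half_up(min_workload(51616, 196, 77) / 1000) == 12.3
        assert round_half_up(min_workload(20000, 196, 77) / 1000) == 4.8

    def test_one_scan_when_price_equals_per_case_value(self):
        assert min_workload(per_case_cost(196, 77), 196, 77) == pytest.approx(1.0)

    def test_zero_saved_time_unreachable(self):
        with pytest.raises(ValueError, match="unreachable"):
            min_workload(51616, 196, 0)

    @given(
        p=st.floats(1000, 100_000), s=st.floats(10, 500), dt=st.floats(5, 300)
    )
    def test_workload_times_cost_is_price(self, p, s, dt):
        assert min_workload(p, s, dt) * per_case_cost(s, dt) == pytest.approx(
            p, rel=1e-12
        )


class TestPropagateCi:
    def test_cost_interval_preserves_order(self):
        lo, hi = propagate_ci("cost", 196, (47, 107))
        assert (round_half_up(lo), round_half_up(hi)) == (2.6, 5.8)

    def test_workload_interval_swaps_bounds(self):
        lo, hi = propagate_ci("workload", 196, (47, 107), price_eur=51616)
        assert lo < hi
        assert (round_half_up(lo / 1000), round_half_up(hi / 1000)) == (8.9, 20.2)

    def test_degenerate_interval(self):
        lo, hi = propagate_ci("cost", 196, (77, 77))
        assert lo == hi == per_case_cost(196, 77)

    def test_non_positive_lower_bound_rejected_for_workload(self):
        with pytest.raises(ValueError):
            propagate_ci("workload", 196, (0, 107), price_eur=51616)


class TestEvaluateGrid:
    def test_default_grid_cardinality(self, settings):
        results = evaluate_grid(settings.countries, settings.pricing, ROWS)
        assert len(results) == 27

    def test_point_always_inside_propagated_interval(self, settings):
        for r in evaluate_grid(settings.countries, settings.pricing, ROWS):
            point, lo, hi = r.per_case_cost_eur or r.min_workload_scans
            assert lo <= point <= hi

    def test_concurrent_pay_per_use_uk(self, settings):
        res = next(
            r
            for r in evaluate_grid(settings.countries, settings.pricing, ROWS)
            if r.country == "UK"
            and r.pricing_kind.value == "pay_per_use"
            and r.reading_mode_or_scenario == "concurrent_reader"
        )
        point, lo, hi = res.per_case_cost_eur
        assert (round_half_up(point), round_half_up(lo), round_half_up(hi)) == (2.7, 1.7, 3.8)

    def test_second_reader_flagged_no_break_even(self, settings):
        rows = [SavedTimeRow(label="second_reader", saved_time_s=-41)]
        results = evaluate_grid(settings.countries, settings.pricing, rows)
        assert all(r.no_break_even for r in results)
        assert all(r.per_case_cost_eur is None and r.min_workload_scans is None for r in results)

    def test_country_workload_ordering(self, settings):
        # lower salary => more scans to break even, for every row and price
        results = evaluate_grid(settings.countries, settings.pricing, ROWS)
        for row in ROWS:
            for kind in ("one_off_license", "yearly_subscription"):
                w = {
                    r.country: r.min_workload_scans[0]
                    for r in results
                    if r.pricing_kind.value == kind
                    and r.reading_mode_or_scenario == row.label
                }
                assert w["Poland"] > w["UK"] > w["USA"]

    def test_subscription_to_one_off_ratio(self, settings):
        results = evaluate_grid(settings.countries, settings.pricing, ROWS)
        for row in ROWS:
            for country in ("USA", "UK", "Poland"):
                get = lambda kind: next(
                    r.min_workload_scans[0]
                    for r in results
                    if r.country == country
                    and r.pricing_kind.value == kind
                    and r.reading_mode_or_scenario == row.label
                )
                assert get("yearly_subscription") / get("one_off_license") == pytest.approx(
                    20000 / 51616, rel=1e-12
                )

    def test_empty_inputs_rejected(self, settings):
        with pytest.raises(ValueError):
            evaluate_grid([], settings.pricing, ROWS)


class TestBreakevenCurve:
    def test_point_on_usa_curve_matches_grid(self):
        curve = dict(breakeven_curve(51616, 196, [47, 77, 107]))
        assert curve[77] == pytest.approx(min_workload(51616, 196, 77))
        assert round_half_up(curve[77] / 1000) == 12.3

    def test_strictly_decreasing_and_halving(self):
        grid = [20, 40, 60, 80, 120, 160]
        curve = breakeven_curve(51616, 196, grid)
        ws = [w for _, w in curve]
        assert all(a > b for a, b in zip(ws, ws[1:]))
        assert dict(curve)[40] == pytest.approx(dict(curve)[80] * 2, rel=1e-12)

    def test_poland_curve_above_usa_curve(self):
        grid = list(range(10, 181, 10))
        usa = [w for _, w in breakeven_curve(51616, 196, grid)]
        pol = [w for _, w in breakeven_curve(51616, 45, grid)]
        assert all(p > u for p, u in zip(pol, usa))

    def test_non_positive_grid_rejected(self):
        with pytest.raises(ValueError):
            breakeven_curve(51616, 196, [10, 0, 30])
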