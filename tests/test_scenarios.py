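"""Scenario transforms: ED scaling, COPD sensitivity, partial adoption."""

import numpy as np
import pytest

from bansim.model import OUTCOME_FIELDS, analytic_expectation, evaluate_draw
from bansim.scenarios import (
    Scenario,
    apply_adoption,
    apply_copd_reduction,
    scale_to_ed,
    standard_report_suite,
)
from bansim.simulation import run_simulation


class TestScaleToEd:
    def test_small_ed_values_at_means(self, table, means):
        national = evaluate_draw(means)
        ed = scale_to_ed(national, 30_000, means)
        assert ed.ban_units == pytest.approx(291.3, abs=0.5)
        assert ed.admission_savings_copd == pytest.approx(124_220, rel=1e-3)
        assert ed.net_bed_hours == pytest.approx(40.1, abs=0.1)

    def test_identity_when_volume_is_national_total(self, means):
        national = evaluate_draw(means)
        same = scale_to_ed(national, means["A"] + means["B"], means)
        for field in OUTCOME_FIELDS:
            assert getattr(same, field) == pytest.approx(getattr(national, field))

    def test_scaling_composes(self, means):
        national = evaluate_draw(means)
        direct = scale_to_ed(national, 130_000, means)
        via = scale_to_ed(national, 30_000, means).scaled(130_000 / 30_000)
        for field in OUTCOME_FIELDS:
            assert getattr(via, field) == pytest.approx(getattr(direct, field))

    def test_per_unit_cost_is_intensive(self, means):
        national = evaluate_draw(means)
        ed = scale_to_ed(national, 30_000, means)
        assert ed.unit_cost_delta == national.unit_cost_delta


class TestCopdReduction:
    def test_target_mean_and_cv_preserved(self, table):
        adjusted = apply_copd_reduction(table, 0.137)
        assert adjusted["S"].mean == 0.137
        assert adjusted["S"].sd / adjusted["S"].mean == pytest.approx(
            table["S"].sd / table["S"].mean
        )
        # every other row untouched
        for lbl in table.specs:
            if lbl != "S":
                assert adjusted[lbl] == table[lbl]

    def test_copd_savings_scale_linearly_in_expectation(self, table):
        base = analytic_expectation(table)
        adj = analytic_expectation(apply_copd_reduction(table, 0.137))
        assert adj.admission_savings_copd == pytest.approx(
            base.admission_savings_copd * 0.137 / 0.456
        )
        assert adj.admission_savings_ped == base.admission_savings_ped
        assert adj.admission_savings_adult == base.admission_savings_adult

    def test_national_total_at_137_percent_point(self, table):
        adj = analytic_expectation(apply_copd_reduction(table, 0.137))
        assert adj.admission_savings_total == pytest.approx(358.96e6, rel=1e-3)

    def test_zero_target_leaves_asthma_only(self, table):
        adj = analytic_expectation(apply_copd_reduction(table, 0.0))
        assert adj.admission_savings_copd == 0.0
        assert adj.admission_savings_total == pytest.approx(
            adj.admission_savings_ped + adj.admission_savings_adult
        )

    def test_out_of_range_target_rejected(self, table):
        with pytest.raises(ValueError):
            apply_copd_reduction(table, 1.5)


class TestAdoption:
    def test_full_adoption_is_identity(self, means):
        out = evaluate_draw(means)
        assert apply_adoption(out, 1.0) is out

    @pytest.mark.parametrize("rate", [0.25, 0.5, 0.75])
    def test_exact_linearity_per_draw(self, table, rate):
        rng = np.random.default_rng(33)
        from bansim.simulation import draw_parameters

        draw = draw_parameters(table, rng)
        full = evaluate_draw(draw)
        partial = apply_adoption(full, rate)
        for field in OUTCOME_FIELDS:
            if field == "unit_cost_delta":
                assert partial.unit_cost_delta == full.unit_cost_delta
            else:
                assert getattr(partial, field) == pytest.approx(
                    rate * getattr(full, field)
                )

    def test_quarter_adoption_units_at_means(self, table):
        exp = analytic_expectation(table, Scenario(adoption_rate=0.25))
        assert exp.ban_units == pytest.approx(1_291_356 / 4)

    def test_invalid_rate_rejected(self, means):
        with pytest.raises(ValueError):
            apply_adoption(evaluate_draw(means), 0.0)
        with pytest.raises(ValueError):
            Scenario(adoption_rate=1.5)


class TestReportSuite:
    def test_covers_all_standard_cell_families(self, table):
        suite = standard_report_suite(table, seed=50, n_iterations=30)
        keys = set(suite)
        assert "national/adoption_1" in keys
        for v in (30_000, 80_000, 130_000):
            assert f"ed_{v}/adoption_1" in keys
        for s in (0.228, 0.137):
            assert f"national/adoption_1/copd_s_{s:g}" in keys
        for rate in (0.25, 0.5, 0.75):
            assert f"ed_30000/adoption_{rate:g}" in keys
        # 4 scopes x (3 COPD settings + 3 partial adoptions) = 24 runs
        assert len(keys) == 24

    def test_base_national_cell_near_oracle(self, table):
        suite = standard_report_suite(table, seed=60, n_iterations=400)
        base = suite["national/adoption_1"]
        oracle = analytic_expectation(table)
        se = base.sd("admission_savings_total") / np.sqrt(400)
        assert abs(
            base.mean("admission_savings_total") - oracle.admission_savings_total
        ) < 4 * se


def test_ed_scenario_inherits_national_uncertainty(table):
    s = run_simulation(
        table, n_iterations=400, seed=70, scenario=Scenario(ed_visits=30_000)
    )
    assert s.sd("ban_units") > 0
    assert s.mean("ban_units") == pytest.approx(291, rel=0.1)
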