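"""Outcome model arithmetic against hand-derived values at the input means."""

import pytest

from bansim.model import (
    admission_savings,
    analytic_expectation,
    averted_admissions,
    ban_units,
    eligible_visits,
    evaluate_draw,
    marginal_supply_cost,
    mean_draw,
    mode_difference_supply_cost,
    net_bed_hours,
    net_bed_hours_all_visits,
)


@pytest.fixture(scope="module")
def counts(means):
    return eligible_visits(means)


class TestCohorts:
    def test_visit_volumes_at_means(self, counts):
        assert counts.visits_ped == pytest.approx(484_000)
        assert counts.visits_adult == pytest.approx(954_600)
        assert counts.visits_copd == pytest.approx(1_043_400)

    def test_nebulizer_visits_at_means(self, counts):
        assert counts.neb_ped == pytest.approx(319_440)
        assert counts.neb_adult == pytest.approx(544_122)
        assert counts.neb_copd == pytest.approx(427_794)

    def test_zero_proportions_empty_cohort(self, means):
        d = dict(means, C=0.0, D=0.0, E=0.0)
        c = eligible_visits(d)
        assert c.visits_ped == c.neb_adult == c.neb_copd == 0.0


class TestUnitsAndSupplyCost:
    def test_units_at_means(self, counts):
        assert ban_units(counts) == pytest.approx(1_291_356)

    def test_units_additivity(self, counts):
        solo = type(counts)(0, 0, 0, counts.neb_ped, 0, 0)
        assert ban_units(solo) == counts.neb_ped

    def test_mode_difference_supply_cost(self, table):
        # 1,291,356 units x ($5.45 - $0.75)
        assert mode_difference_supply_cost(table) == pytest.approx(6_069_373.2)

    @pytest.mark.parametrize(
        "units, ban, cn, expected",
        [(1_291_356, 5.45, 0.75, 6_069_373.2), (100, 3.0, 3.0, 0.0),
         (0, 5.45, 0.75, 0.0), (10, 1.0, 2.0, -10.0)],
    )
    def test_marginal_supply_cost(self, units, ban, cn, expected):
        assert marginal_supply_cost(units, ban, cn) == pytest.approx(expected)


class TestAdmissions:
    def test_averted_at_means(self, means, counts):
        ped, adult, copd = averted_admissions(means, counts)
        assert ped == pytest.approx(8_190.76, rel=1e-4)
        assert adult == pytest.approx(22_565.8, rel=1e-4)
        assert copd == pytest.approx(80_370.5, rel=1e-4)

    def test_full_prevention_bound(self, means, counts):
        d = dict(means, Q=1.0, R=1.0, S=1.0)
        ped, adult, copd = averted_admissions(d, counts)
        assert ped == pytest.approx(counts.neb_ped * means["J"])
        assert copd == pytest.approx(counts.neb_copd * means["L"])

    def test_savings_at_means(self, means, counts):
        averted = averted_admissions(means, counts)
        ped, adult, copd, total = admission_savings(averted, means)
        assert ped == pytest.approx(42.59e6, rel=1e-3)
        assert adult == pytest.approx(150.92e6, rel=1e-3)
        assert copd == pytest.approx(550.70e6, rel=1e-3)
        assert total == ped + adult + copd  # exact additivity

    def test_savings_linearity_in_unit_cost(self, means, counts):
        averted = averted_admissions(means, counts)
        base = admission_savings(averted, means)
        doubled = admission_savings(averted, dict(means, U=2 * means["U"]))
        assert doubled[0] == pytest.approx(2 * base[0])
        assert doubled[1] == base[1] and doubled[2] == base[2]


class TestBedHours:
    def test_discharged_only_rule_reproduces_headline(self, means, counts):
        assert net_bed_hours(means, counts) == pytest.approx(177_972, abs=1.0)

    def test_rejected_all_visits_variant_differs(self, means, counts):
        # regression guard pinning the design decision: applying LOS
        # effects to every treated visit overshoots by ~10%
        # (319,440 x 59 - 544,122 x 13.1) / 60
        assert net_bed_hours_all_visits(means, counts) == pytest.approx(
            195_316.03, abs=0.1
        )

    def test_zero_los_effects(self, means, counts):
        assert net_bed_hours(dict(means, O=0.0, P=0.0), counts) == 0.0

    def test_adult_increase_enters_negatively(self, means, counts):
        more_adult = dict(means, P=means["P"] * 2)
        assert net_bed_hours(more_adult, counts) < net_bed_hours(means, counts)


class TestExpectationOracle:
    def test_los_savings_at_means(self, table):
        exp = analytic_expectation(table)
        assert exp.los_cost_savings == pytest.approx(
            exp.net_bed_hours * 58.20
        )
        assert exp.los_cost_savings == pytest.approx(10.358e6, rel=1e-3)

    def test_expectation_equals_pipeline_at_means(self, table, means):
        assert analytic_expectation(table) == evaluate_draw(means)

    def test_homogeneity_in_visit_volumes(self, table, means):
        base = evaluate_draw(means)
        scaled = evaluate_draw(dict(means, A=2 * means["A"], B=2 * means["B"]))
        for field in ("ban_units", "admission_savings_total", "net_bed_hours"):
            assert getattr(scaled, field) == pytest.approx(
                2 * getattr(base, field)
            )

    def test_monotone_in_own_factors(self, table, means):
        base = evaluate_draw(means).admission_savings_copd
        for lbl in ("E", "H", "L", "S", "W"):
            bumped = evaluate_draw(dict(means, **{lbl: means[lbl] * 1.1}))
            assert bumped.admission_savings_copd > base

    def test_mean_draw_uses_pert_mean_for_prices(self, means):
        assert means["M"] == pytest.approx(6.05)
        assert means["N"] == pytest.approx(0.92)
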