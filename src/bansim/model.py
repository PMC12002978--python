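"""Deterministic per-draw arithmetic of the budget-impact model.

Given one joint realization of the 22 inputs (a *draw*, a mapping from
label to value), this module computes, for a national cohort of ED
visits for asthma and COPD exacerbation:

* cohort sizes — visits and nebulizer-treated visits per subgroup
  (pediatric asthma, adult asthma, COPD),
* annual breath-actuated nebulizer (BAN) units needed (one per treated
  visit),
* marginal supply cost of buying BANs instead of continuous nebulizers,
* admissions averted by the BAN effect, and the dollar savings from
  them, per subgroup and in total,
* the net change in ED bed-hours (pediatric length-of-stay reduction
  net of the adult increase, applied to visits not admitted at the
  baseline rate) and its dollar value.

Every output is a multilinear polynomial in the draw values. Because
the Monte Carlo engine samples inputs independently, the expectation of
each output equals the output evaluated at the input means — the
closed-form oracle :func:`analytic_expectation` exploited by the test
suite and the reports.

Sign conventions: ``net_bed_hours > 0`` means a net *reduction* in bed
occupancy; the adult LOS effect is an increase and enters negatively.
"One nebulizer per visit" is assumed throughout, and values are kept
fractional — rounding is a reporting concern, not a modelling one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .parameters import ParameterTable

__all__ = [
    "ParameterDraw",
    "CohortCounts",
    "OutcomeSet",
    "OUTCOME_FIELDS",
    "eligible_visits",
    "ban_units",
    "marginal_supply_cost",
    "averted_admissions",
    "admission_savings",
    "net_bed_hours",
    "net_bed_hours_all_visits",
    "los_cost_savings",
    "evaluate_draw",
    "mean_draw",
    "analytic_expectation",
    "mode_difference_supply_cost",
]

#: One Monte Carlo realization: label -> value in native units.
ParameterDraw = Mapping[str, float]


@dataclass(frozen=True)
class CohortCounts:
    """Annual visits and nebulizer-treated visits per subgroup."""

    visits_ped: float
    visits_adult: float
    visits_copd: float
    neb_ped: float
    neb_adult: float
    neb_copd: float


@dataclass(frozen=True)
class OutcomeSet:
    """All model outputs for one draw (or for the expectation oracle).

    ``scope`` tags whether the numbers are national or scaled to a
    single ED of a given annual volume; ``adoption_rate`` records any
    partial-adoption multiplier already applied.
    """

    ban_units: float
    unit_cost_delta: float  # USD/unit, BAN minus CN (intensive: never rescaled)
    marginal_supply_cost: float
    averted_ped: float
    averted_adult: float
    averted_copd: float
    admission_savings_ped: float
    admission_savings_adult: float
    admission_savings_copd: float
    admission_savings_total: float
    net_bed_hours: float
    los_cost_savings: float
    scope: str = "national"
    adoption_rate: float = 1.0

    def as_dict(self) -> dict[str, float]:
        """Numeric outcomes only, keyed by field name."""
        return {name: getattr(self, name) for name in OUTCOME_FIELDS}

    def scaled(self, factor: float, **tag_changes) -> "OutcomeSet":
        """Multiply every extensive outcome by ``factor`` (per-unit cost
        is intensive and kept)."""
        changes = {name: getattr(self, name) * factor for name in OUTCOME_FIELDS}
        changes["unit_cost_delta"] = self.unit_cost_delta
        changes.update(tag_changes)
        return replace(self, **changes)


#: Numeric outcome fields, in report order (scenario tags excluded).
OUTCOME_FIELDS: tuple[str, ...] = (
    "ban_units",
    "unit_cost_delta",
    "marginal_supply_cost",
    "averted_ped",
    "averted_adult",
    "averted_copd",
    "admission_savings_ped",
    "admission_savings_adult",
    "admission_savings_copd",
    "admission_savings_total",
    "net_bed_hours",
    "los_cost_savings",
)


def eligible_visits(draw: ParameterDraw) -> CohortCounts:
    """Cohort sizes from visit volumes, diagnosis shares, treatment shares."""
    visits_ped = draw["B"] * draw["C"]
    visits_adult = draw["A"] * draw["D"]
    visits_copd = draw["A"] * draw["E"]
    return CohortCounts(
        visits_ped=visits_ped,
        visits_adult=visits_adult,
        visits_copd=visits_copd,
        neb_ped=visits_ped * draw["F"],
        neb_adult=visits_adult * draw["G"],
        neb_copd=visits_copd * draw["H"],
    )


def ban_units(counts: CohortCounts) -> float:
    """Annual BAN units: one per nebulizer-treated visit, all subgroups."""
    return counts.neb_ped + counts.neb_adult + counts.neb_copd


def marginal_supply_cost(units: float, ban_price: float, cn_price: float) -> float:
    """Extra annual supply spending: units x (BAN price - CN price).

    Negative if the comparator is dearer; passed through unmodified.
    """
    return units * (ban_price - cn_price)


def averted_admissions(
    draw: ParameterDraw, counts: CohortCounts
) -> tuple[float, float, float]:
    """Admissions prevented per subgroup: treated visits x baseline
    admission rate x relative reduction from BAN."""
    return (
        counts.neb_ped * draw["J"] * draw["Q"],
        counts.neb_adult * draw["K"] * draw["R"],
        counts.neb_copd * draw["L"] * draw["S"],
    )


def admission_savings(
    averted: tuple[float, float, float], draw: ParameterDraw
) -> tuple[float, float, float, float]:
    """Dollar savings from averted admissions, per subgroup and total."""
    ped = averted[0] * draw["U"]
    adult = averted[1] * draw["V"]
    copd = averted[2] * draw["W"]
    return ped, adult, copd, ped + adult + copd


def net_bed_hours(draw: ParameterDraw, counts: CohortCounts) -> float:
    """Net annual ED bed-hour reduction from the asthma LOS effects.

    The LOS effects apply only to visits *not* admitted at the baseline
    admission rates (an admitted patient's ED stay ends with boarding,
    not discharge): pediatric reduction minus adult increase, minutes
    to hours. COPD contributes no LOS term.
    """
    minutes = (
        counts.neb_ped * (1.0 - draw["J"]) * draw["O"]
        - counts.neb_adult * (1.0 - draw["K"]) * draw["P"]
    )
    return minutes / 60.0


def net_bed_hours_all_visits(draw: ParameterDraw, counts: CohortCounts) -> float:
    """Rejected variant: LOS effects applied to *all* treated visits.

    Kept as a regression guard for the design decision above — on the
    default means it yields ~195,300 bed-hours versus ~178,000 for the
    discharged-only rule.
    """
    return (counts.neb_ped * draw["O"] - counts.neb_adult * draw["P"]) / 60.0


def los_cost_savings(net_hours: float, draw: ParameterDraw) -> float:
    """Dollar value of the bed-hour change at the per-bed-hour cost."""
    return net_hours * draw["T"]


def evaluate_draw(draw: ParameterDraw) -> OutcomeSet:
    """Run the full national pipeline on one draw."""
    counts = eligible_visits(draw)
    units = ban_units(counts)
    averted = averted_admissions(draw, counts)
    sav_ped, sav_adult, sav_copd, sav_total = admission_savings(averted, draw)
    hours = net_bed_hours(draw, counts)
    return OutcomeSet(
        ban_units=units,
        unit_cost_delta=draw["M"] - draw["N"],
        marginal_supply_cost=marginal_supply_cost(units, draw["M"], draw["N"]),
        averted_ped=averted[0],
        averted_adult=averted[1],
        averted_copd=averted[2],
        admission_savings_ped=sav_ped,
        admission_savings_adult=sav_adult,
        admission_savings_copd=sav_copd,
        admission_savings_total=sav_total,
        net_bed_hours=hours,
        los_cost_savings=los_cost_savings(hours, draw),
    )


def mean_draw(table: ParameterTable) -> dict[str, float]:
    """The draw whose entries are each parameter's distribution mean."""
    return table.central_values()


def analytic_expectation(table: ParameterTable, scenario=None) -> OutcomeSet:
    """Exact expectation of every outcome under independent sampling.

    Each outcome is a sum of products of *distinct* independent inputs,
    so its expectation is the same expression evaluated at the input
    means (normal/lognormal: the stated mean; BetaPERT:
    ``(min + 4*mode + max)/6``). An optional scenario applies the same
    transformations as the Monte Carlo engine, at the means.
    """
    if scenario is not None:
        # local import: scenarios builds on this module
        from .scenarios import apply_adoption, apply_copd_reduction, scale_to_ed

        if scenario.copd_reduction is not None:
            table = apply_copd_reduction(table, scenario.copd_reduction)
        draw = mean_draw(table)
        out = evaluate_draw(draw)
        if scenario.ed_visits is not None:
            out = scale_to_ed(out, scenario.ed_visits, draw)
        return apply_adoption(out, scenario.adoption_rate)
    return evaluate_draw(mean_draw(table))


def mode_difference_supply_cost(table: ParameterTable) -> float:
    """Deterministic national supply cost at the most-likely prices.

    Expected annual units multiplied by the difference of the *modes*
    of the two BetaPERT price distributions. This is the headline
    deterministic figure; the Monte Carlo mean of the sampled-price
    difference (which uses the PERT means, not modes) is slightly
    larger and reported alongside it.
    """
    units = ban_units(eligible_visits(mean_draw(table)))
    return units * (table["M"].mode - table["N"].mode)
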