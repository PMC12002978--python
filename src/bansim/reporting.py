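"""Rendering of simulation summaries as "mean (±SD)" report rows.

Report tables round each cell to a granularity that depends on
scope and outcome kind: nebulizer units to the nearest 10 (100
nationally), per-ED dollars to the nearest $100, national dollars to
the nearest $1,000, bed-hours to the nearest 10 per-ED and 1,000
nationally. Rounding is applied only when rendering — machine-readable
output always retains the unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import OUTCOME_FIELDS
from .simulation import SimulationSummary

__all__ = ["RoundingProfile", "NATIONAL_PROFILE", "PER_ED_PROFILE", "render_summary"]

_DOLLAR_FIELDS = frozenset(
    {
        "marginal_supply_cost",
        "admission_savings_ped",
        "admission_savings_adult",
        "admission_savings_copd",
        "admission_savings_total",
        "los_cost_savings",
    }
)
_COUNT_FIELDS = frozenset(
    {"ban_units", "averted_ped", "averted_adult", "averted_copd"}
)


@dataclass(frozen=True)
class RoundingProfile:
    """Granularity (in native units) per outcome kind."""

    name: str
    counts: float  # units, averted admissions
    dollars: float
    bed_hours: float
    per_unit: float = 0.01  # intensive USD/unit deltas


NATIONAL_PROFILE = RoundingProfile(
    name="national", counts=100, dollars=1000, bed_hours=1000
)
PER_ED_PROFILE = RoundingProfile(name="per_ed", counts=10, dollars=100, bed_hours=10)


def _granularity(field: str, profile: RoundingProfile) -> float:
    if field in _DOLLAR_FIELDS:
        return profile.dollars
    if field in _COUNT_FIELDS:
        return profile.counts
    if field == "net_bed_hours":
        return profile.bed_hours
    return profile.per_unit


def round_to(value: float, nearest: float) -> float:
    """Round to the nearest multiple of ``nearest``."""
    return round(value / nearest) * nearest


def _format(value: float, field: str, nearest: float) -> str:
    rounded = round_to(value, nearest)
    if nearest >= 1:
        text = f"{rounded:,.0f}"
    else:
        text = f"{rounded:,.2f}"
    if field in _DOLLAR_FIELDS or field == "unit_cost_delta":
        text = "$" + text
    return text


def render_summary(
    summary: SimulationSummary, profile: RoundingProfile | None = None
) -> list[dict[str, object]]:
    """Rows of ``{outcome, cell, mean, sd}``: rendered plus raw values.

    The profile defaults to per-ED granularity for ED-scope summaries
    and national granularity otherwise.
    """
    if profile is None:
        profile = (
            PER_ED_PROFILE
            if summary.scenario.ed_visits is not None
            else NATIONAL_PROFILE
        )
    rows = []
    for field in OUTCOME_FIELDS:
        mean = summary.mean(field)
        sd = summary.sd(field)
        nearest = _granularity(field, profile)
        # SDs print one step finer than means ("$1400 (±$260)")
        sd_nearest = nearest / 10 if nearest >= 100 else nearest
        cell = f"{_format(mean, field, nearest)} (±{_format(sd, field, sd_nearest)})"
        rows.append({"outcome": field, "cell": cell, "mean": mean, "sd": sd})
    return rows
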