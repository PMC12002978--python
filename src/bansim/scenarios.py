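"""Scenario transformations: per-ED scaling and the two sensitivity axes.

Three knobs modify the base national model:

* **ED scope** — outcomes for a single ED of annual volume ``V`` are the
  national outcomes times ``V / (A + B)``, the ED's share of national
  visits, using the *realized* A and B of each draw so per-ED spread
  inherits national parameter uncertainty. Case-mix is assumed equal to
  the national survey mix.
* **COPD admission-reduction sensitivity** — replace the mean of the
  COPD admission-reduction parameter (label S, base 45.6%) with a
  smaller value (22.8% and 13.7% in the standard suite), rescaling its SD to keep
  the coefficient of variation.
* **Partial adoption** — if only a fraction of eligible visits switch to
  BAN, every intervention delta (units, supply cost, averted
  admissions, savings, bed-hours) scales linearly with that fraction;
  non-adopters contribute zero delta.

All outcomes are multilinear, so adoption and ED scaling commute and can
be applied per-iteration after the national evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import OutcomeSet, ParameterDraw
from .parameters import ParameterTable

__all__ = [
    "ED_VOLUMES",
    "COPD_REDUCTIONS",
    "ADOPTION_RATES",
    "Scenario",
    "scale_to_ed",
    "apply_copd_reduction",
    "apply_adoption",
    "standard_report_suite",
]

#: Small / medium / large ED annual visit volumes for the report suite.
ED_VOLUMES: tuple[int, ...] = (30_000, 80_000, 130_000)
#: COPD admission-reduction means: base case, 50% and 70% adjustments.
COPD_REDUCTIONS: tuple[float, ...] = (0.456, 0.228, 0.137)
#: Adoption fractions examined in the report suite.
ADOPTION_RATES: tuple[float, ...] = (0.25, 0.50, 0.75, 1.0)


@dataclass(frozen=True)
class Scenario:
    """One model configuration.

    ``ed_visits=None`` means national scope; ``copd_reduction`` is an
    absolute replacement mean for parameter S (``None`` = table value).
    """

    ed_visits: float | None = None
    adoption_rate: float = 1.0
    copd_reduction: float | None = None

    def __post_init__(self) -> None:
        if self.ed_visits is not None and not self.ed_visits > 0:
            raise ValueError(f"ed_visits must be > 0, got {self.ed_visits}")
        if not 0 < self.adoption_rate <= 1:
            raise ValueError(
                f"adoption_rate must be in (0, 1], got {self.adoption_rate}"
            )
        if self.copd_reduction is not None and not 0 <= self.copd_reduction <= 1:
            raise ValueError(
                f"copd_reduction must be in [0, 1], got {self.copd_reduction}"
            )

    def describe(self) -> str:
        scope = "national" if self.ed_visits is None else f"ed_{int(self.ed_visits)}"
        parts = [scope, f"adoption_{self.adoption_rate:g}"]
        if self.copd_reduction is not None:
            parts.append(f"copd_s_{self.copd_reduction:g}")
        return "/".join(parts)


def scale_to_ed(
    national: OutcomeSet, ed_visits: float, draw: ParameterDraw
) -> OutcomeSet:
    """Scale national outcomes to one ED's share of realized total visits."""
    if not ed_visits > 0:
        raise ValueError(f"ed_visits must be > 0, got {ed_visits}")
    factor = ed_visits / (draw["A"] + draw["B"])
    return national.scaled(factor, scope=f"ed_{int(ed_visits)}")


def apply_copd_reduction(table: ParameterTable, target_s: float) -> ParameterTable:
    """Copy of the table with S's mean replaced, SD/mean ratio preserved."""
    if not 0 <= target_s <= 1:
        raise ValueError(f"target S must be in [0, 1], got {target_s}")
    spec = table["S"]
    new_sd = spec.sd * (target_s / spec.mean) if spec.mean else spec.sd
    return table.replace_spec("S", mean=target_s, sd=new_sd)


def apply_adoption(outcomes: OutcomeSet, rate: float) -> OutcomeSet:
    """Scale all intervention deltas by the adopting fraction."""
    if not 0 < rate <= 1:
        raise ValueError(f"adoption rate must be in (0, 1], got {rate}")
    if rate == 1.0:
        return outcomes
    return outcomes.scaled(rate, adoption_rate=outcomes.adoption_rate * rate)


def standard_report_suite(
    table: ParameterTable | None = None,
    seed: int | None = None,
    n_iterations: int = 1000,
) -> dict[str, "SimulationSummary"]:
    """Every standard scenario cell family, keyed by scenario descriptor.

    Covers the base national run; the three ED volumes; the three COPD
    admission-reduction means crossed with all four scopes; and the four
    adoption fractions crossed with all four scopes. Each scenario is an
    independent seeded run derived from the master seed.
    """
    from .simulation import DEFAULT_SEED, run_simulation

    if table is None:
        from .parameters import default_parameter_table

        table = default_parameter_table()
    if seed is None:
        seed = DEFAULT_SEED

    scopes: list[float | None] = [None, *ED_VOLUMES]
    scenarios: list[Scenario] = []
    for scope in scopes:
        for s_target in COPD_REDUCTIONS:
            scenarios.append(
                Scenario(
                    ed_visits=scope,
                    copd_reduction=None if s_target == COPD_REDUCTIONS[0] else s_target,
                )
            )
        for rate in ADOPTION_RATES[:-1]:
            scenarios.append(Scenario(ed_visits=scope, adoption_rate=rate))

    suite: dict[str, "SimulationSummary"] = {}
    for offset, scenario in enumerate(scenarios):
        summary = run_simulation(
            table, n_iterations=n_iterations, seed=seed + offset, scenario=scenario
        )
        suite[scenario.describe()] = summary
    return suite
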