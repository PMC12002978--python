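"""Synthetic parameter tables with controlled statistical structure.

These generators let every stage of the pipeline be exercised without
the packaged defaults: a zero-variance collapse for exact determinism
checks, randomly jittered-but-valid tables for fuzzing, and a tiny
round-number worked example whose outcomes can be audited by hand.
They are shipped in the package (not the test suite) so an installed
copy can be smoke-tested.
"""

from __future__ import annotations

import numpy as np

from .distributions import betapert_mean
from .model import OutcomeSet
from .parameters import (
    PROPORTION_LABELS,
    ParameterSpec,
    ParameterTable,
    default_parameter_table,
)

__all__ = ["zero_variance_table", "perturbed_table", "tiny_worked_example"]


def zero_variance_table(base: ParameterTable | None = None) -> ParameterTable:
    """Copy of ``base`` with all dispersion removed.

    Normal/lognormal SDs become 0; each BetaPERT collapses to a point at
    its PERT mean. Model output under this table is fully deterministic
    and equals the analytic expectation. Idempotent.
    """
    if base is None:
        base = default_parameter_table()
    specs = {}
    for lbl, spec in base.specs.items():
        if spec.dist_family == "betapert":
            specs[lbl] = ParameterSpec(
                label=spec.label,
                name=spec.name,
                dist_family="point",
                units=spec.units,
                mean=betapert_mean(spec.min, spec.mode, spec.max),
                source=spec.source,
            )
        elif spec.dist_family in ("normal", "lognormal"):
            specs[lbl] = ParameterSpec(
                label=spec.label,
                name=spec.name,
                dist_family=spec.dist_family,
                units=spec.units,
                mean=spec.mean,
                sd=0.0,
                source=spec.source,
            )
        else:
            specs[lbl] = spec
    return ParameterTable(specs=specs, metadata=base.metadata + " [zero variance]")


def perturbed_table(
    seed: int, cv: float = 0.1, bounds_respecting: bool = True
) -> ParameterTable:
    """Random valid table: default means jittered by Normal(1, cv).

    Proportions are re-clipped to [0, 1]; BetaPERT triples are re-sorted
    so min <= mode <= max survives the jitter (``bounds_respecting``
    additionally keeps jittered values positive). For ``cv > 0`` each
    dispersion is reset to 10% of the new mean; ``cv = 0`` returns the
    default table unchanged. Always passes validation.
    """
    if not 0 <= cv <= 0.5:
        raise ValueError(f"cv must be in [0, 0.5], got {cv}")
    base = default_parameter_table()
    if cv == 0:
        return base
    rng = np.random.default_rng(seed)
    specs = {}
    for lbl, spec in base.specs.items():
        if spec.dist_family == "betapert":
            jittered = [
                v * rng.normal(1.0, cv) for v in (spec.min, spec.mode, spec.max)
            ]
            if bounds_respecting:
                jittered = [max(v, 1e-9) for v in jittered]
            lo, mode, hi = sorted(jittered)
            if not lo < hi:  # fully collapsed jitter; re-open the range
                hi = lo + max(abs(lo), 1.0) * 1e-6
            specs[lbl] = ParameterSpec(
                label=spec.label,
                name=spec.name,
                dist_family="betapert",
                units=spec.units,
                min=lo,
                mode=mode,
                max=hi,
                source=spec.source,
            )
        else:
            mean = spec.mean * rng.normal(1.0, cv)
            if bounds_respecting:
                mean = max(mean, 1e-9)
            if lbl in PROPORTION_LABELS:
                mean = min(max(mean, 0.0), 1.0)
            specs[lbl] = ParameterSpec(
                label=spec.label,
                name=spec.name,
                dist_family=spec.dist_family,
                units=spec.units,
                mean=mean,
                sd=0.1 * mean,
                source=spec.source,
            )
    return ParameterTable(specs=specs, metadata=f"perturbed (seed={seed}, cv={cv})")


def _point(label: str, name: str, value: float, units: str) -> ParameterSpec:
    return ParameterSpec(
        label=label, name=name, dist_family="point", units=units, mean=value
    )


def tiny_worked_example() -> tuple[ParameterTable, OutcomeSet]:
    """A hand-auditable zero-variance table and its pencil-and-paper result.

    1,000 adult visits, all asthma, half treated with a nebulizer
    (500 treated visits; 10% admitted, halved by BAN → 25 averted
    admissions at $1,000 each → $25,000); 1,000 pediatric visits, all
    asthma, half treated, no admission effect but a 60-minute LOS
    reduction on the 90% discharged (450 bed-hours at $1/hour);
    BAN $2 vs CN $1 on 1,000 total units → $1,000 marginal cost.
    """
    specs = {
        "A": _point("A", "adult ED visits", 1000, "visits/year"),
        "B": _point("B", "pediatric ED visits", 1000, "visits/year"),
        "C": _point("C", "pediatric asthma share", 1.0, "proportion"),
        "D": _point("D", "adult asthma share", 1.0, "proportion"),
        "E": _point("E", "COPD share", 0.0, "proportion"),
        "F": _point("F", "pediatric nebulizer share", 0.5, "proportion"),
        "G": _point("G", "adult nebulizer share", 0.5, "proportion"),
        "H": _point("H", "COPD nebulizer share", 0.0, "proportion"),
        "J": _point("J", "pediatric admission rate", 0.1, "proportion"),
        "K": _point("K", "adult admission rate", 0.1, "proportion"),
        "L": _point("L", "COPD admission rate", 0.0, "proportion"),
        "M": _point("M", "BAN price", 2.0, "USD"),
        "N": _point("N", "CN price", 1.0, "USD"),
        "O": _point("O", "pediatric LOS reduction", 60.0, "minutes"),
        "P": _point("P", "adult LOS increase", 0.0, "minutes"),
        "Q": _point("Q", "pediatric admission reduction", 0.0, "proportion"),
        "R": _point("R", "adult admission reduction", 0.5, "proportion"),
        "S": _point("S", "COPD admission reduction", 0.0, "proportion"),
        "T": _point("T", "bed-hour cost", 1.0, "USD/bed-hour"),
        "U": _point("U", "pediatric admission cost", 1000.0, "USD/admission"),
        "V": _point("V", "adult admission cost", 1000.0, "USD/admission"),
        "W": _point("W", "COPD admission cost", 1000.0, "USD/admission"),
    }
    table = ParameterTable(specs=specs, metadata="tiny worked example")
    # Pencil-and-paper outcomes (frozen, not recomputed here):
    expected = OutcomeSet(
        ban_units=1000.0,  # 500 pediatric + 500 adult treated visits
        unit_cost_delta=1.0,
        marginal_supply_cost=1000.0,  # 1000 units x ($2 - $1)
        averted_ped=0.0,
        averted_adult=25.0,  # 500 x 0.1 x 0.5
        averted_copd=0.0,
        admission_savings_ped=0.0,
        admission_savings_adult=25_000.0,  # 25 x $1000
        admission_savings_copd=0.0,
        admission_savings_total=25_000.0,
        net_bed_hours=450.0,  # 500 x 0.9 x 60 min / 60
        los_cost_savings=450.0,  # 450 h x $1/h
    )
    return table, expected
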