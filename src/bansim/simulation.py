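"""Seeded Monte Carlo engine: draw inputs, evaluate, summarize.

Each iteration samples every parameter independently from its family —
normals resample-clipped to their physical support ([0, 1] for
proportions, [0, ∞) otherwise), BetaPERT prices on their stated range,
lognormal LOS effects matched to their arithmetic moments — evaluates
the outcome model, applies any scenario transformations, and records
the full outcome set.

Reproducibility: one master seed is expanded through a
``numpy.random.SeedSequence`` into one independent substream per
iteration, so results do not depend on how iterations might be batched
or parallelised. Within an iteration, parameters are sampled in
alphabetical label order regardless of table serialization order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import distributions as dist
from .model import OUTCOME_FIELDS, OutcomeSet, evaluate_draw
from .parameters import LABELS, ParameterTable
from .scenarios import Scenario, apply_adoption, apply_copd_reduction, scale_to_ed

__all__ = [
    "DEFAULT_SEED",
    "DEFAULT_ITERATIONS",
    "SimulationSummary",
    "draw_parameters",
    "run_simulation",
    "summarize",
]

#: Documented default master seed, so out-of-the-box runs are stable.
DEFAULT_SEED = 112358

#: Iteration count used for all published summaries.
DEFAULT_ITERATIONS = 1000

#: Quantiles reported per outcome (2.5% / median / 97.5%).
_QUANTILES = (0.025, 0.5, 0.975)


@dataclass
class SimulationSummary:
    """Per-outcome mean, SD and quantiles over the iterations.

    ``stats`` is a DataFrame indexed by outcome name with columns
    ``mean``, ``sd``, ``q025``, ``q500``, ``q975``. The SD uses the
    sample (n−1) denominator and is reported as 0 for a single
    iteration, flagged via ``degenerate``. Quantiles use linear
    interpolation between order statistics.
    """

    stats: pd.DataFrame
    n_iterations: int
    seed: int
    scenario: Scenario
    degenerate: bool = False
    iterations: pd.DataFrame | None = None

    def mean(self, outcome: str) -> float:
        return float(self.stats.loc[outcome, "mean"])

    def sd(self, outcome: str) -> float:
        return float(self.stats.loc[outcome, "sd"])


def _sample_spec(spec, rng: dist.RandomStream) -> float:
    if spec.dist_family == "point":
        return float(spec.mean)
    if spec.dist_family == "betapert":
        return dist.sample_betapert(spec.min, spec.mode, spec.max, rng)
    if spec.dist_family == "lognormal":
        return dist.sample_lognormal_from_moments(spec.mean, spec.sd, rng)
    upper = 1.0 if spec.units == "proportion" else math.inf
    return dist.sample_normal(spec.mean, spec.sd, lower=0.0, upper=upper, rng=rng)


def draw_parameters(table: ParameterTable, rng: dist.RandomStream) -> dict[str, float]:
    """One joint realization, sampling labels in alphabetical order."""
    return {lbl: _sample_spec(table[lbl], rng) for lbl in sorted(table.specs)}


def run_simulation(
    table: ParameterTable,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = DEFAULT_SEED,
    scenario: Scenario | None = None,
    keep_iterations: bool = False,
) -> SimulationSummary:
    """Monte Carlo run: ``n_iterations`` draws through the outcome model.

    The scenario's COPD-reduction replacement is applied to the table
    before sampling; ED scaling and partial adoption are applied to
    each iteration's outcomes. Deterministic given
    ``(table, n_iterations, seed, scenario)``.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    if scenario is None:
        scenario = Scenario()
    if scenario.copd_reduction is not None:
        table = apply_copd_reduction(table, scenario.copd_reduction)

    children = np.random.SeedSequence(seed).spawn(n_iterations)
    rows = np.empty((n_iterations, len(OUTCOME_FIELDS)))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        draw = draw_parameters(table, rng)
        out = evaluate_draw(draw)
        if scenario.ed_visits is not None:
            out = scale_to_ed(out, scenario.ed_visits, draw)
        out = apply_adoption(out, scenario.adoption_rate)
        rows[i] = [getattr(out, name) for name in OUTCOME_FIELDS]

    records = pd.DataFrame(rows, columns=list(OUTCOME_FIELDS))
    summary = summarize(records, seed=seed, scenario=scenario)
    if keep_iterations:
        summary.iterations = records
    return summary


def summarize(
    records: pd.DataFrame,
    seed: int = DEFAULT_SEED,
    scenario: Scenario | None = None,
) -> SimulationSummary:
    """Reduce per-iteration outcome records to a SimulationSummary."""
    n = len(records)
    if n < 1:
        raise ValueError("need at least one iteration record")
    degenerate = n == 1
    mean = records.mean(axis=0)
    if degenerate:
        sd = mean * 0.0
    else:
        values = records.to_numpy()
        sd = pd.Series(np.std(values, axis=0, ddof=1), index=records.columns)
        # a constant column has exactly zero spread (zero-variance runs);
        # np.mean of a constant is off by an ulp, so guard explicitly
        constant = np.ptp(values, axis=0) == 0
        sd[constant] = 0.0
        mean[constant] = values[0, constant]
    quantiles = records.quantile(list(_QUANTILES), interpolation="linear")
    stats = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "q025": quantiles.loc[_QUANTILES[0]],
            "q500": quantiles.loc[_QUANTILES[1]],
            "q975": quantiles.loc[_QUANTILES[2]],
        }
    )
    stats.index.name = "outcome"
    return SimulationSummary(
        stats=stats,
        n_iterations=n,
        seed=seed,
        scenario=scenario if scenario is not None else Scenario(),
        degenerate=degenerate,
    )
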