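# Methods

## Model structure

The model is a static, one-year, multiplicative cohort model with Monte
Carlo uncertainty propagation. Each iteration draws all 22 inputs
independently, evaluates a fixed arithmetic pipeline, and records
twelve outcomes; summaries report the per-outcome mean, sample SD
(n−1 denominator) and 2.5/50/97.5% quantiles (linear interpolation
between order statistics). The default run uses 1000 iterations —
enough that the mean of each outcome is stable to well under 1% — and
the test suite uses 10,000 where it checks Monte Carlo means against
closed forms at 4 standard errors.

Assumptions inherited from the model's framing:

- every nebulizer-treated visit consumes exactly one nebulizer unit,
  with no added nursing or training cost for BAN;
- all treated visits use CN at baseline; "adoption" switches a fraction
  of them to BAN, and all BAN effects (admission reductions, LOS
  changes, unit-price delta) accrue only to switched visits, making
  every outcome exactly linear in the adoption fraction;
- inputs are statistically independent — there is no correlation
  structure between, say, visit volumes and admission rates;
- no dynamics: no queueing, revisits, readmissions, discounting or
  currency-year adjustment.

## The bed-hour rule

The asthma LOS effects are applied only to treated visits *not*
admitted at the **baseline** admission rates: an admitted patient's ED
course ends in boarding, so a faster treatment response does not free
the bed. Net bed-hours are

    [ped_treated · (1 − J) · O − adult_treated · (1 − K) · P] / 60,

with the adult term negative because the adult effect is a LOS
*increase*. Two near-variants were considered and rejected: applying
effects to all treated visits (overshoots the discharged-only figure by
~10%, 195,316 vs 177,972 bed-hours at the input means — a regression
test pins both numbers), and using post-BAN admission rates (a ~2%
shift). COPD contributes no LOS term. Bed-hour savings are valued at
the ED bed-hour cost but reported separately from admission savings;
"total savings" means admission savings only.

## Supply cost: two figures, deliberately

The Monte Carlo marginal supply cost samples both unit prices from
their BetaPERT distributions and differences them; its per-unit mean is
the difference of the two PERT means, $6.05 − $0.92 = $5.13. A separate
deterministic figure multiplies expected units by the difference of the
*most likely* (mode) prices, $5.45 − $0.75 = $4.70. Both are exposed
(`marginal_supply_cost` in the simulation output;
`mode_difference_supply_cost` as a closed form) because they answer
different questions — expected spend under price uncertainty versus
spend at the most likely prices — and reports label which is which.

## Distributions and numerical choices

- **Clipped normal**: rejection sampling into the physical support
  ([0, 1] for proportions, [0, ∞) otherwise). At the table's ~10%
  coefficients of variation the clipping is numerically inert
  (<10⁻⁶ of mass) but guarantees valid draws; a cap of 1000 attempts
  makes a pathological user table fail loudly instead of looping.
  Zero SD returns the mean exactly.
- **BetaPERT**: classical shape constant λ = 4, i.e.
  α = 1 + 4(mode−min)/(max−min), β = 1 + 4(max−mode)/(max−min), mean
  (min + 4·mode + max)/6. "BetaPERT" without qualification is taken to
  mean this standard form.
- **Lognormal by arithmetic moments**: σ² = ln(1 + sd²/mean²),
  μ = ln(mean) − σ²/2, so the sampled arithmetic mean and SD match the
  stated values. The stated LOS values are plainly arithmetic effects
  (59 minutes), so they are not reinterpreted as log-scale parameters.
- **SDs as stated**: each normal input uses its stated SD verbatim
  (mostly 10% of the mean, but not for all rows) rather than imposing a
  uniform coefficient of variation.
- **Reproducibility**: one master seed feeds a `SeedSequence` that
  spawns one substream per iteration, so results are independent of
  any batching of iterations; within an iteration parameters are
  sampled in alphabetical label order, independent of table
  serialization order. Same seed ⇒ bit-identical summaries.
- Constant outcome columns are reported with SD exactly 0 (a two-pass
  variance plus an explicit zero-spread guard), so zero-variance tables
  give fully deterministic summaries.
- No rounding happens inside the model; report rendering rounds to the
  report granularity (per-ED dollars to $100, national dollars to
  $1,000, units to 10/100, SDs one step finer) while machine output
  keeps full precision.

## Scenarios

Per-ED outcomes multiply national outcomes by V/(A+B) with the
*realized* A and B of each iteration, so per-ED SDs inherit national
uncertainty; case-mix is assumed identical to the national mix. The
medium ED is 80,000 visits/year. The COPD sensitivity replaces the
admission-reduction mean (45.6% base) with 22.8% or 13.7%, rescaling
its SD to preserve the coefficient of variation. Adoption is a post-hoc
multiplier on outcome deltas — mathematically identical to re-running a
reduced cohort for this multilinear model.

## Synthetic fixtures

`zero_variance_table` collapses every distribution to its mean (PERT
mean for prices), making output deterministic and equal to the
analytic expectation — the strongest end-to-end exactness check.
`perturbed_table` jitters the default means multiplicatively by
N(1, cv), repairs proportion bounds and PERT ordering, and resets
dispersions to 10% of the new means; `cv = 0` is defined to return the
default table unchanged (the 10%-SD reset would otherwise alter the
few rows whose default SD is not 10% of the mean).
`tiny_worked_example` is a round-number table whose outcomes are frozen
from pencil-and-paper arithmetic. These fixtures emulate parameter
*tables*, not patient-level data: passing tests demonstrate correct
arithmetic and uncertainty propagation under the stated distributions,
not the external validity of the input estimates themselves, which
come from single-site studies in several cases.

## Known limitations

- The single-site COPD admission-reduction estimate drives ~60% of
  total savings; the built-in sensitivity analysis halves and
  near-quarters it for exactly this reason.
- Per-ED proportional scaling is the only rule consistent with the
  national figures and the per-ED LOS row; the package reports these
  internally consistent proportional values throughout.
- Savings are avoidable-cost estimates; realizing them depends on the
  payment model (most direct under global budgets or capitation).
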