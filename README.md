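# bansim

A seeded Monte Carlo budget-impact model of switching US emergency
departments (EDs) from continuous nebulizers (CN) to breath-actuated
nebulizers (BAN) for asthma and COPD exacerbations. It estimates, with
full uncertainty propagation, the national and per-ED marginal supply
cost, hospital admissions averted, dollar savings from those
admissions, and the net change in ED bed-hours — for health-services
researchers, ED operations analysts, and anyone costing a BAN-first
purchasing decision.

## The model

The cohort is annual US ED visits with a primary diagnosis of asthma or
COPD exacerbation that receive nebulizer therapy, split into three
subgroups: pediatric asthma, adult asthma, and adult COPD. With
national adult/pediatric visit volumes *A*, *B*, diagnosis shares,
nebulizer-treatment shares, baseline admission rates, BAN
admission-reduction effects, unit prices, length-of-stay (LOS) effects
and unit costs (22 parameters in all, each with a distribution), the
per-draw arithmetic is:

- treated visits, e.g. pediatric: `B · C · F` (volume × diagnosis share
  × nebulizer share), one BAN unit per treated visit;
- marginal supply cost: `units · (P_BAN − P_CN)`;
- averted admissions per subgroup: `treated · admission rate · relative
  reduction`, valued at the subgroup's cost per admission;
- net bed-hours: the pediatric LOS reduction minus the adult LOS
  increase, applied only to visits *not* admitted at the baseline rate,
  valued at the ED bed-hour cost.

Input uncertainty: normals (resample-clipped to physical support) for
survey-derived rates and costs, BetaPERT(min, mode, max) for unit
prices reported as ranges, and lognormals matched to arithmetic
mean/SD for the right-skewed LOS effects. Parameters are sampled
independently; every outcome is a sum of products of distinct inputs,
so its exact expectation is the same expression evaluated at the input
means — the built-in `analytic_expectation` oracle that the Monte Carlo
engine is tested against.

Scenario axes: per-ED scaling by annual volume (share of national
visits), partial adoption (exactly linear), and a sensitivity analysis
on the single-site COPD admission-reduction estimate.

## Worked example

```python
from bansim import analytic_expectation, default_parameter_table, run_simulation

table = default_parameter_table()
exact = analytic_expectation(table)
mc = run_simulation(table, n_iterations=1000, seed=112358)
print(f"{exact.ban_units:,.0f} units, ${exact.admission_savings_total:,.0f} saved")
print(f"MC: {mc.mean('ban_units'):,.0f} (±{mc.sd('ban_units'):,.0f}) units")
```

prints

```
1,291,356 units, $744,210,977 saved
MC: 1,295,261 (±155,610) units
```

— about 1.29 million BAN units a year nationally, $744M in expected
annual savings from averted admissions (≈60% from COPD), and a Monte
Carlo mean within sampling noise of the closed form, with the SD
showing how input uncertainty propagates. The same run yields ≈178,000
net ED bed-hours freed per year, worth ≈$10.4M. The scripts in
`examples/` walk through the national run, per-ED scaling, both
sensitivity analyses, and user-supplied parameter tables; the `bansim`
console command (`simulate`, `report-suite`, `validate`, `fixtures`)
exposes the same workflows from the shell.

Parameter tables are YAML, one record per single-letter label (A–H,
J–W); see `src/bansim/data/default_parameters.yaml` for the schema and
the packaged defaults. `inherit: default` lets a file override only the
labels it names.

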