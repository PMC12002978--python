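# Default model inputs: the 22 labelled parameters of the national
# budget-impact model for breath-actuated nebulizer (BAN) adoption.
#
# Schema (one record per single-letter label; the letter "I" is
# intentionally unused so labels stay alignable with the published
# input table):
#   name:   human-readable description
#   dist:   normal | betapert | lognormal | point
#   mean:   central value in native units      (normal, lognormal, point)
#   sd:     standard deviation, native units   (normal, lognormal)
#   min/mode/max: three-point range            (betapert; mean is derived
#                 as (min + 4*mode + max) / 6)
#   units:  visits/year | proportion | USD | minutes | USD/bed-hour |
#           USD/admission
#   source: free-text citation
#
# Proportions are stored as fractions in [0, 1], never percentages.
# A file may set the top-level key `inherit: default` to fill labels it
# omits from this packaged table; otherwise all 22 labels are required.
metadata: >-
  Packaged default inputs: national ED visit volumes and diagnosis/treatment
  shares (NHAMCS 2016-2021 summary values), nebulizer unit prices (IQVIA
  purchasing data), admission-reduction effects and LOS effects of
  breath-actuated vs continuous nebulizers (single-site comparative
  studies), and unit costs per admission and per ED bed-hour.
parameters:
  A:
    name: Annual US ED visit volume (adults)
    dist: normal
    mean: 111000000
    sd: 11000000
    units: visits/year
    source: NHAMCS 2016-2021, CDC
  B:
    name: Annual US ED visits (pediatrics excluding <2 years old)
    dist: normal
    mean: 22000000
    sd: 2200000
    units: visits/year
    source: NHAMCS 2016-2021, CDC
  C:
    name: Share of ED visits for asthma exacerbation (pediatrics)
    dist: normal
    mean: 0.022
    sd: 0.0022
    units: proportion
    source: NHAMCS 2016-2021, primary analysis
  D:
    name: Share of ED visits for asthma exacerbation (adults)
    dist: normal
    mean: 0.0086
    sd: 0.0010
    units: proportion
    source: NHAMCS 2016-2021, primary analysis
  E:
    name: Share of ED visits for COPD/emphysema exacerbation
    dist: normal
    mean: 0.0094
    sd: 0.0010
    units: proportion
    source: NHAMCS 2016-2021, primary analysis
  F:
    name: Share of pediatric asthma visits receiving nebulizer therapy
    dist: normal
    mean: 0.66
    sd: 0.066
    units: proportion
    source: NHAMCS 2016-2021, primary analysis
  G:
    name: Share of adult asthma visits receiving nebulizer therapy
    dist: normal
    mean: 0.57
    sd: 0.050
    units: proportion
    source: NHAMCS 2016-2021, primary analysis
  H:
    name: Share of COPD/emphysema visits receiving nebulizer therapy
    dist: normal
    mean: 0.41
    sd: 0.041
    units: proportion
    source: NHAMCS 2016-2021, primary analysis
  J:
    name: Admission rate after nebulizer therapy, pediatric asthma
    dist: normal
    mean: 0.077
    sd: 0.007
    units: proportion
    source: NHAMCS 2016-2021, primary analysis
  K:
    name: Admission rate after nebulizer therapy, adult asthma
    dist: normal
    mean: 0.0576
    sd: 0.0058
    units: proportion
    source: NHAMCS 2016-2021, primary analysis
  L:
    name: Admission rate after nebulizer therapy, COPD/emphysema
    dist: normal
    mean: 0.412
    sd: 0.0412
    units: proportion
    source: NHAMCS 2016-2021, primary analysis
  M:
    name: Per-unit price of BAN (AeroEclipse II)
    dist: betapert
    min: 5.43
    mode: 5.45
    max: 9.07
    units: USD
    source: IQVIA medical device and supply purchase data
  N:
    name: Per-unit price of continuous nebulizer
    dist: betapert
    min: 0.69
    mode: 0.75
    max: 1.83
    units: USD
    source: IQVIA medical device and supply purchase data
  O:
    name: ED LOS reduction from BAN, pediatric asthma
    dist: lognormal
    mean: 59
    sd: 29.5
    units: minutes
    source: Single-site prospective nonrandomized study (159 patients)
  P:
    name: ED LOS increase from BAN, adult asthma
    dist: lognormal
    mean: 13.1
    sd: 1.31
    units: minutes
    source: Single-site prospective randomized comparative study (54 patients)
  Q:
    name: Reduction in admissions after converting to BAN, pediatric asthma
    dist: normal
    mean: 0.333
    sd: 0.0333
    units: proportion
    source: Single-site randomized comparative study (149 patients)
  R:
    name: Reduction in admissions after converting to BAN, adult asthma
    dist: normal
    mean: 0.72
    sd: 0.072
    units: proportion
    source: Single-site randomized study (2-year period)
  S:
    name: Reduction in admissions after converting to BAN, COPD
    dist: normal
    mean: 0.456
    sd: 0.046
    units: proportion
    source: Single-site randomized study (3600 patients, 2-year period)
  T:
    name: Average ED bed-hour cost
    dist: normal
    mean: 58.20
    sd: 5.80
    units: USD/bed-hour
    source: Cost analysis from a single-site urban academic center
  U:
    name: Average cost per admission, pediatric asthma
    dist: normal
    mean: 5200
    sd: 520.00
    units: USD/admission
    source: Center for Medicare and Medicaid Services
  V:
    name: Average cost per admission, adult asthma
    dist: normal
    mean: 6688
    sd: 668.80
    units: USD/admission
    source: HCUP Nationwide Inpatient Dataset
  W:
    name: Average cost per admission, COPD/emphysema
    dist: normal
    mean: 6852
    sd: 685.20
    units: USD/admission
    source: Systematic literature review
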