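# Fully populated example run configuration (base case).
# Every field shown here equals the built-in default, so `cea run all`
# without --config produces the same outputs; edit to explore alternatives,
# or replace the `synthetic:` block with a `tables:` block pointing at
# transcribed life-table CSVs:
#
#   tables:
#     disease_csv: results/tables/disease_mortality.csv
#     allcause_csv: results/tables/all_cause_mortality.csv
#     rr_csv: results/tables/former_smoker_rr.csv

synthetic:
  seed: 0
  slope: 0.085                # Gompertz log-slope of all-cause mortality per year
  target_le_at_20: [60.6, 64.0]  # never-smoker LE at 20 (male, female)
  max_annual_prob: 0.28       # late-life cap on annual death probability
  disease_shares: [0.025, 0.015, 0.150]   # lung, COPD, CVD share of all-cause at ref age
  current_multipliers: [32.0, 18.0, 5.0]  # current- vs never-smoker excess risk
  onset_age: 20.0
  reference_age: 40.0
  rr_decay_halflife_years: 5.0
  jitter: 0.0

full:
  name: full_coverage
  participation: 0.073        # 10% of the 73% who want to quit
  attempt_cessation_prob: 0.0704
  natural_cessation_prob: 0.026
  n_attempts: 4
  attempt_frequency_years: 2
  consult_cost: 132.0         # EUR 2009 per covered attempt
  drug_cost: 201.0

comparator:
  name: fifty_euro
  participation: 0.0375       # claim the subsidy once; quit at the natural rate
  attempt_cessation_prob: 0.026
  natural_cessation_prob: 0.026
  n_attempts: 1
  attempt_frequency_years: 1
  consult_cost: 14.4
  drug_cost: 50.0

costs:
  chronic_costs: {lung_cancer: 13872.0, copd: 6562.0, cvd: 7976.0}  # EUR/person/year
  inflation: {gp_visits: 0.0023, drugs: 0.0219, chronic: -0.015}

discount:
  rate: 0.03
  discount_costs: true
  discount_benefits: true

population:
  national_smokers: 10000000  # smokers aged 15-75 at national scale
  cohort_size: 1000

psa_iterations: 1000
seed: 0
survival_mode: reciprocal      # or: exponential, fixed
out_dir: results
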