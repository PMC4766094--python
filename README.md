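# quitcea

Cost-effectiveness and budget-impact modelling of reimbursing smoking-cessation
treatment, from the statutory health insurer's perspective.

Smoking drives three major diseases — lung cancer, chronic obstructive pulmonary
disease (COPD) and cardiovascular disease (CVD) — whose treatment the French
long-term-illness scheme pays for almost entirely. This package asks whether the
payer should fully reimburse medically managed cessation attempts (consultations
plus pharmacotherapy) instead of the existing €50 annual drug subsidy, crediting
the avoided chronic-disease spending against the programme's cost. It is aimed at
health-economic modellers and at readers who want to re-run, probe or re-parameterize
this class of decision model.

## The model

A six-state Markov cohort model with one-year cycles follows 1,000 smokers aged
15–75 (age/gender strata) for life:

* **S** — smoker; **F(d)** — former smoker, tunnelled by completed years since
  cessation *d* so risk can decay with abstinence; **C/O/V** — diagnosed lung
  cancer / COPD / CVD; **D** — dead (absorbing).
* Disease incidence is proxied by disease-specific mortality at the person's
  current smoking status (a conservative choice: mortality understates
  incidence for COPD and CVD). Former-smoker risk equals never-smoker risk
  times a relative risk that falls across cessation-duration bands
  [1,3), [3,6), [6,11), [11,16), [16,∞).
* Other-cause mortality is the all-cause (never-smoker background) schedule
  minus the never-smoker burden of the three diseases; smoking's excess
  mortality flows entirely through the modelled diseases.
* Diagnosed persons face an annual death probability 1/LE fixed by their
  post-diagnosis life expectancy (by disease, age band and smoking status at
  diagnosis; e.g. two years for lung cancer).
* Cessation: participants (7.3% = 10% of the 73% of smokers who want to quit)
  receive up to four biennial covered attempts, each succeeding definitively
  with probability 7.04% (natural rate 2.6% × odds ratios 1.95 × 1.39); relapse
  is folded into that definitive rate. Everyone else quits at 2.6%/year.
* Economics (€2009): full coverage prices each attempt at €132 consultations +
  €201 drugs; the comparator claims €14.4 + €50 once. Chronic-illness costs
  (€13,872 / €6,562 / €7,976 per person-year for lung cancer / COPD / CVD) are
  inflated on stream-specific indexes and discounted at 3%. The headline output
  is the incremental cost-effectiveness ratio
  ICER = (C_full − C_€50) / (E_full − E_€50) in € per life-year gained (LYG).

Because the stratified mortality tables behind the original analysis are not
public, a calibrated synthetic generator (Gompertz all-cause baseline, disease
shares, smoker excess-risk multipliers, decaying former-smoker relative risks)
stands in by default; transcribed tables can be supplied as CSV.

## Worked example

```sh
python analysis/01_build_tables.py
python analysis/02_base_case.py
```

prints

```
full coverage vs 50-euro subsidy (lifetime, 3% discount):
  incremental cost   EUR       45,653
  incremental effect    11.80 life-years per 1,000 smokers
  ICER               EUR    3,869 per life-year gained [icer]
  deaths from the three diseases avoided: 2.06 per 1,000
against no coverage at all: EUR 4,074 per LYG
most efficient stratum: male entering at 50 (EUR 1,950/LYG)
```

Read: over the cohort's lifetime, full coverage costs the payer €45,653 more
than the €50 subsidy per 1,000 smokers and buys 11.8 discounted life-years, i.e.
about €3,869 per life-year gained — far below conventional willingness-to-pay
thresholds. The remaining drivers continue the analysis: `03_sensitivity.py`
(attempts sweep and 1,000-draw Monte Carlo of the ICER), `04_budget_impact.py`
(first-year national cost ≈ €243M for 10M smokers, and disease-cost offsets
at 5/10/20 years) and `05_validation.py` (model life expectancy at age 20 —
smokers lose ≈ 8 years; time-since-diagnosis distributions; a 1,000-quitter
scenario gaining ≈ 46 life-years over 10 years).

The same stages run from a single config through the CLI:

```sh
cea run all --config configs/example.yaml --seed 0 --out results
```

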