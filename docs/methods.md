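# Methods

## Model structure

The engine is a deterministic state-transition cohort model: expected
occupancy of six states is propagated through one-year cycles until the
whole cohort is absorbed in death or reaches age 110 (survivors at the cap
are moved to the dead state, with disease-state occupants tallied under
their disease). Everyone starts as a smoker; former smokers move through
tunnel sub-states F(1), F(2), … so that transition probabilities can depend
on completed years since cessation; the tunnel saturates at the lower edge
of the last relative-risk band (16 years by default), beyond which risk no
longer changes. Relapse is not an explicit transition — the per-attempt
cessation probability is *definitive* (lifetime relapse already folded in),
so P(F→S) = 0.

Within a cycle, a smoker's exits are: diagnosis with one of the three
diseases (at current-smoker disease-specific rates), other-cause death, and
cessation on this cycle's schedule; the remainder stays smoking. Transition
rows are assembled so they sum to one exactly; a row whose exits exceed one
raises an error rather than being renormalized.

### Other-cause mortality and the smoking gradient

The all-cause schedule is interpreted as the **never-smoker background life
table**. Other-cause mortality — shared by every smoking status — is that
schedule minus the never-smoker burden of the three diseases. A smoker
therefore faces the background other-cause rate plus elevated
disease-specific rates, and their implied total mortality exceeds the
background table, while a lifelong never-smoker reproduces it exactly.
This wiring is what lets the model produce the observed smoker/non-smoker
life-expectancy gap: if instead each status's own disease burden were
subtracted from a *shared* all-cause table, every status would face the same
total exit hazard and the extra disease diagnoses of smokers — each granting
a few further years of post-diagnosis survival — would perversely make
smoking life-prolonging. The package's `residual_other_cause_mortality`
still computes the residual for any requested status (and conserves
all-cause = residual + disease sum exactly); the engine uses the
never-smoker residual.

### Post-diagnosis survival

Diagnosed persons enter a terminal track whose mortality is pinned by the
post-diagnosis life expectancy LE(disease, age band at diagnosis, smoking
status at diagnosis): lung cancer 2 years for all; COPD 18/10/3 years for
smokers (<70 / 70–79 / ≥80), 20/15/5 for former smokers, 20/5 for never
smokers (<80 / ≥80); CVD 15/6/3/1 years (<65 / 65–74 / 75–84 / ≥85). Three
conversions of LE into cycle dynamics are available:

* `reciprocal` (default): constant annual death probability 1/LE — a
  geometric lifetime whose mean is LE in whole cycles;
* `exponential`: 1 − exp(−1/LE), a constant-hazard reading;
* `fixed`: survival of exactly LE years after diagnosis.

The validation suite uses `fixed` for the time-since-diagnosis table: with
duration-certain survival, alive lung-cancer patients at any horizon sit
entirely within two completed years of diagnosis (≈50%/50% across the two
bins) and CVD patients never exceed 15 years — the structure such models
report. Under `reciprocal`, a geometric(1/2) tail would leave ≈9% of alive
lung-cancer patients beyond two years, so the two modes are genuinely
different readings, not numerical variants; expected life-years are the
same under both, so life-expectancy results barely move.

### Cycle accounting

No half-cycle correction: one full life-year is credited per executed cycle
to persons alive at the cycle start, and the occupancy recorded at the
final horizon boundary earns nothing. Chronic-illness costs accrue for
every person-cycle in a disease state *including* the diagnosis cycle.
Covered-attempt events are the participating smokers present at attempt
cycles 0, f, 2f, … (n attempts at frequency f years); each event is priced
at one consultation plus one drug course, inflated from 2009 on separate
price indexes (GP visits +0.23%/y, drugs +2.19%/y; chronic costs −1.50%/y)
and discounted at the cost rate. Costs and benefits are discounted at 3% by
default, with independent switches so the "benefits undiscounted"
convention of the attempts sweep is available.

## Strategy arms

* **Full coverage** — participation 7.3%, four biennial covered attempts at
  definitive success 7.04% each, €132 + €201 per attempt. The 7.04% is the
  natural rate 2.6% times odds ratios 1.95 and 1.39 applied as direct
  multipliers (reproducing the printed parameter); a strict odds-scale
  composition (≈6.8%) is available via `scale="odds"`.
* **€50 subsidy (comparator)** — 3.75% of smokers claim €14.4 + €50 once at
  entry; effectiveness is the natural rate for everyone (the subsidy has no
  demonstrated effect on quitting). Modelled as a one-attempt strategy whose
  attempt probability *equals* the natural rate, so participation is
  cost-only by construction. The comparator doctor fee follows the €14.4
  figure (a printed €14 appears elsewhere; configurable).
* **No coverage** — natural cessation, no payer spending; used for the
  secondary comparison.

## Synthetic life tables

The stratified mortality schedules the model needs (by gender, single year
of age 15–110, and smoking status) are not publicly available, so a
generator emulates them:

* **All-cause baseline**: Gompertz q(a) = A·e^(b(a−20)) per gender, capped
  at 0.28/year (late-life mortality deceleration; the cap also keeps
  transition rows feasible near the age cap). The slope is b = 0.085/year,
  typical of adult human mortality; the intercept A is calibrated by root
  finding so never-smoker life expectancy at age 20 equals 60.6 years (men)
  and 64.0 years (women).
* **Disease burden**: never-smoker disease mortality is a share of
  all-cause mortality — 2.5% (lung cancer), 1.5% (COPD), 15% (CVD) at the
  reference age — ramping linearly from zero at age 20 to its full value at
  age 40 (smoking-related disease mortality is negligible in adolescence).
  Current smokers carry excess-risk multipliers 32 / 18 / 5. The
  multipliers sit at the upper end of the published relative-risk ranges
  for lung cancer and COPD and above the usual ~2–3 for vascular disease;
  together with the shares they are the calibration that reproduces an
  ≈8-year smoker/non-smoker life-expectancy gap at age 20 (8.1 years men,
  8.6 women) under the feasibility constraint that a smoker's total annual
  exit probability stays below 0.75 at the capped ages.
* **Former smokers**: relative risk versus never smokers decays
  geometrically with the band's lower edge (half-life 5 years) from the
  current-smoker multiplier toward 1, evaluated on the bands [1,3), [3,6),
  [6,11), [11,16), [16,∞), and is capped at the current-smoker rate.
  Durations under one year use the first band; beyond the last band the
  last value is the floor.
* **Gender**: both genders are generated directly from their own calibrated
  baselines. For transcribed (male-only) tables, the adjustment pipeline
  derives female rates via the male/female lung-cancer death ratio (other
  diseases default to ratio 1), after spatial (France/UK) and temporal
  ratio adjustments — each a per-disease multiplicative factor with
  probabilities clipped at 1.
* **Randomized draws**: a `jitter` parameter perturbs shares and multipliers
  with a seeded uniform relative factor, producing families of random
  tables that still satisfy every invariant — used by the property sweeps.
  With jitter 0 the generator is fully deterministic and seed-independent.

What the generator does **not** emulate: cohort (period vs generation)
effects, secular mortality trends, heterogeneity in smoking intensity, and
any correlation between diseases. Tests passing on synthetic tables
establish the *mechanics* (bookkeeping, ordering, conservation,
dose-response) and the calibrated orders of magnitude, not the original
point estimates, which require the transcribed tables.

## Cohort

1,000 smokers, six entry-age bands (midpoints 20…70) by gender, weighted to
resemble the age profile of French daily smokers (20/22/20/18/13/7% across
bands, 55% male). Weights are persons; doubling them doubles life-years and
costs and leaves ICERs unchanged (tested).

## Sensitivity analysis

The deterministic sweep varies covered attempts over {2, 4, 6}, reporting
the discounted ICER and the benefit-undiscounted life-year gain.

The probabilistic analysis redraws, independently per iteration: the
per-attempt cessation probability (log-normal anchored at 7.04% as the
*median*, σ = ln(9.47/5.64)/(2·1.96) ≈ 0.132 from the reported 95% CI — the
printed CI is slightly asymmetric about the point on the log scale, so the
fitted interval deviates marginally from it); participation ~
triangular(5%, 7.3%, 73%); drug cost ~ triangular(€120, €201, €220);
attempts {2,4,6}; frequency {1,2,4} years; discount {0,3,6}%; and the
inflation alternates per stream — all discrete supports sampled uniformly.
The comparator's natural rate is not sampled (no evidence base for its
variation). Both arms of an iteration share the same draw, so differences
are purely strategic. Cost-saving iterations (ΔC<0, ΔE>0) keep their
negative ratio in the summaries. The triangular sampler is an explicit
inverse-CDF transform (tested against scipy's); 1,000 iterations is the
default.

## Budget impact

Cohort results scale linearly to a national count of smokers aged 15–75
(configurable; the example uses 10 million, which prices the deterministic
first year at 73 participants/1,000 × €333 × 10,000 ≈ €243M). Budget
streams follow payer convention: undiscounted, inflation-adjusted. Offsets
are the comparator-minus-full-coverage chronic-cost streams accumulated
over 5/10/20-year horizons; the probabilistic variant reuses the
sensitivity sampler and reports both the confidence interval of the Monte
Carlo *mean* and the 95% interval of the *draws*, since either reading of a
"95% interval" is defensible.

## Validation computations

Lifelong-smoker and lifelong never-smoker life expectancies at age 20 come
from single-stratum runs with cessation disabled (the never-smoker run uses
a status override so the smoker state carries never-smoker rates). The
time-since-diagnosis table bins completed years as <1, 1–2, 3–5, 5–9,
10–15, >15; the printed bin labels overlap at their edges, so the partition
[0,1), [1,3), [3,5), [5,10), [10,16), [16,∞) is adopted. A disease with no
alive patients at the horizon reports NaN shares rather than dividing by
zero. The accomplished-quitter scenario starts the whole cohort in the
first former-smoker tunnel year and compares against continuing smokers
over a finite horizon, reporting life-years gained and avoided disease
spending.

## Numerical and reproducibility choices

* Probabilities are plain annual probabilities, not hazards; adjustment
  ratios that push an entry above 1 clip it with a logged warning.
* Conservation is enforced structurally (remainders computed as 1 − exits)
  and verified to 1e−12 in tests; occupancy is conserved to rounding and
  the dead state is monotone.
* All randomness (synthetic-table jitter, PSA, budget impact,
  microsimulation) flows from one master seed through named sub-streams
  (`synthetic-tables`, `psa`, `bia`), so stages are independently
  reproducible and re-runs are byte-identical.
* An individual-level microsimulation of the same state structure serves as
  an independent oracle: cohort occupancies match 200,000 simulated walkers
  within binomial sampling error (≥99.5% of stratum×cycle×state cells
  inside 3 SE).
* Problem sizes used by the shipped analyses: 1,000-person cohort, 12
  strata, lifetime horizon (≤95 cycles), 1,000 Monte Carlo iterations —
  chosen to match the modelled study design while keeping any stage's run
  under a minute on one core.

## Known limitations

* Mortality is a downward-biased proxy for incidence (COPD, CVD), so
  disease costs and offsets are conservative.
* Disease states are terminal tracks: no comorbidity, no return to the
  smoker/former states, no other-cause mortality once diagnosed.
* The €50-subsidy arm's participation is cost-only; if the subsidy had any
  real effect on quitting, the incremental benefit of full coverage would
  shrink.
* Synthetic tables are calibrated stand-ins (see above); value-level
  comparisons with published point estimates need transcribed schedules.
* Life-years only — no quality-of-life weighting; payer perspective only.
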