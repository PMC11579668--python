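# Methods

`llee` implements a modeled local-level economic evaluation (LLEE) of
hospital services that prevent inpatient hypoglycemia.  The pipeline has
four stages: (1) simulate an admission-level baseline cohort matched to the
hospital's printed event counts; (2) translate each intervention's published
or expert-elicited relative risk (RR) onto a common event-level measure;
(3) apply the intervention event by event under a stochastic prevention
rule and stabilise the outputs by bootstrap; (4) convert the simulated
reductions into cost-consequence outputs.  This note records the model, its
assumptions, the defaults, and what the synthetic data can and cannot show.

## Outcome definitions

Events are categorised from point-of-care blood-glucose (PoC-BGL)
measurements: severe hypoglycemia (<2.2 mmol/L), non-severe hypoglycemia
(2.2 to <4.0 mmol/L; the union of the two is "total hypoglycemia",
<4.0 mmol/L), and hyperglycemia (>15.0 mmol/L).  Hyperglycemia is never an
intervention outcome here — baseline hyperglycemia rates could not be
estimated from the available local data — but it enters the virtual
glycemic management service (vGMS) reporting criteria.  Admission days are
0-based (day 0 = day of admission); the "previous 24 hours" of the daily
vGMS report is approximated by one model day.

## Synthetic baseline cohort

The generator emulates the analysis cohort of an ~800-bed hospital over one
year: all adult admissions excluding obstetric patients, of which 641
admissions experience at least one hypoglycemia event and 1,732 events
occur in total (mean 2.702 events per affected admission), with 63% of
affected admissions experiencing two or more events.

* **Event counts.** Hypoglycemia events per affected admission follow a
  zero-truncated negative binomial (ZTNB).  Only two summaries of the count
  distribution are known (the mean and the multi-event share), so a
  two-parameter family is the minimal faithful choice; `fit_generator`
  solves the (mean, dispersion) pair so both implied moments match the
  targets to 1e-6 (bisection in a numerically stable `expm1`/`log1p`
  parameterisation; sampling is by inverse CDF, so cohorts are bitwise
  reproducible per seed).  The fitted dispersion at the default targets is
  r ≈ 1.0.
* **Population size.** The eligible population size is not printed anywhere;
  the default is 40,000 admissions with `p_affected` set so the expected
  number of affected eligible admissions is exactly 641.  All baseline and
  reduction quantities scale linearly with this choice.
* **Severity split.** Baseline severe-event counts are not printed.  Default
  `severe_share = 0.10` of hypoglycemia events are severe; the parameter is
  exposed in `CohortConfig` and varied in sensitivity-style tests.  Headline
  severe-event reductions are proportional to it.
* **Day assignment.** Uniform over the stay by default.  A `front_loaded`
  profile (geometric decay, ratio 0.75/day) is available because
  insulin-titration events cluster early in admissions; the source material
  is silent on timing.
* **Length of stay.** 1 + Poisson(`los_mean` − 1) days, default mean 5 days
  — a typical acute overnight-stay mean.  Stay length matters only through
  the patient-day measure and the within-stay spread of events.
* **Hyperglycemia.** Poisson per admission-day.  Dysglycemia clusters in
  the same (largely insulin-treated) patients, so affected admissions use
  `hyper_rate_affected = 0.75`/day — chosen so the probability of at least
  one hyperglycemia event in a given day is ≈53%, the audited share of
  hypoglycemia events preceded by hyperglycemia within 24 h — against a
  background `hyper_rate = 0.05`/day.  This choice is load-bearing for the
  vGMS analysis: without clustered hyperglycemia almost no patient would
  meet the reporting criteria before their first hypoglycemia event and the
  count of fully-prevented patients would be structurally zero.
* **Coded HACs.** A hospital-acquired complication (HAC) code attracts a
  funding penalty per episode.  Coded HACs are Bernoulli per affected
  admission: 25.5% for surgical admissions and the rate for non-surgical
  admissions solved so the all-patient fraction is 24.0% in expectation.
* **Cohort mix.** Defaults: 35% surgical, 5% ICU, 10% obstetric
  (obstetric admissions are ineligible and receive no hypoglycemia events).

**What passing tests show.** The generator reproduces the *marginal*
summaries above.  It does not reproduce real-data features such as
correlated event severities within a patient, non-stationary event rates,
readmissions, or the several audit percentages whose denominators are
internally inconsistent in the source material (these are deliberately not
targeted).  Conclusions about real hospital data therefore rest on the
pipeline's arithmetic and calibration behaviour, not on the synthetic
cohort being a statistical twin of any hospital.

## Prevention rule and intervention model

For each hypoglycemia event of an admission in the intervention's target
population, a uniform draw U is taken and the event is prevented iff
U > RR of its severity channel (RR = 0 is the prevent-everything boundary,
RR = 1 the null).  Events within a patient are independent — mirroring the
original evaluation design; positive correlation would raise the number of
patients with *all* events prevented, so fully-prevented counts are
conservative.  Hyperglycemia events are never prevented.

The vGMS acts only on patients in its daily report: an event is eligible
iff, within the previous model day (including earlier same-day events), the
admission already had ≥2 hyperglycemia events or ≥1 hypoglycemia event.
Eligibility is evaluated against the pre-intervention record — an event
prevented earlier in the same replicate still counts toward the criteria —
which is the simplest self-consistent reading of a reactive daily report.

Outputs are stabilised by resampling admissions (with their event lists,
preserving within-patient clustering) with replacement, 5,000 replicates by
default, each with an independent random substream; means and percentile
intervals are reported.  The bootstrap kernel is vectorised (flattened
event arrays with `reduceat` grouping), so a 5,000-replicate run over a
40,000-admission cohort takes a few seconds.

Three intervention specifications ship as YAML: the root-cause survey
(published RR 0.68 on events; elicited 0.85, range 0.80–0.90, severe
channel inheriting the total RR), the vGMS (published 0.64/0.31 on
patient-days; elicited 0.76/0.50, ranges 0.70–0.82 and 0.20–0.75, with the
reporting criteria above), and the pharmacist-led peri-operative team
(published 0.46 or 0.38 on patients, surgical cohort; retained so its
exclusion on staffing-cost grounds is reproducible).  Elicited three-point
estimates must satisfy optimistic ≤ realistic ≤ pessimistic (smaller RR =
stronger effect).

## Calibration onto the common measure

Published effects arrive on three measures: events, patient-days with ≥1
event, patients with ≥1 event.  Under independent per-event prevention the
expected aggregate RR implied by an event-level RR is

    RR_measure(rr) = mean over units u with ≥1 relevant event of
                     1 − (1 − rr)^(k_u)

with units = patients or patient-days and k_u the unit's relevant event
count.  The map is strictly increasing, so `calibrate` inverts it by
bisection on [0, 1] (max 60 iterations gives a bracket far below the 0.001
convergence tolerance; the iteration trace is serialised for audit).  A
`monte_carlo` mode reproduces the simulate–compare–refine loop by
evaluating the aggregate RR from bootstrap resamples built with common
random numbers (one fixed resampling seed per calibration, making the
objective deterministic and exactly monotone for the root-finder); it
agrees with the closed form to within about twice the tolerance.

When a study reports both severe and total RRs (vGMS), the severe channel
is calibrated first against the severe-event aggregate measure, then the
non-severe channel is calibrated so the combined measure matches the total
RR with the severe channel fixed.  The ordering is an interpretation — the
source material does not state how the two channels were coupled — and an
explicit infeasibility error is raised if, with the severe channel fixed,
even full non-severe prevention cannot reach the total target.  A
patient-day counts as "severe" if it has ≥1 severe event that day; "total"
days need ≥1 hypoglycemia event of either category.

Because events cluster, the calibrated event-level RR is always below a
patients- or patient-days-measure RR (e.g. an all-two-event cohort maps a
patients RR of 0.64 to an event RR of 1 − √0.36 = 0.400).

## Effect-size preprocessing

`rr_from_2x2` computes the risk ratio from raw arm counts with a Katz
log-normal confidence interval, exp(ln RR ± z·√(1/a − 1/n1 + 1/c − 1/n0)),
and a Pearson chi-squared p-value without continuity correction (a flag
enables Yates).  Zero intervention-arm events give RR 0 with the CI flagged
undefined; zero control-arm events raise.  Zero-margin tables (all subjects
sharing one outcome) return p = 1 rather than failing.  `or_to_rr` applies
the Zhang–Yu conversion RR = OR / (1 − p0 + p0·OR) for studies reporting
odds ratios.

## Cost-consequence accounting

Unit values (Australian, 2019–2022): HAC penalty AU$1,132 per coded
episode; bed-day cost AU$1,450 (the derivable product of the long-stay
outlier per-diem price weight 0.2641 and the AU$5,597 national efficient
price is 1,478.17 — `derive_bed_day_cost` exposes the discrepancy, and the
adopted 1,450 is used throughout because every downstream published saving
is an exact multiple of it); 3 bed-days released per admission with all
hypoglycemia events prevented (partially-prevented admissions release
none, a deliberate conservatism); nursing time 25/5 minutes per
severe/non-severe event; 1 minute per root-cause survey; FTE = 38 h/week
× 52 weeks, with annual staff hours truncated to whole hours (3 × 0.2 FTE
→ 1,185 h).

HAC reductions follow the proportional rule: coded HACs are a fixed
fraction of patients with ≥1 hypoglycemia event (24.0% all-patients, 25.5%
surgical), so each replicate's HAC reduction is that fraction of its drop
in affected patients.  In the rendered table, bootstrap-mean HAC and
fully-prevented counts are rounded to whole admissions before unit costs
apply, so every dollar cell is an exact integer multiple of its unit cost;
all other arithmetic is exact until display.  Unfunded time (e.g. nursing
minutes absorbed by existing rosters) is reported as hours with an
opportunity-cost annotation and never silently monetised.  Survey time for
the root-cause intervention is charged against the events that still occur
(one survey per remaining event), which reproduces the ~25 annual nursing
hours of the published costing.

## Numerical and design choices

* Bisection everywhere a monotone map is inverted (robust; no derivatives).
* RNG: numpy `SeedSequence` spawning — the pipeline derives every stream
  from one master seed, so identical run configurations give byte-identical
  artifacts (asserted by test).
* Degenerate inputs: empty cohorts, all-zero effects (RR = 1), full
  prevention (RR = 0), mean-1 count targets (degenerate one-event
  distribution), and HAC fractions with no affected admissions (reported as
  absent, not 0) are all defined behaviours with tests.
* Problem sizes in the shipped tests and acceptance script: 40,000-admission
  cohorts with 5,000 bootstrap replicates for headline runs; smaller
  event-dense cohorts (500–1,500 admissions) for statistical property
  tests, sized so Monte-Carlo error is well below the asserted tolerances.

## Known limitations

* Independence of events within a patient (see above): fully-prevented
  counts are conservative.
* The calibration's channel-coupling order is one defensible reading.
* Effect decay over time ("alert fatigue") and broader spillover effects of
  the vGMS beyond reported patients are noted qualitatively and not
  modeled.
* Length-of-stay benefits for partially-prevented admissions are excluded
  by design.
* The headline simulation outputs depend on distributional features of the
  original local dataset (severity split, within-stay timing, hyperglycemia
  burden) that were never published; the pipeline reproduces printed
  arithmetic exactly and printed simulation outputs only to the order of
  magnitude that those unpublished features permit.
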