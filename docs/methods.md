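# Methods

`icubench` implements a federated benchmarking analysis for intensive-care
quality registries whose data are standardized to the OMOP Common Data Model:
the same analysis code runs locally at each data source with a per-source
configuration, and only registry-level aggregates (observed deaths, expected
deaths, SMRs) cross the source boundary.

## The model

Severity of illness is scored with APACHE II. For each ICU admission the most
deranged value of 12 physiologic variables in the first 24 hours (temperature,
mean arterial pressure, heart rate, respiratory rate, oxygenation, arterial
pH, serum sodium, potassium, creatinine, haematocrit, leukocyte count,
Glasgow Coma Scale) contributes 0–4 points (GCS contributes 15 − GCS;
creatinine points double under acute renal failure; oxygenation is scored on
the alveolar–arterial gradient when FiO2 ≥ 0.5 and on PaO2 otherwise). Age
adds 0–6 points and chronic organ insufficiency adds 5 points (nonoperative
or emergency postoperative) or 2 (elective postoperative), for a total score
in [0, 71]. Predicted ICU mortality risk is

    logit(R) = −3.517 + 0.146·score + 0.603·1{emergency surgery} + w_dx

with `w_dx` the admission-diagnosis category weight. All numeric content of
the model lives in `src/icubench/data/apache2_scoring.yaml`, a transcription
of the published scoring sheet and coefficients, validated at load (ordered,
non-overlapping bands; a unique normal band; points weakly increasing away
from normal) and checked in the tests against an independently written
brute-force band lookup and three hand-scored vignettes.

Benchmarking uses the standardized mortality ratio: per unit (ICU or
registry), SMR = O/E where O is the count of deaths at ICU discharge and
E = Σ R_i, the sum of predicted risks (identically mean risk × n). Registry
E is the exact sum over its ICUs; a registry SMR is a ratio of sums, never a
mean of ICU SMRs. Funnel plots draw SMR against E with control limits for the
null SMR = 1, computed from exact Poisson tail quantiles with continuity
interpolation: with F the Poisson(E) CDF and k the smallest integer with
F(k) ≥ p, the interpolated quantile is (k−1) + (p − F(k−1))/(F(k) − F(k−1)),
and lower/upper limits are q(α/2)/E and q(1−α/2)/E. Exact limits behave
correctly at small E and converge to 1 ± z_{α/2}/√E; no overdispersion
adjustment is applied by default.

## Scoring conventions

Deliberate, documented conventions where the printed scoring sheet is
ambiguous:

* a value exactly on a band edge, or in the printed gap between two bands
  (e.g. temperature 38.45), belongs to the adjacent band with the **higher**
  point value;
* the component score is the worse of the recorded lowest/highest extrema;
* the first-24-hour window is half-open, [admission, admission + 24 h), so a
  measurement at exactly +24 h is not double-counted;
* age at admission is admission year − year of birth (OMOP stores year only);
  "less than 17 years" excludes, so computed age 17 is eligible;
* venous bicarbonate bands are shipped in the scoring file but not used by
  default (arterial pH is the default acid–base input);
* events whose recorded unit differs from the configured unit are dropped
  with a warning, never silently converted.

## Cohort selection

ICU encounters (OMOP `visit_detail`) are filtered in a fixed, reported order:
admission date inside the study window (2019-07-01 to 2022-12-31, inclusive)
→ age ≥ 17 → no burns diagnosis → a recorded reason for admission → first
ICU stay per hospital visit only (ties on start time break on the lower
`visit_detail_id`). The attrition report counts each step, so the counts are
order-dependent by construction and sum to the cohort size. Reasons for
admission are mapped to APACHE II diagnostic categories through a per-source
mapping table, optionally via an intermediate classification (emulating a
source that collects SNOMED-CT-like codes and maps them through an
APACHE-IV-style grouping); unmapped codes are reported and excluded, never
defaulted.

## Missing data: two context-specific strategies

* **Normal-range fill** (for a source where clinicians omit values they judge
  normal): an absent physiologic component contributes 0 points. The fill
  acts on points, never invents raw values, so it commutes with scoring and
  can only leave the observed-component APS unchanged.
* **Multiple imputation with predictive mean matching** (for a source where
  missingness reflects resource constraints): chained equations over the wide
  table's extremum columns, visiting variables in a fixed order; per variable
  a linear model on all other columns plus the always-present predictors
  (registry indicators, ICU survival status, ICU length of stay), with
  coefficients drawn from the standard noninformative posterior (proper
  imputation); each missing cell receives the observed value of one of
  `donors_k = 5` donors with nearest predictive mean (type-1 matching:
  observed means from the least-squares fit, missing means from the
  coefficient draw), so every imputed value is an observed value. Defaults
  are m = 30 imputations × 100 cycles; both are configurable. FiO2 and the
  alveolar–arterial gradient are never imputed: the gradient's absence is
  structural (it exists only when FiO2 ≥ 0.5), not informative.

Per-patient risks under MI are reported as the mean over the m completed
datasets. Registry-level inference pools the per-imputation expected deaths
E_j with Rubin's rules: point = mean, total variance T = W + (1 + 1/m)B with
W the mean within-imputation variance and B the between-imputation sample
variance; the 95% interval uses a t reference with ν = (m−1)(1 + W/((1+1/m)B))²
degrees of freedom (normal when B = 0). The within-imputation variance of
expected deaths is Σ R(1−R), treating risks as independent Bernoulli means —
a documented, swappable choice. The SMR interval endpoints are O/E_hi and
O/E_lo (division reverses the order), and funnels can be overlaid for the
point and both bounds.

## The synthetic data generator

Real registry extracts are access-controlled, so the package ships a seeded
generator whose output is the test bed for every stage. Per admission a
latent severity z ~ N(0,1) is drawn; each variable's worst value derives from
a noisy copy of z ((z + ε)/√2) cut at fixed thresholds into five severity
levels, then sampled uniformly inside the scoring band of that level on a
randomly chosen derangement side (per-variable side probabilities reflect the
common direction of derangement, e.g. hypotension more often than
hypertension). This calibration spans total scores roughly 0–40 with a median
near 13–15 and mean predicted risk ≈ 0.2, in the range the two registries
report. Death is Bernoulli(min(1, multiplier × R)) with R the APACHE II risk
of the generated values and a per-ICU multiplier (the *true* SMR), which
makes registry benchmarking a parameter-recovery experiment. Raw measurement
events (2–6 per variable per stay) are timestamped inside the 24 h window
with extrema equal to the truth values; occasional more-extreme distractor
events after the window exercise the window filter. Structural dialect
differences between two emulated sources — leukocyte concept 3000905
(automated) vs 3003282 (manual), comorbidities in `condition_occurrence` vs
`observation`, a one-stage vs two-stage reason vocabulary — are pure
relabelings: the same seed produces stores that extract to identical wide
tables under their own configurations.

Missingness mechanisms: MCAR deletes individual events at the target rate;
MAR deletes all of a stay's events for a variable with probability
expit(a + s), where s is an **observed**-severity score (ICU death indicator
plus standardised log length of stay) and a is solved so the marginal rate is
exact. Linking deletion to observed outcome variables — which the imputation
protocol always conditions on — makes the mechanism genuinely missing at
random for that protocol. An earlier design linked deletion to the latent z
itself; that mechanism is residually missing-not-at-random given any
realistic predictor set (pooled expected deaths came out 7–8% low for this
package's imputer and for an independent reference implementation alike), so
it was replaced. The coverage experiments apply MAR to the seven laboratory
components only (PaO2, pH, sodium, potassium, creatinine, haematocrit,
leukocytes): resource constraints plausibly affect tests, not continuously
monitored bedside vitals.

What the generator does not emulate: longitudinal physiology trajectories,
inter-variable correlation beyond the single severity factor, drug exposures,
pediatric case mix, unit conversions across sites, or data-entry error.
Passing tests therefore demonstrate correctness of the pipeline's mechanics
and statistical calibration under a known model — not performance on real
registry data.

## Problem sizes and numerical choices

The test-suite experiments use sizes chosen to pin the statistics tightly at
desk scale: 200 ICUs × 500 admissions for funnel null coverage (fraction
inside the 95% limits within 3 Monte-Carlo SEs of 0.95); registries of 2000
admissions at true SMRs 0.7/1.0/1.5 recovered within ±3·√O/E; 50 replicates
of n = 5000 with MAR rate 0.3, m = 10 imputations × 20 cycles for interval
coverage (≥ 90%) of complete-data expected deaths. Matrix solves add a 1e-8
ridge for degenerate designs; the PMM donor search uses a sorted
2k-neighbour window; all simulation randomness flows from named integer
seeds through `numpy.random.default_rng`, and the SVG renderer pins its hash
salt and strips timestamps so reruns are byte-identical.

## Known limitations

* The chronic-health and acute-renal-failure flags are taken as recorded
  presence variables; no phenotyping logic is applied.
* The within-imputation variance of expected deaths ignores risk-estimation
  uncertainty (the APACHE II coefficients are treated as fixed constants).
* ICU identity relies on the optional `care_site` table; sources that strip
  it (as one real registry does for privacy) can only be benchmarked at
  registry level — which is the default.
* Hospital mortality is out of scope; the outcome is death during the ICU
  stay, a death-table record timestamped inside [admission, discharge].
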