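# Methods

## The case/non-case design

Spontaneous-report databases have no denominators: exposure prevalence and
event incidence are unknowable from reports alone. The case/non-case design
sidesteps this by comparing, *within* the database, the odds that a report
mentions the exposure among event reports (cases) versus all other reports
(non-cases). The resulting reporting odds ratio (ROR) measures
disproportionate *reporting*, not risk; the design inherits all reporting
biases (under-reporting, notoriety effects, channeling) and supports no
causal or incidence claims. `nwsignal` implements this design for one
event: withdrawal syndrome in neonates after in-utero antidepressant
exposure.

**Case definition.** A report is a case when (i) any reaction carries a
withdrawal preferred term from the packaged term dictionary or a
`drug withdrawal` standardized-query tag, and (ii) the patient's recorded
age is 1–27 days inclusive. Reports without a recorded age are non-cases:
a neonate cannot be confirmed, and we prefer a deterministic rule over
imputation. Day-of-birth (age 0) reports are excluded by the default
window; the window is a parameter (`age_window`) because reasonable
variants exist (0–27 days). The term `drug withdrawal maintenance therapy`
is retained in the dictionary although its clinical reading as a withdrawal
reaction is debatable; the dictionary is an editable YAML resource, and the
case flag is monotone in it (adding terms never unsets a case).

**Exposure.** Only drugs in the `suspected` or `interacting` role count as
exposure; `concomitant` mentions never do. 27 antidepressants are mapped to
three classes (7 TCAs, 6 SSRIs, 14 others) by name with ATC-code fallback;
St John's wort is matched by name and synonyms since it lacks a unique
common ATC code. Counting is report-level throughout: a report naming two
antidepressants contributes once to pooled and class tables.

## Estimators

For a 2×2 table (a = exposed cases, b = exposed non-cases, c, d likewise in
the comparator arm):

- ROR = (a·d)/(b·c); 95% CI by the Woolf log-normal method,
  exp(ln ROR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)). With `correction="haldane"`
  (the analysis-suite default) 0.5 is added to every cell *only when* some
  cell is zero, so corrected and uncorrected estimates coincide on
  non-degenerate tables. A zero cell without correction yields an
  *undefined* result carrying its reason, never an exception; an all-zero
  table is undefined under either setting.
- IC = log₂((a+½)/(E+½)) with E = (a+b)(a+c)/N. The ½-shrinkage pulls
  rare-pair estimates toward 0. Credibility bounds are log₂ quantiles of
  Gamma(shape a+½, rate E+½) evaluated by `scipy.stats.gamma.ppf`; an
  optional Wald interval (IC ± z/(ln2·√(a+½))) is provided as the cheaper
  large-count approximation (`ic_method="wald"`).

E is computed **inside each contrast's comparator frame**, not over the
whole database, so ROR and IC always describe the same comparison. This is
a deliberate internal-consistency choice; a whole-database E would inflate
IC for contrasts with small comparator arms.

**Signal rule.** `signal = (ROR lower bound > 1) and (IC lower bound > 0)`.
Requiring both estimators to agree trades sensitivity for robustness. No
multiplicity adjustment is applied, matching standard practice for this
design.

**Comparator schemes.** `main`: comparator = reports with no
antidepressant exposure (this includes positive-control reports — "all
other drugs"); `positive_control`: comparator = methadone-exposed reports;
`intraclass`: comparator = reports exposed to another antidepressant of the
same class. A report qualifying for both arms is assigned to the exposed
arm. Drug-level output requires ≥ `min_cases` exposed cases (default 4,
i.e. more than three reports).

## Priority score

Four criteria, totalled 0–7, banded weak (0–1, green), moderate (2–5,
yellow), strong (6–7, red):

1. withdrawal share of the drug's ADR reports: >10% → 2, 5–10% → 1, <5% → 0
   (values in (4,5)% score 0, continuous with the 5% band edge);
2. confounder-free share of the drug's withdrawal reports: ≥71% → 2,
   >50% → 1, ≤50% → 0. **Note:** the published thresholds for this
   criterion ("⩽71%: 2 … ⩽50%: 0") are internally contradictory; we read
   the first relation as a typographical inversion (≥71) and close the
   (50, 51)% gap with `>50`, consistent with both stated bands;
3. dual ROR/IC significance in all three schemes → 2, in two → 1, in at
   most one → 0;
4. lower 95% ROR bound in the main analysis > 10 → 1, else 0.

A report is confounder-free iff no drug from the psychotropic confounder
list (benzodiazepines/Z-drugs, antipsychotics, opioids, mood
stabilizers/antiepileptics) and no second antidepressant appears in *any*
role. The drug-level list is editable config; class membership is the
analysis-relevant part. A structural consequence worth knowing: when only
the main analysis can signal (criterion 3 = 0), the maximum total is 5 —
strong priority is unreachable, which is exactly the situation when neither
the positive-control nor the intraclass contrast is significant.

## Cohort analysis

`summarize_cohort` reports counts at report and patient level (patients
keyed by `patient_id` when present, else one report = one patient), medians
with quartiles for symptom duration (days), maternal treatment duration
(weeks) and daily dose (DDD multiples), and co-medication shares. Sex and
seriousness percentages use the all-patients denominator (the convention of
published case-series tables); known-value denominators are carried
alongside so either convention can be recomputed. Medians and group
comparisons silently skip missing values — missing data are excluded, never
imputed.

`compare_serious` contrasts serious vs non-serious cases (seriousness per
the regulatory definition: death, hospitalization, life threat, congenital
anomaly, permanent sequelae): two-sided Wilcoxon rank-sum
(`scipy.stats.mannwhitneyu`) for continuous variables, Fisher's exact test
with a Woolf odds-ratio CI (Haldane-corrected on zero cells) for binary
ones. "Non-parametric tests" admits several choices; these two are the
standard pairing for small, heavily unbalanced groups. Empty groups mark
the comparison not-computable rather than raising. The monotherapy variant
restricts to cases with exactly one antidepressant exposure and no
psychotropic co-medication.

## Symptom network

Nodes are symptom *categories* (a packaged, editable PT→category map), not
raw PTs. The subset is patient-level: monotherapy cases with ≥ 2 distinct
categories, merging multiple reports of one patient before filtering. Node
weight = patients with the category; edge weight = patients with both
endpoints; duplicate PTs within a category count once per patient. Exports:
GraphML, GEXF, edge-list CSV (node attribute `frequency`, edge attribute
`weight`). No layout, community detection or edge filtering — the graph
carries raw co-occurrence counts for external rendering.

## Synthetic data generator

The generator emulates a *deduplicated* spontaneous-report database at the
moment of extraction. Per report: one index drug drawn by configurable
report-share weights; the withdrawal-event probability is the odds
transform of the background odds times the drug's planted ROR, so the
case/non-case odds ratio is the estimand *by construction* and parameter
recovery is exact in expectation. Cases are neonates (age uniform 1–27
days) with a withdrawal term (5% via SMQ tag only) plus 1–4 co-reported
symptom PTs; non-cases draw unrelated PTs, with a configurable fraction of
neonates. Co-medications are sampled independently per class; duplicates
are exact clones appended with fresh ids.

Default conditions (all config): class-level planted RORs 10.55 / 4.68 /
5.90 (TCA / SSRI / other; bupropion at the null; methadone at 40 with a
0.2% report share), co-medication rates 30.1 / 23.2 / 13.5 / 11.9 / 9.5 %
(benzodiazepine / antipsychotic / opioid / second antidepressant / mood
stabilizer), 83.9% of cases serious, 36.7% of cases female, symptom-category
frequencies ordered respiratory > irritability/agitation > tremor > feeding
problems > seizures, 5% cloned duplicates, and field-level missingness
(dose 50%, treatment duration 55%, symptom duration 70%, sex 8%). The
background reporting rate of the withdrawal event is 0.01 and the default
database size 2·10⁵ reports — scaled-down database conditions chosen once
so that drug-level cells are large enough for interval estimation while a
full multi-seed simulation study remains a desktop computation; the tests
run the recovery study at this full size over 20 seeds.

Three generator details matter for interpretation:

- *Comparator contamination.* The main-scheme comparator includes
  positive-control reports ("all other drugs"). With methadone planted at
  ROR 40 and a 0.2% share, every main-scheme ROR is deflated by a factor
  ≈ 1.07 relative to its planted value. The truth table therefore reports
  both `planted_ror` (vs clean background) and `implied_ror` (vs the actual
  comparator frame); `recovery_config` (all drugs null except one) makes
  the two coincide and is the reference setup for coverage and recovery
  studies.
- *Collision resolution.* Duplicate detection uses an exact key (country,
  sex, age, drug-name multiset, PT multiset). The generator resolves
  accidental key collisions between independently drawn reports by
  appending an extra background reaction, so planted clones — and only
  they — are removed by deduplication, making pre/post-dedup counts exact.
- *Age completeness on cases.* Case reports always carry an age (the
  neonatal window is part of any realistic extraction query); age
  missingness applies to the configurable non-case missingness budget.
  Uniform age missingness on cases would silently reclassify them as
  non-cases and bias recovery.

What the generator does **not** emulate: reporting dynamics over time,
notoriety bias, country effects, drug–drug interaction effects on the
event, correlated co-medication patterns, probabilistic near-duplicates,
or free-text verbatims. Passing tests therefore demonstrate that the
*estimators and pipeline logic* are correct under known truth — not that
real spontaneous-report data meet the design's assumptions.

## Numerical and degenerate-input choices

- z₀.₉₇₅ is carried at full double precision (1.959963984540054).
- Empty table / empty arm: ROR undefined-with-reason; IC of an empty frame
  is reported as 0 with zero-width bounds (pure shrinkage, no information);
  empty network subset → empty graph; empty cohort → absent medians, never 0.
- Ties between exposed and comparator arm membership resolve to exposed;
  reports in neither arm are ignored for that table.
- Intraclass contrast for a single-member class raises (no comparator
  exists).
- Drug names are lowercased/trimmed and ATC codes uppercased at ingest;
  missing numerics are absent (`None`/NaN), never sentinels.
- Deduplication keeps the first occurrence and never edits survivors; it is
  idempotent by construction.

## Problem sizes in the shipped checks

The test suite runs the planted-recovery and null-coverage study at
2·10⁵ reports × 20 seeds, law-of-large-numbers calibration at 10⁵, the
type-I-error study of the serious/non-serious comparison over 2000 null
datasets of 150 vs 150, Monte-Carlo validation of the IC credibility bounds
with 10⁶ gamma draws per grid point, and network-vs-brute-force equality up
to 200 patients. The acceptance script pools the planted-drug 2×2 over
three replicate databases before estimating: a single replicate's log-scale
SE is ≈ 0.09, so pooling narrows a ±20% single-seed wobble to a stable
point estimate without touching the per-replicate distributional checks in
the tests.

## Known limitations

Disproportionality is not risk: no incidence, no causality, no
between-drug risk ranking beyond reporting patterns. The exact-match
deduplicator is conservative compared to probabilistic record linkage and
will miss near-duplicates in real data. The packaged term dictionary,
symptom-category map and confounder formulary are deliberately miniature;
production use requires licensed terminology and a curated formulary. The
serious vs non-serious comparison is typically underpowered when the
non-serious group is small, and its p-values carry no multiplicity
adjustment.
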