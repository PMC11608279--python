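# Methods

This note documents the models and procedures implemented in `hicost`,
the defaults chosen where the design was genuinely open, and what the
synthetic data can and cannot tell you about real claims.

## Cohort definition

A patient's annual total spending is the sum of `total_spend` over all of
their index-year encounters, outpatient and inpatient alike.  High-cost
patients are the top `fraction` (default 0.10) of patients by that total.
Selection takes **exactly `floor(fraction * N)`** patients after a stable
sort by (spending descending, patient_id ascending).  The tie-break is
arbitrary but fixed; it only matters when spending ties straddle the
cutoff, and it keeps every run reproducible.  Patients with no encounter
in the index year are not part of `N` — the population is *patients who
utilized services*, not the insured roll.

"Average LOS" is computed per patient as total inpatient days divided by
admissions (0 for patients without admissions), then averaged across
patients for tables.  The alternative — pooling all admissions — gives
more weight to frequent admitters; the per-patient version was chosen
because the cohort table describes patients, and the choice is isolated
in `summarize_patient_year`.

## Clustering variables

Each high-cost patient becomes a row of binary variables:

* **demographic** — one gender indicator plus one-hot age bins
  (0–14, 15–44, 45–64, 65+ by default, configurable).  Clustering inputs
  are binary throughout, so age must be binned; the bins follow the
  standard paediatric / working-age / older-adult / elderly split.
  Poverty status is *not* a clustering variable — economic status is used
  descriptively only.
* **ADRG** — one indicator per adjacent diagnosis-related group, set when
  any index-year encounter's principal diagnosis classifies into the
  group (longest-prefix match on dot-stripped ICD-10 codes).
* **comorbidity** — one indicator per chronic-condition category, with a
  lookback over the full claims window (default 2017–2019): a chronic
  diagnosis seen only in an earlier year still sets its flag.
* **department** — hospitalized in that department in the index year.

Low-variance columns are removed before clustering: ADRG columns with
prevalence < 1% and comorbidity columns with prevalence < 0.1% (strict
inequalities, measured on the high-cost cohort before deduplication).
Demographic and department columns are never dropped.  Duplicate rows
(identical on every variable) are collapsed; the representative map and
per-row multiplicities allow cluster labels to be propagated back to all
patients and cluster sizes to be measured in patients rather than unique
rows.

## Dimension reduction and clustering

Columns are standardized (centered, unit variance) before PCA so that
high-prevalence binaries do not dominate the leading eigenvectors.  PCA
keeps the smallest number of components whose cumulative explained
variance reaches the target (default 80%).  The component scores are
embedded in 2-D with Barnes–Hut t-SNE (perplexity 30, theta 0.5, 1000
iterations, PCA initialization, explicit seed).  These t-SNE defaults are
the library's own choices — the procedure this package follows specifies
the algorithm but not its parameter values — and all are exposed in
config.

OPTICS with xi cluster extraction runs on the 2-D embedding over a grid
(min_samples ∈ {10, 20, 40, 80} × xi ∈ {0.01, 0.02, 0.05}).  Solutions
are *compliant* when they yield at least 5 clusters, each holding at
least 1% of the high-cost patients (shares measured after expanding
deduplicated rows).  Among compliant solutions the one with the largest
clustered (non-noise) patient share wins; ties go to fewer clusters.
This selection rule is again the package's own: it prefers solutions that
leave the least of the cohort unexplained while respecting the
operational constraints.  When no grid point is compliant the failure is
structured, listing the nearest misses.

Comparators: Ward-linkage agglomerative clustering and PAM k-medoids
(seeded build + swap-by-alternation, implemented here) over a k range,
with the same constraint flags.  Solution quality is scored by one-vs-
rest ridge classifiers predicting each cluster (≥ 10 members) from the
filtered clinical variables under 5-fold stratified cross-validation,
reported as mean ± SD of per-cluster AUCs.  Arbitrary labels score ≈ 0.5;
clinically coherent clusters score near 1.

## Profiling and subgroups

A cluster's profile is the ratio of its mean to the clustering
population's mean for every variable.  The population is the full
deduplicated sample expanded to patients, noise included, so the
size-weighted cluster means (noise as its own bucket) reconstruct the
population mean exactly — a conservation identity the tests verify.
Variables with zero population mean get flagged undefined ratios, never a
silent 0.  The top 3–5 finite ratios per cluster (ties broken by cluster
mean, then name) are its distinguishing factors, tagged with their source
category.  Merging clusters into clinically named subgroups is a pure
relabeling driven by an external CSV map; the package validates totality
over non-noise clusters and conserves label counts but encodes no
clinical judgment of its own.

## Preventable inpatient cost

An admission is potentially preventable when its principal diagnosis
falls in the ambulatory-care-sensitive code list (longest-prefix match);
outpatient encounters are never flagged.  No age restrictions and no
complication/comorbidity exclusions are applied by default — an
exclusion-list hook exists but ships empty, matching analyses that have
only the principal diagnosis to work with.  A patient's PIC is the summed
`total_spend` of their flagged admissions, so ΣPIC over patients equals
the total spending of flagged admissions exactly, and per patient
PIC ≤ inpatient spend ≤ total spend always.  All storage is in CNY; USD
conversion (CNY 6.90 per US$ 1.00, configurable) happens only in
reports, and report percentages are rounded half-up at presentation.

## Synthetic data: what it emulates

The generator produces, from one integer seed, a three-year claims
window whose index year drives the analysis:

* **Spending tail** — a lognormal patient-severity multiplier
  (sigma 0.85, calibrated once by simulation so the top decile holds
  ~74% of annual spending) combined with negative-binomial admission
  counts (claims are overdispersed; the LOS SD exceeding its mean in real
  cohort tables motivates the lognormal stay lengths, truncated to
  [1, 365] days).
* **Costs** — admission spending = department base cost × (0.5 + 0.08 ×
  LOS) × lognormal noise × patient severity; outpatient visits are cheap
  (~80 CNY base), so inpatient care dominates high-cost spending as in
  real claims.  Out-of-pocket share per encounter is uniform on
  [0.25, 0.55].
* **Planted subgroups** — each `LatentGroupSpec` fixes a population
  share, a weighted ICD-10 diagnosis pool, chronic-condition and
  department profiles, admission and LOS distributions, a demographic
  range, and a PPH rate.  Members' admission counts and costs push them
  into the top decile.  The default ten groups mirror the clinical mix of
  a rural high-cost population (chronic disease, surgery-needing
  non-trauma disease, female disease, cancer, eye disease, respiratory
  infection, fracture, liver disease, mental disease, renal failure);
  `recovery_benchmark_groups()` provides six well-separated,
  demographically coherent groups with pairwise-disjoint pools for
  recovery benchmarking.
* **Chronic persistence** — chronic conditions are assigned per patient
  and surface as outpatient visits in the lookback years, so the
  comorbidity lookback has something to find.
* **PPH ground truth** — `plant_pph_admissions` resamples each group's
  admission diagnoses so the fraction carrying an ambulatory-care-
  sensitive code matches its `pph_fraction` in expectation; it rejects
  configurations whose pools cannot supply the required side.
* **Ground-truth isolation** — latent group labels live in a separate
  sidecar table so the pipeline cannot consume them as features.

What it does **not** emulate: prices changing over time, reimbursement
policy rules, within- vs outside-county cost mechanisms (outside-county
is an independent Bernoulli per admission), procedure codes, and real
code lists — the packaged ADRG / chronic / PPH maps are structurally
equivalent stand-ins, replaceable via config.  Passing tests on this data
therefore demonstrate that the *pipeline machinery* is correct and that
recoverable structure is recovered; they do not validate clinical
taxonomies derived from any particular real population.

## Evaluation scales and seeds

End-to-end recovery is benchmarked on populations of 20 000 patients
(top decile 2 000; ~1 200 unique rows after dedup), three seeded
replicates, requiring adjusted Rand index ≥ 0.8 against the sidecar.
The ARI is computed over patients belonging to planted groups and
assigned to a cluster: the unstructured background has no ground-truth
partition, so including it would penalize a clustering for refusing to
lump miscellaneous patients into one class (density-based methods
rightly leave many of them as noise).  Decile arithmetic is exercised at
the full scale of 321 082 patients, where generation plus selection takes
well under a minute.  Every randomized stage takes an explicit seed, and
the pipeline derives all stage seeds from one master seed.

## Known limitations

* OPTICS xi extraction can split one planted group across adjacent
  clusters or absorb part of the diffuse background into a cluster;
  the constraint-based selection mitigates but does not eliminate this.
  Real analyses add an expert merge step for exactly this reason.
* t-SNE coordinates (and hence the clustering) are reproducible only for
  a fixed seed and library version; the manifest records both.
* The PQI-style flagger uses the principal diagnosis only; analyses with
  procedure data should populate the exclusion hook.
* `cohort_table` reports unweighted means; no survey weights or risk
  adjustment are implemented.
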