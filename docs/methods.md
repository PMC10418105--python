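# Methods

This note documents the models, defaults and design choices behind
`leakforensics`, and what the synthetic experiments do and do not show.

## 1. Sequence model and provenance

Genomes are i.i.d. base strings with a specified GC fraction (default host
0.41, microbes 0.50). Every genome carries a segment track tiling its
sequence with `(start, end, source_id, source_label)` records; a
contaminated draft is built by **appending** a contiguous host substring
(uniform random start) to a microbial genome while leaving its claimed
taxonomy untouched. Appending rather than inserting keeps provenance
bookkeeping trivial, and position is irrelevant to exact k-mer
classification.

Reads are single-end, fixed-length (default 150 bp), drawn uniformly over
non-wrapping placements, with i.i.d. substitution errors only (default
0.1%); indels are omitted because they could only dilute exact k-mer hits,
not create false ones. A read's hidden `true_source` is resolved from the
segment covering its *start* position; reads spanning a segment junction
are counted toward their start segment (a per-read ambiguity of at most
one read length, negligible at the simulated scales and irrelevant to any
reported statistic's direction).

Random genome pairs of these sizes share essentially no 31-mers (expected
collisions ≈ L₁·L₂/4³¹ < 10⁻⁵ for megabase genomes), so any cross-genome
hit in the simulations traces to the deliberately copied contig.

## 2. Classifier

Exact canonical 31-mer LCA classification. Canonical form = lexicographic
minimum of a window and its reverse complement; windows with non-ACGT
characters are skipped; k is configurable (odd, 11–31) with default 31,
the match length of the classifier family being modeled. The database maps
each canonical k-mer to the LCA of all genomes containing it, computed on
a fixed-depth taxonomy (root / domain / genus / genome) built from the
genome labels themselves.

Read assignment collects hit counts per taxon, scores each root-to-leaf
path by the sum of hits on its nodes, and returns the leaf of the maximal
path; ties resolve to the LCA of the tied leaves (so a read whose hits all
sit at the root is "assigned" to the root, contributing to no genus).
Genus-level aggregation counts reads assigned at or below genus rank.

The host is modeled as a taxon under its own domain, so a k-mer shared by
the host genome and a contaminated draft has LCA = root. This is exactly
the mechanism by which adding the host genome to the database removes
false genus assignments. A two-pass alignment filter against the host
reference is abstracted as an optional pre-filter dropping reads whose
fraction of host-matching k-mers is ≥ 0.5; the claims under study concern
database composition, not aligner behavior, so no aligner is reimplemented.

Unique-k-mer (coverage-style) counting is not implemented; all counts are
read counts.

## 3. Count matrices and normalization

Simulated raw matrices have common features drawn negative-binomial with
variance μ + φμ² (default φ = 0.5, μ = 50, identical across classes — no
true class signal), rare features nonzero in exactly a chosen number of
samples, and identically-zero features. Library size is the row sum plus a
host-read allowance (default 10⁶), mimicking tissue sequencing where the
host dominates.

`voom_logcpm` computes `log2((c+0.5)/(N+1)·10⁶)` and records which
features were all-zero in the raw counts; precision weights and the
mean–variance trend of the full voom machinery are omitted because the
leakage phenomena live in the values, not the weights.

`supervised_normalize` fits each feature by OLS (numpy least squares) on
an intercept, reference-level one-hot biological covariate, and
reference-level one-hot adjustment covariate, then subtracts the fitted
adjustment component only. Consequences of that convention: a constant
adjustment covariate makes the transform the identity, and data of the
form (class means + batch offsets with reference batch at zero) are
recovered exactly in the noiseless case. A rank-deficient design raises an
error naming the collinear columns.

Two **explicitly labeled misuse modes** generate the class-tagging
artifact. The published forensic evidence identifies the artifact (per-class
constant or near-constant normalized values on raw-zero features) without
pinning down the precise code-path mistake that produced it, so this
package ships two plausible generators rather than claiming either is the
true one:

* `class_offsets` — every raw-all-zero feature is overwritten with its
  fitted class mean plus a per-(class, feature) offset ~ N(0, `offset_sd`)
  and optional within-class noise ~ N(0, `noise_sd`, default 0). With the
  default noise of zero each class receives exactly one distinct value —
  the duplicate-value fingerprint.
* `libsize_coupling` — raw-all-zero features are recomputed as the
  zero-count log-CPM value under class-dependent library sizes (log-normal
  across classes, σ = 0.5), so the pseudo-count anchor alone separates
  classes.

## 4. Forensic statistics

* **Inflation report:** for entries where the suspect matrix A ≥ T
  (T ∈ {10, 100}), count entries with A ≥ 10·B against re-analysis B (B = 0
  counts as ≥ 10×, the ratio being infinite), and — at the lowest T —
  entries with B ≥ 1 and 0.5·B ≤ A ≤ 1.5·B ("within 50%", defined relative
  to B; the ≥ T universe is used for both columns). Fractions are exact
  rationals; rounding is display-only.
* **Duplicate-value clusters:** values equal after rounding to 9
  significant digits (the precision at which published normalized values
  are printed) form clusters; singletons are dropped; sorted by size.
* **Threshold rules:** `threshold_rule_eval` computes the confusion matrix
  of "positive when value ⟨ge|gt|le|lt⟩ t" with exact fractional
  sensitivity/specificity/error rate. `best_threshold_rule` scans
  midpoints of sorted unique values in both orientations (positive-if-high
  `ge`, positive-if-low `le`; comparisons on integer balanced-accuracy
  numerators so ties are exact, broken toward the smallest threshold then
  `ge`). Including the `le` orientation is required for the guarantee
  that the optimum is ≥ 0.5 and for tags that mark a class with *low*
  values.
* **Discordance scan:** a feature is flagged when its raw column is
  all-zero (or nonzero in < 1% of samples) yet its best one-vs-rest rule
  exceeds balanced accuracy 0.75. No multiple-testing correction is
  applied: these are diagnostics meant to be inspected, not hypothesis
  tests.

## 5. Case-study fixtures

Three fixtures rebuild published normalized-value pathologies from their
printed summary statistics (tag values, cluster sizes, group counts); the
surrounding unprinted values are drawn from seeded uniform ranges chosen
only to respect the stated orderings.

The tagged-virus fixture (17,625 samples, 79 positives) is constructed so
that the inclusive rule at the printed tag value yields exactly the
printed accuracy: 71 positives at the tag, 8 positives below it, 69
negatives at or above it — sensitivity 71/79 (90%) and 77/17,625 (0.4%)
total errors. The source description of the value geometry is internally
inconsistent with its own error count (77 "other" samples at-or-below the
tag plus 8 missed positives would give 85 errors); the fixture preserves
the printed rule statistics, which are the quantities every downstream
check consumes, at the cost of mirroring which side of the threshold the
bulk of negatives sits on.

The duplicated-tag fixture (906 samples, all raw zero) pins the 70
normal-tissue samples to low values with identical-value clusters of sizes
38/18/5 at the three printed 9-digit values, the remaining 9 normals to
distinct low values, and all 693 tumor plus 143 blood samples to higher
values. The tumor-vs-normal fixture (51 + 41 samples, seven raw counts of
one) gives tumors an almost disjoint higher value range.

## 6. Leakage pipeline

`extract_empty_submatrix` keeps genera nonzero in fewer than 50 samples
(the prevalence filter) and then drops samples with any nonzero retained
entry, yielding an identically-zero matrix; `populate_from_normalized`
fills it by (sample, genus) key, dropping and counting features absent
from the normalized data; the evaluation restricts to primary-tumor
samples.

One-vs-all evaluation uses gradient-boosted shallow trees — 150
estimators, depth 3, learning rate 0.1 (xgboost, histogram method, single
thread, seeded, hence bit-reproducible) — with stratified 10-fold CV
(folds reduced and logged for classes smaller than the fold count).
Out-of-fold probabilities give sensitivity, specificity, PPV and NPV at
threshold 0.5 and trapezoidal ROC AUC; undefined ratios (0/0) are NaN and
excluded from the cross-class medians. Hard-call metrics and AUC are both
reported because published accuracy tables list them side by side without
stating an operating point.

## 7. Study conditions and problem sizes

The two headline simulations run at fixed, seeded conditions:

* **Contamination:** 1 Mb host, ten 200 kb microbes in distinct genera,
  one microbe augmented with a 100 kb host contig; 100,000 error-free
  150 bp host reads plus 50 reads from the clean portion of the
  contaminated microbe; k = 31. Expected outcome: ≈ 10⁴ host reads fall in
  the copied region and are assigned to the contaminated genus when the
  host genome is absent, collapsing to ≈ 50 genuine reads when it is
  present (fold decline ≈ 200, host-origin fraction ≈ 99.5%).
* **Leakage:** 32 classes × 100 samples, 66 identically-zero features,
  class-independent log-normal library sizes, log-CPM +
  `class_offsets` normalization (offset SD 1.0, within-class noise SD
  0.05), default classifier config. Expected outcome: median sensitivity
  and specificity near 1.0; with `leak_mode="none"` the same pipeline sits
  at median AUC ≈ 0.5.

Examples, the CLI demo and several tests run smaller versions of the same
scenarios (e.g. 200 kb host / 20,050 reads; 8 classes × 25–40 samples with
50–60 trees and 5 folds), chosen so the full test suite completes in a few
minutes while exercising identical code paths; the mechanisms are
scale-free apart from sampling noise, and the full-scale conditions above
are what the acceptance script and acceptance tests execute.

## 8. What the synthetic data does and does not show

The generators reproduce the *structural* features that drive both
artifacts — host-dominated read sets, a mislabeled contig, class
structure, rare and all-zero features, value tags — with exact provenance,
which real data never offers. They do not attempt realistic sequence
composition (repeats, homopolymers, true human/bacterial k-mer sharing),
paired ends, quality scores, indels, real taxonomies, or the empirical
mean–variance structure of real microbiome counts. Passing tests therefore
demonstrate that the *mechanisms* behave as described and that the
diagnostics detect them; they do not quantify how much contamination or
leakage any particular real dataset contains. The read length (150 bp) and
error rate (0.1%) defaults are unremarkable short-read values, not
calibrated to any specific instrument.

## 9. Numerical conventions

All randomness flows from one integer master seed through SHA-256-derived
per-stage child seeds (< 2³¹); no global RNG state is used or mutated.
K-mers are 2-bit packed into uint64 and looked up by binary search in a
sorted array. Rule metrics and report fractions are exact `Fraction`s
until display. JSON reports are serialized with sorted keys so identical
seeds give byte-identical files. Degenerate inputs are defined rather than
special-cased where a definition exists (empty read set → zero counts;
constant-value column → balanced accuracy 0.5 at that value; empty
extraction result → warning, not error).
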