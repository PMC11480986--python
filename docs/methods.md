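# Methods

This note documents the models and procedures implemented in
`fragqsar`, the defaults and why they were chosen, what the synthetic
benchmark does and does not emulate, and the numerical conventions that
make runs reproducible.

## Data model and curation

An activity record is a molecule plus an IC50 in mol/L and a censoring
qualifier. `exact` records carry a measured value; `less_than` /
`greater_than` records carry only an entry bound, the way large
collections record compounds entered as "active" (IC50 < 0.1 μM, or
< 0.001 μM for the strongest) or "inactive" (IC50 > 10 μM). pIC50 =
−log₁₀(IC50) is derived on ingestion, along with a binary label
(active ⇔ pIC50 ≥ 7) and a 3-category label (breakpoints at 7 and 8).

Conventions worth stating explicitly:

* **Boundary**: pIC50 = 7.0 exactly counts as active. The "active"
  entry criterion IC50 < 0.1 μM technically excludes equality, but
  equality is measure-zero in real data and a fixed convention keeps
  labels deterministic.
* **Censored labels** are assigned only when the whole feasible
  interval of the true pIC50 falls inside one class. "< 0.1 μM" (true
  pIC50 > 7) is binary-active but its 3-category label stays unset —
  it could be category 2 or 3. Consequently the 3-category task trains
  on fewer records than the binary one.
* **Curation** rejects structureless rows, multi-component entries
  (salts/mixtures are *removed*, not desalted), structures without
  carbon, and duplicates by canonical structure key (canonical SMILES,
  aromatic form, stereochemistry and isotopes ignored — no stereo
  policy is defensible when sources rarely report it consistently).
  Duplicates with several exact values collapse to the median pIC50;
  all-censored duplicate groups keep the tightest bound. Median over
  mean: robust to the order-of-magnitude discrepancies typical of
  cross-study duplicates.
* Censored records are excluded from regression (their "values" are
  entry bounds, not measurements) but participate in classification.

## Fragment descriptors

The descriptor of molecule *i* is the indicator vector of all its
connected edge-induced subgraphs ("subfragments") with 1–7 bonds.
Fragment identity is the canonical SMILES of the subgraph written with
the parent's perceived aromaticity: element, charge, aromatic flags and
bond orders are kept; hydrogens stay implicit; stereo and isotopes are
dropped; no attachment points are marked. Enumeration uses RDKit's
connected-subgraph walk and collapses duplicates by key; an independent
brute-force enumerator over all connected edge subsets (union-find
connectivity) serves as the oracle in the tests.

The 1–7 bond window bounds the combinatorics (a 30-bond drug-like
molecule yields a few hundred distinct keys, milliseconds per molecule)
while still covering rings up to 7 bonds and all common substituents;
it is configurable. The vocabulary is built from **building-set
molecules only** and support filtering (default: a fragment must occur
in ≥ 2 distinct molecules — singletons cannot generalize) is a pipeline
step *fitted inside each cross-validation fold*, so neither the column
space nor the support threshold ever sees validation or holdout rows.
Matrices are stored sparse (CSR; Matrix Market + vocabulary TSV on
disk).

## Modeling protocol

One stratified 80/20 split (classification: by class label; regression:
by pIC50 quartile, degrading to coarser bins when a quartile has fewer
members than folds) separates a holdout set that no training-time
computation may touch — `evaluate_holdout` enforces id-disjointness and
raises on overlap. The building set gets a stratified 5-fold partition;
grid search scores each hyperparameter point by mean fold performance
(R² / ROC AUC / −log loss for the regression / binary / 3-category
task), ties break toward the earlier grid point, and the winner is
refit on the full building set. Three estimator families sit behind one
interface: ridge / logistic regression (with optional top-*m*
univariate selection inside the pipeline), random forests, and LightGBM
gradient boosting. Which family is best is dataset-dependent
configuration, not a scientific claim of this package.

Defaults: the regression task uses ridge on the top-64 fragments by
univariate F — the synthetic activity model is additive in fragment
indicators, exhaustive fingerprints are massively collinear, and a
reduced linear model both predicts well and keeps the leverage-based
domain analysis in a sensibly sized subspace. The binary task defaults
to gradient boosting (it must capture threshold structure at pIC50 = 7
from additive effects). The 3-category task defaults to multinomial
logistic regression. Binary decisions threshold the active probability
at 0.5; 3-category labels take the argmax with ties resolved toward the
lower category.

## Validation suite

Binary metrics are computed from confusion counts; ratios with a zero
denominator return 0 with a `degenerate` flag rather than raising, so
batch evaluation never aborts. AUC is the Mann–Whitney probability with
midrank tie handling. Multiclass log loss is multinomial cross-entropy
with probabilities clipped to [1e−15, 1−1e−15] (finite loss; standard
practice); balanced accuracy is the mean of per-class sensitivities.

The external-acceptance test computes the through-origin slopes
k = Σyᵢŷᵢ/Σŷᵢ² and k′ = Σyᵢŷᵢ/Σyᵢ², and the through-origin
determination coefficients R₀² = 1 − Σ(yᵢ−kŷᵢ)²/Σ(yᵢ−ȳ)² and
R₀′² = 1 − Σ(ŷᵢ−k′yᵢ)²/Σ(ŷᵢ−ŷ̄)². Several variants of these statistics
circulate in the QSAR literature; the formulas implemented are exactly
the above, and the suite cross-checks them against the worked
criterion-3 value (0.08) reproducible from published summary
statistics. A model passes when R²_cv > 0.5, R²_test > 0.6, criterion 3
(< 0.1 closeness, either orientation) and criterion 4 (either slope in
[0.85, 1.15]) all hold.

Y-scrambling permutes the activity vector (seeded, never the identity
permutation), reruns the *entire* grid search, and records
cross-validated and holdout R² per run (default 10 runs). Rerunning
the grid search, rather than refitting the originally selected
hyperparameters, is the stricter test — the scrambled model gets every
chance to overfit; refit-only mode is available as an option.

## Applicability domain

Leverage h = xᵀ(XᵀX)⁻¹x is computed in the trained model's
selected-feature subspace — over the full ~10⁴-column fragment space
XᵀX is hopelessly rank-deficient and every query would be "novel".
XᵀX is inverted by pseudo-inverse with relative cutoff 1e−10, so
residual collinearity inside the subspace is handled; the hat-matrix
trace equals rank(X) to 1e−6 by construction (tested against dense
pseudo-inverse computation). The warning threshold is the standard
h* = 3(p+1)/n (overridable in config), the residual band is ±3
standardized residuals with σ = training RMSE, and a point is
in-domain iff both tests pass. At prediction time only the leverage
test is available; a query whose descriptor row is all zeros (no known
fragment) is defined out-of-domain outright — the model has literally
no information about it. Williams plots (leverage vs standardized
residual, h* and ±3σ reference lines) render to PNG with a TSV of the
underlying points.

## Structural alerts

Alerts are ranked by permutation importance of descriptor columns,
measured on rows disjoint from the final model's training set (the
holdout set by default) with a seeded generator, as the mean drop in
the task metric over repeats. Two properties of exhaustive fragment
fingerprints required design decisions a generic importance routine
does not face:

1. **Bit-identical columns.** Nested fragments of the same substituent
   (e.g. `CF`, `FCF`, `FC(F)F` for a trifluoromethyl group) have
   identical presence patterns; no data can distribute credit among
   them. Identical-pattern classes are permuted jointly (one shared row
   permutation, preserving within-group structure) and reported as one
   alert whose representative is the most specific member (most bonds,
   then lexicographic) with the rest listed as `equivalent_keys`.
2. **Context specializations.** The model may split on a fragment that
   is a substituent *in a particular ring context*; its pattern is a
   row-subset of the substituent's. Ranking uses **total importance**:
   a class is permuted together with every class whose pattern
   specializes it, so a substituent-level alert accumulates the credit
   the model assigned to its refinements and outranks each individual
   refinement.

A chi-squared univariate screen (building-set rows only, default top
500 columns) keeps the computation linear in practice; screened-out
columns report importance 0, as do constant columns (permuting them
can change nothing). Class-enrichment odds ratios (Haldane–Anscombe
+0.5 correction when any 2×2 cell is zero) and example molecule ids
accompany each alert as context; they do not affect the ranking.

## Synthetic benchmark

The generator emulates the statistical structure of a proprietary
kinase-inhibitor collection, not its chemistry. Molecules come from a
grammar of 9 heteroaromatic scaffolds (pyrimidine, quinazoline,
benzimidazole, pyridine, pyrazole, thiazole, pyrrolopyridine, purine,
indole) × 16 substituents on up to two attachment sites (~2,300
distinct products; sampling is uniform without replacement). Activity
is additive: pIC50 = 5.5 + Σ β_f·1[f ⊆ molecule] + N(0, 0.3²), clipped
to the assay window [3, 10]. The five default planted effects (+1.5
each) are the characteristic subgraphs of five substituents —
trifluoromethyl, methylsulfonyl, morpholine, isopropoxy, primary
amide — chosen so each is producible by the grammar and arises from no
other grammar element; their keys are derived through the same
fragment-keying routine the descriptors use, so ground truth and
feature space agree exactly (with σ = 0, a linear fit on the full
matrix is perfect — tested). Censoring then mimics database entry:
35% of records become "< 0.1 μM" entries (drawn from molecules whose
noiseless pIC50 ≥ 7; "< 0.001 μM" when the recorded value ≥ 9) and 25%
become "> 10 μM" entries (from those below 7), leaving ~40% exact —
the proportions and bounds of the study design this package follows.
The default n = 600 keeps every recovery experiment minutes-scale on
one CPU; (config, seed) determine the dataset bit-for-bit, recorded as
a SHA-256 hash in the manifest.

What passing tests on this benchmark show: the pipeline recovers
additive fragment-driven signal through censoring and class imbalance,
its validation machinery is numerically correct, scrambling removes
exactly the planted signal, and alert extraction points back at the
causal substructures. What they do not show: performance under
activity cliffs, non-additive SAR, scaffold-hopping chemistry,
assay heterogeneity, or realistic property distributions — real
collections are harder in all of these ways.

## Orchestration and reproducibility

`run_pipeline` executes curate → featurize → train (per task) →
validate → scramble → domain → alerts from a schema-validated config
(YAML). Every stage writes its artifacts plus a manifest keyed by a
hash of the stage's inputs; re-running an unchanged stage is a no-op
and interrupted runs resume. All randomness derives from the single
top-level seed through a per-stage SHA-256 offset (`stage_seed`), so a
report is reproducible from its config echo alone. Wall-clock noted in
reports is informational; every number in a report is recomputable
from the persisted artifacts.

## Known limitations

* The fragment window (1–7 bonds) cannot represent alerts larger than
  7 bonds; fused-ring pharmacophores are covered only by their ≤7-bond
  pieces.
* Leverage is meaningful only in the selected-feature subspace; with
  feature selection disabled, p may exceed n and h* = 3(p+1)/n loses
  its discriminating power (everything, or nothing, is flagged).
* The 3-category task inherits a structurally small top class from the
  censoring rules; its per-class accuracy on category 3 is poor at
  benchmark scale and configs on small datasets should train the
  binary/regression tasks only.
* Total-importance alert ranking promotes general patterns; a very
  generic skeleton fragment (e.g. `CC`) that is a superset of several
  causal patterns can legitimately out-rank each individual one.
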