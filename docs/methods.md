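# Methods

## Scope and data model

The package analyzes threshold-cycle (Ct) matrices from multiplexed
qPCR miRNA panels profiled on FFPE lymph-node tissue, with three
diagnostic classes: reactive lymph node (RLN), nodal
T-follicular-helper-cell lymphoma (nTFHL) and peripheral T-cell
lymphoma NOS (nPTCL).  A Ct value is the PCR cycle at which
fluorescence crosses threshold; lower Ct means higher abundance, and
one cycle corresponds to one log2 unit.  A well is *detected* iff it
has a numeric Ct at or below `max_ct` (default 35 cycles, the
conventional qPCR quantification limit; panel vendors rarely publish
an amplification-call rule, so the Ct cutoff is the declared
convention here).

Matrices are oriented miRNAs × samples.  Spike-in control rows are
identified by a configurable id prefix (default `SPIKE_`).

## Normalization chain

Order: spike-in normalization → low-detection filter → global-mean
normalization.  This follows the narrative order of standard qPCR
workflows (technical correction first, then feature QC, then
biological normalization).

**Spike-in normalization.**  The offset of sample *j* is the mean
spike-in Ct of that sample minus the cohort *median* of those means;
the offset is subtracted from every detected Ct of the sample.  The
median reference makes one aberrant sample unable to move the cohort
anchor.  The operation is idempotent and requires spike-ins detected
in every sample (failing loudly otherwise).

**Low-detection filter.**  A miRNA is removed iff its detected
fraction is strictly below `min_fraction` (default 0.10): a miRNA
detected in exactly 10% of samples is retained.  Spike-in rows are
always dropped at this step, having served their purpose.

**Global-mean normalization.**  Undetected wells that survive the
filter are imputed at the detection limit (35), a conservative choice
that biases weak signals toward "no change" rather than inventing
expression.  Then ΔCt(i,j) = Ct(i,j) − mean_i Ct(i,j) and the reported
value is −ΔCt, so that positive differences mean upregulation.  Every
sample's values average to zero by construction, which also makes the
output exactly invariant to any per-sample additive Ct offset (a
second, algebraic guarantee of technical-offset removal).

**QC summaries.**  Hierarchical clustering uses Euclidean distance
with complete linkage (merge heights are then non-decreasing); tie
ordering follows scipy's deterministic merge order.  PCA treats
samples as observations and centers but does not scale variables,
since all variables already share the Ct scale.  Note that per-sample
zero-mean data lives on a zero-sum hyperplane, so one PCA dimension is
always empty; tests account for this.

## Differential expression

log2FC is the difference of group means on the −ΔCt scale (group minus
RLN reference).  Significance uses the classic equal-variance
two-sample Student's *t* (df = n₁+n₂−2); Welch's variant is available
behind a flag but is not the default because the reference procedure
is the textbook Student test.  Zero pooled variance is resolved by
convention: equal means → p = 1; unequal means → the p = 0 limit.
Benjamini–Hochberg adjustment is applied per comparison (one FDR
family per contrast), and "differentially expressed" means q < 0.05
with no fold-change floor.  The unique/shared partition across
comparisons is plain set algebra on the significant sets.

## Nested cross-validation

Both learners follow the same discipline: anything fitted — feature
ranking, standardization statistics, hyperparameters — is fitted on
training folds only.

*Elastic-net logistic regression* (binary): outer 5-fold / inner
10-fold stratified CV.  Inside every inner training split, miRNAs are
ranked by ascending two-sample *t*-test p-value (the simplest filter
consistent with the DE stage; the selection statistic is otherwise a
free design choice) and the top percentage is kept
(round(pct/100 × p), minimum 1; on the 246-miRNA panel 20% → 49,
10% → 25, 5% → 12).  Features are standardized with training
statistics, then an elastic-net logistic model is fitted (saga solver,
objective = cross-entropy + (1/C)·[α·L1 + (1−α)/2·L2], tolerance 1e-6,
iteration cap with the best iterate returned and flagged on
non-convergence).  The grid combination with the highest mean inner
AUC wins; ties break toward the smaller feature percentage, then
smaller C, then larger L1 ratio — i.e. toward sparser, more
reproducible models.  The winner is refitted on the full outer
training split and scored on the held-out fold.  Reported: per-fold
AUCs, their mean, a 95% CI half-width (t₀.₉₇₅,df=4·SD/√5 — the
interval definition is the package's choice), the best fold AUC, the
per-fold winning parameters and selected features, and the pooled
out-of-fold scores (every sample scored exactly once).

*Random forest* (3-class): outer 5-fold / inner 3-fold; inner
selection by mean one-vs-rest macro AUC; `auto` max-features maps to
`sqrt` (its conventional classification meaning) and the forest size
is fixed at 500 trees by default (a standard stable choice; the grid
axes are depth, bootstrap, max-features and split criterion).  The
confusion matrix pools the single out-of-fold prediction of every
sample over the 5 outer folds — the only reading of "averaged over the
validation rounds" that yields integer counts summing to the cohort
size.  Class imbalance (19 vs 49 vs 20) is handled by stratification
only; no class weighting.

*AUC* is computed rank-based (Mann–Whitney with midrank tie
correction).  *Permutation importance* of feature f is the baseline
held-out metric minus the mean metric after shuffling column f
(independent shuffles per repeat; AUC for binary models, accuracy for
multi-class); per-fold tables are pooled across outer folds.  The
*common panel* is the intersection, across comparisons, of features
selected in ≥80% of a run's outer folds.

If an outer training split has a class rarer than the requested inner
fold count, the inner fold count is capped at that class size (with a
warning) so stratification always places both classes in every fold.

## Enrichment with a miRNA-permutation null

A DE miRNA set maps to the union of its target genes (strong-evidence
interactions only, by default `Functional MTI`).  The default gene
universe is all genes in the target map — a competitive null over
measurable targets; a GMT-defined universe is available by
configuration.  Three statistics per gene set:

* overlap count k with an upper-tail inclusive hypergeometric p
  (diagnostic output);
* a two-sample KS statistic D comparing per-gene targeting scores
  (number of DE miRNAs hitting the gene) between set members and
  non-members — the construction of the KS ranking is a documented
  package choice;
* the primary permutation p: B draws (default 1000) of same-size miRNA
  sets uniformly without replacement from the measured panel, each
  mapped to targets and scored; p = (1 + #{perm ≥ obs})/(B + 1).

The permutation draws are shared across gene sets within one call
(statistically equivalent, and it turns the null into two matrix
products over a miRNA × gene incidence matrix).  BH adjustment runs
over the permutation p-values within the collection.

Because the statistic is discrete, the (1+…)/(B+1) convention is
conservatively biased in the presence of ties; the overlap count k has
few achievable values, while the KS-D statistic's support is much
richer.  Uniformity calibration of the permutation p therefore uses
the KS-D statistic; `hypergeom-k` remains the default for enrichment
runs, where the bias is conservative (never anti-conservative).

Transcription-factor target collections run through exactly the same
machinery; no special-case code.

## Synthetic cohorts

The generator's defaults are the emulated study conditions: 19 + 49 +
20 samples, 376 panel miRNAs plus 3 spike-ins, 130 low-detection
miRNAs, baselines uniform in [22, 32] Ct, within-class SD 1.0 Ct,
technical offset SD 0.5 Ct.  The model is additive Gaussian on the Ct
scale:

    Ct(i,j) = baseline_i + class_shift(i, class_j) + offset_j + noise

Planted effects are (row, target class, Ct shift) triples where the
target may be a single class or "both-lymphomas"; the implied log2FC
is the negated shift, and subtype-specific effects appear diluted in
the pooled-lymphoma truth by the subtype's share of the pooled group.
Spike-in rows carry the offset with no biological noise, so the
offsets are exactly recoverable in the noise-free limit.  Rows with an
upward (toward the detection limit) planted shift get their baseline
redrawn so baseline + shift + 3·SD stays below `max_ct`; otherwise
censoring at the detection limit would make the realized group
difference smaller than the planted shift, breaking the ground-truth
contract.  Low-detection rows receive per-well dropout (probability
0.95) with rejection resampling so that every realization is strictly
below the 10% detection threshold; effect rows are never selected as
low-detection.

What the generator does *not* emulate: pre-amplification chemistry,
primer-efficiency differences, batch structure beyond one additive
per-sample offset, correlated miRNA co-regulation, or heavy-tailed
noise.  Passing tests therefore demonstrate the pipeline's correctness
and calibration under an idealized additive-Gaussian regime, not
performance on real FFPE data.

Default planted effect sizes: recovery-style runs use Ct shifts with
magnitudes uniform in [1.5, 2.0] and random sign.  At these shifts the
per-effect detection power at q < 0.05 is essentially 1, so a missed
effect signals an implementation defect rather than sampling noise —
the property a recovery oracle should have.  (At shifts near 1.0 Ct
with SD 1.0 and n = 19 vs 69, per-effect power is only ≈0.9, so
"every planted effect recovered" would fail on a substantial fraction
of seeds by chance alone.)  The AUC surrogate runs use shifts in
[1.0, 2.0], where discrimination is driven by the joint signal of 22
miRNAs rather than per-miRNA significance.

## Problem sizes used by the test suite

Simulation-heavy checks run at reduced sizes chosen so the measured
property is unaffected: the permuted-label null calibration uses an
80-miRNA panel with a reduced 2×3×3 logistic grid (chance-level AUC
under label permutation is a leakage property, not a grid-size
property); the random-forest confusion-pattern run uses an 80-miRNA
panel with 100 trees; importance recovery uses a 40-miRNA panel.  The
three AUC surrogate runs use the full 376-miRNA panel and the complete
135-combination grid.  The enrichment uniformity calibration uses 500
replicates at B = 199 with a 246-miRNA panel over a 4000-gene
universe.

## Reproducibility

Every stochastic stage derives its seed as SHA-256(global seed, stage
name) mod 2³¹, so stages can be rerun in isolation and the full
pipeline is byte-identical across reruns with the same seed.  Grids,
fold layouts and permutation counts are all explicit in the run
configuration, which is echoed (with artifact checksums) into the
manifest.

## Known limitations

* The equal-variance t-test is anti-conservative under strong
  variance heterogeneity between classes; Welch's test is available
  but non-default.
* Limit-imputation of undetected wells compresses fold changes of
  weakly expressed miRNAs toward zero.
* The permutation p is bounded below by 1/(B+1); q-values inherit the
  bound.
* The elastic-net path refits from scratch for every grid point; no
  warm starts.  At the default grid this is ≈6,750 small fits per
  nested-CV run.
* Single-threaded by design (deterministic); no parallel fold
  execution.
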