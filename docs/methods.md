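# Methods

## Genotype simulation from aggregate allele frequencies

The central trick is to train individual-level classifiers without
individual-level data. An aggregate allele-frequency table gives, for
each population *p* and biallelic SNV *v*, the alternate-allele
frequency q. We draw a diploid genotype for a simulated member of *p*
as the number of alternate alleles among two independent Bernoulli(q)
draws, i.e. from the Hardy–Weinberg proportions

    P(0) = (1−q)²,   P(1) = 2q(1−q),   P(2) = q².

This is the only parameter-free genotype model consistent with a single
published frequency; it assumes random mating within each population and
no inbreeding at the simulated sites. Sites are simulated independently:
linkage disequilibrium is deliberately not modelled, so simulated
individuals are "typical" members of their population in marginal
genotype frequencies but carry variant combinations that need not exist
on real haplotypes. Classifiers trained on such cohorts learn marginal
population-frequency differences, which is exactly the signal used at
prediction time; they cannot learn haplotype structure, and nothing here
supports admixture-proportion estimation.

Missing (population, variant) frequency cells always simulate as
genotype 0, mirroring the encoding rule below. One PCG64 generator per
simulation call, consumed population-major, makes every cohort a pure
function of (table, n_per_population, seed).

## Genotype encoding

VCF genotypes collapse to alt-allele dosage: hom-alt = 2, het = 1 (phase
ignored), and hom-ref, missing (`./.`) and half-calls (`./1`) all = 0.
Conflating missing with hom-ref is intentional — it is the encoding the
classifiers are trained on, and it is what makes prediction on sparse
query VCFs well-defined: model features absent from the query are
zero-filled, which is indistinguishable from a hom-ref call. How
half-calls should map is genuinely ambiguous; we chose 0 (consistent
with "reference or missing") and note it here rather than asserting it
as the only reading. Only biallelic SNVs are representable; indels,
multiallelic records and non-diploid records are dropped with logged
counts. Genome builds are carried as tags and compared for equality —
no liftover is attempted; mismatches are hard errors.

## Synthetic worlds (Balding–Nichols)

Test worlds draw an ancestral frequency p ~ Uniform(0.05, 0.95) per SNV
and per-population frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F), whose
mean is p and variance F·p(1−p); F is an FST-like divergence knob.
Nested worlds re-apply the draw inside each continental group with a
smaller F_sub. The ancestral range excludes near-fixed sites because
aggregate panels are dominated by polymorphic sites after the frequency
prefilter (> 0.1%), and because Beta parameters degenerate as p → 0, 1.
Default study conditions used throughout testing: continental F = 0.15,
subcontinental F_sub = 0.03, 2,000 SNVs, 200 individuals per
subpopulation — divergences in the range of human continental/
subcontinental differentiation, and small enough to run in minutes on
one core. What passing these tests shows is that the pipeline recovers
population structure of that strength under Hardy–Weinberg sampling; it
does not show robustness to LD, batch effects, call-rate structure or
admixture, none of which the generator emulates.

## Chi-square SNV scan

Each SNV is tested for independence between population label and
genotype category with a Pearson chi-square statistic on the
populations × {0,1,2} contingency table; all-zero genotype columns are
dropped and dof = (rows−1)(kept−1). A variant with a single observed
genotype category is untestable: statistic 0, p = 1. We use genotype
counts rather than allele counts because genotype categories are what
the downstream model consumes; an allele-count scan would weight
heterozygotes differently. No continuity correction and no minimum
expected count are applied — the scan is a mass ranking device, not an
inferential test, and its operating thresholds (default 7.5×10⁻⁴⁹ at the
continental level) sit so deep in the tail that p-values must be
computed in log space. `scipy.stats.chi2.logsf` covers statistics up to
~1490 at 1 dof; beyond that even the log survival function underflows,
and we switch to the standard asymptotic expansion of the upper
incomplete gamma function, keeping log10 p finite and strictly ordered
in the statistic for any input. Thresholding happens by comparing
log10 p ≤ log10(threshold); no p-value is ever exponentiated.

Multiple-testing correction is intentionally absent: thresholds are
selected by cross-validated accuracy, not by error-rate control.

## Grid search

The nested search iterates population size × p-value threshold. Per
cell and repeat: simulate a cohort, split 80/20 stratified, chi-square
scan **on the training portion only**, drop sub-threshold SNVs, train a
GBT, record validation accuracy; five repeats are averaged. Because the
scan depends only on the training split, it is computed once per
(size, repeat) and shared across thresholds. Ties prefer the smallest
threshold (fewer features), then the smallest size (cheaper training).
The winner is retrained on a fresh full-size cohort (scan on all of it)
and scored on a freshly simulated holdout, 20% of the training size per
population by default. Cells whose threshold eliminates every feature
are recorded as failed (NaN) and skipped by the argmax.

## Classifiers

* **GBT** (`GradientBoostedAncestryClassifier`): XGBoost, `hist` tree
  method, multi:softprob objective even for two classes (so per-class
  margins and attributions always exist). Defaults: 200 rounds, depth 4,
  learning rate 0.3 — conservative settings that saturate accuracy on
  the synthetic study conditions; all hyperparameters are exposed and
  recorded in model metadata. Single-threaded by default so a seed fully
  determines the model; `n_jobs` trades that determinism for speed.
* **RBF-SVM** (`RbfSvmAncestryClassifier`): gamma fixed at the library
  default ("scale"); C selected from a user grid by stratified 5-fold
  CV with shuffling, maximising macro-F1 (unweighted over classes, the
  right average for imbalanced cohorts); ties go to the smallest C. The
  final model refits on all data with Platt sigmoid calibration
  (libsvm's internal CV) to obtain simplex probabilities; the
  calibration method is recorded in metadata because the hierarchical
  weighting consumes the probabilities directly. Classes smaller than
  the fold count reduce the fold count with a warning (or error, per
  config).

Prediction aligns query variants to the model's ordered feature list by
(chrom, pos, ref, alt); absent features are zero-filled. A query VCF
sharing no variants at all with the feature list is refused rather than
silently predicted from an all-zero profile.

## Hierarchical weighting

Subcontinental models are trained per continental group on that group's
samples only. At prediction, child probabilities are multiplied by the
parent's continental probability and **not renormalised**: the reported
numbers are joint-style scores whose children sum exactly to the parent
probability, and the per-report validator enforces both that identity
and the continental simplex to 10⁻⁶. Whether to renormalise is a
genuine design fork; we pass the product through unchanged because it
preserves the parent-level uncertainty in the subcontinental numbers
(a 0.95 parent with a (0.5, 0.5) sub-model reports 0.475, not 0.5).
Argmax ties break lexicographically for determinism. A minimum
reporting threshold on the top probability is available (default 0) for
settings where an indeterminate call is preferable to a weak one.

## Relatedness pruning

Pairs with kinship φ ≥ 0.0442 (third-degree, inclusive) form a graph.
While any node has degree ≥ 2, the maximal-degree node is removed (ties:
lexicographically smallest ID — the rule is arbitrary but must be fixed
for reproducibility). Remaining components are single edges or
singletons; one member of each edge is kept via the seeded generator,
singletons are all kept. The keep set therefore always induces an
edge-free subgraph, in at most |nodes| removals. Max-degree removal is
a greedy heuristic for keeping many samples, not a maximum-independent-
set algorithm, and is documented (and tested) as such.

The optional built-in estimator implements the robust between-family
kinship of Manichaikul et al. (2010):
φ = (N_het,het − 2·N_opposing-hom) / (N_het(i) + N_het(j)). It yields
≈ 0.5 for duplicates, ≈ 0.25 for parent–offspring and ≈ 0 for unrelated
pairs under HWE; pairs where both samples lack heterozygous calls are
reported as missing. External KING output can be supplied instead as a
(ID1, ID2, phi) table.

## Attribution

For GBT models we use XGBoost's built-in exact TreeSHAP
(`pred_contribs`): per sample, feature and label, additive attributions
on the margin scale satisfying local accuracy (base value + sum of
attributions = margin) to well below 10⁻⁴. For non-tree models a
background-substitution attribution is provided: the change in predicted
probability when one feature is replaced by background values, averaged
over a seeded 100-row stratum of the data. It is additive-ish but not a
Shapley value; the method tag is carried on the tensor and the two are
never mixed. Kernel-style attribution over very large feature sets is
refused with guidance (cost grows as features × background), matching
the practical infeasibility of kernel explainers on 10⁵-feature SVMs.

Aggregation: overlapping gene intervals merge into composites
(names joined by "+"); each SNV maps to at most one merged interval, and
unmapped SNVs are counted and excluded. Per interval and label we sum
member attributions within each sample, take |·|, then average across
samples. "Mean absolute value" admits several orders of operations; we
sum-then-abs-then-mean because within-gene cancellation is real signal
(opposite-sign SNVs in one gene do cancel in the model's output); the
abs-first alternative is available behind a flag. Signed means are kept
alongside so suppressor genes (strong negative attribution toward a
label) remain visible. Cytoband mode tags each interval with the label
of maximum absolute aggregate.

## Numerical and reproducibility choices

* All randomness flows from `numpy.random.default_rng` (PCG64); derived
  seeds use `SeedSequence.spawn` and stay below 2³¹.
* Probability sanity: every prediction row must sum to 1 within 10⁻⁶.
* Report JSON rounds to 6 decimals at serialisation only.
* Model bundles are pickles with a format-version field; loads verify
  the version and the feature-list/estimator consistency, and corrupted
  files raise instead of degrading.
* Problem sizes in the test suite and acceptance script (≤ 2,000 SNVs,
  ≤ 200 individuals per population, 5 seeds) were chosen as the smallest
  sizes at which the studied effects are stable; everything runs in a
  few minutes on one core.

## Known limitations

* No LD, no haplotypes, no admixed individuals — by construction of the
  simulator (see above).
* The 0 encoding cannot distinguish hom-ref from no-call; cohorts with
  systematic missingness will look subtly more reference-like.
* The pruning heuristic does not guarantee the maximum number of
  retained samples.
* The chi-square scan's en-masse use ignores small expected counts;
  a diagnostics pass can report the affected fraction but no correction
  is applied.
* Liftover between genome builds is out of scope; inputs must share a
  build tag.
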