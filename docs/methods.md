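# Methods

## Model and procedure

The package compares the *structure* of gene co-expression between two
groups of samples (normal vs disease) rather than testing pairs one at a
time. Within each group the co-expression level of an unordered gene pair
is the absolute Pearson correlation of the two genes' profiles over that
group's samples only. The absolute value treats strong positive and strong
negative relationships alike; pooling samples across groups is never done,
since a between-group mean shift would masquerade as correlation.

All g(g−1)/2 pair-level values per group form two empirical distributions,
summarized by their exceedance functions F(c) = Prob(|r| ≥ c). The maximum
deviation D = max_c |F_d(c) − F_n(c)| is the classical two-sample
Kolmogorov–Smirnov statistic (the survival-function difference and the
CDF difference have the same supremum). The search grid is the union of
all observed values in both groups: a difference of step functions attains
its supremum on its jump points, so this is exact rather than a
discretization. When several thresholds attain D the smallest is returned;
this tie-break is arbitrary but deterministic. The threshold attaining D,
the disease-specific cutoff point C, classifies each pair as strong
(|r| ≥ C, boundary inclusive) or weak per group, giving the four galaxy
regions: normal-specific strong (= disease-specific weak),
disease-specific strong (= normal-specific weak), common strong, common
weak.

Significance of D uses the asymptotic Smirnov critical value
c(α)·√((n₁+n₂)/(n₁n₂)) with the standard coefficient table (c(0.05) =
1.36; supported α: 0.10, 0.05, 0.025, 0.01, 0.005, 0.001), and the
decision is strict (D > D_critical). Pair-level values share genes and are
therefore not independent; the nominal KS significance level is
approximate, every report carries that caveat, and the null calibration
experiment below measures the practical effect at a typical problem size.
A permutation null that respects the dependence is a known limitation, not
implemented.

## Candidate-target consensus

When per-database miRNA target predictions are supplied, candidate genes
are those predicted for a miRNA by at least `min_databases` (default 4) of
the databases covering that miRNA, united over all cluster members and
intersected with the measured genes. A gene counts once per database
regardless of transcript multiplicity. The vote is taken among databases
that cover the miRNA (a database lacking the miRNA entirely does not count
against its targets). Prediction tables are frozen local files by design:
web databases drift, and reproducibility requires pinned inputs. Without
predictions, the pipeline analyzes all measured genes.

## Enrichment and pair mapping

Term enrichment of the candidate list uses the EASE score: the one-tailed
hypergeometric upper tail recomputed after removing one gene from the
list–term overlap (overlaps of 0 or 1 score exactly 1). It is always at
least the plain Fisher tail, penalizing terms supported by few genes.
Multiplicity is controlled with Benjamini–Hochberg adjusted q-values;
terms pass at ease_p < 0.05 AND q < 0.05 (strict). The default background
universe is the union of all gene-set members, overridable to all measured
genes or a user list. Because enrichment depends on the annotation release
and background of whatever service originally produced a given result,
numeric agreement with external annotation services is out of scope; the
selection logic is what is implemented and tested.

For each selected term, all unordered pairs of its analyzed genes are
mapped onto the classification. The 2×2 table counts only group-specific
pairs — a = normal-specific strong, b = normal-specific weak, c =
disease-specific strong, d = disease-specific weak — so b = c and a = d
identically (a normal-specific strong pair *is* a disease-specific weak
pair), and common pairs enter no cell. This orientation (rows = the two
group-specific views, columns = strong/weak) is the only one consistent
with that symmetry. The one-sided Fisher exact test (upper tail in a)
asks for an excess of normal-specific strong pairs; the direction is fixed
rather than configurable to avoid silent sign errors, and both tails can
be recovered from the emitted table. Correction is Bonferroni over the
number of terms entering the mapping stage, applied to full-precision
p-values (display rounding happens only at serialization, so a corrected
value can differ in the last digit from multiplying a rounded p).

## Synthetic data

The generator emulates a two-group microarray study: genes belong to
correlation blocks or are unstructured noise, and within group g a gene of
block b is x = √ρ_bg·z + √(1−ρ_bg)·e with a shared per-sample block factor
z and independent Gaussian noise e. Two same-block genes then have
population correlation exactly ρ_bg in that group; cross-block and noise
genes are uncorrelated. A single-factor block model was chosen over a full
covariance specification because it guarantees the target correlation with
O(genes) sampling and models disease-specific decoupling directly
(ρ_disease = 0). Negative planted correlations are not provided: the
absolute-value co-expression measure makes them equivalent to positive
ones. Probe-level artifacts and heteroscedastic microarray noise are not
modeled, so passing recovery tests demonstrates the statistics, not
robustness to platform effects. Default sample sizes are 8 normal and 9
disease, mirroring a typical small two-group design; at that scale |r|
from 8–9 points is extremely noisy, and tests at that scale assert only
the direction of the deviation, never per-pair category accuracy.

### Experiment sizes

* **Recovery**: two blocks of 40 genes with ρ = 0.9 in normal and 0 in
  disease, no extra noise genes (the 1,600 cross-block pairs are the null
  population), 50 samples per group, 20 replicates. Reported accuracy is
  the fraction of within-block pairs whose classified category at the
  detected C matches the planted category, pooled over replicates. Blocks
  of 40 were chosen because the empirical exceedance fluctuations scale
  with the number of *genes*, not pairs (pairs share genes); with small
  blocks the detected cutoff occasionally lands inside the null |r| range,
  an inherent property of the maximum-deviation cutoff at this effect
  size. Per-replicate accuracy still varies; pooled accuracy is the
  meaningful summary.
* **Null calibration**: 30 unstructured genes, 20 samples per group
  (equal on purpose — under the null the |r| sampling distribution depends
  on the per-group sample count, so unequal groups would differ
  systematically even without structure), 100 replicates, reporting how
  often D stays below D_critical at α = 0.05. Gene-sharing dependence
  inflates rejections slightly above the nominal 5%.

## Numerical choices and degenerate inputs

* Probe-to-gene collapsing is the arithmetic mean on the already-normalized
  scale; no re-normalization. Probes missing from the probe map are an
  error, not silently dropped.
* Genes with any missing value, or constant within either group
  (correlation undefined), are removed before the pair table is built,
  with logged counts.
* Gene identifiers are opaque case-sensitive strings; matching across
  expression, predictions and gene sets is exact.
* Correlations use the standard product-moment formula; the n vs n−1
  variance convention cancels in r. Agreement with a two-pass textbook
  implementation is tested to 1e-12.
* Pairs are stored with gene_i < gene_j lexicographically, making joins
  and set operations deterministic.
* All simulation randomness flows from one mandatory integer seed through
  a single generator; reruns are bit-identical.

## Known limitations

* The KS critical value assumes independent observations; pair dependence
  makes the test anti-conservative to a degree quantified only empirically
  here.
* The EASE/FDR stage cannot reproduce numbers computed against external
  annotation databases (unknown background and release).
* The mapping test conditions on the detected cutoff; uncertainty in C is
  not propagated.
* At 8–9 samples per group, individual pair categories are unreliable
  even when the distribution-level deviation is clearly significant.
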