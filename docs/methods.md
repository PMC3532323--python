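# Methods

## Model

Let X (n × p) hold chemical descriptors and Y (n × q) signed gene-set
activations for n compounds. Descriptor columns are standardized before
fitting (descriptor scales are heterogeneous); activation columns are centered
only, since they are already bounded in [−1, 1]. Both choices are
configurable. With centered feature-space covariances
C_xx = X'X/(n−1), C_yy = Y'Y/(n−1), C_xy = X'Y/(n−1), the regularized CCA
problem

P_s = max_{w,v} w'C_xy v / sqrt((w'C_xx w + λ₁ w'w)(v'C_yy v + λ₂ v'v))

is solved as the symmetric eigenproblem of
M = (C_xx+λ₁I)^{-1/2} C_xy (C_yy+λ₂I)^{-1} C_yx (C_xx+λ₁I)^{-1/2}. Canonical
correlations are √eigenvalues clipped to [0, 1]; eigenvector orthogonality
yields uncorrelated components in the regularized metric. Weight vectors are
rescaled so each training variate has unit sample variance, and the sign of
each component is fixed by making the largest-|entry| element of w_s positive
(CCA signs are otherwise arbitrary; this makes the A/B subcomponent labels
deterministic). Reported correlations are the penalized eigenvalue roots; for
comparison across ridge strengths the realized Pearson correlation of the two
variates is the scale-free alternative (used by the acceptance script for the
pipeline study, where the selected ridge may be large).

If a regularized covariance is numerically singular (λ = 0 with p ≥ n or
exactly collinear columns), the fit aborts with an error advising λ > 0 rather
than silently pseudo-inverting.

### Model selection

λ₁, λ₂ are chosen on a grid (default 10⁻³…10³ per axis) by k-fold
cross-validation (default 20 folds): per fold, fit on the training compounds,
project everything with the stored centering/scaling, and compute mean average
precision at depth 10 for the held-out annotated queries in the fused
(chemical ⊕ biological variates) space; fold-averaged MAP is maximized, ties
going to the smaller λ₁ then λ₂. Compounds without annotations contribute to
fitting but not to scoring. Scoring held-out queries against the full
projected library (rather than within the small held-out fold only) keeps the
retrieval task well-posed at 20 folds.

### Significance and component retention

Rows of Y are permuted uniformly at random (breaking the compound pairing),
the model is refitted with the selected penalties, and each component's
correlation is compared with the observed one. We report
p_s = (1 + #{b : P_s^perm(b) ≥ P_s}) / (B + 1) — the add-one estimator is
never exactly zero and gives a valid permutation test — alongside the raw
proportion. Permutation refits reuse the selected (λ₁, λ₂); the test statistic
is held fixed rather than re-cross-validated. Components with p below the
threshold (default 0.05) are retained, capped at the top 10 by correlation.
Note the null distribution of later components' correlations is itself high
in small samples (overfitting), so weak secondary components are only
detectable with enough compounds — the pipeline study in the acceptance
script uses n = 120 for that reason.

### Subcomponents

Each retained component is split into A (canonical score > 0) and B (< 0);
zero scores join neither. The score defaults to the mean of the chemical and
biological variates (configurable to either side): the component is a shared
direction, and averaging the two views' scores is the symmetric choice.

## Preprocessing of expression batches

Per batch: with ≥3 controls, the single control with the largest **summed**
Euclidean distance to the other controls is removed as an outlier and the rest
averaged; with 1–2 controls the plain mean is used (with two controls "the
other controls" is a single point and outlier removal is ill-posed). Exactly
one control is ever removed. Differential expression is the difference of
log2-scale profiles (treatment − consolidated control). The
ceil(fraction × n_genes) genes (default fraction 0.05) with the highest
variance across all control profiles pooled over batches — variation unrelated
to treatment — are discarded, ties at the cutoff broken by gene id. When a
compound has several instances (cell line / concentration / batch), the
instance with the largest response norm is kept, exact ties going to the
lexicographically smallest instance id. Ids are carried as strings; internal
indexing is 0-based.

## Gene-set activation

Genes are ranked by response (descending, ties by gene id). For a set of m
genes the running sum gains |response|^α / N_R at members (α = 1 by default,
N_R the total member weight) and loses 1/(n_genes − m) elsewhere; the
enrichment score ES is the extreme deviation, computed in closed form at the
hit positions. The null is built per set size from random same-size gene sets
(gene-label permutation; default 200 draws), p is the two-sided tail on |ES|,
and q is the Benjamini–Hochberg FDR across the collection within each
compound (per-treatment enrichment runs are transformed independently). The
signed activation is sign(ES) × (1 − q) ∈ [−1, 1]; ES = 0 maps to sign +1
(arbitrary but deterministic). Sets emptied by intersection with the measured
gene universe are dropped globally, with a warning. The scorer is pluggable:
`build_activation_matrix` consumes any per-compound (es, q) table, so
externally computed enrichment results can be substituted. The implementation
reproduces the standard weighted running-sum statistic (verified against an
independent prerank implementation in the test suite) but makes no claim of
numeric agreement with any specific external tool's q-values; the weighting
exponent, permutation count and ranking metric are documented defaults, not
canonical values.

## Retrieval validation

Similarity between compounds is the Pearson correlation of their
representation vectors — scale-free, hence comparable across spaces of very
different dimensionality; zero-variance rows get similarity 0 to everything
and are flagged. Each compound with at least one annotation label shared with
another compound is a query; candidates are ranked by similarity (ties broken
by compound id) and average precision at depth k is the mean precision at the
relevant hits within the top k (0 when no relevant compound appears; relevant
items beyond rank k do not enter the denominator). MAP ± SEM over queries is
reported for k = 5…100 in steps of 5. The fused CCA representation is the
concatenation of chemical and biological variates over retained components.
The exact expectation of AP@k under a uniformly random ranking (hypergeometric
hit count; hit positions a uniform subset of the top-k slots) provides the
analytic random baseline. Caveat: queries sharing labels have correlated
APs, so the per-query SEM understates the sampling spread of MAP itself;
null-conformance checks in the test suite therefore calibrate against an
explicit label-permutation null rather than the SEM.

## Component characterization

Gene sets are associated to a component by the Pearson correlation of their
activation column with the component's biological variate (constant columns
get 0). Candidate genes for a subcomponent are the union of the genes in the
top 20 positively and top 20 negatively associated sets; they are tested
across the subcomponent's top 10 compounds by |score| with a moderated
one-sample t statistic

s̃² = (ν₀ σ₀² + (n−1) s²) / (ν₀ + n − 1),  df = ν₀ + n − 1,

where the background variance σ₀² is the mean sample variance over a sliding
window of 101 genes ordered by mean response and ν₀ (default 10) is the prior
weight. At ν₀ = 0 this is exactly the ordinary Student t. Genes with p < 0.05
(no multiplicity correction — the threshold is a screening rule, mirrored by
the raw-p ranking of the hypergeometric term over-representation that follows)
are reported ranked by p, truncated to 30 for export. Component-pair
similarity uses the Tanimoto coefficient of the top-30 gene lists
(biological) and the intersection size of the top-20 compound lists
(chemical). Target enrichment compares the number of annotation labels shared
by ≥2 of a subcomponent's top compounds against 1000 random same-size draws
from the annotated pool (add-one-corrected p); the alternative statistic —
number of compound pairs sharing a label — is available via `statistic="pairs"`,
since "target sharing" admits both readings. The eye-diagram table exports,
per component, all descriptors with subcomponent-specific weights (mean
standardized descriptor value over the side's members) and the top gene sets
with overall component weights.

## Synthetic data generator

All generators are pure functions of their arguments including the seed.
`simulate_joint_data` draws, per component s, a bivariate-normal latent pair
(u_s, t_s) with correlation ρ_s per compound, pushes the latents through
unit-norm (orthonormalized) loading columns into each view, and adds Gaussian
noise **in the orthogonal complement of the loading span**. Confining the
noise to signal-free directions makes the planted ρ_s the exact population
canonical correlations of the generated views — the property a recovery test
needs from its ground truth; isotropic noise would instead attenuate the
observable correlation by 1/(1+σ²) per view. Activations are bounded by a
gentle error-function squash, erf(y / (3·sd(y))): respects the [−1, 1] range
while staying nearly linear over the bulk of the data.

`simulate_expression_batches` builds log2-scale profiles around a gene
baseline ~N(8, 1.5) with per-batch shifts (sd 0.3) and measurement noise
(sd 0.25), typical microarray scales; each compound's treatment adds its
planted effect (a flat effect on a random gene set, or an arbitrary per-gene
vector), and in batches with ≥3 controls one control is shifted uniformly on
all genes — a shift that provably maximizes the summed Euclidean distance, so
the outlier-flagging test is deterministic. `simulate_annotations` clusters
compounds on their latent scores (k-means) and assigns the cluster's label
with probability `alignment`, a random label otherwise: alignment 1 makes
labels a function of the latent structure, alignment 0 makes them independent.
`simulate_study` ties everything together coherently: gene sets tile the
genome in blocks, each latent component drives its own block of sets, and the
treatment effects are the biological latent scores pushed through those
set-structured gene loadings, so the real preprocessing + enrichment stages
recover activations correlated with the chemical view.

What the generator does **not** emulate: probe-level microarray structure and
normalization artifacts, heavy-tailed and correlated measurement noise,
non-linear structure–response relationships, hierarchical/multi-label
annotation ontologies, and realistic gene-set overlap topology. Passing tests
demonstrate correctness and calibration of the machinery under the linear
low-rank model it assumes, not performance on real compendia.

## Study conditions used in tests and the acceptance script

- Recovery study: n = 500 compounds, p = 15, q = 20, k = 3, planted
  correlations (0.9, 0.7, 0.5), noise sd 2.0, λ = 0.001, 20 replicates.
  Per-feature signal is weak (a realistic descriptor table is mostly noise
  with a low-rank shared signal) while multivariate recovery remains easy;
  noise comparable to the per-column signal also keeps the standardized
  covariance well-conditioned, which the weight-direction estimate needs.
  Recovery metrics (correlation error, largest principal angle between fitted
  and planted weight subspaces) are Monte-Carlo averages over replicates: a
  single replicate's third canonical correlation has sampling sd ≈ 0.03 at
  n = 500, so per-replicate bounds at the ±0.05 level would be
  noise-dominated.
- Permutation calibration: 200 independent-view datasets (n = 60, p = 6,
  q = 5), 199 permutations each; first-component p-values are checked for
  type-I error at α = 0.05 and KS uniformity.
- Retrieval comparison: n = 300, p = 30, q = 40, k = 4, planted correlations
  (0.9, 0.85, 0.8, 0.75), noise sd 1.0, 6 labels at alignment 0.9 (or 0 for
  the null), gene view with 150 features; 20 replicate runs for the dominance
  check.
- Pipeline study (acceptance script): 120 compounds, 480 genes, 24 sets,
  2 planted components (0.9, 0.8), 6 batches × 3 controls, 5-fold CV over a
  3-point grid, 199 permutations, 100 enrichment permutations.

## Numerical and design notes

- Eigen-decompositions use symmetric `eigh`; a regularized covariance is
  declared singular when its smallest eigenvalue is ≤ 10⁻¹⁰ of the largest.
- Degenerate variates (zero variance) are left unscaled rather than divided
  by zero; their correlations are 0.
- All tie-breaks are lexicographic on ids (gene filter cutoff, instance
  selection, similarity ranking, gene-set association ranking), so every
  output is deterministic.
- The global pipeline seed fans out to per-stage child seeds through fixed
  offsets, so adding or disabling a stage does not shift another stage's
  stream.
- Model archives are JSON with a schema version; matrices travel as TSV
  (names may contain commas), gene sets as GMT.
- Plots are deliberately not produced; curves and tables are exported as TSV
  for downstream plotting.

## Limitations

- The linear-Gaussian latent model and the ridge (not sparse) penalty mean
  weights are dense; no variable selection is attempted.
- Enrichment q-values come from gene-label permutations and BH, a simplified
  (if standard) pipeline; phenotype permutation is out of scope.
- With few compounds the permutation null for secondary components is wide
  and only strong leading components are detectable.
- The term-enrichment stage treats any term collection as a flat set of gene
  sets; ontology structure (term hierarchy, redundancy) is ignored.
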