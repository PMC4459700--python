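# Methods

## Model and procedure

`netcca` treats a paired study as two complete real matrices sharing a
sample axis: X (n × p, normalized log expression) and Y (n × q, metabolite
concentrations). The core assumption is that biologically coherent subsets
of genes and metabolites co-vary through a small number of shared latent
signals, so that classical canonical analysis becomes well-posed *within*
a functional group even when it is undefined on the full matrices
(n ≤ p + q). Prior knowledge is used only to delimit groups, never to
weight the statistics.

### Prior-knowledge grouping

The knowledge graph has a bipartite reaction layer (metabolite–gene edges
annotated with a reaction identifier and a substrate/product role) and a
gene–gene interaction layer with per-channel evidence scores on [0, 1]
(raw tables in the 0–1000 combined-score convention are auto-detected by a
maximum above 1 and rescaled). An interaction edge is retained iff at
least one of its channels reaches `score_threshold` (default 0.7, the
conventional high-confidence cut on that scale); nodes referenced anywhere
are always created.

Per metabolite class, seed genes are all genes of every reaction touched
by a class metabolite in either role. Expansion adds, in first-tag-wins
order:

1. `expanded_distance(d)` — genes within `max_distance` hops of a seed
   over retained edges, treated as undirected (default 1: evidence
   channels are largely symmetric, and one hop is the only defensible
   radius without tuning);
2. `expanded_hub` — non-seed neighbors of seeds whose degree reaches the
   `hub_percentile` of the full degree distribution (default 95);
3. `expanded_circuit` — off by default; when on, genes sharing a simple
   directed cycle of length ≤ 4 with a seed. Only edges flagged directed
   carry direction here: treating symmetric evidence as bidirectional
   would make every neighbor a two-cycle member and collapse this
   criterion into distance-1 expansion. The cycle-length bound is a
   configurable interpretation choice, since "co-occurrence in directed
   circuits" has no unique formalization.

Genes may belong to several groups; the complement group collects every
measured feature claimed by no class.

### Correlation prefilter

Within each block, features with |Pearson r| above `threshold` (default
0.7) to an already-retained feature are removed in one greedy pass in
input-feature order. The order rule is deliberate: it is deterministic,
documentable, and matches the temporary-removal framing in which removed
genes re-enter the final ranking as proxies of their representatives.
Absolute correlation is used — a strongly anti-correlated variable is
equally redundant for canonical analysis. Zero-variance features are
removed with a `"constant"` sentinel and an undefined r.

### Canonical analysis

CCA solves the eigenproblem of S_xx⁻¹S_xy S_yy⁻¹S_yx via SVD of
W_x S_xy W_y with W = S⁻¹ᐟ² (symmetric eigendecomposition; an eigenvalue
below 10⁻¹⁰ of the largest raises an error directing the caller to the
prefilter or to rCCA). Covariances use the n − 1 denominator. Variates
have unit sample variance; loadings are plain Pearson correlations of raw
variables with variates. Sign convention: the X variate is oriented so its
largest-|loading| variable loads positively, and the Y variate is then
oriented so the score-pair correlation is non-negative (orienting both
sides independently could flip the realized correlation negative, which
would contradict reporting correlations on [0, 1]).

Bartlett's sequential chi-square is the significance test:
χ²_k = −[n − 1 − (p + q + 1)/2]·ln Λ_k with Λ_k = ∏_{i≥k}(1 − r_i²) and
(p − k + 1)(q − k + 1) degrees of freedom. Rao's F is a known alternative
but is not the default. The Stewart–Love redundancy aggregates over all
s = min(p, q) variates: Rd(Y|X) = Σ_k r_k²·mean_j ℓ_{jk}²; with q ≤ p this
equals the mean squared multiple correlation of each Y variable on X,
which the test suite exploits as an independent identity check.

rCCA replaces S_xx, S_yy by S_xx + λ₁I, S_yy + λ₂I. Reported correlations
are the realized Pearson correlations of the score pairs; because
regularization perturbs the singular-value ordering slightly, variates are
reported sorted by realized correlation. λ selection maximizes the mean
absolute out-of-fold correlation of the first score pair over a K-fold
split (default 5 folds, shuffled under the stage seed); there is no
significance test for rCCA.

PLS extracts, per component, the dominant singular pair of the current
cross-covariance of the centered, unit-scaled blocks; regression mode
deflates both blocks on the X scores, canonical mode each block on its own
scores (the default, matching the symmetric integration framing). The
underlying per-component fits come from scikit-learn's cross-decomposition
implementations (exact SVD algorithm in canonical mode; NIPALS at 10⁻¹⁴
tolerance in regression mode); explained variance per block and component
is the squared Frobenius norm of the rank-1 reconstruction (scores ×
loadings) as a percentage of the centered, scaled block's squared norm.
Components requested beyond the feasible rank are truncated with a
warning.

### Randomized-group null

For a group with g genes and m metabolites, B replicates draw g genes and
m metabolites uniformly *without replacement* from the measured pools
(mirroring real group composition), re-apply the prefilter at the same
threshold, and evaluate the statistic — CCA aggregate redundancy or the
X-block PLS LV1 explained variance. The default B is 1000. Significance is
a two-sided one-sample t-test of the null sample against the observed
value as hypothesized mean, exactly the comparison of a group value with
randomized-group means; since a t-test on B resamples is anti-conservative
almost by construction, the empirical upper percentile
(1 + #{null ≥ observed})/(B + 1) is reported alongside and is the value
the tests rely on. Replicates whose retained counts fall below 2 on either
side are redrawn (cap 10·B); the *observed* group is allowed to collapse
to a single retained metabolite, since q = 1 canonical analysis is
well-defined and refusing it would silently drop exactly the groups whose
metabolites are most strongly co-regulated. The PLS null statistic uses
the X-block LV1 share; the choice of block is a reporting convention, and
both blocks' percentages are exposed everywhere else.

A caveat observed on synthetic data: the CCA-redundancy null can be
anti-conservative against an observed group that loses many collinear
genes to the prefilter, because random draws retain more predictors and
overfit Rd(Y|X) upward at small n. The PLS LV1 statistic does not share
this failure mode and is the recommended default.

### Ranking and enrichment

Genes are ranked by |loading| on CV1 (CCA) or LV1 (PLS); ties preserve
input order; each prefilter-removed gene is listed directly after its
representative with the representative's score and a proxy flag, and is
excluded from top-k counting (no double counting). The top fraction
(default 10%) is computed as ceil(fraction × #distinct non-proxy genes)
with boundary ties included. Over-representation uses the one-sided
hypergeometric upper tail with Benjamini–Hochberg step-up FDR; the default
universe is the measured gene set, not the whole knowledge base, because
candidates are selected from measured genes.

## Synthetic data

The generator emulates the target study shape: 40 samples, three planted
groups of 20 genes and 5 metabolites each, background features to 120
genes and 21 metabolites. Each group has one standard-normal latent factor
per sample; member features load on it with magnitudes uniform on
[0.6, 0.9] and random sign, plus N(0, 0.6²) noise — giving within-group
cross-correlations around 0.5–0.7 and first canonical correlations above
0.9, the regime the method targets. Background features are independent
N(0, 1). For a planted pair with loadings a, b and noise σ the expected
correlation is a·b/√((a²+σ²)(b²+σ²)), which the tests verify empirically.
The matching prior graph makes 30% of each group's genes reaction-linked
seeds, attaches the rest to seeds with score-0.9 edges, and sprinkles
score-0.5 decoy edges among background genes (density 0.05) that fall
below the retention threshold. An option lets genes load on a second
factor to emulate genes shared between groups.

What this generator does *not* emulate: microarray noise structure,
compositional effects in lipid concentrations, correlated backgrounds,
batch effects, or imperfect prior knowledge (wrong or missing reaction
links). Passing tests therefore demonstrate correctness of the machinery
and recoverability under clean planted structure, not field performance on
real annotation databases.

## Numerical choices and degenerate inputs

- Covariance singularity threshold 10⁻¹⁰ (relative); canonical
  correlations clipped to [0, 1].
- Missing values are rejected at read time rather than imputed; duplicate
  identifiers are errors naming the duplicates.
- ChEBI identifiers are normalized to `CHEBI:<integer>`; matching is
  case-sensitive after harmonization; two platform IDs mapping to one
  symbol is an error (aggregation is the caller's decision).
- A perfect canonical correlation yields Wilks Λ = 0 and p = 0 with a
  warning; a constant null distribution makes the t-test undefined and is
  reported as p ∈ {0, 1} with a warning, while the empirical percentile is
  always available.
- The pipeline derives per-stage seeds from one master seed by fixed
  offsets, making every stage re-runnable in isolation; reports serialize
  with sorted keys so equal runs are byte-identical.

## Problem sizes

Default test and acceptance runs use the 40 × 120 / 40 × 21 synthetic
shape; the randomized-group null runs at B = 200 in the acceptance script
and tests (B = 1000 remains the analysis default); Bartlett calibration
uses 2000 independent-block replicates; recovery checks span 10 generator
seeds. These sizes make the whole suite run in a few minutes on one core
while keeping every statistic in its intended regime.

## Known limitations

- Classical CCA on the undivided data is only attempted when n > p + q;
  otherwise it is skipped with a machine-readable reason.
- The rCCA implementation is standard ridge-regularized CCA; published λ
  values from other implementations are accepted as fixed inputs but the
  selection procedure here is plain cross-validation.
- Circuit expansion enumerates simple cycles and is exponential in dense
  directed graphs; the length bound keeps it tractable but approximate.
- Only two blocks are supported; sparse PLS and kernel CCA are out of
  scope.
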