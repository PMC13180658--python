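# Methods

This note documents the model, the simulation that stands in for real
cohorts, and the numerical and design choices, in the package's own words.

## Conditioned C+T features

The unit of analysis is the conditioned clumping+thresholding PRS.  For
each reference cell the clumping **index candidates** are the harmonized
variants lying inside peaks with nonzero accessibility in that cell (a peak
is "captured" iff its count > 0; no count threshold is applied).  Clumping
is greedy: the smallest-p remaining candidate with p ≤ p* becomes an index
and removes every variant — candidate or not — within 250 kb on the same
chromosome with r² above the threshold.  Ties on p break by (chrom, pos)
ascending, so results are deterministic.  Because the greedy scan visits
candidates in ascending p, a single clumping run at the loosest cutoff
yields the index sets of all tighter cutoffs as prefixes; with the default
grid (r² ∈ {0.1, 0.3, 0.5} × p ∈ {1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5})
this costs 3 clumping runs per distinct peak-variant set instead of 21.
Cells with identical candidate sets share one computation; the cache is
bit-identical to recomputation (tested).

In the PRS denominator P·M, M counts the individual's nonmissing variants
**among the selected index set** (the natural reading when scoring a fixed
variant panel); individuals with M = 0 score exactly 0.  LD is estimated
in-sample by default (pairwise-complete squared Pearson correlation of
dosages, stored sparsely within the 250-kb window); an external reference
panel can be supplied through the same genotype reader.  Features are
z-scored per (cell, setting) with training-set statistics; zero-variance
features are set to 0 and the statistics are stored for held-out samples.

## Cell graph

Cell embeddings use LSI: term frequency per cell scaled by
log(1 + M/(1 + df)) inverse document frequency, then truncated SVD (ARPACK,
fixed seed, per-component sign fixed by the largest-magnitude loading).
The first component, usually depth-dominated, is dropped by default.  The
kNN graph on Euclidean distances keeps exactly k neighbors per cell
(self excluded; distance ties break by cell index), and only mutual edges
survive: A = Ĝ ∘ Ĝᵀ.  The penalty matrix is the **symmetric** normalized
Laplacian G_L = I − D^{−1/2} A D^{−1/2}; isolated cells get a zero diagonal
and contribute nothing to the penalty.  (An asymmetric exponent sometimes
appears in print for this matrix; the symmetric form is the one consistent
with its name and with a positive-semidefinite penalty.)

## Network and training

Parameters are deliberately few: the 21-vector W₀ shared across cells, two
scalars (w₁, w₂) per propagation layer, the per-cell readout β and a bias.
All weights on the path from X to h^(T) enter the forward pass through
abs(·), so the latent map is monotone increasing in the inputs — the
property that makes β interpretable as cell importance.  For deg(v) = 0 the
neighbor sum is empty and the self term alone is used with normalization
constant 1.  ‖β‖₂ is read as the squared (ridge) norm by default, the
conventional choice; the unsquared norm sits behind a flag.  Optimization
is mini-batch Adam (lr 10⁻³, β₁ = 0.9, β₂ = 0.999, batch 32, 200 epochs, no
early stopping, batch order reshuffled each epoch from the run seed, last
partial batch kept), implemented in NumPy with analytic gradients; the
gradients are verified against central finite differences in the test
suite, and two fits with the same data, config and seed produce identical
loss traces.  Non-finite loss aborts with diagnostics.  Splits are 60/20/20
train/validation/test, stratified by label for binary tasks; model
selection uses validation AUROC (binary) or Pearson r (regression) at the
final epoch.  Extra feature blocks (nonpeak PRS, covariates) are z-scored
with training statistics and concatenated to h^(T) with their own readout
coefficients, which are not penalized — the penalties exist to structure
the per-cell β.

## Prioritization

An ensemble of models differing only in seed is trained on the full
cohort.  Each cell's β values are compared against the pooled top-15%
weights per repeat with a one-sided Welch t-test (alternative: cell mean
greater); the focal cell's own top weights are *not* excluded from the
background by default (a leave-self-out variant is available).  BY
correction at α = 0.1 defines prioritized cells; a one-sided Fisher test
with BH correction at α = 0.1 defines enriched cell types, excluding types
with fewer than 150 cells (the small simulated atlases in the tests pass an
explicit lower `min_cells`).

The package's default prioritization configuration is one propagation
layer with λ₁ = 1, λ₂ = 10, λ₃ = 2.5, selected once from the model's
hyperparameter grid on simulated cohorts.  The L1 term matters beyond
sparsity: with a deterministic optimizer, cells without consistent signal
would otherwise converge to the same small but reproducible weights in
every ensemble member, and chance correlations could pass the
consistency test.  Under λ₁ = 1 such cells dither around zero across
seeds, which keeps the permuted-label null empty while leaving genuinely
informative cells consistently positive.

## Simulation

The generator reproduces the statistical structure the method assumes,
not any particular organism's genome:

* **Genotypes.**  Per chromosome, a pool of H haplotypes with allele
  frequencies drawn uniformly from the configured MAF range; individuals
  draw two mosaic haplotypes with Poisson-distributed recombination
  breakpoints.  The pool size sets LD strength (H = 2 gives near-perfect
  within-block LD; H → ∞ approaches independence) and the crossover
  density sets its decay length: the default of 12 crossovers per 2-Mb toy
  chromosome makes r² fade over roughly 150–250 kb, mirroring the
  human-scale decay that motivates a 250-kb clumping window.  Returned
  "true MAFs" are realized pool frequencies.  Variants sit every 5 kb, so
  a 250-kb window spans ~50 variants.
* **Atlas.**  Non-overlapping 500-bp peaks anchored on variant positions;
  each cell type opens its own specific peaks with probability 0.85,
  other types' with 0.08 and shared peaks with 0.9, then independent
  dropout (0.15) and small positive integer counts.
* **GWAS.**  True effects β* ~ N(0, 1) only for variants inside the causal
  type's specific peaks, scaled so genetics explains half the discovery
  phenotype variance; reported effects and p-values come from an actual
  per-variant marginal regression on the simulated discovery cohort, so
  LD-induced associations at non-causal variants are present, as in real
  GWAS.
* **Phenotype.**  The standardized C+T PRS of the target cohort restricted
  to the causal peaks (p = 0.5, r² = 0.1, recorded in the truth file),
  plus ε ~ N(0, σ²); σ is the noise ladder.  The phenotype is not
  re-standardized after adding noise.  A median split yields binary labels
  for the classification pathway.  A peak-noise fraction replaces causal
  peaks with other types' specific peaks before scoring.

What the simulation does **not** emulate: realistic human LD maps,
population structure, batch effects in the atlas, covariate confounding,
sex chromosomes.  Passing tests demonstrate that the pipeline recovers
planted cell-level signal under the stated generative model, not
performance on any real cohort.

The negative-control ablation removes every causal-type cell from the
reference atlas, plus any other cell whose open causal-peak count exceeds
a threshold (default 1 of the 40 causal peaks, i.e. a few percent —
proportional to excluding cells carrying more than a small fraction of
the causal program).  The residual performance after ablation comes from
leak accessibility and LD tagging, which is why it degrades rather than
vanishes.

## Problem sizes

The documented generator default is 600 target / 4,000 discovery
individuals, 5,000 variants on 5 chromosomes and 1,500 cells in four
types.  The reproduction protocols (test suite and
`scripts/acceptance.py`) run a compact version — 300 target / 2,500
discovery, 1,200 variants on 3 chromosomes, 240 cells, 40 specific and 40
shared peaks per type — chosen so the ensemble protocols (20-model
ensembles over 10 seeds, 5-seed noise ladders) complete quickly on a
single CPU while preserving every structural property: per-cell candidate
sets still differ through dropout, the 250-kb window still spans dozens of
variants, and cell types still separate in the LSI embedding.

## Known limitations

* The optimizer is exactly reproducible but single-threaded NumPy; very
  large atlases (10⁵ cells) would want the same model in a tensor
  framework.
* In-sample LD with missing dosages uses pairwise-complete correlation,
  which can be slightly indefinite as a matrix; it is only ever used
  entrywise for clumping.
* The DA likelihood-ratio test treats cells as independent; with strong
  per-sample batch structure a mixed model would be more conservative.
* `combine_multi_celltype` fits an unpenalized logistic model; with many
  cell types × 21 settings it may need regularization on real data.
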