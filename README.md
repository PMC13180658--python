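# scprs — single-cell-resolved polygenic risk scoring

Standard polygenic risk scores (PRS) collapse a genome's worth of GWAS
signal into one number per person, discarding *where* in the body that risk
acts.  `scprs` decomposes a clumping+thresholding (C+T) PRS into
**per-cell** risk scores conditioned on single-cell chromatin accessibility
(scATAC-seq), learns to combine them with a small nonnegativity-constrained
graph network over a cell–cell similarity graph, and reads the learned
per-cell coefficients back out to prioritize disease-relevant cells, cell
types, regulatory elements and variants.  It is aimed at statistical
geneticists and single-cell biologists who have GWAS summary statistics, a
genotyped target cohort and a reference scATAC-seq atlas.

## The model

For individual *n*, a conditioned C+T PRS is computed for every reference
cell *j*: the clumping **index variants are restricted to variants inside
peaks open in cell j**, over a grid of 3 LD thresholds
(r² ∈ {0.1, 0.3, 0.5}, 250-kb window) × 7 p-value cutoffs
(10⁻⁵ … 0.5), giving features X_n ∈ ℝ^{M×21}:

    PRS_j = Σ_{i ∈ peaks(j)} β_i · G_i / (P · M)

with β_i the GWAS effect size, G_i the effect-allele dosage, P = 2 the
ploidy and M the individual's nonmissing scored variants.

Cells are embedded by LSI (TF-IDF + truncated SVD) and joined into a
mutual-kNN graph G = Ĝ ∘ Ĝᵀ.  The network is

    h⁽⁰⁾ = X_n · abs(W₀)
    g_v⁽ᵗ⁺¹⁾ = (1/deg v) Σ_{u∈N(v)} ( abs(w₁⁽ᵗ⁾) h_u⁽ᵗ⁾ + abs(w₂⁽ᵗ⁾) h_v⁽ᵗ⁾ )
    h⁽ᵗ⁺¹⁾ = LeakyReLU₀.₁(g⁽ᵗ⁺¹⁾)
    ŷ = σ( β·h⁽ᵀ⁾ + b )

trained with Adam (lr 10⁻³, batch 32, 200 epochs) on

    L = BCE(ŷ, y)  +  λ₁‖β‖₁  +  λ₂‖β‖₂²  +  λ₃ βᵀ G_L β

(mean squared error for quantitative traits), where G_L is the symmetric
normalized graph Laplacian.  Because every weight on the path from X to
h⁽ᵀ⁾ is abs-reparameterized, the latent map is **monotone**: a larger cell
weight β_m genuinely means more genetic risk concentrated in cell *m*.
Cells are then prioritized by training an ensemble of models differing only
in seed and testing each cell's β distribution against the pooled top-15%
weights (one-sided Welch t-test, Benjamini–Yekutieli < 0.1); cell types are
tested for enrichment of prioritized cells (one-sided Fisher, BH < 0.1).

A coupled simulation module generates block-LD genotypes from haplotype
pools, a cell atlas with type-specific peaks, marginal-regression GWAS
summary statistics from a simulated discovery cohort and phenotypes built
as standardized peak-restricted PRS plus Gaussian noise — so the entire
pipeline is testable offline.

## Worked example

```python
import numpy as np
from scprs.workflows import (default_sim_config, prepare_features,
                             recovery_run)

out = recovery_run(seed=1, sigma=0.25, n_models=20)
print(out["types"][["cell_type", "selected_in", "odds_ratio", "adj_p"]])
print("weight AUC:", round(out["weight_auc"], 3))
```

prints (seed 1):

```
cell_type  selected_in  odds_ratio    adj_p
    type0            8         inf 0.000042
    type1            0         0.0 1.000000
    type2            0         0.0 1.000000
    type3            0         0.0 1.000000
weight AUC: 0.989
```

All 8 prioritized cells fall in the causal cell type (`type0`, the type
whose specific peaks carry the simulated genetic effects), its Fisher
enrichment survives BH correction by three orders of magnitude, and
ranking cells by mean ensemble weight separates causal-type cells from the
rest with AUC 0.989.

The same pipeline is scriptable from the shell:

```bash
scprs simulate --seed 1 --out fixtures/run1
scprs qc-sumstats --sumstats fixtures/run1/sumstats.tsv --out ss.tsv
scprs harmonize --sumstats ss.tsv --genotypes fixtures/run1/genotypes.vcf \
      --out-sumstats ss2.tsv --out-genotypes geno.tsv
scprs compute-prs --genotypes geno.tsv --sumstats ss2.tsv \
      --mtx fixtures/run1/matrix.mtx --peaks fixtures/run1/peaks.bed \
      --barcodes fixtures/run1/barcodes.tsv --out tensor.npz
scprs build-graph --mtx fixtures/run1/matrix.mtx --peaks fixtures/run1/peaks.bed \
      --barcodes fixtures/run1/barcodes.tsv --k 25 --out graph.npz
scprs train --tensor tensor.npz --graph graph.npz \
      --labels fixtures/run1/phenotype.tsv --task regression --out fit.npz
```

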