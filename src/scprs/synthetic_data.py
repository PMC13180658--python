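"""Coupled genotype / GWAS / cell-atlas / phenotype simulation.

The generator reproduces the statistical structure the method assumes so the
whole pipeline is testable offline:

* genotypes are drawn from a per-chromosome haplotype pool with random
  recombination breakpoints, giving realistic local LD: the pool size sets
  LD strength and the crossover density sets its decay length, chosen so
  correlation fades over a few hundred kb as in human data;
* a cell atlas assigns each cell type a private set of specific peaks plus
  peaks shared by all types, with cross-type leak accessibility and
  independent dropout;
* GWAS summary statistics come from an actual marginal regression on a
  simulated discovery cohort whose phenotype is driven by variants inside
  the causal cell type's specific peaks, so LD-induced non-causal
  associations exist exactly as in real GWAS;
* the target phenotype is the standardized peak-restricted C+T PRS of the
  target cohort plus Gaussian noise, y~ = y + eps with eps ~ N(0, sigma^2);
  a peak-noise fraction can replace causal peaks by other types' specific
  peaks, and a median split yields binary labels for classification runs.

Every operation is deterministic given the configured seed.
"""

from __future__ import annotations

import os
import shutil
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .cell_prs import CTParams, clump, ct_prs, ld_r2
from .io_harmonize import (CellPeakMatrix, GenotypeMatrix, PeakSet,
                           SumstatsTable, assign_variants_to_peaks)

VARIANT_SPACING = 5_000  # bp between adjacent simulated variants
ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass
class SimConfig:
    """Study conditions for the simulation.

    Defaults describe a small but structured cohort: four cell types with
    private accessibility programs, a discovery GWAS several times larger
    than the target cohort, and a phenotype that is a standardized
    peak-restricted PRS plus Gaussian noise.
    """

    n_target: int = 600
    n_discovery: int = 4_000
    n_variants: int = 5_000
    n_chromosomes: int = 5
    haplotype_pool_size: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    recomb_per_chrom: float = 12.0  # mean crossovers per gamete per chromosome
    missing_rate: float = 0.002
    n_cells: int = 1_500
    cell_types: tuple[str, ...] = ("type0", "type1", "type2", "type3")
    specific_peaks_per_type: int = 60
    shared_peaks: int = 60
    peak_width: int = 500
    p_specific_on: float = 0.85   # accessibility of own-type specific peaks
    p_specific_off: float = 0.08  # leak accessibility of other types' peaks
    p_shared_on: float = 0.9
    dropout_rate: float = 0.15
    causal_type: str = "type0"
    effect_scale: float = 0.5     # heritability-like share of discovery variance
    sigma: float = 0.25           # phenotype noise s.d. (y is standardized)
    peak_noise_frac: float = 0.0
    phenotype_ct: tuple[float, float] = (0.5, 0.1)  # (p, r2) for scoring
    seed: int = 0

    def __post_init__(self):
        for frac in (self.missing_rate, self.dropout_rate,
                     self.peak_noise_frac, self.p_specific_on,
                     self.p_specific_off, self.p_shared_on,
                     self.effect_scale):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.causal_type not in self.cell_types:
            raise ValueError(f"causal_type {self.causal_type!r} not among "
                             f"cell_types {self.cell_types}")
        for count in (self.n_target, self.n_discovery, self.n_variants,
                      self.n_chromosomes, self.haplotype_pool_size,
                      self.n_cells, self.peak_width):
            if count <= 0:
                raise ValueError("counts must be positive")


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    causal_type: str
    causal_peak_ids: list[str]
    scoring_peak_ids: list[str]
    specific_peaks: dict[str, list[str]]
    shared_peak_ids: list[str]
    beta_true: np.ndarray
    causal_variant_idx: np.ndarray
    phenotype_ct: tuple[float, float]
    seed: int
    extras: dict = field(default_factory=dict)


def _variant_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = cfg.n_variants // cfg.n_chromosomes
    counts = [per_chrom] * cfg.n_chromosomes
    counts[-1] += cfg.n_variants - per_chrom * cfg.n_chromosomes
    rows = []
    for c, m in enumerate(counts, start=1):
        for i in range(m):
            ref, alt = ALLELE_PAIRS[rng.integers(len(ALLELE_PAIRS))]
            rows.append((str(c), (i + 1) * VARIANT_SPACING, ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def sim_genotypes(cfg: SimConfig, n_individuals: int | None = None,
                  rng: np.random.Generator | None = None,
                  variants: pd.DataFrame | None = None,
                  missing_rate: float | None = None
                  ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Haplotype-pool genotypes with block LD.

    Each chromosome has a pool of ``haplotype_pool_size`` haplotypes; every
    individual draws two mosaic haplotypes with Poisson(1) recombination
    breakpoints per chromosome.  Returns the genotype matrix and the
    realized pool minor-allele frequencies ("true MAFs").
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = n_individuals if n_individuals is not None else cfg.n_target
    variants = variants if variants is not None else _variant_table(cfg, rng)
    miss = cfg.missing_rate if missing_rate is None else missing_rate
    chroms = variants["chrom"].to_numpy()
    dosage = np.empty((n, len(variants)))
    true_maf = np.empty(len(variants))
    H = cfg.haplotype_pool_size
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        m = idx.size
        freqs = rng.uniform(*cfg.maf_range, size=m)
        pool = (rng.random((H, m)) < freqs).astype(np.int8)
        pf = pool.mean(axis=0)
        true_maf[idx] = np.minimum(pf, 1.0 - pf)
        hap = np.empty((2 * n, m), dtype=np.int8)
        for h in range(2 * n):
            n_bp = rng.poisson(cfg.recomb_per_chrom)
            bps = np.sort(rng.integers(1, m, size=n_bp)) if n_bp else []
            bounds = [0, *bps, m]
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b > a:
                    hap[h, a:b] = pool[rng.integers(H), a:b]
        dosage[:, idx] = (hap[0::2] + hap[1::2]).astype(float)
    if miss > 0:
        mask = rng.random(dosage.shape) < miss
        dosage[mask] = np.nan
    g = GenotypeMatrix(
        sample_ids=np.asarray([f"S{i:05d}" for i in range(n)], dtype=object),
        variants=variants.reset_index(drop=True), dosages=dosage)
    return g, true_maf


def sim_cell_atlas(cfg: SimConfig, variants: pd.DataFrame,
                   rng: np.random.Generator | None = None
                   ) -> tuple[CellPeakMatrix, dict]:
    """Cell atlas with type-specific and shared peaks anchored on variants.

    Peaks are non-overlapping ``peak_width`` windows each containing at
    least one variant.  A cell of type t opens its own specific peaks with
    probability ``p_specific_on``, other types' with ``p_specific_off`` and
    shared peaks with ``p_shared_on``; accessibility then suffers
    independent dropout.  Counts are small positive integers.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    w = cfg.peak_width
    n_types = len(cfg.cell_types)
    n_needed = cfg.shared_peaks + n_types * cfg.specific_peaks_per_type
    # candidate windows: snap each variant to its grid cell, dedupe
    grid = {}
    for i, (c, p) in enumerate(zip(variants["chrom"], variants["pos"])):
        key = (c, (p - 1) // w)
        grid.setdefault(key, []).append(i)
    keys = sorted(grid.keys())
    if len(keys) < n_needed:
        raise ValueError(f"only {len(keys)} candidate peak windows for "
                         f"{n_needed} peaks; increase n_variants")
    chosen = rng.choice(len(keys), size=n_needed, replace=False)
    chosen_keys = [keys[i] for i in sorted(chosen)]
    peak_rows = [(c, gidx * w, gidx * w + w, f"peak_{j:05d}")
                 for j, (c, gidx) in enumerate(chosen_keys)]
    peaks = PeakSet(pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "peak_id"]))
    order = rng.permutation(n_needed)
    shared_ids = order[:cfg.shared_peaks]
    specific: dict[str, np.ndarray] = {}
    ofs = cfg.shared_peaks
    for t in cfg.cell_types:
        specific[t] = order[ofs:ofs + cfg.specific_peaks_per_type]
        ofs += cfg.specific_peaks_per_type

    per_type = cfg.n_cells // n_types
    counts = [per_type] * n_types
    counts[-1] += cfg.n_cells - per_type * n_types
    labels = np.concatenate([[t] * c for t, c in zip(cfg.cell_types, counts)])
    prob = np.full((cfg.n_cells, n_needed), cfg.p_specific_off)
    prob[:, shared_ids] = cfg.p_shared_on
    for t in cfg.cell_types:
        rows = np.flatnonzero(labels == t)
        prob[np.ix_(rows, specific[t])] = cfg.p_specific_on
    open_ = rng.random(prob.shape) < prob
    open_ &= rng.random(prob.shape) >= cfg.dropout_rate
    vals = np.where(open_, 1 + rng.poisson(0.5, size=prob.shape), 0)
    cpm = CellPeakMatrix(
        barcodes=np.asarray([f"C{i:05d}" for i in range(cfg.n_cells)],
                            dtype=object),
        peaks=peaks, matrix=sparse.csr_matrix(vals),
        cell_types=np.asarray(labels, dtype=object))
    truth = {"specific": {t: sorted(int(i) for i in specific[t])
                          for t in cfg.cell_types},
             "shared": sorted(int(i) for i in shared_ids)}
    return cpm, truth


def sim_gwas(cfg: SimConfig, discovery: GenotypeMatrix,
             causal_variant_idx: np.ndarray,
             rng: np.random.Generator | None = None
             ) -> tuple[SumstatsTable, np.ndarray]:
    """Marginal-regression GWAS on a simulated discovery cohort.

    True effects beta* ~ N(0, 1) at ``causal_variant_idx`` (zero elsewhere)
    are scaled so the genetic component explains ``effect_scale`` of the
    discovery phenotype variance; per-variant simple linear regression
    yields reported effect sizes and p-values, so LD leakage to non-causal
    variants is present.  Returns (summary statistics, beta*).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    G = np.nan_to_num(discovery.dosages)
    n, m = G.shape
    beta_true = np.zeros(m)
    causal = np.asarray(causal_variant_idx, dtype=int)
    if causal.size and cfg.effect_scale > 0:
        beta_true[causal] = rng.normal(size=causal.size)
        gcomp = G @ beta_true
        s = gcomp.std()
        if s > 0:
            scale = np.sqrt(cfg.effect_scale) / s
            beta_true *= scale
            gcomp *= scale
        noise_sd = np.sqrt(max(1.0 - cfg.effect_scale, 1e-12))
    else:
        gcomp = np.zeros(n)
        noise_sd = 1.0
    y = gcomp + rng.normal(scale=noise_sd, size=n)

    # vectorized per-variant OLS: y = a + b g
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    var_g = (gc * gc).sum(axis=0)
    var_g[var_g == 0] = np.nan
    bhat = gc.T @ yc / var_g
    resid_ss = (yc @ yc) - bhat * (gc.T @ yc)
    se = np.sqrt(np.maximum(resid_ss, 0) / (n - 2) / var_g)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = bhat / se
    from scipy.stats import t as tdist
    pval = 2 * tdist.sf(np.abs(tstat), df=n - 2)
    pval = np.clip(np.nan_to_num(pval, nan=1.0), np.finfo(float).tiny, 1.0)
    bhat = np.nan_to_num(bhat)
    af = G.mean(axis=0) / 2.0
    df = discovery.variants.copy()
    df["effect_allele"] = df["alt"]
    df["beta"] = bhat
    df["pval"] = pval
    df["maf"] = np.minimum(af, 1 - af)
    df["info"] = 1.0
    return SumstatsTable(df=df.reset_index(drop=True),
                         source="simulated_discovery_gwas"), beta_true


def sim_phenotype(g: GenotypeMatrix, s: SumstatsTable, peaks: PeakSet,
                  causal_peak_idx, other_specific_idx, sigma: float,
                  peak_noise_frac: float, seed: int,
                  ld=None, phenotype_ct: tuple[float, float] = (0.5, 0.1)
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Standardized peak-restricted C+T PRS phenotype plus Gaussian noise.

    The scoring peak set is the causal peaks with a ``peak_noise_frac``
    fraction replaced by randomly chosen other-type-specific peaks.  The
    noiseless phenotype y is the C+T PRS (index candidates restricted to the
    scoring peaks; (p, r2) = ``phenotype_ct``) standardized to mean 0,
    variance 1; the observed phenotype is y~ = y + eps, eps ~ N(0, sigma^2)
    (not re-standardized).  Returns (y~, y, binary labels from a median
    split of y~, scoring peak indices).
    """
    rng = np.random.default_rng(seed)
    causal = list(map(int, causal_peak_idx))
    others = list(map(int, other_specific_idx))
    n_swap = int(round(peak_noise_frac * len(causal)))
    scoring = list(causal)
    if n_swap > 0:
        drop = rng.choice(len(scoring), size=n_swap, replace=False)
        keep = [pidx for i, pidx in enumerate(scoring) if i not in set(drop)]
        add = rng.choice(others, size=min(n_swap, len(others)),
                         replace=False).tolist()
        scoring = keep + [int(a) for a in add]
    if not scoring:
        raise ValueError("empty scoring peak set")
    sub = PeakSet(peaks.df.iloc[sorted(scoring)].reset_index(drop=True))
    membership = assign_variants_to_peaks(s, sub)
    cand = np.asarray(sorted(membership.keys()), dtype=int)
    if cand.size == 0:
        raise ValueError("no variants fall in the scoring peak set")
    p_thr, r2_thr = phenotype_ct
    if ld is None:
        ld = ld_r2(g)
    idx = clump(s, ld, cand, CTParams(p_thresh=p_thr, r2_thresh=r2_thr))
    raw = ct_prs(g, s, idx)
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate phenotype: zero-variance PRS")
    y = (raw - raw.mean()) / sd
    y_obs = y + rng.normal(scale=sigma, size=len(y))
    labels = (y_obs > np.median(y_obs)).astype(int)
    return y_obs, y, labels, sorted(scoring)


# ---------------------------------------------------------------------------
# fixture serialization
# ---------------------------------------------------------------------------

def _write_vcf(path, g: GenotypeMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.variants["chrom"]):
            maxpos = int(g.variants.loc[g.variants["chrom"] == chrom,
                                        "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 10_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.sample_ids)) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in g.variants.iterrows():
            gts = []
            for v in g.dosages[:, j]:
                gts.append("./." if np.isnan(v) else code[int(round(v))])
            fh.write(f"{row['chrom']}\t{row['pos']}\tv{j}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
                     + "\n")


def make_fixture(cfg: SimConfig, out_dir) -> dict:
    """Generate and serialize a complete simulation bundle.

    Writes genotypes.vcf, sumstats.tsv, peaks.bed, matrix.mtx +
    barcodes.tsv + labels.tsv, phenotype.tsv and truth.yaml into
    ``out_dir``; all files round-trip through the readers with zero
    configuration, and the same config + seed yields byte-identical output.
    On a partial write the directory is removed.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    try:
        bundle = simulate(cfg)
        g, s, cpm = bundle["target"], bundle["sumstats"], bundle["atlas"]
        _write_vcf(os.path.join(out_dir, "genotypes.vcf"), g)
        s.df.to_csv(os.path.join(out_dir, "sumstats.tsv"), sep="\t",
                    index=False, float_format="%.10g")
        cpm.peaks.df.to_csv(os.path.join(out_dir, "peaks.bed"), sep="\t",
                            index=False, header=False)
        spio.mmwrite(os.path.join(out_dir, "matrix.mtx"),
                     sparse.coo_matrix(cpm.matrix), field="integer")
        with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(map(str, cpm.barcodes)) + "\n")
        pd.DataFrame({"barcode": cpm.barcodes,
                      "cell_type": cpm.cell_types}).to_csv(
            os.path.join(out_dir, "labels.tsv"), sep="\t", index=False)
        pd.DataFrame({"sample_id": g.sample_ids,
                      "phenotype": bundle["y_obs"],
                      "phenotype_noiseless": bundle["y_true"],
                      "label": bundle["labels"]}).to_csv(
            os.path.join(out_dir, "phenotype.tsv"), sep="\t", index=False,
            float_format="%.10g")
        truth: SimTruth = bundle["truth"]
        with open(os.path.join(out_dir, "truth.yaml"), "w") as fh:
            yaml.safe_dump(
                {"causal_type": truth.causal_type,
                 "causal_peak_ids": truth.causal_peak_ids,
                 "scoring_peak_ids": truth.scoring_peak_ids,
                 "shared_peak_ids": truth.shared_peak_ids,
                 "specific_peaks": truth.specific_peaks,
                 "beta_true": [float(b) for b in truth.beta_true],
                 "causal_variant_idx": [int(i) for i in
                                        truth.causal_variant_idx],
                 "phenotype_ct": list(truth.phenotype_ct),
                 "seed": truth.seed},
                fh, sort_keys=True)
    except Exception:
        shutil.rmtree(out_dir, ignore_errors=True)
        raise
    return {"dir": out_dir,
            "genotypes": os.path.join(out_dir, "genotypes.vcf"),
            "sumstats": os.path.join(out_dir, "sumstats.tsv"),
            "peaks": os.path.join(out_dir, "peaks.bed"),
            "matrix": os.path.join(out_dir, "matrix.mtx"),
            "barcodes": os.path.join(out_dir, "barcodes.tsv"),
            "labels": os.path.join(out_dir, "labels.tsv"),
            "phenotype": os.path.join(out_dir, "phenotype.tsv"),
            "truth": os.path.join(out_dir, "truth.yaml")}


def simulate(cfg: SimConfig) -> dict:
    """Run the full generative chain in memory.

    Returns a dict with the target GenotypeMatrix, SumstatsTable (from the
    discovery cohort), CellPeakMatrix atlas, phenotypes, labels and a
    SimTruth record.
    """
    rng = np.random.default_rng(cfg.seed)
    variants = _variant_table(cfg, rng)
    target, true_maf = sim_genotypes(
        cfg, cfg.n_target, np.random.default_rng(cfg.seed * 7 + 1),
        variants=variants)
    discovery, _ = sim_genotypes(
        cfg, cfg.n_discovery, np.random.default_rng(cfg.seed * 7 + 2),
        variants=variants, missing_rate=0.0)
    cpm, peak_truth = sim_cell_atlas(
        cfg, variants, np.random.default_rng(cfg.seed * 7 + 3))
    causal_peaks = peak_truth["specific"][cfg.causal_type]
    other_specific = sorted(
        i for t, ids in peak_truth["specific"].items()
        if t != cfg.causal_type for i in ids)
    causal_sub = PeakSet(
        cpm.peaks.df.iloc[causal_peaks].reset_index(drop=True))
    stab = SumstatsTable(df=variants.assign(
        effect_allele=variants["alt"], beta=0.0, pval=1.0, maf=0.0,
        info=1.0))
    causal_membership = assign_variants_to_peaks(stab, causal_sub)
    causal_variant_idx = np.asarray(sorted(causal_membership.keys()),
                                    dtype=int)
    sumstats, beta_true = sim_gwas(
        cfg, discovery, causal_variant_idx,
        np.random.default_rng(cfg.seed * 7 + 4))
    ld = ld_r2(target)
    y_obs, y_true, labels, scoring = sim_phenotype(
        target, sumstats, cpm.peaks, causal_peaks, other_specific,
        cfg.sigma, cfg.peak_noise_frac, seed=cfg.seed * 7 + 5, ld=ld,
        phenotype_ct=cfg.phenotype_ct)
    pid = cpm.peaks.df["peak_id"]
    truth = SimTruth(
        causal_type=cfg.causal_type,
        causal_peak_ids=[pid.iloc[i] for i in sorted(causal_peaks)],
        scoring_peak_ids=[pid.iloc[i] for i in scoring],
        specific_peaks={t: [pid.iloc[i] for i in ids]
                        for t, ids in peak_truth["specific"].items()},
        shared_peak_ids=[pid.iloc[i] for i in peak_truth["shared"]],
        beta_true=beta_true, causal_variant_idx=causal_variant_idx,
        phenotype_ct=cfg.phenotype_ct, seed=cfg.seed,
        extras={"true_maf": true_maf,
                "causal_peak_idx": sorted(int(i) for i in causal_peaks),
                "other_specific_idx": other_specific,
                "scoring_peak_idx": scoring})
    return {"config": cfg, "target": target, "discovery": discovery,
            "sumstats": sumstats, "atlas": cpm, "ld": ld,
            "y_obs": y_obs, "y_true": y_true, "labels": labels,
            "truth": truth, "true_maf": true_maf}
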