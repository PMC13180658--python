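"""Reading, quality control and allele harmonization of PRS inputs.

Inputs are GWAS summary statistics (delimited text), target-cohort genotypes
(VCF with GT calls, or a dosage TSV), and a reference single-cell chromatin
accessibility dataset (MatrixMarket cell-by-peak counts plus BED peak
intervals, a barcode list and optional cell-type labels).

Conventions fixed here and relied on everywhere else:

* variant positions are 1-based (VCF convention);
* peak intervals are 0-based half-open (BED convention); a variant at
  1-based position ``q`` falls in peak ``[start, end)`` iff
  ``start <= q - 1 < end``;
* chromosome names are normalized by stripping a leading ``chr`` prefix;
* after :func:`harmonize_alleles`, genotype dosages count copies of the
  summary-statistics effect allele, so a dosage can be multiplied by the
  reported effect size directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import io as spio
from scipy import sparse
from scipy.stats import chi2

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical summary-statistics column names
SUMSTATS_COLUMNS = ("chrom", "pos", "ref", "alt", "effect_allele",
                    "beta", "pval", "maf", "info")


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class SumstatsTable:
    """Per-variant GWAS summary statistics.

    ``df`` columns: chrom, pos (1-based), ref, alt, effect_allele, beta,
    pval in (0, 1], maf in [0, 0.5], info in [0, 1] (NaN when unavailable).
    """

    df: pd.DataFrame
    source: str = ""
    build: str = ""
    n_malformed: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> pd.Index:
        d = self.df
        return pd.Index(list(zip(d["chrom"], d["pos"], d["ref"], d["alt"])))


@dataclass
class GenotypeMatrix:
    """Individuals x variants diploid dosage matrix; NaN marks missing calls.

    ``variants`` columns: chrom, pos, ref, alt.  Dosages count copies of the
    ALT allele as read; :func:`harmonize_alleles` re-expresses them as
    effect-allele counts.
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """In-cohort minor-allele frequency per variant (missing-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            af = np.nanmean(self.dosages, axis=0) / 2.0
        af = np.nan_to_num(af)
        return np.minimum(af, 1.0 - af)


@dataclass
class PeakSet:
    """Accessibility peak intervals, 0-based half-open, with stable ids."""

    df: pd.DataFrame  # columns: chrom, start, end, peak_id

    def __post_init__(self) -> None:
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            row = self.df[bad].iloc[0]
            raise ValueError(
                f"zero- or negative-length peak interval "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CellPeakMatrix:
    """Sparse cells x peaks accessibility counts with barcodes and labels."""

    barcodes: np.ndarray
    peaks: PeakSet
    matrix: sparse.csr_matrix
    cell_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_cells, n_peaks = self.matrix.shape
        if n_cells != len(self.barcodes) or n_peaks != len(self.peaks):
            raise ValueError(
                f"dimension mismatch: matrix {self.matrix.shape}, "
                f"{len(self.barcodes)} barcodes, {len(self.peaks)} peaks"
            )
        if self.matrix.size and self.matrix.data.min() < 0:
            raise ValueError("accessibility counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path, column_map: dict | None = None, source: str = "",
                  build: str = "") -> SumstatsTable:
    """Read GWAS summary statistics from delimited text.

    ``column_map`` maps canonical names (``chrom``, ``pos``, ``ref``, ``alt``,
    ``effect_allele``, ``beta``, ``pval``; optionally ``maf``, ``info``) to
    the file's column names.  Rows with unparseable beta/p, p outside (0, 1]
    or maf outside [0, 0.5] are rejected and counted.  Duplicate keys are
    retained here (they are handled by :func:`qc_sumstats`).
    """
    column_map = column_map or {}
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = ["chrom", "pos", "ref", "alt", "beta", "pval"]
    rename = {column_map.get(k, k): k for k in SUMSTATS_COLUMNS
              if column_map.get(k, k) in raw.columns}
    raw = raw.rename(columns=rename)
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise KeyError(f"missing required sumstats column(s): {missing}")

    df = pd.DataFrame({
        "chrom": raw["chrom"].map(_norm_chrom),
        "pos": pd.to_numeric(raw["pos"], errors="coerce"),
        "ref": raw["ref"].str.upper(),
        "alt": raw["alt"].str.upper(),
        "beta": pd.to_numeric(raw["beta"], errors="coerce"),
        "pval": pd.to_numeric(raw["pval"], errors="coerce"),
    })
    df["effect_allele"] = (raw["effect_allele"].str.upper()
                           if "effect_allele" in raw.columns else df["alt"])
    df["maf"] = (pd.to_numeric(raw["maf"], errors="coerce")
                 if "maf" in raw.columns else np.nan)
    df["info"] = (pd.to_numeric(raw["info"], errors="coerce")
                  if "info" in raw.columns else np.nan)

    ok = (
        df["pos"].notna() & (df["pos"] >= 1)
        & df["beta"].notna()
        & df["pval"].notna() & (df["pval"] > 0) & (df["pval"] <= 1)
        & ((df["effect_allele"] == df["ref"]) | (df["effect_allele"] == df["alt"]))
        & (df["maf"].isna() | ((df["maf"] >= 0) & (df["maf"] <= 0.5)))
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("read_sumstats: rejected %d malformed row(s)", n_bad)
    df = df[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    return SumstatsTable(df=df, source=source or str(path), build=build,
                         n_malformed=n_bad)


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    """A/T and C/G pairs cannot be resolved by strand flipping."""
    return COMPLEMENT.get(ref) == alt


def qc_sumstats(t: SumstatsTable, maf_min: float = 0.001,
                info_min: float = 0.6,
                drop_ambiguous: bool = True) -> SumstatsTable:
    """Filter summary statistics on MAF, imputation INFO and allele sanity.

    Removes variants with maf < ``maf_min`` or info < ``info_min``, every row
    of any duplicated (chrom, pos, ref, alt) key, and strand-ambiguous A/T
    and C/G pairs when ``drop_ambiguous``.  The INFO filter is skipped with a
    notice when the column is entirely absent (e.g. sequenced cohorts).
    """
    df = t.df
    keep = np.ones(len(df), dtype=bool)
    if df["maf"].notna().any():
        keep &= ~(df["maf"] < maf_min).to_numpy()
    if df["info"].notna().any():
        keep &= ~(df["info"] < info_min).to_numpy()
    else:
        logger.info("qc_sumstats: INFO column absent; imputation filter skipped")
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"], keep=False)
    keep &= ~dup.to_numpy()
    if drop_ambiguous:
        amb = np.fromiter(
            (is_strand_ambiguous(r, a) for r, a in zip(df["ref"], df["alt"])),
            dtype=bool, count=len(df))
        keep &= ~amb
    out = df[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no variants survive summary-statistics QC")
    return SumstatsTable(df=out, source=t.source, build=t.build,
                         n_malformed=t.n_malformed, meta=dict(t.meta))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf",
                   split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read diploid genotypes as ALT-allele dosages.

    VCF: GT 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing.  Multiallelic
    records are rejected (dropped with a warning) unless
    ``split_multiallelic``, in which case one row per ALT allele is emitted.
    Dosage TSV: columns chrom, pos, ref, alt then one column per sample;
    entries 0/1/2 or NA.
    """
    if format == "dosage_tsv":
        raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta_cols = ["chrom", "pos", "ref", "alt"]
        samples = [c for c in raw.columns if c not in meta_cols]
        variants = raw[meta_cols].copy()
        variants["chrom"] = variants["chrom"].map(_norm_chrom)
        dosages = raw[samples].to_numpy(dtype=float).T
        if np.nanmax(dosages, initial=0.0) > 2 or np.nanmin(dosages, initial=0.0) < 0:
            raise ValueError("dosages must lie in [0, 2]")
        return GenotypeMatrix(sample_ids=np.asarray(samples, dtype=object),
                              variants=variants.reset_index(drop=True),
                              dosages=dosages)
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}")

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    rows, cols = [], []
    n_multi = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 and not split_multiallelic:
            n_multi += 1
            continue
        gts = rec.genotypes  # [a0, a1, phased] per sample
        for g in gts:
            if len(g) != 3:
                raise ValueError(
                    f"non-diploid genotype at {rec.CHROM}:{rec.POS}")
        for ai, alt in enumerate(alts, start=1):
            dose = np.empty(len(samples))
            for si, g in enumerate(gts):
                a0, a1 = g[0], g[1]
                if a0 < 0 or a1 < 0:
                    dose[si] = np.nan
                else:
                    dose[si] = (a0 == ai) + (a1 == ai)
            rows.append((_norm_chrom(rec.CHROM), rec.POS, rec.REF, alt))
            cols.append(dose)
    if n_multi:
        logger.warning("read_genotypes: rejected %d multiallelic record(s)",
                       n_multi)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = (np.stack(cols, axis=1) if cols
               else np.empty((len(samples), 0)))
    return GenotypeMatrix(sample_ids=samples, variants=variants,
                          dosages=dosages)


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Hardy-Weinberg equilibrium Pearson chi-square p-value (1 df)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(exp == 0):
        return 1.0  # monomorphic: no test
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, df=1))


def _qc_genotypes_once(g, miss_max, maf_min, hwe_pmin, sample_miss_max, het_sd):
    d = g.dosages
    n_s = d.shape[0]
    miss = np.isnan(d)
    vmiss = miss.mean(axis=0)
    maf = g.maf()
    hwe = np.ones(d.shape[1])
    rounded = np.round(d)
    for j in range(d.shape[1]):
        col = rounded[~miss[:, j], j]
        hwe[j] = hwe_chisq_p(int((col == 0).sum()), int((col == 1).sum()),
                             int((col == 2).sum()))
    vkeep = (vmiss <= miss_max) & (maf >= maf_min) & (hwe >= hwe_pmin)
    d = d[:, vkeep]
    variants = g.variants[vkeep].reset_index(drop=True)

    miss = np.isnan(d)
    smiss = miss.mean(axis=1) if d.shape[1] else np.zeros(n_s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        het = np.nanmean(np.round(d) == 1, axis=1) if d.shape[1] else np.zeros(n_s)
    het = np.nan_to_num(het)
    mu, sd = het.mean(), het.std()
    skeep = smiss <= sample_miss_max
    if sd > 0:
        skeep &= np.abs(het - mu) <= het_sd * sd
    if not skeep.any():
        raise ValueError("all samples removed by genotype QC")
    return GenotypeMatrix(sample_ids=g.sample_ids[skeep], variants=variants,
                          dosages=d[skeep], meta=dict(g.meta))


def qc_genotypes(g: GenotypeMatrix, miss_max: float = 0.01,
                 maf_min: float = 0.01, hwe_pmin: float = 1e-6,
                 sample_miss_max: float = 0.01,
                 het_sd: float = 3.0) -> GenotypeMatrix:
    """Variant- and sample-level genotype QC.

    Variants failing missingness (> ``miss_max``), MAF (< ``maf_min``) or a
    1-df Hardy-Weinberg chi-square test (p < ``hwe_pmin``) are removed; then
    samples with missingness above ``sample_miss_max`` or heterozygosity rate
    beyond ``het_sd`` standard deviations from the cohort mean are removed.
    The two passes are iterated to a fixed point so the operation is
    idempotent.
    """
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    prev_shape = None
    out = g
    while prev_shape != (out.n_samples, out.n_variants):
        prev_shape = (out.n_samples, out.n_variants)
        out = _qc_genotypes_once(out, miss_max, maf_min, hwe_pmin,
                                 sample_miss_max, het_sd)
    return out


def harmonize_alleles(s: SumstatsTable,
                      g: GenotypeMatrix) -> tuple[SumstatsTable, GenotypeMatrix]:
    """Intersect and allele-match summary statistics with target genotypes.

    Matching at each (chrom, pos): direct (same ref/alt), swapped (ref/alt
    exchanged), or strand-flipped (complementary alleles, either orientation).
    Output dosages count copies of the effect allele; the output genotype
    variant table is rewritten as (other allele, effect allele) so that a
    second harmonization is the identity.  Unresolvable sites are dropped;
    per-category counts are stored in ``meta['harmonize_report']``.
    """
    sdf = s.df.reset_index(drop=True)
    gkey = {(c, p): i for i, (c, p) in
            enumerate(zip(g.variants["chrom"], g.variants["pos"]))}
    s_idx, g_idx, flips, report = [], [], [], {
        "direct": 0, "swapped": 0, "strand_flipped": 0, "dropped": 0,
        "missing_in_genotypes": 0}
    for i, row in sdf.iterrows():
        j = gkey.get((row["chrom"], row["pos"]))
        if j is None:
            report["missing_in_genotypes"] += 1
            continue
        gref = g.variants.at[j, "ref"]
        galt = g.variants.at[j, "alt"]
        sref, salt = row["ref"], row["alt"]
        cref = COMPLEMENT.get(gref, "?")
        calt = COMPLEMENT.get(galt, "?")
        if (gref, galt) == (sref, salt):
            cat, alt_is = "direct", salt
        elif (gref, galt) == (salt, sref):
            cat, alt_is = "swapped", sref
        elif (cref, calt) == (sref, salt):
            cat, alt_is = "strand_flipped", salt
        elif (cref, calt) == (salt, sref):
            cat, alt_is = "strand_flipped", sref
        else:
            report["dropped"] += 1
            continue
        report[cat] += 1
        s_idx.append(i)
        g_idx.append(j)
        # dosage currently counts `alt_is`; reflect if effect allele differs
        flips.append(row["effect_allele"] != alt_is)
    if not s_idx:
        raise ValueError("no variants overlap between summary statistics "
                         "and genotypes")
    s_out = sdf.loc[s_idx].reset_index(drop=True)
    dos = g.dosages[:, g_idx].copy()
    flips = np.asarray(flips, dtype=bool)
    dos[:, flips] = 2.0 - dos[:, flips]
    eff = s_out["effect_allele"].to_numpy()
    other = np.where(eff == s_out["alt"].to_numpy(),
                     s_out["ref"].to_numpy(), s_out["alt"].to_numpy())
    g_var = pd.DataFrame({"chrom": s_out["chrom"].to_numpy(),
                          "pos": s_out["pos"].to_numpy(),
                          "ref": other, "alt": eff})
    logger.info("harmonize_alleles: %s", report)
    s_ret = SumstatsTable(df=s_out, source=s.source, build=s.build,
                          n_malformed=s.n_malformed,
                          meta={**s.meta, "harmonize_report": report})
    g_ret = GenotypeMatrix(sample_ids=g.sample_ids.copy(), variants=g_var,
                           dosages=dos,
                           meta={**g.meta, "harmonize_report": report})
    return s_ret, g_ret


# ---------------------------------------------------------------------------
# single-cell accessibility
# ---------------------------------------------------------------------------

def read_peaks_bed(path) -> PeakSet:
    """Read BED3+name peak intervals (name column optional)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln + 1}: {line!r}")
            chrom, start, end = _norm_chrom(parts[0]), int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"BED line {ln + 1}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else f"peak_{len(rows)}"
            rows.append((chrom, start, end, name))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                               "peak_id"]))


def read_cell_peak_matrix(mtx_path, peaks_bed, barcodes_path,
                          labels_path=None) -> CellPeakMatrix:
    """Assemble a cells x peaks matrix from MTX + BED + barcode (+ label) files.

    Orientation is auto-detected: if the stored matrix is peaks x cells it is
    transposed.  An irreconcilable dimension mismatch raises with all three
    counts named.
    """
    mat = sparse.csr_matrix(spio.mmread(str(mtx_path)))
    peaks = read_peaks_bed(peaks_bed)
    with open(barcodes_path) as fh:
        barcodes = np.asarray([ln.strip() for ln in fh if ln.strip()],
                              dtype=object)
    n_b, n_p = len(barcodes), len(peaks)
    if mat.shape == (n_b, n_p):
        pass
    elif mat.shape == (n_p, n_b):
        mat = sparse.csr_matrix(mat.T)
    else:
        raise ValueError(
            f"dimension mismatch: matrix {mat.shape}, {n_b} barcodes, "
            f"{n_p} peaks")
    cell_types = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        if "barcode" not in lab.columns:
            lab = pd.read_csv(labels_path, sep="\t", dtype=str, header=None,
                              names=["barcode", "cell_type"])
        mapping = dict(zip(lab["barcode"], lab["cell_type"]))
        missing = [b for b in barcodes if b not in mapping]
        if missing:
            raise ValueError(f"{len(missing)} barcode(s) missing a cell-type "
                             f"label, e.g. {missing[0]!r}")
        cell_types = np.asarray([mapping[b] for b in barcodes], dtype=object)
    return CellPeakMatrix(barcodes=barcodes, peaks=peaks, matrix=mat,
                          cell_types=cell_types)


def assign_variants_to_peaks(s: SumstatsTable, p: PeakSet) -> dict[int, list[int]]:
    """Map each variant (row index of ``s``) to the peak indices containing it.

    Variant at 1-based position q belongs to peak [start, end) iff
    start <= q - 1 < end.  Variants in no peak are absent from the map.
    """
    trees: dict[str, IntervalTree] = {}
    for j, (c, a, b) in enumerate(zip(p.df["chrom"], p.df["start"],
                                      p.df["end"])):
        trees.setdefault(_norm_chrom(c), IntervalTree()).addi(a, b, j)
    out: dict[int, list[int]] = {}
    for i, (c, q) in enumerate(zip(s.df["chrom"], s.df["pos"])):
        tree = trees.get(_norm_chrom(c))
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.at(q - 1))
        if hits:
            out[i] = hits
    return out


def membership_matrix(membership: dict[int, list[int]], n_variants: int,
                      n_peaks: int) -> sparse.csr_matrix:
    """Boolean variants x peaks indicator from an assignment map."""
    ii = [i for i, js in membership.items() for _ in js]
    jj = [j for js in membership.values() for j in js]
    return sparse.csr_matrix(
        (np.ones(len(ii), dtype=bool), (ii, jj)), shape=(n_variants, n_peaks))
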