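"""Variant-effect normalization and enrichment statistics.

These operations are model-agnostic consumers of per-variant accessibility
delta scores (alternative minus reference allele, from any sequence-based
accessibility predictor): Z standardizes the deltas, Q ranks |Z| as an
empirical quantile, and Fisher's exact tests quantify (i) the enrichment of
genome-wide-significant GWAS variants inside selected-cell peaks and (ii)
the concentration of high-|Z| variants inside disease-relevant regulatory
elements.  A covariate-adjusted logistic likelihood-ratio test identifies
peaks differentially accessible in prioritized cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .cell_prs import CTParams, LDMatrix, clump
from .io_harmonize import CellPeakMatrix, SumstatsTable

logger = logging.getLogger(__name__)


@dataclass
class VariantEffectTable:
    """Standardized variant effects per cell type.

    ``delta``, ``z`` and ``q`` are variants x cell-types DataFrames;
    Q in [0, 1] is the quantile rank of |Z| in the normalization pool.
    """

    delta: pd.DataFrame
    z: pd.DataFrame
    q: pd.DataFrame
    pool: str


@dataclass
class EnrichmentResult:
    table: np.ndarray        # 2x2 counts
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    alternative: str
    threshold: float | None = None
    degenerate: bool = False


def _fisher_with_ci(table: np.ndarray, alternative: str = "two-sided",
                    threshold: float | None = None) -> EnrichmentResult:
    a, b, c, d = table.ravel().astype(float)
    orr, p = stats.fisher_exact(table, alternative=alternative)
    degenerate = not np.isfinite(orr) or orr == 0 or 0 in (a, b, c, d)
    if degenerate:
        # Haldane-Anscombe correction for the point estimate and CI only
        ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        point = (ah * dh) / (bh * ch)
        se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    else:
        point = orr
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(point) - 1.96 * se))
    hi = float(np.exp(np.log(point) + 1.96 * se))
    if np.isinf(orr):
        hi = np.inf
    return EnrichmentResult(table=np.asarray(table), odds_ratio=float(point),
                            ci_low=lo, ci_high=hi, pvalue=float(p),
                            alternative=alternative, threshold=threshold,
                            degenerate=bool(degenerate))


def zq_scores(deltas: pd.DataFrame | np.ndarray,
              pool: str = "global") -> VariantEffectTable:
    """Z-standardize variant delta scores and rank |Z| as quantiles.

    ``pool='global'`` (default) computes the mean/s.d. and the quantile rank
    over all (variant, cell type) entries; ``pool='per_celltype'`` does both
    per column.  A constant input has zero spread: Z is defined as 0 there
    (all quantiles collapse), with a warning.
    """
    df = pd.DataFrame(deltas)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 variants")
    vals = df.to_numpy(dtype=float)
    if pool == "global":
        mu, sd = vals.mean(), vals.std()
        if sd == 0:
            logger.warning("zq_scores: constant deltas; Z set to 0")
            z = np.zeros_like(vals)
        else:
            z = (vals - mu) / sd
        flat = np.abs(z).ravel()
        ranks = stats.rankdata(flat, method="max") / flat.size
        q = ranks.reshape(z.shape)
    elif pool == "per_celltype":
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0)
        bad = sd == 0
        if bad.any():
            logger.warning("zq_scores: %d constant column(s); Z set to 0",
                           int(bad.sum()))
        z = np.where(bad, 0.0, (vals - mu) / np.where(bad, 1.0, sd))
        q = np.empty_like(z)
        for c in range(z.shape[1]):
            q[:, c] = stats.rankdata(np.abs(z[:, c]),
                                     method="max") / z.shape[0]
    else:
        raise ValueError("pool must be 'global' or 'per_celltype'")
    mk = lambda arr: pd.DataFrame(arr, index=df.index, columns=df.columns)
    return VariantEffectTable(delta=df, z=mk(z), q=mk(q), pool=pool)


def gwas_peak_enrichment(s: SumstatsTable, ld: LDMatrix,
                         peak_membership, gwas_sig: float = 5e-8,
                         clump_r2: float = 0.1,
                         window_kb: float = 250.0) -> EnrichmentResult:
    """Enrichment of genome-wide-significant variants inside given peaks.

    All variants are clumped (r^2 = ``clump_r2``) to an independent set;
    the 2x2 table crosses significance (p < ``gwas_sig``) with peak
    membership and is tested with a two-sided Fisher's exact test.
    """
    all_idx = np.arange(len(s.df))
    kept = clump(s, ld, all_idx, CTParams(p_thresh=1.0, r2_thresh=clump_r2,
                                          window_kb=window_kb))
    kept = np.asarray(kept, dtype=int)
    in_peak = np.zeros(len(s.df), dtype=bool)
    if isinstance(peak_membership, dict):
        in_peak[list(peak_membership.keys())] = True
    else:
        in_peak[np.asarray(list(peak_membership), dtype=int)] = True
    pv = s.df["pval"].to_numpy()[kept]
    member = in_peak[kept]
    sig = pv < gwas_sig
    if sig.sum() == 0:
        raise ValueError("no genome-wide-significant variants after clumping")
    table = np.array([[np.sum(sig & member), np.sum(sig & ~member)],
                      [np.sum(~sig & member), np.sum(~sig & ~member)]])
    return _fisher_with_ci(table, "two-sided", threshold=gwas_sig)


def functional_enrichment(vet: VariantEffectTable, region_membership,
                          gwas_p, p_max: float = 0.05,
                          q_cutoffs=(0.5, 0.6, 0.7, 0.8, 0.9),
                          celltype=None) -> list[EnrichmentResult]:
    """OR curve of high-Q variants inside disease-relevant regions.

    Restricted to disease-associated variants (GWAS p < ``p_max``); at each
    cutoff q* variants with Q >= q* are "functional" and a two-sided Fisher
    test crosses functionality with region membership.  Degenerate strata
    are skipped with a warning.
    """
    qdf = vet.q
    col = celltype if celltype is not None else qdf.columns[0]
    qs = qdf[col].to_numpy(dtype=float)
    member = np.zeros(len(qs), dtype=bool)
    member[np.asarray(list(region_membership), dtype=int)] = True
    gp = np.asarray(gwas_p, dtype=float)
    keep = gp < p_max
    qs, member = qs[keep], member[keep]
    out = []
    for cut in q_cutoffs:
        func = qs >= cut
        table = np.array([[np.sum(func & member), np.sum(func & ~member)],
                          [np.sum(~func & member), np.sum(~func & ~member)]])
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            logger.warning("functional_enrichment: empty stratum at "
                           "cutoff %.2f; skipped", cut)
            continue
        out.append(_fisher_with_ci(table, "two-sided", threshold=cut))
    return out


def da_test(cpm: CellPeakMatrix, selected: np.ndarray,
            covariate: np.ndarray | None = None, min_pct: float = 0.02,
            logfc_min: float = 0.1, alpha: float = 0.1) -> pd.DataFrame:
    """Differential accessibility of peaks in selected versus other cells.

    Accessibility is binarized; peaks detected in fewer than ``min_pct`` of
    both groups, or with |log2 fold change| of detection fractions below
    ``logfc_min``, are not tested.  Each remaining peak gets a
    likelihood-ratio test between logistic models of group membership with
    and without the peak term, both including the per-cell depth covariate.
    BH correction is applied over tested peaks; DA requires adjusted
    p < ``alpha`` and positive log2FC.
    """
    import statsmodels.api as sm

    sel = np.asarray(selected, dtype=bool)
    if sel.sum() == 0 or (~sel).sum() == 0:
        raise ValueError("both selected and unselected groups must be "
                         "nonempty")
    X = sparse.csr_matrix(cpm.matrix)
    binary = (X > 0).astype(float)
    if covariate is None:
        covariate = np.asarray(X.sum(axis=1)).ravel()
    cov = np.asarray(covariate, dtype=float)
    cov = (cov - cov.mean()) / (cov.std() if cov.std() > 0 else 1.0)

    pct_in = np.asarray(binary[sel].mean(axis=0)).ravel()
    pct_out = np.asarray(binary[~sel].mean(axis=0)).ravel()
    eps = 1e-9
    log2fc = np.log2((pct_in + eps) / (pct_out + eps))
    testable = (np.maximum(pct_in, pct_out) >= min_pct) & \
        (np.abs(log2fc) >= logfc_min)

    y = sel.astype(float)
    base = sm.add_constant(cov)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ll0 = sm.GLM(y, base, family=sm.families.Binomial()).fit().llf
    pvals = np.full(cpm.n_peaks, np.nan)
    for j in np.flatnonzero(testable):
        feat = np.asarray(binary[:, j].todense()).ravel()
        design = np.column_stack([base, feat])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ll1 = sm.GLM(y, design, family=sm.families.Binomial()
                             ).fit(maxiter=100).llf
            except Exception:  # separation or non-convergence
                pvals[j] = 0.0
                continue
        lr = 2.0 * (ll1 - ll0)
        pvals[j] = stats.chi2.sf(max(lr, 0.0), df=1) if np.isfinite(lr) else 0.0

    out = pd.DataFrame({
        "peak_id": cpm.peaks.df["peak_id"].to_numpy(),
        "pct_selected": pct_in, "pct_other": pct_out,
        "log2fc": log2fc, "tested": testable, "pval": pvals})
    out["adj_p"] = np.nan
    if testable.any():
        _, adj, _, _ = multipletests(pvals[testable], alpha=alpha,
                                     method="fdr_bh")
        out.loc[testable, "adj_p"] = adj
    out["da"] = (out["adj_p"] < alpha) & (out["log2fc"] > 0)
    return out
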