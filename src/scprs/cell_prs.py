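"""Chromatin-conditioned clumping+thresholding polygenic risk scores.

For every reference cell, a C+T PRS is computed in which the clumping index
variants are restricted to variants falling inside open-chromatin peaks of
that particular cell.  The default parameter grid crosses LD thresholds
r^2 in {0.1, 0.3, 0.5} with p-value cutoffs
{1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5}, giving 21 PRS features per cell
per individual.  A PRS for individual n over index set I is

    PRS_n = sum_{i in I, nonmissing} beta_i * G_{n,i} / (P * M_n)

with ploidy P = 2 and M_n the individual's count of nonmissing scored
variants (PRS_n = 0 when M_n = 0).  Dosages G count effect-allele copies
(see io_harmonize.harmonize_alleles).

Clumping within one (cell, r^2) pair is performed once at the loosest
p-value cutoff; because the greedy scan visits candidates in ascending
p-value order, the index set for any tighter cutoff is the prefix of
selections passing that cutoff, exactly as if clumping were re-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .io_harmonize import (CellPeakMatrix, GenotypeMatrix, SumstatsTable,
                           membership_matrix)

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLDS = (1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5)
DEFAULT_R2_THRESHOLDS = (0.1, 0.3, 0.5)
DEFAULT_WINDOW_KB = 250.0
PLOIDY = 2


@dataclass(frozen=True)
class CTParams:
    """One clumping+thresholding setting."""

    p_thresh: float
    r2_thresh: float
    window_kb: float = DEFAULT_WINDOW_KB

    def __post_init__(self):
        if not 0 < self.p_thresh <= 1:
            raise ValueError("p_thresh must be in (0, 1]")
        if not 0 < self.r2_thresh <= 1:
            raise ValueError("r2_thresh must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")

    @property
    def label(self) -> str:
        return f"r2={self.r2_thresh:g},p={self.p_thresh:g}"


@dataclass(frozen=True)
class CTGrid:
    """Ordered collection of unique C+T settings (default 3 x 7 = 21)."""

    params: tuple[CTParams, ...]

    def __post_init__(self):
        if len(set(self.params)) != len(self.params):
            raise ValueError("duplicate C+T parameter combinations")

    def __len__(self) -> int:
        return len(self.params)

    def __iter__(self):
        return iter(self.params)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.params]

    @classmethod
    def default(cls, window_kb: float = DEFAULT_WINDOW_KB) -> "CTGrid":
        return cls(tuple(CTParams(p, r2, window_kb)
                         for r2 in DEFAULT_R2_THRESHOLDS
                         for p in DEFAULT_P_THRESHOLDS))


@dataclass
class LDMatrix:
    """Sparse symmetric r^2 between same-chromosome variants within a window."""

    r2: sparse.csr_matrix
    window_kb: float
    source: str = "in_sample"  # or "reference_panel"

    def neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        row = self.r2.getrow(i)
        return row.indices, row.data


@dataclass
class CellPRSTensor:
    """Individuals x cells x grid PRS features plus bookkeeping.

    ``counts[j, f]`` is the number of index variants scored for cell j at
    grid setting f.  ``mu``/``sd`` hold per-(cell, feature) normalization
    statistics once :func:`normalize_prs` has been applied.
    """

    values: np.ndarray  # (N, M, F)
    counts: np.ndarray  # (M, F) int
    labels: list[str]
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None
    fit_samples: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# LD estimation
# ---------------------------------------------------------------------------

def ld_r2(g: GenotypeMatrix, window_kb: float = DEFAULT_WINDOW_KB,
          source: str = "in_sample") -> LDMatrix:
    """Pairwise-complete squared Pearson correlation of dosages.

    Only same-chromosome pairs within ``window_kb`` are stored.  Monomorphic
    pairs (zero variance on the joint support) get r^2 = 0 with a warning.
    """
    n_var = g.n_variants
    chroms = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    window = window_kb * 1000.0
    rows, cols, vals = [], [], []
    n_mono = 0
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        X = g.dosages[:, idx]
        M = (~np.isnan(X)).astype(float)
        A = np.nan_to_num(X)
        A2 = A * A
        n = M.T @ M
        sx = A.T @ M
        sy = sx.T
        sxy = A.T @ A
        sx2 = A2.T @ M
        sy2 = sx2.T
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * sxy - sx * sy
            varx = n * sx2 - sx * sx
            vary = n * sy2 - sy * sy
            denom = varx * vary
            r2 = np.where(denom > 0, cov * cov / np.where(denom > 0, denom, 1.0), 0.0)
        n_mono += int(np.sum((denom <= 0) & (n > 1))) // 2
        p = pos[idx]
        within = np.abs(p[:, None] - p[None, :]) <= window
        r2 = np.where(within, r2, 0.0)
        np.fill_diagonal(r2, 1.0)
        ii, jj = np.nonzero(r2)
        rows.append(idx[ii])
        cols.append(idx[jj])
        vals.append(r2[ii, jj])
    if n_mono:
        logger.warning("ld_r2: %d monomorphic pair(s) set to r2 = 0", n_mono)
    mat = sparse.csr_matrix(
        (np.concatenate(vals) if vals else np.empty(0),
         (np.concatenate(rows) if rows else np.empty(0, int),
          np.concatenate(cols) if cols else np.empty(0, int))),
        shape=(n_var, n_var))
    return LDMatrix(r2=mat, window_kb=window_kb, source=source)


# ---------------------------------------------------------------------------
# clumping and scoring
# ---------------------------------------------------------------------------

def clump(s: SumstatsTable, ld: LDMatrix, index_candidates,
          params: CTParams) -> list[int]:
    """Greedy LD clumping with a restricted index-candidate set.

    Repeatedly selects the smallest-p remaining candidate with
    p <= ``params.p_thresh`` as an index variant and removes every variant
    (candidate or not) on the same chromosome within ``window_kb`` whose r^2
    with the index is >= ``r2_thresh``.  Ties on p are broken by (chrom, pos)
    ascending.  Returns positional indices in selection order.
    """
    cand = np.asarray(sorted(index_candidates), dtype=int)
    if cand.size == 0:
        return []
    df = s.df
    pvals = df["pval"].to_numpy()[cand]
    order = np.lexsort((df["pos"].to_numpy()[cand],
                        df["chrom"].to_numpy()[cand], pvals))
    cand = cand[order]
    pvals = pvals[order]
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    window = params.window_kb * 1000.0
    removed = np.zeros(len(df), dtype=bool)
    selected: list[int] = []
    for i, p in zip(cand, pvals):
        if p > params.p_thresh:
            break
        if removed[i]:
            continue
        selected.append(int(i))
        nbr, r2 = ld.neighbors(i)
        hit = nbr[(r2 >= params.r2_thresh)
                  & (chroms[nbr] == chroms[i])
                  & (np.abs(pos[nbr] - pos[i]) <= window)]
        removed[hit] = True
        removed[i] = True
    return selected


def ct_prs(g: GenotypeMatrix, s: SumstatsTable, index_set) -> np.ndarray:
    """Per-individual C+T PRS over a fixed index set (ploidy-normalized)."""
    idx = np.asarray(list(index_set), dtype=int)
    n = g.n_samples
    if idx.size == 0:
        return np.zeros(n)
    D = g.dosages[:, idx]
    betas = s.df["beta"].to_numpy()[idx]
    nonmiss = ~np.isnan(D)
    num = np.nansum(D * betas, axis=1)
    m = nonmiss.sum(axis=1)
    out = np.zeros(n)
    ok = m > 0
    out[ok] = num[ok] / (PLOIDY * m[ok])
    return out


def _prefix_prs(g: GenotypeMatrix, s: SumstatsTable, selected: list[int],
                p_threshs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PRS at every p-value cutoff from one clumping run.

    ``selected`` is in ascending-p selection order, so the index set at
    cutoff p* is the prefix with p <= p*.  Returns (N x n_cut scores,
    n_cut index-set sizes).
    """
    n = g.n_samples
    n_cut = len(p_threshs)
    if not selected:
        return np.zeros((n, n_cut)), np.zeros(n_cut, dtype=int)
    sel = np.asarray(selected, dtype=int)
    pv = s.df["pval"].to_numpy()[sel]
    cut_sizes = np.searchsorted(pv, p_threshs, side="right")
    D = g.dosages[:, sel]
    betas = s.df["beta"].to_numpy()[sel]
    contrib = np.nan_to_num(D) * betas
    nonmiss = (~np.isnan(D)).astype(float)
    cum_num = np.cumsum(contrib, axis=1)
    cum_m = np.cumsum(nonmiss, axis=1)
    scores = np.zeros((n, n_cut))
    for f, k in enumerate(cut_sizes):
        if k == 0:
            continue
        m = cum_m[:, k - 1]
        ok = m > 0
        scores[ok, f] = cum_num[ok, k - 1] / (PLOIDY * m[ok])
    return scores, cut_sizes.astype(int)


def _grid_by_r2(grid: CTGrid):
    """Group grid settings by (r2, window); p cutoffs sorted ascending."""
    groups: dict[tuple[float, float], list[tuple[int, float]]] = {}
    for f, prm in enumerate(grid):
        groups.setdefault((prm.r2_thresh, prm.window_kb), []).append(
            (f, prm.p_thresh))
    out = []
    for (r2, win), fps in groups.items():
        fps.sort(key=lambda t: t[1])
        out.append((r2, win, [f for f, _ in fps],
                    np.asarray([p for _, p in fps])))
    return out


def _conditioned_block(g, s, ld, candidates, grid_groups, n_features):
    """21-feature PRS block for one index-candidate set."""
    n = g.n_samples
    vals = np.zeros((n, n_features))
    cnts = np.zeros(n_features, dtype=int)
    for r2, win, feat_idx, p_cuts in grid_groups:
        prm = CTParams(p_thresh=float(p_cuts[-1]), r2_thresh=r2, window_kb=win)
        selected = clump(s, ld, candidates, prm)
        scores, sizes = _prefix_prs(g, s, selected, p_cuts)
        for pos_in_group, f in enumerate(feat_idx):
            vals[:, f] = scores[:, pos_in_group]
            cnts[f] = sizes[pos_in_group]
    return vals, cnts


def cell_prs_tensor(g: GenotypeMatrix, s: SumstatsTable, cpm: CellPeakMatrix,
                    grid: CTGrid | None = None,
                    membership: dict[int, list[int]] | None = None,
                    ld: LDMatrix | None = None,
                    cache: bool = True) -> CellPRSTensor:
    """Conditioned PRS tensor: individuals x cells x grid settings.

    For cell j the index candidates are the harmonized variants lying inside
    peaks with nonzero accessibility in cell j.  Cells sharing an identical
    candidate set share one computation when ``cache`` is on (bit-identical
    to recomputation).
    """
    grid = grid or CTGrid.default()
    if membership is None:
        from .io_harmonize import assign_variants_to_peaks
        membership = assign_variants_to_peaks(s, cpm.peaks)
    if ld is None:
        ld = ld_r2(g, max(p.window_kb for p in grid))
    vp = membership_matrix(membership, len(s.df), cpm.n_peaks).tocsc()
    acc = cpm.matrix.tocsr()
    groups = _grid_by_r2(grid)
    n, m_cells, n_feat = g.n_samples, cpm.n_cells, len(grid)
    values = np.zeros((n, m_cells, n_feat))
    counts = np.zeros((m_cells, n_feat), dtype=int)
    memo: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    for j in range(m_cells):
        peaks_j = acc.indices[acc.indptr[j]:acc.indptr[j + 1]]
        cand = np.unique(vp[:, peaks_j].tocoo().row) if peaks_j.size else \
            np.empty(0, dtype=int)
        key = cand.tobytes()
        hit = memo.get(key) if cache else None
        if hit is None:
            hit = _conditioned_block(g, s, ld, cand, groups, n_feat)
            if cache:
                memo[key] = hit
        values[:, j, :], counts[j, :] = hit
    return CellPRSTensor(values=values, counts=counts, labels=grid.labels)


def nonpeak_prs(g: GenotypeMatrix, s: SumstatsTable, cpm: CellPeakMatrix,
                grid: CTGrid | None = None,
                membership: dict[int, list[int]] | None = None,
                ld: LDMatrix | None = None) -> np.ndarray:
    """Individuals x grid PRS using only variants outside every peak."""
    grid = grid or CTGrid.default()
    if membership is None:
        from .io_harmonize import assign_variants_to_peaks
        membership = assign_variants_to_peaks(s, cpm.peaks)
    if ld is None:
        ld = ld_r2(g, max(p.window_kb for p in grid))
    in_peak = set(membership.keys())
    cand = np.asarray([i for i in range(len(s.df)) if i not in in_peak],
                      dtype=int)
    vals, _ = _conditioned_block(g, s, ld, cand, _grid_by_r2(grid), len(grid))
    return vals


def celltype_prs(g: GenotypeMatrix, s: SumstatsTable, cpm: CellPeakMatrix,
                 labels: np.ndarray | None = None,
                 grid: CTGrid | None = None,
                 membership: dict[int, list[int]] | None = None,
                 ld: LDMatrix | None = None) -> dict[str, np.ndarray]:
    """One individuals x grid PRS block per cell type.

    A cell type's peaks are those with nonzero accessibility in at least one
    cell of that type; types with no peaks yield a zero block with a warning.
    """
    grid = grid or CTGrid.default()
    labels = labels if labels is not None else cpm.cell_types
    if labels is None:
        raise ValueError("cell-type labels required")
    if membership is None:
        from .io_harmonize import assign_variants_to_peaks
        membership = assign_variants_to_peaks(s, cpm.peaks)
    if ld is None:
        ld = ld_r2(g, max(p.window_kb for p in grid))
    vp = membership_matrix(membership, len(s.df), cpm.n_peaks).tocsc()
    groups = _grid_by_r2(grid)
    blocks: dict[str, np.ndarray] = {}
    for ct in pd.unique(pd.Series(labels)):
        rows = np.flatnonzero(np.asarray(labels) == ct)
        peak_any = np.asarray(
            cpm.matrix[rows].sum(axis=0)).ravel() > 0
        peaks_ct = np.flatnonzero(peak_any)
        cand = (np.unique(vp[:, peaks_ct].tocoo().row) if peaks_ct.size
                else np.empty(0, dtype=int))
        if cand.size == 0:
            logger.warning("celltype_prs: cell type %r has no peaks; "
                           "zero block", ct)
            blocks[str(ct)] = np.zeros((g.n_samples, len(grid)))
            continue
        vals, _ = _conditioned_block(g, s, ld, cand, groups, len(grid))
        blocks[str(ct)] = vals
    return blocks


def combine_multi_celltype(blocks: dict[str, np.ndarray], y: np.ndarray,
                           train_idx, test_idx, seed: int = 0) -> np.ndarray:
    """Combine per-cell-type PRS blocks with a logistic model.

    The model is fit on ``train_idx`` only (features z-scored with training
    statistics); returns predicted case probabilities for ``test_idx``.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.concatenate([blocks[k] for k in sorted(blocks)], axis=1)
    tr = np.asarray(train_idx, dtype=int)
    te = np.asarray(test_idx, dtype=int)
    mu = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(Xz[tr], np.asarray(y)[tr])
    return clf.predict_proba(Xz[te])[:, 1]


def normalize_prs(t: CellPRSTensor, fit_samples) -> CellPRSTensor:
    """Z-score each (cell, setting) feature using ``fit_samples`` statistics.

    Features with zero variance on the fit samples are set to zero.  The
    statistics are stored so unseen individuals are transformed identically.
    """
    fit = np.asarray(list(fit_samples), dtype=int)
    if fit.size == 0:
        raise ValueError("fit_samples must be nonempty")
    mu = t.values[fit].mean(axis=0)
    sd = t.values[fit].std(axis=0)
    vals = np.where(sd > 0, (t.values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return CellPRSTensor(values=vals, counts=t.counts.copy(),
                         labels=list(t.labels), mu=mu, sd=sd,
                         fit_samples=fit, meta=dict(t.meta))


def apply_normalization(t: CellPRSTensor, values: np.ndarray) -> np.ndarray:
    """Transform new raw values with stored normalization statistics."""
    if t.mu is None or t.sd is None:
        raise ValueError("tensor has no stored normalization statistics")
    return np.where(t.sd > 0, (values - t.mu) / np.where(t.sd > 0, t.sd, 1.0),
                    0.0)
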