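"""Ensemble cell prioritization and cell-type enrichment.

The readout coefficients beta learned by the network measure each cell's
contribution to predicted risk, but a single fit is noisy.  We therefore
train an ensemble of models differing only in random seed, and call a cell
disease-relevant when its weight distribution across the ensemble sits
significantly above the per-repeat top-ranking weights (top 15% of cell
weights per model, pooled), by a one-sided Welch t-test with
Benjamini-Yekutieli correction at alpha = 0.1.  Cell types are then tested
for enrichment of the selected cells with a one-sided Fisher's exact test
(BH-corrected), excluding types with fewer than 150 cells by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scprs_model import FitResult, ModelData, TrainConfig, fit

logger = logging.getLogger(__name__)


@dataclass
class CellWeightEnsemble:
    """Learned readout weights, one row per trained model."""

    weights: np.ndarray        # (n_models, n_cells)
    seeds: list[int]
    config: TrainConfig

    @property
    def n_models(self) -> int:
        return self.weights.shape[0]

    @property
    def n_cells(self) -> int:
        return self.weights.shape[1]


def fit_ensemble(data: ModelData, cfg: TrainConfig, n_models: int = 100,
                 base_seed: int = 0) -> CellWeightEnsemble:
    """Train ``n_models`` models on the entire cohort, varying only the seed.

    Diverging fits are recorded and excluded; if fewer than 80% of the
    requested fits survive the ensemble is rejected.
    """
    n = len(data.y)
    full = replace(cfg)
    d = ModelData(X=data.X, y=data.y, graph=data.graph, extra=data.extra,
                  train_idx=np.arange(n), val_idx=None, test_idx=None)
    rows, seeds, failed = [], [], []
    for i in range(n_models):
        seed = int(base_seed + i) % (2 ** 31)
        try:
            res: FitResult = fit(d, replace(full, seed=seed))
        except RuntimeError as err:
            logger.warning("ensemble fit with seed %d diverged: %s", seed, err)
            failed.append(seed)
            continue
        rows.append(res.params.beta.copy())
        seeds.append(seed)
    if len(rows) < math.ceil(0.8 * n_models):
        raise RuntimeError(
            f"only {len(rows)}/{n_models} ensemble fits converged "
            f"(failed seeds: {failed})")
    return CellWeightEnsemble(weights=np.vstack(rows), seeds=seeds,
                              config=cfg)


def prioritize_cells(e: CellWeightEnsemble, top_frac: float = 0.15,
                     alpha: float = 0.1,
                     leave_self_out: bool = False) -> pd.DataFrame:
    """Per-cell significance of ensemble weights against top-ranking weights.

    The background pools, across ensemble repeats, the top
    ``ceil(top_frac * M)`` weights of each repeat.  Each cell's weights are
    compared against the background with a one-sided Welch t-test
    (alternative: cell mean greater).  ``leave_self_out`` removes the focal
    cell's own contributions from the background.  Returns a DataFrame with
    columns raw_p, adj_p (Benjamini-Yekutieli) and selected.
    """
    if e.n_models < 10:
        raise ValueError("need at least 10 ensemble repeats")
    W = e.weights
    n_models, m = W.shape
    n_top = math.ceil(top_frac * m)
    # per-repeat top indices (descending weight)
    top_idx = np.argsort(-W, axis=1)[:, :n_top]
    rows = np.repeat(np.arange(n_models), n_top)
    flat_idx = top_idx.ravel()
    background = W[rows, flat_idx]
    raw = np.ones(m)
    for j in range(m):
        cell = W[:, j]
        bg = background
        if leave_self_out:
            bg = background[flat_idx != j]
        if cell.std() == 0 and bg.std() == 0:
            logger.warning("cell %d: zero-variance weights; p = 1", j)
            raw[j] = 1.0
            continue
        raw[j] = stats.ttest_ind(cell, bg, equal_var=False,
                                 alternative="greater").pvalue
    raw = np.nan_to_num(raw, nan=1.0)
    _, adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_by")
    return pd.DataFrame({"cell": np.arange(m), "raw_p": raw, "adj_p": adj,
                         "selected": adj < alpha})


def celltype_enrichment(selected: np.ndarray, labels: np.ndarray,
                        min_cells: int = 150,
                        alpha: float = 0.1) -> pd.DataFrame:
    """Fisher enrichment of selected cells within each cell type.

    One-sided (enrichment direction) Fisher's exact test per type on the
    2x2 table of selected/unselected x in-type/out-of-type; BH correction
    across tested types.  Types with fewer than ``min_cells`` cells are
    excluded from testing.
    """
    sel = np.asarray(selected, dtype=bool)
    labels = np.asarray(labels)
    types, counts = np.unique(labels, return_counts=True)
    tested = [t for t, c in zip(types, counts) if c >= min_cells]
    if not tested:
        raise ValueError(f"no cell type has >= {min_cells} cells")
    rows = []
    for t in tested:
        in_t = labels == t
        a = int(np.sum(sel & in_t))
        b = int(np.sum(~sel & in_t))
        c = int(np.sum(sel & ~in_t))
        d = int(np.sum(~sel & ~in_t))
        orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"cell_type": t, "n_cells": int(in_t.sum()),
                     "selected_in": a, "unselected_in": b,
                     "selected_out": c, "unselected_out": d,
                     "odds_ratio": float(orr), "fisher_p": float(p)})
    out = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(out["fisher_p"], alpha=alpha,
                                 method="fdr_bh")
    out["adj_p"] = adj
    out["enriched"] = out["adj_p"] < alpha
    return out


def subpopulation_split(cpm, selected: np.ndarray, marker_peaks,
                        cells_mask: np.ndarray | None = None
                        ) -> tuple[np.ndarray, dict]:
    """Split cells by marker-peak accessibility; test selection enrichment.

    Within ``cells_mask`` (default all cells), cells with any marker peak
    accessible (count > 0) form the marker-positive subtype.  A two-sided
    chi-square test compares observed and expected selected-cell counts
    across the two subtypes.  Empty subtypes skip the test with a warning.
    Returns (subtype labels, result dict with observed, expected, ratio,
    chi2, p).
    """
    marker_peaks = np.asarray(list(marker_peaks), dtype=int)
    sel = np.asarray(selected, dtype=bool)
    mask = (np.ones(cpm.n_cells, dtype=bool) if cells_mask is None
            else np.asarray(cells_mask, dtype=bool))
    any_marker = np.asarray(
        (cpm.matrix[:, marker_peaks] > 0).sum(axis=1)).ravel() > 0
    labels = np.where(any_marker, "marker+", "marker-")
    labels = np.asarray(labels, dtype=object)
    labels[~mask] = "excluded"
    pos, neg = (labels == "marker+"), (labels == "marker-")
    result: dict = {"labels": labels}
    if pos.sum() == 0 or neg.sum() == 0:
        logger.warning("subpopulation_split: empty subtype; test skipped")
        result.update({"chi2": np.nan, "p": np.nan})
        return labels, result
    table = np.array([[np.sum(sel & pos), np.sum(~sel & pos)],
                      [np.sum(sel & neg), np.sum(~sel & neg)]], dtype=float)
    chi2_stat, p, _, expected = stats.chi2_contingency(table,
                                                       correction=False)
    n_sel_mask = sel[mask].sum()
    exp_pos = pos.sum() * n_sel_mask / mask.sum()
    result.update({
        "observed": {"marker+": int(table[0, 0]), "marker-": int(table[1, 0])},
        "expected_selected_markerpos": float(exp_pos),
        "ratio_obs_exp_markerpos": (float(table[0, 0] / exp_pos)
                                    if exp_pos > 0 else np.nan),
        "chi2": float(chi2_stat), "p": float(p)})
    return labels, result
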