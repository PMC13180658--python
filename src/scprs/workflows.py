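"""End-to-end pipelines gluing simulation, PRS, graph, model and ranking.

These are the compositions used by the command-line interface, the test
suite and the reproduction script: simulate a cohort, build the conditioned
PRS tensor and the cell graph, train (an ensemble of) models and score the
recovery of the causal cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cell_graph import CellGraph, build_cell_graph, lsi_embed
from .cell_prs import CellPRSTensor, CTGrid, cell_prs_tensor, normalize_prs
from .io_harmonize import assign_variants_to_peaks
from .prioritization import (CellWeightEnsemble, celltype_enrichment,
                             fit_ensemble, prioritize_cells)
from .scprs_model import ModelData, TrainConfig, evaluate, fit, forward, split_data
from .synthetic_data import SimConfig, simulate


@dataclass
class PipelineData:
    """Simulation bundle plus derived features ready for model training."""

    bundle: dict
    tensor: CellPRSTensor
    graph: CellGraph
    cell_types: np.ndarray


def prepare_features(bundle: dict, grid: CTGrid | None = None,
                     n_components: int = 12, k: int = 25,
                     cells_mask: np.ndarray | None = None) -> PipelineData:
    """Conditioned PRS tensor and mutual-kNN graph for a simulated bundle.

    ``cells_mask`` restricts the reference atlas to a subset of cells (used
    by the ablation control).
    """
    g, s, cpm = bundle["target"], bundle["sumstats"], bundle["atlas"]
    if cells_mask is not None:
        from scipy import sparse

        from .io_harmonize import CellPeakMatrix

        mask = np.asarray(cells_mask, dtype=bool)
        cpm = CellPeakMatrix(
            barcodes=cpm.barcodes[mask], peaks=cpm.peaks,
            matrix=sparse.csr_matrix(cpm.matrix[mask]),
            cell_types=(None if cpm.cell_types is None
                        else cpm.cell_types[mask]))
    membership = assign_variants_to_peaks(s, cpm.peaks)
    tensor = cell_prs_tensor(g, s, cpm, grid or CTGrid.default(),
                             membership, ld=bundle.get("ld"))
    emb = lsi_embed(cpm, n_components=n_components, seed=0)
    graph = build_cell_graph(emb, k=min(k, cpm.n_cells - 1))
    return PipelineData(bundle=bundle, tensor=tensor, graph=graph,
                        cell_types=cpm.cell_types)


def model_data(pipe: PipelineData, task: str = "regression",
               seed: int = 0) -> ModelData:
    """Split the cohort, normalize the tensor on the training samples."""
    y = (pipe.bundle["labels"] if task == "binary"
         else pipe.bundle["y_obs"])
    train, val, test = split_data(y, seed=seed, task=task)
    tens = normalize_prs(pipe.tensor, train)
    return ModelData(X=tens.values, y=np.asarray(y, dtype=float),
                     graph=pipe.graph, train_idx=train, val_idx=val,
                     test_idx=test)


def train_and_test(pipe: PipelineData, cfg: TrainConfig,
                   seed: int = 0) -> dict:
    """One split/normalize/fit cycle; returns held-out test metrics."""
    data = model_data(pipe, task=cfg.task, seed=seed)
    res = fit(data, replace(cfg, seed=seed))
    return {"fit": res, "test": res.test_metrics, "val": res.val_metric}


def ensemble_prioritize(pipe: PipelineData, cfg: TrainConfig,
                        n_models: int = 20, base_seed: int = 0,
                        top_frac: float = 0.15, alpha: float = 0.1,
                        min_cells: int = 150) -> dict:
    """Full-cohort ensemble, cell selection and cell-type enrichment."""
    y = (pipe.bundle["labels"] if cfg.task == "binary"
         else pipe.bundle["y_obs"])
    tens = normalize_prs(pipe.tensor, np.arange(len(y)))
    data = ModelData(X=tens.values, y=np.asarray(y, dtype=float),
                     graph=pipe.graph)
    ens = fit_ensemble(data, cfg, n_models=n_models, base_seed=base_seed)
    cells = prioritize_cells(ens, top_frac=top_frac, alpha=alpha)
    types = None
    if pipe.cell_types is not None:
        try:
            types = celltype_enrichment(cells["selected"].to_numpy(),
                                        pipe.cell_types,
                                        min_cells=min_cells, alpha=alpha)
        except ValueError:
            types = None
    return {"ensemble": ens, "cells": cells, "types": types}


def weight_auc(ens: CellWeightEnsemble, causal_mask: np.ndarray) -> float:
    """AUROC of mean ensemble weights for separating causal-type cells."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(np.asarray(causal_mask, dtype=int),
                               ens.weights.mean(axis=0)))


#: prioritization default, chosen once from the model's hyperparameter grid
#: on simulated cohorts: one propagation layer, L1 sparsity 1 (keeps cells
#: without consistent signal dithering around zero, which calibrates the
#: top-weight background test), ridge 10, Laplacian smoothing 2.5
DEFAULT_PRIORITIZATION_CONFIG = TrainConfig(
    task="regression", n_layers=1, lambda1=1.0, lambda2=10.0, lambda3=2.5)

#: small validation-selection grid used by the prediction workflows
PREDICTION_GRID = tuple(
    TrainConfig(task="regression", n_layers=T, lambda1=0.0, lambda2=l2,
                lambda3=l3)
    for T in (0, 1) for l2 in (1.0,) for l3 in (0.1, 2.5))


def default_sim_config(**overrides) -> SimConfig:
    """The simulation conditions used by the reproduction protocols.

    A compact cohort (300 target individuals, 240 cells in four types over
    1,200 variants) keeps the ensemble protocols tractable on one CPU while
    preserving the statistical structure of the full-size default.
    """
    base = dict(n_target=300, n_discovery=2_500, n_variants=1_200,
                n_chromosomes=3, haplotype_pool_size=120, n_cells=240,
                specific_peaks_per_type=40, shared_peaks=40,
                sigma=0.25, seed=0)
    base.update(overrides)
    return SimConfig(**base)


def predict_run(seed: int, sigma: float, grid=None,
                sim_overrides: dict | None = None,
                cells_mask: np.ndarray | None = None,
                bundle: dict | None = None) -> dict:
    """Simulate, featurize and train with validation-based model selection.

    Trains every configuration in ``grid`` (default: the small prediction
    grid) on one 60/20/20 split, picks the best validation Pearson r and
    reports its held-out test r.
    """
    from .scprs_model import grid_search

    if bundle is None:
        sim_cfg = default_sim_config(sigma=sigma, seed=seed,
                                     **(sim_overrides or {}))
        bundle = simulate(sim_cfg)
    pipe = prepare_features(bundle, cells_mask=cells_mask)
    data = model_data(pipe, task="regression", seed=seed)
    best, fits = grid_search(data, list(grid or PREDICTION_GRID), seed=seed)
    return {"test_r": best.test_metrics["pearson_r"],
            "val_r": best.val_metric, "config": best.config,
            "bundle": bundle, "pipe": pipe}


def noise_ladder(sigmas=(0.0, 1.0, 3.0, 7.0), seeds=(0, 1, 2, 3, 4),
                 sim_overrides: dict | None = None) -> dict:
    """Mean held-out Pearson r per phenotype-noise level."""
    out = {}
    for sigma in sigmas:
        rs = [predict_run(seed, sigma, sim_overrides=sim_overrides)["test_r"]
              for seed in seeds]
        out[sigma] = {"mean_r": float(np.mean(rs)), "r": rs}
    return out


def ablation_delta(seeds=(0, 1, 2, 3, 4), sigma: float = 0.0,
                   max_causal_peaks: int = 1,
                   sim_overrides: dict | None = None) -> dict:
    """Test-r drop when causal-type cells are removed from the atlas.

    The ablated atlas removes all causal-type cells plus any other cell
    whose accessible causal-peak count exceeds ``max_causal_peaks``.
    """
    full_r, ablated_r = [], []
    for seed in seeds:
        sim_cfg = default_sim_config(sigma=sigma, seed=seed,
                                     **(sim_overrides or {}))
        bundle = simulate(sim_cfg)
        cpm = bundle["atlas"]
        causal_idx = bundle["truth"].extras["causal_peak_idx"]
        n_causal_open = np.asarray(
            (cpm.matrix[:, causal_idx] > 0).sum(axis=1)).ravel()
        keep = (cpm.cell_types != sim_cfg.causal_type) & \
            (n_causal_open <= max_causal_peaks)
        full_r.append(predict_run(seed, sigma, bundle=bundle)["test_r"])
        ablated_r.append(predict_run(seed, sigma, bundle=bundle,
                                     cells_mask=keep)["test_r"])
    return {"full_mean_r": float(np.mean(full_r)),
            "ablated_mean_r": float(np.mean(ablated_r)),
            "delta": float(np.mean(full_r) - np.mean(ablated_r)),
            "full_r": full_r, "ablated_r": ablated_r}


def recovery_run(seed: int, sigma: float = 0.25, n_models: int = 20,
                 cfg_model: TrainConfig | None = None,
                 min_cells: int = 30, sim_overrides: dict | None = None
                 ) -> dict:
    """Simulate, featurize, ensemble-train and score causal-type recovery."""
    sim_cfg = default_sim_config(sigma=sigma, seed=seed,
                                 **(sim_overrides or {}))
    bundle = simulate(sim_cfg)
    pipe = prepare_features(bundle)
    cfg = cfg_model or DEFAULT_PRIORITIZATION_CONFIG
    out = ensemble_prioritize(pipe, cfg, n_models=n_models,
                              base_seed=seed * 1_000 % (2 ** 31),
                              min_cells=min_cells)
    causal_mask = pipe.cell_types == sim_cfg.causal_type
    out["weight_auc"] = weight_auc(out["ensemble"], causal_mask)
    out["sim_cfg"] = sim_cfg
    out["pipe"] = pipe
    if out["types"] is not None:
        row = out["types"][out["types"]["cell_type"] == sim_cfg.causal_type]
        if len(row):
            out["causal_or"] = float(row["odds_ratio"].iloc[0])
            out["causal_adj_p"] = float(row["adj_p"].iloc[0])
    return out
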