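"""The single-cell PRS network: embedding, graph propagation, readout.

Given normalized per-cell PRS features X_n in R^{M x 21} for individual n
and a mutual-kNN cell graph, the model computes

    h^(0)   = X_n . abs(W0)                               (feature embedding)
    g^(t+1) = abs(w1) D^{-1} A h^(t) + abs(w2) h^(t)      (graph propagation)
    h^(t+1) = leaky_relu(g^(t+1)),  alpha = 0.1
    y       = sigma(beta . h^(T) + b)                     (readout)

with sigma the logistic function for binary phenotypes and the identity for
quantitative ones.  The abs reparameterization keeps the effective
embedding/propagation weights nonnegative, so the map X -> h^(T) is
monotonically increasing and the readout coefficient beta_m is interpretable
as the importance of cell m for predicted risk.  Optional extra feature
blocks (nonpeak PRS, covariates) are concatenated to h^(T) with their own
readout coefficients.

Training minimizes mean binary cross-entropy (or mean squared error) plus
lambda1 * ||beta||_1 + lambda2 * ||beta||_2^2 + lambda3 * beta^T G_L beta,
where G_L is the symmetric normalized graph Laplacian.  Optimization is
mini-batch Adam (lr 1e-3, batch 32, 200 epochs by default) implemented
directly in NumPy with analytic gradients; parameters are few (21 + 2T + M
+ 1), so this is fast and exactly reproducible under a seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.stats import pearsonr

from .cell_graph import CellGraph

logger = logging.getLogger(__name__)

LEAKY_ALPHA = 0.1
_EPS = 1e-12

#: hyperparameter grids considered in model selection
GRID_T = (0, 1, 2)
GRID_LAMBDA1 = (0, 1, 10)
GRID_LAMBDA2 = (1, 10, 50, 100, 250, 500, 750)
GRID_LAMBDA3 = (0.01, 0.1, 0.5, 1, 2.5, 5, 10, 50, 100)
GRID_K = (25, 50)


@dataclass
class ModelParams:
    """Learnable parameters; forward passes use abs(W0), abs(w1), abs(w2)."""

    W0: np.ndarray       # (F,)
    w1: np.ndarray       # (T,)
    w2: np.ndarray       # (T,)
    beta: np.ndarray     # (M,)
    b: float
    gamma: np.ndarray | None = None  # (K,) readout for extra feature blocks

    @property
    def n_layers(self) -> int:
        return len(self.w1)

    def copy(self) -> "ModelParams":
        return ModelParams(self.W0.copy(), self.w1.copy(), self.w2.copy(),
                           self.beta.copy(), float(self.b),
                           None if self.gamma is None else self.gamma.copy())


@dataclass(frozen=True)
class TrainConfig:
    """Training-time hyperparameters and schedule."""

    n_layers: int = 1
    lambda1: float = 0.0
    lambda2: float = 1.0
    lambda3: float = 0.1
    k: int = 25
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0
    task: str = "binary"          # or "regression"
    l2_squared: bool = True       # ridge reading of ||beta||_2
    use_extra: bool = False

    def __post_init__(self):
        if self.task not in ("binary", "regression"):
            raise ValueError("task must be 'binary' or 'regression'")


@dataclass
class FitResult:
    params: ModelParams
    loss_trace: list[float]
    val_trace: list[float]
    val_metric: float
    test_metrics: dict
    splits: dict
    seed: int
    config: TrainConfig


def leaky_relu(x: np.ndarray, alpha: float = LEAKY_ALPHA) -> np.ndarray:
    return np.where(x >= 0, x, alpha * x)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_cache(p: ModelParams, X: np.ndarray, P: sparse.csr_matrix,
                   extra: np.ndarray | None):
    """Forward pass keeping the per-layer intermediates for backprop."""
    a0 = np.abs(p.W0)
    h = np.einsum("nmf,f->nm", X, a0)
    hs, gs = [h], []
    for t in range(p.n_layers):
        g = np.abs(p.w1[t]) * (h @ P.T) + np.abs(p.w2[t]) * h
        h = leaky_relu(g)
        gs.append(g)
        hs.append(h)
    z = h @ p.beta + p.b
    if extra is not None:
        if p.gamma is None:
            raise ValueError("extra features supplied but gamma is None")
        z = z + extra @ p.gamma
    return z, hs, gs


def forward(p: ModelParams, X: np.ndarray, g: CellGraph,
            extra: np.ndarray | None = None,
            task: str = "binary") -> tuple[np.ndarray, np.ndarray]:
    """Predicted scores and latent cell features h^(T).

    X is the normalized N x M x F tensor; returns (scores, latent) where
    scores are probabilities for the binary task and raw values for
    regression.
    """
    if X.shape[1] != g.n_cells:
        raise ValueError(f"X has {X.shape[1]} cells but graph has "
                         f"{g.n_cells}")
    if X.shape[2] != len(p.W0):
        raise ValueError(f"X has {X.shape[2]} features but W0 has "
                         f"{len(p.W0)}")
    z, hs, _ = _forward_cache(p, X, g.propagation_matrix(), extra)
    scores = _sigmoid(z) if task == "binary" else z
    return scores, hs[-1]


def loss(scores: np.ndarray, labels: np.ndarray, beta: np.ndarray,
         G_L: sparse.spmatrix, lambda1: float, lambda2: float,
         lambda3: float, task: str = "binary",
         l2_squared: bool = True) -> float:
    """Mean BCE (or MSE) plus L1, L2 and Laplacian-smoothness penalties."""
    y = np.asarray(labels, dtype=float)
    if task == "binary":
        pclip = np.clip(scores, _EPS, 1 - _EPS)
        data = -np.mean(y * np.log(pclip) + (1 - y) * np.log(1 - pclip))
    else:
        data = np.mean((scores - y) ** 2)
    l2 = beta @ beta if l2_squared else np.sqrt(beta @ beta)
    lap = float(beta @ (sparse.csr_matrix(G_L) @ beta))
    return float(data + lambda1 * np.abs(beta).sum() + lambda2 * l2
                 + lambda3 * lap)


def split_data(labels: np.ndarray, seed: int, task: str = "binary",
               stratify: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random 60/20/20 train/validation/test split, stratified for binary."""
    from sklearn.model_selection import train_test_split

    y = np.asarray(labels)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    strat = None
    if task == "binary" and stratify:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 3:
            raise ValueError("each class needs at least 3 members for a "
                             "stratified 60/20/20 split")
        strat = y
    idx = np.arange(n)
    train, rest = train_test_split(idx, test_size=0.4, random_state=seed,
                                   stratify=strat)
    strat_rest = y[rest] if strat is not None else None
    val, test = train_test_split(rest, test_size=0.5, random_state=seed,
                                 stratify=strat_rest)
    return np.sort(train), np.sort(val), np.sort(test)


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _gradients(p: ModelParams, Xb, yb, P, L, cfg: TrainConfig, extra_b):
    """Analytic gradients of the mini-batch loss w.r.t. all parameters."""
    B = Xb.shape[0]
    z, hs, gs = _forward_cache(p, Xb, P, extra_b)
    if cfg.task == "binary":
        pred = _sigmoid(z)
        dz = (pred - yb) / B
        pclip = np.clip(pred, _EPS, 1 - _EPS)
        data_loss = -np.mean(yb * np.log(pclip) + (1 - yb) * np.log(1 - pclip))
    else:
        dz = 2.0 * (z - yb) / B
        data_loss = np.mean((z - yb) ** 2)

    hT = hs[-1]
    l2 = p.beta @ p.beta if cfg.l2_squared else np.sqrt(p.beta @ p.beta)
    lap = float(p.beta @ (L @ p.beta))
    total = (data_loss + cfg.lambda1 * np.abs(p.beta).sum()
             + cfg.lambda2 * l2 + cfg.lambda3 * lap)

    d_beta = dz @ hT
    d_beta += cfg.lambda1 * np.sign(p.beta)
    if cfg.l2_squared:
        d_beta += 2.0 * cfg.lambda2 * p.beta
    else:
        nrm = np.sqrt(p.beta @ p.beta)
        if nrm > 0:
            d_beta += cfg.lambda2 * p.beta / nrm
    d_beta += 2.0 * cfg.lambda3 * (L @ p.beta)
    d_b = float(dz.sum())
    d_gamma = (dz @ extra_b) if extra_b is not None else None

    dH = np.outer(dz, p.beta)
    d_w1 = np.zeros_like(p.w1)
    d_w2 = np.zeros_like(p.w2)
    for t in range(p.n_layers - 1, -1, -1):
        dg = dH * np.where(gs[t] >= 0, 1.0, LEAKY_ALPHA)
        prop = hs[t] @ P.T
        d_w1[t] = np.sign(p.w1[t]) * float(np.sum(dg * prop))
        d_w2[t] = np.sign(p.w2[t]) * float(np.sum(dg * hs[t]))
        dH = np.abs(p.w1[t]) * (dg @ P) + np.abs(p.w2[t]) * dg
    d_a0 = np.einsum("nm,nmf->f", dH, Xb)
    d_W0 = np.sign(p.W0) * d_a0
    return total, [d_W0, d_w1, d_w2, d_beta, np.array([d_b])] + \
        ([d_gamma] if d_gamma is not None else [])


def init_params(n_features: int, n_cells: int, n_layers: int,
                n_extra: int = 0, seed: int = 0) -> ModelParams:
    rng = np.random.default_rng(seed)
    return ModelParams(
        W0=rng.normal(scale=1.0 / np.sqrt(n_features), size=n_features),
        w1=np.full(n_layers, 0.5),
        w2=np.full(n_layers, 0.5),
        beta=rng.normal(scale=1.0 / np.sqrt(n_cells), size=n_cells),
        b=0.0,
        gamma=(rng.normal(scale=0.1, size=n_extra) if n_extra else None),
    )


@dataclass
class ModelData:
    """Everything a fit needs: normalized features, labels, graph, splits."""

    X: np.ndarray                      # N x M x F, normalized
    y: np.ndarray                      # N
    graph: CellGraph
    extra: np.ndarray | None = None    # N x K, train-scaled
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None


def evaluate(scores: np.ndarray, labels: np.ndarray,
             task: str = "binary") -> dict:
    """AUROC/AUPRC for binary labels, Pearson r for regression."""
    if task == "binary":
        from sklearn.metrics import average_precision_score, roc_auc_score

        y = np.asarray(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("AUROC undefined for single-class labels")
        return {"auroc": float(roc_auc_score(y, scores)),
                "auprc": float(average_precision_score(y, scores))}
    r = pearsonr(np.asarray(labels, dtype=float), np.asarray(scores))[0]
    return {"pearson_r": float(r)}


def _val_metric(metrics: dict, task: str) -> float:
    return metrics["auroc"] if task == "binary" else metrics["pearson_r"]


def fit(data: ModelData, cfg: TrainConfig) -> FitResult:
    """Train by mini-batch Adam; fully reproducible under ``cfg.seed``.

    Records the mean per-epoch training loss and, when a validation split is
    present, the per-epoch validation metric.  Raises on non-finite loss.
    """
    rng = np.random.default_rng(cfg.seed)
    tr = (data.train_idx if data.train_idx is not None
          else np.arange(len(data.y)))
    n_extra = data.extra.shape[1] if (cfg.use_extra and data.extra is not None) else 0
    extra = data.extra if n_extra else None
    p = init_params(data.X.shape[2], data.X.shape[1], cfg.n_layers,
                    n_extra, cfg.seed)
    P = data.graph.propagation_matrix()
    L = data.graph.laplacian
    plist = [p.W0, p.w1, p.w2, p.beta, np.array([p.b])]
    if p.gamma is not None:
        plist.append(p.gamma)
    opt = _Adam([q.shape for q in plist], cfg.lr)

    Xtr, ytr = data.X[tr], np.asarray(data.y, dtype=float)[tr]
    Etr = extra[tr] if extra is not None else None
    loss_trace, val_trace = [], []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(tr))
        batch_losses = []
        for start in range(0, len(tr), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            lb, grads = _gradients(
                p, Xtr[sel], ytr[sel], P, L, cfg,
                Etr[sel] if Etr is not None else None)
            if not np.isfinite(lb):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={lb!r}, "
                    f"config={cfg}")
            opt.step(plist, grads)
            p.b = float(plist[4][0])
            batch_losses.append(lb)
        loss_trace.append(float(np.mean(batch_losses)))
        if data.val_idx is not None and len(data.val_idx):
            sc, _ = forward(p, data.X[data.val_idx], data.graph,
                            extra[data.val_idx] if extra is not None else None,
                            cfg.task)
            try:
                val_trace.append(_val_metric(
                    evaluate(sc, data.y[data.val_idx], cfg.task), cfg.task))
            except ValueError:
                val_trace.append(float("nan"))

    val_metric = val_trace[-1] if val_trace else float("nan")
    test_metrics = {}
    if data.test_idx is not None and len(data.test_idx):
        sc, _ = forward(p, data.X[data.test_idx], data.graph,
                        extra[data.test_idx] if extra is not None else None,
                        cfg.task)
        test_metrics = evaluate(sc, data.y[data.test_idx], cfg.task)
    return FitResult(params=p, loss_trace=loss_trace, val_trace=val_trace,
                     val_metric=float(val_metric), test_metrics=test_metrics,
                     splits={"train": tr,
                             "val": data.val_idx,
                             "test": data.test_idx},
                     seed=cfg.seed, config=cfg)


def default_grid(task: str = "binary", **overrides) -> list[TrainConfig]:
    """Full hyperparameter grid (T x lambda1 x lambda2 x lambda3 x k)."""
    out = []
    for T, l1, l2, l3, k in itertools.product(GRID_T, GRID_LAMBDA1,
                                              GRID_LAMBDA2, GRID_LAMBDA3,
                                              GRID_K):
        out.append(TrainConfig(n_layers=T, lambda1=l1, lambda2=l2,
                               lambda3=l3, k=k, task=task, **overrides))
    return out


def grid_search(data: ModelData, grids: list[TrainConfig],
                seed: int | None = None) -> tuple[FitResult, list[FitResult]]:
    """Train one model per configuration; select by validation metric.

    Returns (best fit, all fits).  The validation metric is AUROC for the
    binary task and Pearson r for regression; held-out test metrics are
    reported on the selected model.
    """
    if not grids:
        raise ValueError("empty hyperparameter grid")
    fits = []
    for cfg in grids:
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        fits.append(fit(data, cfg))
    best = max(fits, key=lambda f: f.val_metric)
    return best, fits


def cross_validate(data: ModelData, cfgs: list[TrainConfig], folds: int = 5,
                   repeats: int = 5, seed: int = 0
                   ) -> tuple[TrainConfig, FitResult, np.ndarray]:
    """Repeated k-fold selection, then a final fit on the entire dataset.

    Each configuration's score is its mean validation metric across
    folds x repeats; the argmax configuration is refit on all samples.
    Returns (best config, final fit, per-config mean scores).
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    y = np.asarray(data.y)
    n = len(y)
    if n < folds:
        raise ValueError("fewer samples than folds")
    scores = np.zeros((len(cfgs), repeats * folds))
    col = 0
    for rep in range(repeats):
        if cfgs[0].task == "binary":
            kf = StratifiedKFold(n_splits=folds, shuffle=True,
                                 random_state=seed + rep)
            splits = kf.split(np.zeros(n), y)
        else:
            kf = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
            splits = kf.split(np.zeros(n))
        for tr, va in splits:
            d = replace_data(data, train_idx=np.sort(tr),
                             val_idx=np.sort(va), test_idx=None)
            for ci, cfg in enumerate(cfgs):
                scores[ci, col] = fit(d, cfg).val_metric
            col += 1
    mean_scores = scores.mean(axis=1)
    best_cfg = cfgs[int(np.argmax(mean_scores))]
    final = fit(replace_data(data, train_idx=np.arange(n), val_idx=None,
                             test_idx=None), best_cfg)
    return best_cfg, final, mean_scores


def replace_data(data: ModelData, **kw) -> ModelData:
    base = dict(X=data.X, y=data.y, graph=data.graph, extra=data.extra,
                train_idx=data.train_idx, val_idx=data.val_idx,
                test_idx=data.test_idx)
    base.update(kw)
    return ModelData(**base)
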