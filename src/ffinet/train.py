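"""Dataset splitting, Adam optimisation with early stopping, and metrics.

Defaults: batch size 128, Adam lr 1e-3 with plateau decay x0.5, early
stopping on validation loss with patience 30, 8:1:1 random split.  Regression
labels are z-scored on the training split and de-standardised at evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .geometry import BasisScaler, assemble_basis
from .khop import build_khop_index
from .model import FFiNet, GraphData, batch_graphs, forward

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "random_split",
    "fit",
    "evaluate",
    "run_repeats",
    "rmse",
    "mae",
    "pearson_r",
    "sd_metric",
    "masked_roc_auc",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 1e-3
    max_epochs: int = 300
    patience: int = 30
    lr_patience: int = 10
    lr_decay: float = 0.5
    seed: int = 0
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    monitor: str = "val_loss"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")


@dataclass
class MetricsReport:
    rmse: float = float("nan")
    mae: float = float("nan")
    roc_auc: float = float("nan")
    pearson_r: float = float("nan")
    sd: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "roc_auc": self.roc_auc,
            "pearson_r": self.pearson_r,
            "sd": self.sd,
        }


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def random_split(
    n: int,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint exhaustive train/val/test index sets.

    Sizes follow largest-remainder rounding of the ratios; the permutation is
    reproducible per seed.
    """
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    raw = np.asarray(ratios, dtype=float) * n
    sizes = np.floor(raw).astype(int)
    rem = raw - sizes
    for idx in np.argsort(-rem)[: n - sizes.sum()]:
        sizes[idx] += 1
    perm = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return perm[:a], perm[a:b], perm[b:]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(yhat)) ** 2)))


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(y) - np.asarray(yhat))))


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(sps.pearsonr(np.asarray(y), np.asarray(yhat)).statistic)


def sd_metric(y: np.ndarray, yhat: np.ndarray) -> float:
    """Residual standard deviation about the least-squares line of y on yhat
    (Pafnucy convention): sqrt( sum(y - (a + b*yhat))^2 / (N - 1) )."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    b, a = np.polyfit(yhat, y, 1)
    resid = y - (a + b * yhat)
    return float(np.sqrt(np.sum(resid**2) / (len(y) - 1)))


def masked_roc_auc(labels: np.ndarray, scores: np.ndarray, mask: np.ndarray) -> float:
    """Macro ROC-AUC over tasks using only unmasked labels; single-class
    tasks are skipped with a warning."""
    labels = np.atleast_2d(np.asarray(labels, dtype=float).T).T
    scores = np.atleast_2d(np.asarray(scores, dtype=float).T).T
    mask = np.atleast_2d(np.asarray(mask, dtype=bool).T).T
    aucs = []
    for t in range(labels.shape[1]):
        m = mask[:, t]
        yt = labels[m, t]
        if m.sum() == 0 or len(np.unique(yt)) < 2:
            logger.warning("task %d has a single class; skipped in ROC-AUC", t)
            continue
        aucs.append(roc_auc_score(yt, scores[m, t]))
    return float(np.mean(aucs)) if aucs else float("nan")


def evaluate(model: FFiNet, records: Sequence, task: str | None = None) -> MetricsReport:
    """Compute the metric suite on a labelled record set."""
    task = task or model.config.task
    preds = model.predict(records)
    labels = np.stack([r.labels for r in records])
    mask = np.stack([r.label_mask for r in records])
    rep = MetricsReport()
    if task == "regression":
        y = labels[:, 0][mask[:, 0]]
        yhat = preds[:, 0][mask[:, 0]]
        rep.rmse = rmse(y, yhat)
        rep.mae = mae(y, yhat)
        rep.pearson_r = pearson_r(y, yhat)
        rep.sd = sd_metric(y, yhat)
    else:
        rep.roc_auc = masked_roc_auc(labels, preds, mask)
    return rep


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _masked_mse(pred, labels, mask):
    diff = (pred - labels) * mask
    return anp.sum(diff**2) / anp.maximum(anp.sum(mask), 1.0)


def _masked_bce(logits, labels, mask):
    # stable binary cross-entropy with logits
    loss = anp.maximum(logits, 0.0) - logits * labels + anp.log1p(anp.exp(-anp.abs(logits)))
    return anp.sum(loss * mask) / anp.maximum(anp.sum(mask), 1.0)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

def _prepare(model: FFiNet, records: Sequence, fit_stats: bool) -> list[GraphData]:
    """Build graphs; when ``fit_stats`` freeze scaler/label statistics from
    these (training) records first."""
    if fit_stats:
        bases = []
        for r in records:
            if hasattr(r, "bonds") and not hasattr(r, "nonbonded_pairs"):
                idx = build_khop_index(r.bonds, r.n_atoms, dedupe_hops=model.config.dedupe_hops)
                bases.append(assemble_basis(r.positions, idx))
            else:
                idx = build_khop_index(r.bonds, r.n_atoms)
                bases.append(assemble_basis(r.positions, idx))
        model.scaler = BasisScaler().fit(bases)
        if model.config.task == "regression":
            labels = np.stack([r.labels for r in records])
            mask = np.stack([r.label_mask for r in records])
            mean = np.array(
                [labels[mask[:, t], t].mean() if mask[:, t].any() else 0.0
                 for t in range(labels.shape[1])]
            )
            std = np.array(
                [labels[mask[:, t], t].std() if mask[:, t].any() else 1.0
                 for t in range(labels.shape[1])]
            )
            model.label_mean = mean
            model.label_std = np.where(std > 1e-12, std, 1.0)
    return [model.graph_for(r) for r in records]


def _epoch_loss(model: FFiNet, graphs, labels, mask) -> float:
    batch = batch_graphs(graphs)
    out = forward(model.params, batch, model.config)
    if model.config.task == "regression":
        std_labels = (labels - model.label_mean) / model.label_std
        return float(_masked_mse(out, std_labels, mask))
    return float(_masked_bce(out, labels, mask))


def fit(
    model: FFiNet,
    train_records: Sequence,
    val_records: Sequence,
    config: TrainConfig | None = None,
) -> tuple[FFiNet, list[dict]]:
    """Train with Adam + early stopping; restores the best-validation
    parameters on the model and returns (model, per-epoch history)."""
    config = config or TrainConfig()
    if not len(train_records) or not len(val_records):
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)

    train_graphs = _prepare(model, train_records, fit_stats=True)
    val_graphs = [model.graph_for(r) for r in val_records]
    n_tasks = model.config.n_tasks
    tr_labels = np.stack([r.labels for r in train_records]).reshape(-1, n_tasks)
    tr_mask = np.stack([r.label_mask for r in train_records]).reshape(-1, n_tasks).astype(float)
    va_labels = np.stack([r.labels for r in val_records]).reshape(-1, n_tasks)
    va_mask = np.stack([r.label_mask for r in val_records]).reshape(-1, n_tasks).astype(float)

    flat_params, unflatten = flatten(model.params)
    m_adam = np.zeros_like(flat_params)
    v_adam = np.zeros_like(flat_params)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    step = 0

    cfg = model.config
    drop = cfg.dropout

    def batch_loss(params, batch, labels, mask, masks_drop):
        out = forward(params, batch, cfg, dropout_masks=masks_drop)
        if cfg.task == "regression":
            std_labels = (labels - model.label_mean) / model.label_std
            return _masked_mse(out, std_labels, mask)
        return _masked_bce(out, labels, mask)

    loss_grad = value_and_grad(batch_loss)

    best_loss = np.inf
    best_flat = flat_params.copy()
    best_epoch = -1
    bad_epochs = 0
    lr_bad = 0
    history: list[dict] = []

    n = len(train_graphs)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_train_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = batch_graphs([train_graphs[i] for i in idx])
            masks_drop = None
            if drop > 0:
                masks_drop = [
                    (rng.random((batch.n_atoms, cfg.hidden_dim)) >= drop) / (1.0 - drop)
                    for _ in range(cfg.n_layers)
                ]
            model.params = unflatten(flat_params)
            loss, grads = loss_grad(model.params, batch, tr_labels[idx], tr_mask[idx], masks_drop)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; try a lower learning rate "
                    f"(current {lr:g}) or check input geometry for near-coincident atoms"
                )
            g, _ = flatten(grads)
            step += 1
            m_adam = beta1 * m_adam + (1 - beta1) * g
            v_adam = beta2 * v_adam + (1 - beta2) * g * g
            mhat = m_adam / (1 - beta1**step)
            vhat = v_adam / (1 - beta2**step)
            flat_params = flat_params - lr * mhat / (np.sqrt(vhat) + eps)
            epoch_train_loss += float(loss)
            n_batches += 1

        model.params = unflatten(flat_params)
        val_loss = _epoch_loss(model, val_graphs, va_labels, va_mask)
        improved = val_loss < best_loss - 1e-12
        if improved:
            best_loss = val_loss
            best_flat = flat_params.copy()
            best_epoch = epoch
            bad_epochs = 0
            lr_bad = 0
        else:
            bad_epochs += 1
            lr_bad += 1
            if lr_bad > config.lr_patience:
                lr *= config.lr_decay
                lr_bad = 0
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_train_loss / max(n_batches, 1),
                "val_loss": val_loss,
                "best_val_loss": best_loss,
                "lr": lr,
            }
        )
        logger.info(
            "epoch %d train %.5f val %.5f best %.5f", epoch,
            history[-1]["train_loss"], val_loss, best_loss,
        )
        if bad_epochs > config.patience:
            break

    model.params = unflatten(best_flat)
    logger.info("best epoch %d (val loss %.5f)", best_epoch, best_loss)
    return model, history


def search_hyperparameters(
    space: dict[str, Sequence],
    train_records: Sequence,
    val_records: Sequence,
    n_features: int,
    n_trials: int = 8,
    seed: int = 0,
    base_model: dict | None = None,
    base_train: dict | None = None,
) -> tuple[dict, list[dict]]:
    """Small-budget random search over model/train settings.

    ``space`` maps a ModelConfig or TrainConfig field name to candidate
    values; each trial samples one value per field, trains, and is scored by
    best validation loss.  Returns (best setting dict, all trial records).
    A deliberate hook, not a full Bayesian optimiser.
    """
    from .model import FFiNet, ModelConfig

    model_fields = {f.name for f in ModelConfig.__dataclass_fields__.values()}
    train_fields = {f.name for f in TrainConfig.__dataclass_fields__.values()}
    unknown = set(space) - model_fields - train_fields
    if unknown:
        raise ValueError(f"unknown hyperparameter(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    trials = []
    for t in range(n_trials):
        setting = {k: v[int(rng.integers(len(v)))] for k, v in space.items()}
        mkw = dict(base_model or {})
        tkw = dict(base_train or {})
        mkw.update({k: v for k, v in setting.items() if k in model_fields})
        tkw.update({k: v for k, v in setting.items() if k in train_fields})
        model = FFiNet(ModelConfig(**mkw), n_features)
        _, hist = fit(model, train_records, val_records, TrainConfig(**tkw))
        score = min(h["val_loss"] for h in hist)
        trials.append({"trial": t, "setting": setting, "val_loss": score})
        logger.info("trial %d %s -> val loss %.5f", t, setting, score)
    best = min(trials, key=lambda r: r["val_loss"])
    return best["setting"], trials


def run_repeats(
    experiment: Callable[[int], MetricsReport],
    seeds: Iterable[int] = (0, 1, 2),
) -> dict[str, tuple[float, float]]:
    """Run an experiment per seed and aggregate each metric's mean and std."""
    seeds = list(seeds)
    if len(seeds) == 1:
        logger.warning("run_repeats with a single seed: std reported as 0")
    reports = [experiment(s) for s in seeds]
    out: dict[str, tuple[float, float]] = {}
    for key in MetricsReport().to_dict():
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        if np.all(np.isnan(vals)):
            continue
        out[key] = (float(np.nanmean(vals)), float(np.nanstd(vals)) if len(seeds) > 1 else 0.0)
    return out
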