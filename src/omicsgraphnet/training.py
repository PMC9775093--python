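"""Losses, dataset splitting, and the two-stage training loop.

The composite objective is

    L = sum_l alpha_l * L_GCN_l + lambda_f * L_F,

where L_GCN_l is the sum of per-sample cross-entropies of omics module
l and L_F the same for the fused output. Stage 1 ("pretraining") trains
each omics module alone on its own loss, optionally weighting each
sample's term by the label affinity of its 1-hop graph neighborhood;
stage 2 ("fine-tuning") jointly optimizes all modules plus the fusion
head, with separate learning rates for the modules and the terminal
head. All losses are sums (not means) over samples, so their scale
grows with the partition size; Adam's per-parameter normalization makes
the optimization insensitive to that scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .datatypes import LabelVector, OmicsMatrix
from .graph import SimilarityGraph
from .model import MultiOmicsGcn

__all__ = [
    "LR_GRID",
    "TrainConfig",
    "SplitSpec",
    "cross_entropy",
    "module_loss",
    "total_loss",
    "smooth_sample_weights",
    "label_affinity",
    "pretrain",
    "finetune",
    "split_dataset",
    "kfold_splits",
    "grid_search_learning_rates",
]

#: Learning-rate search space shared by all three stages.
LR_GRID = (1e-7, 5e-7, 1e-6, 5e-6, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults: 500 pretraining epochs, 2500 fine-tuning epochs, Adam,
    Xavier initialization, per-omics loss weights alpha_l = 1 and fusion
    weight lambda_f = 1. The three learning rates (pretraining, joint
    training, terminal head) each come from :data:`LR_GRID`; the
    defaults here are mid-grid values that converge reliably on the
    synthetic cohorts.
    """

    pretrain_epochs: int = 500
    finetune_epochs: int = 2500
    lr_pretrain: float = 1e-3
    lr_train: float = 5e-4
    lr_terminal: float = 1e-3
    alpha: tuple[float, ...] = (1.0, 1.0)
    lambda_f: float = 1.0
    seed: int = 0
    optimizer: str = "adam"
    init: str = "xavier"
    use_affinity_weights: bool = True
    clip_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.init != "xavier":
            raise ValueError("only xavier initialization is supported")


@dataclass
class SplitSpec:
    """A stratified train/validation/test partition of sample IDs."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    ratios: tuple[float, float, float] = (0.55, 0.15, 0.30)
    seed: int = 0

    @property
    def all_ids(self) -> list[str]:
        return self.train_ids + self.val_ids + self.test_ids


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def cross_entropy(
    y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-12
) -> float:
    """Cross-entropy of one probability row against a one-hot row."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if abs(y_pred.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"prediction row sums to {y_pred.sum():.6g}, not a distribution"
        )
    p = np.clip(y_pred, eps, 1.0 - eps)
    return float(-(y_true * np.log(p)).sum())


def module_loss(Y: np.ndarray, probs: np.ndarray) -> float:
    """Sum of per-sample cross-entropies for one omics module."""
    Y = np.asarray(Y, float)
    probs = np.asarray(probs, float)
    if Y.shape[0] != probs.shape[0]:
        raise ValueError(
            f"label count {Y.shape[0]} != prediction count {probs.shape[0]}"
        )
    return float(sum(cross_entropy(y, p) for y, p in zip(Y, probs)))


def total_loss(
    module_losses: list[float],
    fusion_loss: float,
    alphas: list[float],
    lambda_f: float,
) -> float:
    """Composite objective: sum_l alpha_l * L_l + lambda_f * L_F."""
    if len(module_losses) != len(alphas):
        raise ValueError(
            f"{len(module_losses)} module losses but {len(alphas)} alphas"
        )
    return float(
        sum(a * l for a, l in zip(alphas, module_losses))
        + lambda_f * fusion_loss
    )


# ---------------------------------------------------------------------------
# graph-informed sample weighting and outlier clipping
# ---------------------------------------------------------------------------


def smooth_sample_weights(
    X: OmicsMatrix,
    graph: SimilarityGraph,
    labels: LabelVector,
    clip_sd: float = 3.0,
    labeled_mask: np.ndarray | None = None,
) -> tuple[OmicsMatrix, np.ndarray]:
    """Clip outlying feature values and compute 1-hop label affinities.

    Returns ``(clipped_matrix, affinity)`` where

    * every feature value further than ``clip_sd`` standard deviations
      from its feature mean is clipped to that bound (restraining
      protruding components of the per-sample weight vectors), and
    * ``affinity[k, c]`` is the fraction of sample k's 1-hop graph
      neighbors carrying class c; samples with no (labeled) neighbor get
      (0.5, 0.5). ``labeled_mask`` restricts the neighbor count to
      samples whose labels may be used (the training partition in a
      transductive graph); by default all samples count.

    During pretraining each sample's cross-entropy term is weighted by
    the affinity of its true class, down-weighting samples whose labels
    disagree with their graph neighborhood.
    """
    values = X.values
    if math.isfinite(clip_sd):
        mean = values.mean(axis=0)
        sd = values.std(axis=0)
        lo, hi = mean - clip_sd * sd, mean + clip_sd * sd
        values = np.clip(values, lo, hi)
    clipped = OmicsMatrix(
        values, list(X.sample_ids), list(X.feature_ids), X.omics_kind
    )
    affinity = label_affinity(graph.adjacency, labels.labels, labeled_mask)
    return clipped, affinity


def label_affinity(
    adjacency: np.ndarray,
    y: np.ndarray,
    labeled_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Fraction of each sample's 1-hop neighbors carrying each class.

    Neighbors outside ``labeled_mask`` (when given) are ignored; samples
    with no labeled neighbor default to (0.5, 0.5).
    """
    neighbor = np.asarray(adjacency) > 0
    if labeled_mask is not None:
        neighbor = neighbor & np.asarray(labeled_mask, bool)[None, :]
    y = np.asarray(y, int)
    n = y.size
    affinity = np.full((n, 2), 0.5)
    counts = neighbor.sum(axis=1)
    pos = neighbor.astype(float) @ (y == 1).astype(float)
    has = counts > 0
    affinity[has, 1] = pos[has] / counts[has]
    affinity[has, 0] = 1.0 - affinity[has, 1]
    return affinity


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def _check_finite(loss: float, epoch: int, stage: str) -> None:
    if not math.isfinite(loss):
        raise FloatingPointError(
            f"{stage} diverged to non-finite loss at epoch {epoch}"
        )


def pretrain(
    model: MultiOmicsGcn,
    X_list: list[np.ndarray],
    A_hat_list: list[np.ndarray],
    Y: np.ndarray,
    train_mask: np.ndarray,
    config: TrainConfig,
    affinity: np.ndarray | list[np.ndarray] | None = None,
) -> list[list[float]]:
    """Stage 1: train each omics module independently on its own loss.

    ``train_mask`` selects the samples whose loss terms count (the graph
    and forward pass are transductive over all rows of ``X_list``).
    ``affinity`` optionally carries per-sample class affinities from
    :func:`smooth_sample_weights` — one array shared by all modules or a
    list with one array per omics block; the weight of sample k is then
    the affinity of its true class. Returns per-module epoch loss curves.
    """
    if affinity is None or not config.use_affinity_weights:
        weight_list = [None] * len(model.modules)
    elif isinstance(affinity, (list, tuple)):
        weight_list = [(a * Y).sum(axis=1) for a in affinity]
    else:
        weight_list = [(affinity * Y).sum(axis=1)] * len(model.modules)
    histories: list[list[float]] = []
    for m, X, A_hat, weights in zip(
        model.modules, X_list, A_hat_list, weight_list
    ):
        opt = nn.Adam(m.params(), lr=config.lr_pretrain)
        history: list[float] = []
        for epoch in range(config.pretrain_epochs):
            logits = m.forward(X, A_hat, training=True)
            loss, dlogits = nn.softmax_cross_entropy(
                logits, Y, sample_weight=weights, mask=train_mask
            )
            _check_finite(loss, epoch, "pretraining")
            opt.zero_grad()
            m.backward(dlogits)
            opt.step()
            history.append(loss)
        histories.append(history)
    return histories


def finetune(
    model: MultiOmicsGcn,
    X_list: list[np.ndarray],
    A_hat_list: list[np.ndarray],
    Y: np.ndarray,
    train_mask: np.ndarray,
    config: TrainConfig,
) -> list[float]:
    """Stage 2: jointly train all modules and the fusion head.

    Modules step with ``lr_train``, the terminal head with
    ``lr_terminal``. Returns the epoch history of the composite loss.
    """
    alphas = list(config.alpha)[: len(model.modules)]
    if len(alphas) != len(model.modules):
        raise ValueError(
            f"{len(alphas)} alpha weights for {len(model.modules)} modules"
        )
    opt_modules = nn.Adam(model.module_params(), lr=config.lr_train)
    opt_head = nn.Adam(model.head_params(), lr=config.lr_terminal)
    history: list[float] = []
    for epoch in range(config.finetune_epochs):
        module_logits, fused = model.forward(X_list, A_hat_list, training=True)
        losses, dlogits = [], []
        for logits in module_logits:
            loss, d = nn.softmax_cross_entropy(logits, Y, mask=train_mask)
            losses.append(loss)
            dlogits.append(d)
        fusion_loss, dfused = nn.softmax_cross_entropy(
            fused, Y, mask=train_mask
        )
        loss = total_loss(losses, fusion_loss, alphas, config.lambda_f)
        _check_finite(loss, epoch, "fine-tuning")
        opt_modules.zero_grad()
        opt_head.zero_grad()
        fusion_grads = model.backward_fused(config.lambda_f * dfused)
        for m, d, a, gf in zip(model.modules, dlogits, alphas, fusion_grads):
            if model.spec.fusion_input == "logits":
                m.backward(a * d + gf)
            else:
                m.backward(a * d, grad_penultimate=gf)
        opt_modules.step()
        opt_head.step()
        history.append(loss)
    return history


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _largest_remainder(quotas: np.ndarray) -> np.ndarray:
    """Integer apportionment preserving the total, ties to earlier slots."""
    floors = np.floor(quotas).astype(int)
    deficit = int(round(quotas.sum())) - floors.sum()
    order = np.lexsort((np.arange(quotas.size), -(quotas - floors)))
    for i in order[:deficit]:
        floors[i] += 1
    return floors


def split_dataset(
    labels: LabelVector,
    ratios: tuple[float, float, float] = (0.55, 0.15, 0.30),
    seed: int = 0,
) -> SplitSpec:
    """Stratified train/validation/test split with exact global sizes.

    Global part sizes follow largest-remainder rounding of
    ``n * ratios``; within that constraint each class is apportioned as
    proportionally as integers allow (controlled rounding), so realized
    class balance per part is within one sample of proportional. The
    assignment of individual samples is a seeded shuffle within class.
    """
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios {ratios} do not sum to 1")
    y = labels.labels
    n = y.size
    classes = sorted(np.unique(y))
    for c in classes:
        if (y == c).sum() < 3:
            raise ValueError(
                f"class {c} has fewer than 3 samples; cannot split 3 ways"
            )
    global_counts = _largest_remainder(np.array([n * r for r in ratios]))
    # controlled rounding of the class x part allocation table
    quotas = np.array(
        [[(y == c).sum() * r for r in ratios] for c in classes]
    )
    alloc = np.floor(quotas).astype(int)
    row_deficit = quotas.sum(axis=1).round().astype(int) - alloc.sum(axis=1)
    col_deficit = global_counts - alloc.sum(axis=0)
    remainders = quotas - np.floor(quotas)
    cells = sorted(
        ((ci, pi) for ci in range(len(classes)) for pi in range(3)),
        key=lambda cp: (-remainders[cp], cp[1], cp[0]),
    )
    for ci, pi in cells:
        if row_deficit[ci] > 0 and col_deficit[pi] > 0:
            alloc[ci, pi] += 1
            row_deficit[ci] -= 1
            col_deficit[pi] -= 1
    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[], [], []]
    ids = np.asarray(labels.sample_ids, dtype=object)
    for ci, c in enumerate(classes):
        members = ids[y == c]
        rng.shuffle(members)
        start = 0
        for pi in range(3):
            parts[pi].extend(members[start : start + alloc[ci, pi]])
            start += alloc[ci, pi]
    return SplitSpec(parts[0], parts[1], parts[2], ratios, seed)


def kfold_splits(
    train_ids: list[str],
    labels: LabelVector,
    k: int = 5,
    seed: int = 0,
) -> list[list[str]]:
    """Stratified k-fold partition of the training IDs.

    Returns k disjoint validation folds (their union is ``train_ids``),
    each with class balance within one sample of proportional.
    """
    if k > len(train_ids):
        raise ValueError(f"k={k} exceeds {len(train_ids)} training samples")
    sub = labels.subset(list(train_ids))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    ids = np.asarray(train_ids, dtype=object)
    for _, val_idx in skf.split(np.zeros(len(train_ids)), sub.labels):
        folds.append(list(ids[val_idx]))
    return folds


# ---------------------------------------------------------------------------
# learning-rate search
# ---------------------------------------------------------------------------


def grid_search_learning_rates(
    evaluate,
    grid: list[tuple[float, float, float]] | None = None,
    n_sample: int | None = None,
    seed: int = 0,
) -> tuple[tuple[float, float, float], float]:
    """Pick the (lr_pretrain, lr_train, lr_terminal) triple by validation F1.

    ``evaluate(triple)`` must return the mean validation macro F1 across
    cross-validation folds for that learning-rate triple. The default
    grid is the full cube over :data:`LR_GRID` (1000 triples);
    ``n_sample`` draws a random subset for desk-scale runs. Ties are
    broken toward the smaller ``lr_train``, then ``lr_pretrain``, then
    ``lr_terminal``. Returns ``(best_triple, best_score)``.
    """
    if grid is None:
        grid = [tuple(t) for t in itertools.product(LR_GRID, repeat=3)]
    if not grid:
        raise ValueError("empty learning-rate grid")
    if n_sample is not None and n_sample < len(grid):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(grid), size=n_sample, replace=False)
        grid = [grid[i] for i in sorted(idx)]
    best_triple, best_score = None, -np.inf
    for triple in grid:
        score = float(evaluate(tuple(triple)))
        better = score > best_score
        tie = score == best_score and best_triple is not None
        if tie:
            key = (triple[1], triple[0], triple[2])
            best_key = (best_triple[1], best_triple[0], best_triple[2])
            better = key < best_key
        if better:
            best_triple, best_score = tuple(triple), score
    return best_triple, best_score
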