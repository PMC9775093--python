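"""Baseline classifiers and the cross-validated comparison harness.

Three baselines mirror the main model's shared settings (LeakyReLU
slope 0.25, Adam, cross-entropy, 400 hidden units, 200-dimensional FC
layers, dropout 0.5):

* ``cnn`` — a 1-D convolution over the feature axis, max pooling with
  kernel 2 / stride 1 / zero padding, dropout, then the FC stack;
* ``logistic_regression`` — batch normalization, dropout, and a single
  affine layer to the 2-class logits;
* ``naive_bayes`` — an FC stack whose weights carry a standard-normal
  prior, realized as an L2 penalty (the negative log-prior) added to
  the cross-entropy objective.

The comparison harness runs every model on identical preprocessed
inputs and identical cross-validation folds and tabulates all seven
metrics as mean +/- SD across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .datatypes import CohortBundle, LabelVector
from .metrics import evaluate_predictions
from .pipeline import PipelineConfig, preprocess_features, run_pipeline
from .training import SplitSpec

__all__ = [
    "BaselineSpec",
    "BaselineModel",
    "build_baseline",
    "compare_models",
    "make_baseline_runner",
    "make_gcn_runner",
]

BASELINE_KINDS = ("cnn", "logistic_regression", "naive_bayes")


@dataclass
class BaselineSpec:
    """Configuration of one baseline, mirroring the main model's settings."""

    kind: str
    hidden_units: int = 400
    fc_dim: int = 200
    dropout_rate: float = 0.5
    leaky_slope: float = 0.25
    cnn_channels: int = 8
    cnn_kernel: int = 5
    epochs: int = 500
    lr: float = 1e-3
    nb_prior_scale: float = 1.0  # std-normal prior => unit L2 coefficient

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise ValueError(
                f"unknown baseline kind {self.kind!r}; expected one of "
                f"{BASELINE_KINDS}"
            )


class BaselineModel:
    """A trainable baseline with the fit/predict surface of the harness."""

    def __init__(self, spec: BaselineSpec, input_dim: int, seed: int = 0):
        self.spec = spec
        self.input_dim = input_dim
        rng = np.random.default_rng(seed)
        s = spec
        act = lambda: nn.LeakyReLU(s.leaky_slope)  # noqa: E731
        if s.kind == "cnn":
            self._reshape_3d = True
            self.net = nn.Sequential(
                nn.Conv1d(1, s.cnn_channels, s.cnn_kernel, rng),
                act(),
                nn.MaxPool1d(),
                nn.Dropout(s.dropout_rate, rng),
                nn.Flatten(),
                nn.Dense(s.cnn_channels * input_dim, s.hidden_units, rng),
                act(),
                nn.Dropout(s.dropout_rate, rng),
                nn.Dense(s.hidden_units, s.fc_dim, rng),
                act(),
                nn.Dense(s.fc_dim, 2, rng),
            )
        elif s.kind == "logistic_regression":
            self._reshape_3d = False
            self.net = nn.Sequential(
                nn.BatchNorm(input_dim),
                nn.Dropout(s.dropout_rate, rng),
                nn.Dense(input_dim, 2, rng),
            )
        else:  # naive_bayes
            self._reshape_3d = False
            self.net = nn.Sequential(
                nn.Dense(input_dim, s.hidden_units, rng),
                act(),
                nn.Dropout(s.dropout_rate, rng),
                nn.Dense(s.hidden_units, s.fc_dim, rng),
                act(),
                nn.Dense(s.fc_dim, 2, rng),
            )

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        X = np.asarray(X, float)
        if self._reshape_3d:
            X = X[:, None, :]
        return self.net.forward(X, training)

    def fit(self, X: np.ndarray, y: np.ndarray) -> list[float]:
        """Full-batch Adam training on cross-entropy; returns loss history."""
        Y = np.zeros((len(y), 2))
        Y[np.arange(len(y)), np.asarray(y, int)] = 1.0
        wd = (
            self.spec.nb_prior_scale
            if self.spec.kind == "naive_bayes"
            else 0.0
        )
        opt = nn.Adam(self.net.params(), lr=self.spec.lr, weight_decay=wd)
        history = []
        for epoch in range(self.spec.epochs):
            logits = self.forward(X, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, Y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"{self.spec.kind} diverged at epoch {epoch}"
                )
            opt.zero_grad()
            self.net.backward(dlogits)
            opt.step()
            history.append(loss)
        return history

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """P(cancer) per sample, inference mode."""
        return nn.softmax(self.forward(X, training=False))[:, 1]

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False).argmax(axis=1)


def build_baseline(
    spec: BaselineSpec, input_dim: int, seed: int = 0
) -> BaselineModel:
    """Construct one baseline model for ``input_dim`` input features."""
    return BaselineModel(spec, input_dim, seed)


# ---------------------------------------------------------------------------
# comparison harness
# ---------------------------------------------------------------------------

_METRICS = (
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "auc_roc",
    "macro_f1",
    "weighted_f1",
)


def make_baseline_runner(
    spec: BaselineSpec, cohort: CohortBundle, config: PipelineConfig, seed: int = 0
):
    """Fold runner for a baseline on concatenated preprocessed omics.

    Preprocessing (log transform, z-scoring, clipping) is refit on each
    fold's training rows so no held-out statistics leak in.
    """
    pos = {s: i for i, s in enumerate(cohort.sample_ids)}

    def run(train_ids: list[str], val_ids: list[str]):
        tr = np.array([pos[s] for s in train_ids])
        va = np.array([pos[s] for s in val_ids])
        mask = np.zeros(cohort.n_samples, bool)
        mask[tr] = True
        X = np.concatenate(
            preprocess_features(cohort, mask, config), axis=1
        )
        y = cohort.labels.labels
        model = build_baseline(spec, X.shape[1], seed)
        model.fit(X[tr], y[tr])
        return model.predict_labels(X[va]), model.predict_scores(X[va])

    return run


def make_gcn_runner(cohort: CohortBundle, config: PipelineConfig):
    """Fold runner for the multi-omics GCN (transductive over the fold)."""

    def run(train_ids: list[str], val_ids: list[str]):
        split = SplitSpec(list(train_ids), [], list(val_ids))
        fitted = run_pipeline(cohort, split, config)
        pred = fitted.predict()
        va = fitted.partition_indices("test")
        return pred.predicted_labels[va], pred.cancer_score[va]

    return run


def compare_models(
    runners: dict[str, callable],
    labels: LabelVector,
    folds: list[list[str]],
) -> tuple[pd.DataFrame, dict]:
    """Cross-validated seven-metric comparison on identical folds.

    ``runners`` maps model name to a callable
    ``run(train_ids, val_ids) -> (predicted_labels, scores)`` evaluated
    on the validation fold. Every model sees exactly the same folds.
    Returns a long-format table (model, metric, mean, sd) and the raw
    per-fold metric values; a failed fold is recorded as missing with a
    warning rather than aborting the comparison.
    """
    if len(runners) < 2:
        raise ValueError("comparison needs at least 2 models")
    all_ids = [s for fold in folds for s in fold]
    raw: dict[str, dict[str, list[float]]] = {
        name: {m: [] for m in _METRICS} for name in runners
    }
    for fold_idx, val_ids in enumerate(folds):
        fold_set = set(val_ids)
        train_ids = [s for s in all_ids if s not in fold_set]
        y_val = labels.subset(list(val_ids))
        for name, run in runners.items():
            try:
                pred, scores = run(train_ids, list(val_ids))
                report = evaluate_predictions(y_val, pred, scores)
            except Exception as err:  # noqa: BLE001 - recorded, not silent
                warnings.warn(
                    f"model {name!r} failed on fold {fold_idx}: {err}",
                    stacklevel=2,
                )
                for m in _METRICS:
                    raw[name][m].append(np.nan)
                continue
            values = report.as_dict()
            for m in _METRICS:
                raw[name][m].append(float(values[m]))
    rows = []
    for name in runners:
        for m in _METRICS:
            vals = np.asarray(raw[name][m], float)
            ok = vals[~np.isnan(vals)]
            rows.append(
                {
                    "model": name,
                    "metric": m,
                    "mean": ok.mean() if ok.size else np.nan,
                    "sd": ok.std(ddof=1) if ok.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows), raw
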