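"""End-to-end orchestration: preprocess, build graphs, train, evaluate.

The pipeline is transductive: graphs and forward passes cover the whole
cohort (train + validation + test rows), but only training-partition
labels ever enter a loss or an affinity weight; held-out samples are
scored with their labels masked.

Preprocessing is deliberately minimal: expression values are
log-transformed (log1p) and every feature is z-scored with
training-partition statistics, then clipped at ``clip_sd`` standard
deviations. Cosine similarity, and hence the sample graph, is computed
on these processed features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .datatypes import CohortBundle, MetricsReport, OmicsKind
from .feature_selection import (
    FeatureStats,
    compute_feature_stats,
    influence_scores,
    primary_filter,
    select_top_features,
)
from .graph import SimilarityGraph, build_graph
from .metrics import confusion, evaluate_predictions, macro_f1
from .model import GcnModelSpec, MultiOmicsGcn, PredictionMatrix, match_therapy
from .training import (
    TrainConfig,
    SplitSpec,
    finetune,
    label_affinity,
    pretrain,
)

__all__ = [
    "PipelineConfig",
    "TrainedPipeline",
    "FeatureSelectionResult",
    "run_pipeline",
    "preprocess_features",
    "run_feature_selection",
]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one training run."""

    model: GcnModelSpec = field(default_factory=GcnModelSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    tau: float | None = None
    target_mean_degree: float = 10.0
    log_transform_expression: bool = True
    standardize: bool = True


def preprocess_features(
    cohort: CohortBundle, train_mask: np.ndarray, config: PipelineConfig
) -> list[np.ndarray]:
    """Per-omics processed feature arrays (n_samples x p)."""
    out = []
    for m in cohort.matrices:
        X = m.values.copy()
        if (
            m.omics_kind is OmicsKind.EXPRESSION
            and config.log_transform_expression
        ):
            X = np.log1p(X)
        if config.standardize:
            mu = X[train_mask].mean(axis=0)
            sd = X[train_mask].std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
        clip = config.train.clip_sd
        if np.isfinite(clip):
            c_mu = X.mean(axis=0)
            c_sd = X.std(axis=0)
            X = np.clip(X, c_mu - clip * c_sd, c_mu + clip * c_sd)
        out.append(X)
    return out


@dataclass
class TrainedPipeline:
    """A fitted model together with the data and split it was fitted on."""

    cohort: CohortBundle
    split: SplitSpec
    config: PipelineConfig
    model: MultiOmicsGcn
    graphs: list[SimilarityGraph]
    A_hats: list  # per-omics propagation operators (sparse when the graph is)
    X_proc: list[np.ndarray]
    train_mask: np.ndarray
    pretrain_history: list[list[float]]
    finetune_history: list[float]

    def _indices(self, ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.cohort.sample_ids)}
        return np.array([pos[s] for s in ids], dtype=int)

    def partition_indices(self, partition: str) -> np.ndarray:
        ids = {
            "train": self.split.train_ids,
            "val": self.split.val_ids,
            "test": self.split.test_ids,
            "all": self.cohort.sample_ids,
        }[partition]
        return self._indices(ids)

    def predict(self, therapy_rules=None) -> PredictionMatrix:
        """Fused predictions for every cohort sample (inference mode)."""
        pred = self.model.predict(
            self.X_proc, self.A_hats, self.cohort.sample_ids
        )
        if therapy_rules is not None and self.cohort.variants is not None:
            pred.therapy = match_therapy(self.cohort.variants, therapy_rules)
        return pred

    def evaluate(self, partition: str = "test") -> MetricsReport:
        idx = self.partition_indices(partition)
        pred = self.predict()
        y = self.cohort.labels.labels[idx]
        return evaluate_predictions(
            y,
            pred.predicted_labels[idx],
            pred.cancer_score[idx],
            metadata={
                "partition": partition,
                "seed": self.config.train.seed,
                "tau": [g.tau for g in self.graphs],
            },
        )

    # -- influence support ------------------------------------------------
    def masked_macro_f1(
        self, omics_idx: int, feature_id: str, eval_idx: np.ndarray
    ) -> float:
        """Macro F1 on ``eval_idx`` with one feature masked out.

        The feature's processed column is replaced by its
        training-partition mean, the affected omics module re-run, and
        the fused prediction re-evaluated; the sample graph is kept
        fixed (it encodes overall similarity, which one feature barely
        moves, and a fixed graph keeps per-feature scoring cheap).
        """
        m = self.cohort.matrices[omics_idx]
        try:
            col = m.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(
                f"unknown feature ID {feature_id!r} in omics block {omics_idx}"
            ) from None
        X = self.X_proc[omics_idx].copy()
        X[:, col] = X[self.train_mask, col].mean()
        module_logits = []
        for i, mod in enumerate(self.model.modules):
            Xi = X if i == omics_idx else self.X_proc[i]
            module_logits.append(
                mod.forward(Xi, self.A_hats[i], training=False)
            )
        fusion_in = self.model._fusion_inputs(module_logits)
        fused = self.model.fusion_head.forward(
            np.concatenate(fusion_in, axis=1), training=False
        )
        y = self.cohort.labels.labels[eval_idx]
        return macro_f1(confusion(y, fused.argmax(axis=1)[eval_idx]))


def run_pipeline(
    cohort: CohortBundle,
    split: SplitSpec,
    config: PipelineConfig | None = None,
) -> TrainedPipeline:
    """Preprocess, build per-omics graphs, pretrain, fine-tune."""
    config = config or PipelineConfig()
    pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    train_mask = np.zeros(cohort.n_samples, dtype=bool)
    train_mask[[pos[s] for s in split.train_ids]] = True

    X_proc = preprocess_features(cohort, train_mask, config)
    graphs = [
        build_graph(
            X, tau=config.tau, target_mean_degree=config.target_mean_degree
        )
        for X in X_proc
    ]
    # a sparse propagation operator pays off well below ~25% edge density
    A_hats = [
        sparse.csr_array(g.normalized)
        if (g.normalized != 0).mean() < 0.25
        else g.normalized
        for g in graphs
    ]
    y = cohort.labels.labels
    Y = np.zeros((y.size, 2))
    Y[np.arange(y.size), y] = 1.0

    affinities = [
        label_affinity(g.adjacency, y, labeled_mask=train_mask) for g in graphs
    ]

    n_feats = [X.shape[1] for X in X_proc]
    train_cfg = config.train
    if len(train_cfg.alpha) != len(n_feats):
        train_cfg.alpha = tuple([1.0] * len(n_feats))
    model = MultiOmicsGcn(n_feats, config.model, seed=train_cfg.seed)
    pre_hist = pretrain(
        model, X_proc, A_hats, Y, train_mask, train_cfg, affinity=affinities
    )
    fine_hist = finetune(model, X_proc, A_hats, Y, train_mask, train_cfg)
    return TrainedPipeline(
        cohort,
        split,
        config,
        model,
        graphs,
        A_hats,
        X_proc,
        train_mask,
        pre_hist,
        fine_hist,
    )


@dataclass
class FeatureSelectionResult:
    """Per-omics differential statistics, survivors, and top-k selection."""

    stats: list[list[FeatureStats]]  # one list per omics block
    survivors: list[list[str]]
    selected: list[list[FeatureStats]]
    baseline_macro_f1: float
    pipeline: TrainedPipeline


def run_feature_selection(
    cohort: CohortBundle,
    split: SplitSpec,
    config: PipelineConfig | None = None,
    k_per_omics: tuple[int, ...] = (200, 300),
    mode: str = "mask",
    pipeline: TrainedPipeline | None = None,
) -> FeatureSelectionResult:
    """Two-stage biomarker selection on a trained pipeline.

    Stage 1 (Welch + effect filter) uses training-partition samples
    only. Stage 2 scores each surviving feature's influence as the drop
    in validation macro F1 when it is excluded: ``mode="mask"`` masks
    the feature column on the trained model (default), ``mode="retrain"``
    retrains the whole pipeline without the feature (slow, exact).
    """
    if mode not in ("mask", "retrain"):
        raise ValueError("mode must be 'mask' or 'retrain'")
    config = config or PipelineConfig()
    if pipeline is None:
        pipeline = run_pipeline(cohort, split, config)
    train_labels = cohort.labels.subset(split.train_ids)
    val_idx = pipeline.partition_indices("val")
    pred = pipeline.predict()
    y_val = cohort.labels.labels[val_idx]
    f1_with = macro_f1(confusion(y_val, pred.predicted_labels[val_idx]))

    all_stats: list[list[FeatureStats]] = []
    all_survivors: list[list[str]] = []
    all_selected: list[list[FeatureStats]] = []
    for omics_idx, matrix in enumerate(cohort.matrices):
        train_matrix = matrix.subset_samples(split.train_ids)
        stats = compute_feature_stats(train_matrix, train_labels)
        survivors = primary_filter(stats)

        if mode == "mask":

            def f1_without(fid: str, _oi=omics_idx) -> float:
                return pipeline.masked_macro_f1(_oi, fid, val_idx)

        else:

            def f1_without(fid: str, _oi=omics_idx, _m=matrix) -> float:
                reduced = [
                    (
                        mm.subset_features(
                            [f for f in mm.feature_ids if f != fid]
                        )
                        if i == _oi
                        else mm
                    )
                    for i, mm in enumerate(cohort.matrices)
                ]
                sub = CohortBundle(
                    reduced, cohort.labels, cohort.variants
                )
                p = run_pipeline(sub, split, config)
                rpred = p.predict()
                return macro_f1(
                    confusion(y_val, rpred.predicted_labels[val_idx])
                )

        influence_scores(stats, f1_with, f1_without, feature_ids=survivors)
        k = k_per_omics[omics_idx] if omics_idx < len(k_per_omics) else 200
        selected = select_top_features(
            [s for s in stats if s.feature_id in set(survivors)], k
        )
        all_stats.append(stats)
        all_survivors.append(survivors)
        all_selected.append(selected)
    return FeatureSelectionResult(
        all_stats, all_survivors, all_selected, f1_with, pipeline
    )
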