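"""The multi-omics GCN classifier.

One graph-convolutional module per omics block maps sample features
through the sample-similarity graph to 2-class logits
(p -> hidden -> ... -> fc_dim -> 2); a terminal fully connected fusion
head (the "mutation FC" stage) combines the per-omics outputs into the
final cancer / non-cancer prediction. DNA-sequencing variants are
matched against a user-editable therapy-rule table and attached to the
prediction as an annotation only — they never feed gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .datatypes import OmicsMatrix, TherapyRuleTable, VariantTable
from .graph import SimilarityGraph

__all__ = [
    "GcnModelSpec",
    "PredictionMatrix",
    "GcnModule",
    "MultiOmicsGcn",
    "gcn_layer_forward",
    "gcn_module_forward",
    "fuse_predictions",
    "match_therapy",
]


@dataclass
class GcnModelSpec:
    """Architecture hyperparameters shared by all omics modules.

    Defaults: 400 hidden units, 200-dimensional FC layers, LeakyReLU
    slope 0.25, dropout 0.5 (FC layers only), sum neighbor aggregation,
    two graph-convolution layers per omics module, and a fusion head
    reading the concatenated per-omics class logits.
    """

    hidden_units: int = 400
    fc_dim: int = 200
    n_classes: int = 2
    leaky_slope: float = 0.25
    dropout_rate: float = 0.5
    n_graph_layers: int = 2
    aggregation: str = "sum"
    fusion_input: str = "logits"  # "logits" (2 per omics) or "penultimate"
    dropout_on_graph_layers: bool = False

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("binary classification only: n_classes must be 2")
        if not 1 <= self.n_graph_layers <= 3:
            raise ValueError("n_graph_layers must be 1, 2, or 3")
        if self.aggregation != "sum":
            raise ValueError("only sum neighbor aggregation is supported")
        if self.fusion_input not in ("logits", "penultimate"):
            raise ValueError("fusion_input must be 'logits' or 'penultimate'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class PredictionMatrix:
    """Per-sample 2-class logits with derived softmax probabilities."""

    logits: np.ndarray
    sample_ids: list[str] | None = None
    therapy: dict[str, list[str]] = field(default_factory=dict)

    @property
    def probabilities(self) -> np.ndarray:
        return nn.softmax(self.logits)

    @property
    def predicted_labels(self) -> np.ndarray:
        return self.logits.argmax(axis=1)

    @property
    def cancer_score(self) -> np.ndarray:
        """P(cancer) per sample — the score used for ROC analysis."""
        return self.probabilities[:, 1]


def gcn_layer_forward(
    H: np.ndarray, A_hat: np.ndarray, W: np.ndarray, slope: float = 0.25
) -> np.ndarray:
    """One graph-convolution layer: LeakyReLU(A_hat @ H @ W)."""
    H = np.asarray(H, float)
    W = np.asarray(W, float)
    if A_hat.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: A_hat {A_hat.shape}, H {H.shape}, W {W.shape}"
        )
    Z = A_hat @ H @ W
    return np.where(Z >= 0, Z, slope * Z)


class GcnModule:
    """One omics block's classifier: graph-conv stack then FC layers."""

    def __init__(
        self, n_features: int, spec: GcnModelSpec, rng: np.random.Generator
    ):
        self.spec = spec
        dims = [n_features] + [spec.hidden_units] * spec.n_graph_layers
        self.graph_layers = [
            nn.GraphConv(dims[i], dims[i + 1], rng, spec.leaky_slope)
            for i in range(spec.n_graph_layers)
        ]
        self.graph_dropouts = [
            nn.Dropout(spec.dropout_rate, rng)
            for _ in range(spec.n_graph_layers)
        ]
        self.fc = nn.Dense(spec.hidden_units, spec.fc_dim, rng)
        self.act = nn.LeakyReLU(spec.leaky_slope)
        self.dropout = nn.Dropout(spec.dropout_rate, rng)
        self.out = nn.Dense(spec.fc_dim, spec.n_classes, rng)
        self._penultimate: np.ndarray | None = None

    def params(self) -> list[nn.Param]:
        ps = [p for gl in self.graph_layers for p in gl.params()]
        return ps + self.fc.params() + self.out.params()

    def forward(
        self, X: np.ndarray, A_hat: np.ndarray, training: bool = False
    ) -> np.ndarray:
        h = X
        for gl, gdrop in zip(self.graph_layers, self.graph_dropouts):
            gl.A_hat = A_hat
            h = gl.forward(h, training)
            if self.spec.dropout_on_graph_layers:
                h = gdrop.forward(h, training)
        h = self.act.forward(self.fc.forward(h, training), training)
        h = self.dropout.forward(h, training)
        self._penultimate = h
        return self.out.forward(h, training)

    def backward(
        self, grad_logits: np.ndarray, grad_penultimate: np.ndarray | None = None
    ) -> None:
        g = self.out.backward(grad_logits)
        if grad_penultimate is not None:
            g = g + grad_penultimate
        g = self.fc.backward(self.act.backward(self.dropout.backward(g)))
        for gl, gdrop in zip(
            reversed(self.graph_layers), reversed(self.graph_dropouts)
        ):
            if self.spec.dropout_on_graph_layers:
                g = gdrop.backward(g)
            g = gl.backward(g)


def fuse_predictions(
    y1: np.ndarray, y2: np.ndarray, head: nn.Dense, training: bool = False
) -> np.ndarray:
    """Concatenate two per-sample score blocks and apply the terminal FC.

    This is the fusion operation of the mutation-FC stage: per sample,
    the two omics outputs are concatenated and mapped to final 2-class
    logits by one affine layer.
    """
    if y1.shape[0] != y2.shape[0]:
        raise ValueError(
            f"sample count mismatch between omics outputs: "
            f"{y1.shape[0]} vs {y2.shape[0]}"
        )
    return head.forward(np.concatenate([y1, y2], axis=1), training)


class MultiOmicsGcn:
    """Per-omics GCN modules plus the terminal fusion head."""

    def __init__(
        self,
        n_features_per_omics: list[int],
        spec: GcnModelSpec | None = None,
        seed: int = 0,
    ):
        self.spec = spec or GcnModelSpec()
        rng = np.random.default_rng(seed)
        self.modules = [
            GcnModule(p, self.spec, rng) for p in n_features_per_omics
        ]
        per_omics = (
            self.spec.n_classes
            if self.spec.fusion_input == "logits"
            else self.spec.fc_dim
        )
        self.fusion_head = nn.Dense(
            per_omics * len(self.modules), self.spec.n_classes, rng
        )

    # -- forward ---------------------------------------------------------
    def forward(
        self,
        X_list: list[np.ndarray],
        A_hat_list: list[np.ndarray],
        training: bool = False,
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Return (per-module logits, fused logits) for all samples."""
        if len(X_list) != len(self.modules):
            raise ValueError(
                f"{len(X_list)} omics blocks for {len(self.modules)} modules"
            )
        module_logits = [
            m.forward(X, A, training)
            for m, X, A in zip(self.modules, X_list, A_hat_list)
        ]
        fusion_in = self._fusion_inputs(module_logits)
        fused = self.fusion_head.forward(
            np.concatenate(fusion_in, axis=1), training
        )
        return module_logits, fused

    def _fusion_inputs(self, module_logits):
        if self.spec.fusion_input == "logits":
            return module_logits
        return [m._penultimate for m in self.modules]

    def backward_fused(self, grad_fused: np.ndarray) -> list[np.ndarray]:
        """Backprop the fusion head; return grads w.r.t. each fusion input."""
        g = self.fusion_head.backward(grad_fused)
        per = g.shape[1] // len(self.modules)
        return [g[:, i * per : (i + 1) * per] for i in range(len(self.modules))]

    def predict(
        self,
        X_list: list[np.ndarray],
        A_hat_list: list[np.ndarray],
        sample_ids: list[str] | None = None,
    ) -> PredictionMatrix:
        _, fused = self.forward(X_list, A_hat_list, training=False)
        return PredictionMatrix(fused, sample_ids)

    # -- parameters ------------------------------------------------------
    def module_params(self) -> list[nn.Param]:
        return [p for m in self.modules for p in m.params()]

    def head_params(self) -> list[nn.Param]:
        return self.fusion_head.params()

    def params(self) -> list[nn.Param]:
        return self.module_params() + self.head_params()

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w


def gcn_module_forward(
    X: OmicsMatrix | np.ndarray,
    graph: SimilarityGraph | np.ndarray,
    module: GcnModule,
    training: bool = False,
    sample_ids: list[str] | None = None,
) -> PredictionMatrix:
    """Forward one omics block through its GCN module."""
    values = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, float)
    A_hat = graph.normalized if isinstance(graph, SimilarityGraph) else graph
    if A_hat.shape[0] != values.shape[0]:
        raise ValueError(
            f"graph has {A_hat.shape[0]} nodes but matrix has "
            f"{values.shape[0]} samples"
        )
    if sample_ids is None and isinstance(X, OmicsMatrix):
        sample_ids = X.sample_ids
    return PredictionMatrix(module.forward(values, A_hat, training), sample_ids)


def match_therapy(
    variants: VariantTable, rules: TherapyRuleTable
) -> dict[str, list[str]]:
    """Per-sample agent sets from the (gene, alteration) rule table.

    A rule matches a variant when genes are equal and the rule's
    alteration pattern equals the variant's alteration type (the pattern
    ``"*"`` matches any alteration of the gene). Returns sorted,
    deduplicated agent lists; samples without matches are absent.
    """
    out: dict[str, set[str]] = {}
    if rules.rules.empty or variants.records.empty:
        return {}
    lookup: dict[tuple[str, str], list[str]] = {}
    for _, r in rules.rules.iterrows():
        lookup.setdefault((r["gene"], r["alteration_pattern"]), []).append(
            r["agent"]
        )
    for _, v in variants.records.iterrows():
        agents = lookup.get((v["gene"], v["alteration"]), []) + lookup.get(
            (v["gene"], "*"), []
        )
        if agents:
            out.setdefault(v["sample_id"], set()).update(agents)
    return {s: sorted(a) for s, a in out.items()}
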