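"""Sample-similarity graph construction and symmetric normalization.

Each omics block induces a graph over samples: pairwise cosine
similarity S, thresholded at tau to give the adjacency A (with zero
diagonal), then renormalized with the self-loop trick

    A_hat = D~^{-1/2} (A + I) D~^{-1/2},   D~_ii = sum_j (A + I)_ij,

which is the standard propagation operator for graph-convolution layers
over the sample graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import OmicsMatrix

__all__ = [
    "SimilarityGraph",
    "cosine_similarity_matrix",
    "apply_threshold",
    "select_threshold",
    "normalize_adjacency",
    "build_graph",
]


@dataclass
class SimilarityGraph:
    """Raw similarities, thresholded adjacency, and its normalized form."""

    similarity: np.ndarray
    adjacency: np.ndarray
    tau: float
    normalized: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.adjacency.shape[0]


def cosine_similarity_matrix(X: OmicsMatrix | np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between sample rows.

    Raises if any sample row has zero norm (cosine undefined).
    """
    values = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, float)
    norms = np.linalg.norm(values, axis=1)
    if (norms == 0).any():
        i = int(np.argmax(norms == 0))
        name = X.sample_ids[i] if isinstance(X, OmicsMatrix) else str(i)
        raise ValueError(f"sample {name!r} has zero-norm feature vector")
    unit = values / norms[:, None]
    S = unit @ unit.T
    np.clip(S, -1.0, 1.0, out=S)
    return (S + S.T) / 2.0


def apply_threshold(S: np.ndarray, tau: float) -> np.ndarray:
    """Zero out similarities below tau and the diagonal.

    Entries exactly at tau are retained (only strictly-below values are
    dropped). The diagonal is always zero; self-links enter later via
    the +I of the normalization.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T):
        raise ValueError("similarity matrix must be symmetric")
    A = np.where(S >= tau, S, 0.0)
    np.fill_diagonal(A, 0.0)
    return A


def select_threshold(S: np.ndarray, target_mean_degree: float) -> float:
    """Largest tau whose graph keeps a mean degree >= ``target_mean_degree``.

    The mean degree of apply_threshold(S, tau) is monotone non-increasing
    in tau, so the answer is found by scanning the distinct off-diagonal
    similarity values from high to low. If even the min-similarity graph
    misses the target, that minimum is returned (densest reachable graph).
    """
    if target_mean_degree <= 0:
        raise ValueError("target_mean_degree must be positive")
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to select a threshold")
    off = S[~np.eye(n, dtype=bool)]
    candidates = np.unique(off)[::-1]  # descending
    for tau in candidates:
        degree = (off >= tau).sum() / n
        if degree >= target_mean_degree:
            return float(tau)
    return float(candidates[-1])


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops.

    With A~ = A + I and D~ the diagonal degree matrix of A~, returns
    D~^{-1/2} A~ D~^{-1/2}. D~_ii >= 1 always, so this never divides by
    zero; isolated nodes get a pure self-loop of weight 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(A)).max(initial=0.0) != 0.0:
        raise ValueError("adjacency diagonal must be zero")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    A_hat = A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return (A_hat + A_hat.T) / 2.0


def build_graph(
    X: OmicsMatrix | np.ndarray,
    *,
    tau: float | None = None,
    target_mean_degree: float = 10.0,
) -> SimilarityGraph:
    """Similarity -> threshold -> normalize, in one call.

    Either fix ``tau`` directly or let it be chosen so that the mean node
    degree reaches ``target_mean_degree`` (default 10), the package's
    deterministic realization of a threshold "determined as a function of
    the numbers of linked nodes".
    """
    S = cosine_similarity_matrix(X)
    if tau is None:
        tau = select_threshold(S, target_mean_degree)
    A = apply_threshold(S, tau)
    return SimilarityGraph(S, A, float(tau), normalize_adjacency(A))
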