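"""Two-stage biomarker identification.

Stage 1 is a univariate differential filter: Welch's t-test per feature
(cancer vs. non-cancer, unequal variances) combined with an effect-size
criterion — |log2 fold change| > 0.5 on linear-scale group means for
expression, absolute beta-value difference > 0.2 for methylation (a
log-ratio is not meaningful for proportions). Stage 2 ranks the
survivors by their influence on the trained classifier: the drop in
macro F1 when the feature is excluded (masked to its training mean, or
the model retrained without it), and keeps the top-k per omics block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from .datatypes import LabelVector, OmicsKind, OmicsMatrix

__all__ = [
    "FeatureStats",
    "welch_t_test",
    "log2_fold_change",
    "compute_feature_stats",
    "primary_filter",
    "influence_scores",
    "select_top_features",
    "DEFAULT_ABS_LOG2FC_MIN",
    "DEFAULT_DELTA_BETA_MIN",
]

DEFAULT_ABS_LOG2FC_MIN = 0.5
DEFAULT_DELTA_BETA_MIN = 0.2


@dataclass
class FeatureStats:
    """Differential and influence statistics for one feature."""

    feature_id: str
    t_stat: float
    df: float
    p_value: float
    effect: float  # log2 fold change (expression) or delta beta (methylation)
    effect_kind: str  # "log2_fc" | "delta_beta"
    influence_delta_f1: float | None = None
    rank: int | None = None


def welch_t_test(
    group_pos: np.ndarray, group_neg: np.ndarray
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    degrees of freedom. Requires >= 2 values per group and nonzero
    variance in at least one group.
    """
    a = np.asarray(group_pos, float)
    b = np.asarray(group_neg, float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        raise ValueError("both groups have zero variance; degenerate feature")
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def log2_fold_change(
    mean_pos: float, mean_neg: float, pseudocount: float = 1.0
) -> float:
    """log2((mean_pos + c) / (mean_neg + c)) on linear-scale group means."""
    if mean_pos < 0 or mean_neg < 0:
        raise ValueError(
            "negative group mean on the expression scale; log2 fold change "
            "requires non-negative means"
        )
    return float(np.log2((mean_pos + pseudocount) / (mean_neg + pseudocount)))


def compute_feature_stats(
    matrix: OmicsMatrix,
    labels: LabelVector,
    pseudocount: float = 1.0,
) -> list[FeatureStats]:
    """Per-feature Welch test plus effect size for one omics block.

    Degenerate features (zero variance in both classes) are excluded
    with a warning rather than failing the whole block.
    """
    if matrix.sample_ids != labels.sample_ids:
        raise ValueError("matrix and labels are not sample-aligned")
    y = labels.labels
    pos = matrix.values[y == 1]
    neg = matrix.values[y == 0]
    is_meth = matrix.omics_kind is OmicsKind.METHYLATION
    out: list[FeatureStats] = []
    for j, fid in enumerate(matrix.feature_ids):
        try:
            t, df, p = welch_t_test(pos[:, j], neg[:, j])
        except ValueError:
            warnings.warn(
                f"feature {fid!r} has zero variance in both classes; excluded",
                stacklevel=2,
            )
            continue
        if is_meth:
            effect = float(pos[:, j].mean() - neg[:, j].mean())
            kind = "delta_beta"
        else:
            effect = log2_fold_change(
                pos[:, j].mean(), neg[:, j].mean(), pseudocount
            )
            kind = "log2_fc"
        out.append(FeatureStats(fid, t, df, p, effect, kind))
    return out


def primary_filter(
    stats: list[FeatureStats],
    p_max: float = 0.05,
    abs_fc_min: float = DEFAULT_ABS_LOG2FC_MIN,
    delta_beta_min: float = DEFAULT_DELTA_BETA_MIN,
) -> list[str]:
    """Keep features with p < p_max and a strict effect-size exceedance.

    Both inequalities are strict: a feature at exactly p = 0.05 or
    |effect| = threshold is dropped. The effect threshold is
    ``abs_fc_min`` for log2 fold changes and ``delta_beta_min`` for
    beta-value differences.
    """
    kept = []
    for s in stats:
        threshold = delta_beta_min if s.effect_kind == "delta_beta" else abs_fc_min
        if s.p_value < p_max and abs(s.effect) > threshold:
            kept.append(s.feature_id)
    return kept


def influence_scores(
    stats: list[FeatureStats],
    f1_with: float,
    f1_without: Callable[[str], float],
    feature_ids: list[str] | None = None,
) -> list[FeatureStats]:
    """Fill each feature's influence: dF1 = F1(with) - F1(without).

    ``f1_without(feature_id)`` must return the evaluation macro F1 with
    that single feature excluded (masked or retrained out — the caller
    fixes the mode); ``f1_with`` is the same evaluation with all
    features. Scores are written in place and the list returned.
    """
    by_id = {s.feature_id: s for s in stats}
    targets = feature_ids if feature_ids is not None else list(by_id)
    for fid in targets:
        if fid not in by_id:
            raise KeyError(f"unknown feature ID {fid!r}")
        by_id[fid].influence_delta_f1 = float(f1_with - f1_without(fid))
    return stats


def select_top_features(
    stats: list[FeatureStats], k: int
) -> list[FeatureStats]:
    """Rank scored features by influence and keep the top k.

    Descending influence; ties broken by larger |t|, then feature ID.
    If fewer than k features carry influence scores, all of them are
    returned with a warning. Ranks (1-based) are written in place.
    """
    scored = [s for s in stats if s.influence_delta_f1 is not None]
    if len(scored) < k:
        warnings.warn(
            f"only {len(scored)} scored features available for top-{k} "
            "selection; returning all",
            stacklevel=2,
        )
    scored.sort(
        key=lambda s: (-s.influence_delta_f1, -abs(s.t_stat), s.feature_id)
    )
    top = scored[:k]
    for i, s in enumerate(top):
        s.rank = i + 1
    return top


def stats_to_frame(stats: list[FeatureStats]):
    """FeatureStats list as a DataFrame in the on-disk TSV column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "feature_id": s.feature_id,
                "t": s.t_stat,
                "df": s.df,
                "p": s.p_value,
                "log2_fc_or_delta_beta": s.effect,
                "effect_kind": s.effect_kind,
                "delta_f1": s.influence_delta_f1,
                "rank": s.rank,
            }
            for s in stats
        ]
    )
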