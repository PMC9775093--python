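"""Core data containers for multi-omics cohorts.

A cohort is a set of samples measured on one or more omics blocks
(continuous expression values, or DNA-methylation beta values in [0, 1]),
a binary cancer / non-cancer label per sample, and optionally a table of
DNA-sequencing-derived variant calls used for therapy-rule annotation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsKind",
    "AlterationType",
    "OmicsMatrix",
    "LabelVector",
    "VariantTable",
    "TherapyRuleTable",
    "ConfusionCounts",
    "MetricsReport",
    "CohortBundle",
]


class OmicsKind(str, enum.Enum):
    """Kind of molecular measurement in an omics block."""

    EXPRESSION = "expression"
    METHYLATION = "methylation"


class AlterationType(str, enum.Enum):
    """Genomic alteration categories recorded in a variant table."""

    SNV = "SNV"
    INDEL = "indel"
    FUSION = "fusion"
    REARRANGEMENT = "rearrangement"


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """One omics block: an ``n_samples x n_features`` real matrix.

    Samples are rows, features are columns. Methylation blocks hold beta
    values and are validated to lie in [0, 1].
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    omics_kind: OmicsKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.omics_kind = OmicsKind(self.omics_kind)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample IDs for {n} matrix rows"
            )
        if len(self.feature_ids) != p:
            raise ValueError(
                f"{len(self.feature_ids)} feature IDs for {p} matrix columns"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                "missing value at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )
        if self.omics_kind is OmicsKind.METHYLATION:
            if (self.values < 0).any() or (self.values > 1).any():
                bad = np.argwhere((self.values < 0) | (self.values > 1))[0]
                raise ValueError(
                    "methylation beta value outside [0, 1] at sample "
                    f"{self.sample_ids[bad[0]]!r}, "
                    f"feature {self.feature_ids[bad[1]]!r}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Return a copy restricted (and reordered) to ``sample_ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return OmicsMatrix(
            self.values[rows].copy(),
            list(sample_ids),
            list(self.feature_ids),
            self.omics_kind,
        )

    def subset_features(self, feature_ids: list[str]) -> "OmicsMatrix":
        """Return a copy restricted (and reordered) to ``feature_ids``."""
        index = {f: j for j, f in enumerate(self.feature_ids)}
        cols = [index[f] for f in feature_ids]
        return OmicsMatrix(
            self.values[:, cols].copy(),
            list(self.sample_ids),
            list(feature_ids),
            self.omics_kind,
        )


@dataclass
class LabelVector:
    """Binary labels: 1 = cancer (positive class), 0 = non-cancer."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.sample_ids) != self.labels.size:
            raise ValueError("labels and sample_ids must have equal length")
        _check_unique(self.sample_ids, "sample")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def one_hot(self) -> np.ndarray:
        """n x 2 one-hot encoding (column 0 = non-cancer, 1 = cancer)."""
        out = np.zeros((self.n_samples, 2))
        out[np.arange(self.n_samples), self.labels] = 1.0
        return out

    def subset(self, sample_ids: list[str]) -> "LabelVector":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return LabelVector(list(sample_ids), self.labels[rows].copy())


@dataclass
class VariantTable:
    """Simplified variant calls: one record per (sample, gene, alteration).

    Duplicate records are allowed (a sample may carry several alterations
    of the same gene).
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "gene", "alteration", "detail"]
        )
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = ["sample_id", "gene", "alteration", "detail"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        df = df[required].astype(str)
        if (df["gene"].str.len() == 0).any():
            raise ValueError("variant record with empty gene symbol")
        valid = {a.value for a in AlterationType}
        bad = set(df["alteration"]) - valid
        if bad:
            raise ValueError(
                f"unknown alteration type(s) {sorted(bad)}; expected {sorted(valid)}"
            )
        self.records = df.reset_index(drop=True)

    def subset(self, sample_ids: list[str]) -> "VariantTable":
        keep = self.records["sample_id"].isin(set(sample_ids))
        return VariantTable(self.records[keep].reset_index(drop=True))


@dataclass
class TherapyRuleTable:
    """User-editable (gene, alteration_pattern) -> agent lookup table.

    ``alteration_pattern`` is matched against a variant's alteration type;
    the literal ``"*"`` matches any alteration of that gene.
    """

    rules: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "alteration_pattern", "agent"]
        )
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rules)
        required = ["gene", "alteration_pattern", "agent"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"therapy rule table missing columns: {missing}")
        df = df[required].astype(str)
        dup = df.duplicated(subset=["gene", "alteration_pattern"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate therapy rule for "
                f"({row['gene']}, {row['alteration_pattern']})"
            )
        self.rules = df.reset_index(drop=True)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with cancer (label 1) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """The seven-metric evaluation of one binary classification run."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    auc_roc: float
    macro_f1: float
    weighted_f1: float
    confusion: ConfusionCounts
    n_samples: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.confusion, ConfusionCounts):
            self.confusion = ConfusionCounts(**dict(self.confusion))
        if self.n_samples is None:
            self.n_samples = self.confusion.total
        if self.n_samples != self.confusion.total:
            raise ValueError(
                f"confusion counts sum to {self.confusion.total}, "
                f"but n_samples = {self.n_samples}"
            )
        for name in (
            "sensitivity",
            "specificity",
            "accuracy",
            "precision",
            "auc_roc",
            "macro_f1",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "auc_roc": self.auc_roc,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            },
            "n_samples": self.n_samples,
            "metadata": dict(self.metadata),
        }


@dataclass
class CohortBundle:
    """Sample-aligned omics matrices, labels, and optional variants."""

    matrices: list[OmicsMatrix]
    labels: LabelVector
    variants: VariantTable | None = None
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.sample_ids

    @property
    def n_samples(self) -> int:
        return self.labels.n_samples

    def __post_init__(self) -> None:
        for m in self.matrices:
            if m.sample_ids != self.labels.sample_ids:
                raise ValueError("cohort matrices are not sample-aligned")


def align_cohort(
    matrices: list[OmicsMatrix],
    labels: LabelVector,
    variants: VariantTable | None = None,
) -> CohortBundle:
    """Reorder all inputs to the intersection of their sample IDs.

    The order of the first matrix is adopted for the intersection; samples
    missing from any input are dropped and reported in
    ``CohortBundle.dropped_samples``.
    """
    if not matrices:
        raise ValueError("at least one omics matrix is required")
    common = set(labels.sample_ids)
    for m in matrices:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("empty sample intersection across omics and labels")
    order = [s for s in matrices[0].sample_ids if s in common]
    dropped = sorted(
        (set(labels.sample_ids) | {s for m in matrices for s in m.sample_ids})
        - common
    )
    aligned = [m.subset_samples(order) for m in matrices]
    new_labels = labels.subset(order)
    new_variants = variants.subset(order) if variants is not None else None
    return CohortBundle(aligned, new_labels, new_variants, dropped)
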