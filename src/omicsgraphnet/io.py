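"""Readers and writers for the package's plain-text interchange formats.

Feature matrices are TSV/CSV with a header row of feature IDs and the
first column holding sample IDs (samples as rows). Labels are two-column
TSV (sample_id, label), variants four-column TSV, therapy rules
three-column TSV, metrics reports JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    LabelVector,
    MetricsReport,
    OmicsKind,
    OmicsMatrix,
    TherapyRuleTable,
    VariantTable,
)

__all__ = [
    "read_omics_matrix",
    "write_omics_matrix",
    "read_labels",
    "write_labels",
    "read_variant_table",
    "write_variant_table",
    "read_therapy_rules",
    "write_therapy_rules",
    "read_metrics_report",
    "write_metrics_report",
    "read_config",
    "config_hash",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_omics_matrix(
    path: str | Path,
    omics_kind: OmicsKind | str,
    *,
    transpose: bool = False,
    impute_missing: bool = False,
) -> OmicsMatrix:
    """Load one omics block from a TSV/CSV feature table.

    Parameters
    ----------
    path
        TSV (default) or CSV file; header row = feature IDs, first
        column = sample IDs. With ``transpose=True`` the file is read as
        genes-as-rows and transposed into the samples-as-rows convention.
    omics_kind
        ``"expression"`` or ``"methylation"``; methylation values are
        validated to lie in [0, 1].
    impute_missing
        When True, missing cells are replaced by their column mean;
        otherwise any missing cell is an error.
    """
    path = Path(path)
    sep = _sep_for(path)
    # pandas silently mangles duplicate header names; check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            what = "sample" if transpose else "feature"
            raise ValueError(f"duplicate {what} ID {name!r} in {path}")
        seen.add(name)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    for ids, what in ((sample_ids, "sample"), (feature_ids, "feature")):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise ValueError(f"duplicate {what} ID {x!r} in {path}")
            seen.add(x)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ValueError(
                    f"non-numeric value {df[col].iloc[i]!r} at sample "
                    f"{sample_ids[i]!r}, feature {feature_ids[j]!r} in {path}"
                ) from None
        values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_missing:
            i, j = map(int, np.argwhere(np.isnan(values))[0])
            raise ValueError(
                f"missing value at sample {sample_ids[i]!r}, feature "
                f"{feature_ids[j]!r} in {path}; pass impute_missing=True "
                "for column-mean imputation"
            )
        col_means = np.nanmean(values, axis=0)
        if np.isnan(col_means).any():
            j = int(np.argwhere(np.isnan(col_means))[0])
            raise ValueError(
                f"feature {feature_ids[j]!r} is entirely missing; "
                "cannot impute"
            )
        idx = np.where(np.isnan(values))
        values[idx] = np.take(col_means, idx[1])
    return OmicsMatrix(values, sample_ids, feature_ids, OmicsKind(omics_kind))


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        matrix.values, index=matrix.sample_ids, columns=matrix.feature_ids
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def read_labels(path: str | Path) -> LabelVector:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs columns (sample_id, label)")
    return LabelVector(
        [str(s) for s in df.iloc[:, 0]], df.iloc[:, 1].to_numpy(dtype=int)
    )


def write_labels(labels: LabelVector, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": labels.sample_ids, "label": labels.labels}
    ).to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_variant_table(path: str | Path) -> VariantTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return VariantTable(df)


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    table.records.to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_therapy_rules(path: str | Path) -> TherapyRuleTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return TherapyRuleTable(df)


def write_therapy_rules(table: TherapyRuleTable, path: str | Path) -> None:
    table.rules.to_csv(path, sep=_sep_for(Path(path)), index=False)


def default_therapy_rules() -> TherapyRuleTable:
    """A minimal starter rule table for targetable NSCLC alterations.

    The table only illustrates the (gene, alteration pattern) -> agent
    mechanism; it is meant to be replaced by a curated clinical table.
    """
    return TherapyRuleTable(
        pd.DataFrame(
            [
                ("EGFR", "SNV", "osimertinib"),
                ("EGFR", "indel", "afatinib"),
                ("KRAS", "SNV", "sotorasib"),
                ("BRAF", "SNV", "dabrafenib+trametinib"),
                ("ALK", "fusion", "alectinib"),
                ("ALK", "rearrangement", "alectinib"),
                ("ROS1", "fusion", "crizotinib"),
                ("RET", "fusion", "selpercatinib"),
                ("NTRK1", "fusion", "larotrectinib"),
            ],
            columns=["gene", "alteration_pattern", "agent"],
        )
    )


def write_metrics_report(report: MetricsReport, path: str | Path) -> None:
    """Serialize a validated report as deterministic, sorted-key JSON."""
    payload = report.as_dict()
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )


def read_metrics_report(path: str | Path) -> MetricsReport:
    payload = json.loads(Path(path).read_text())
    return MetricsReport(
        sensitivity=payload["sensitivity"],
        specificity=payload["specificity"],
        accuracy=payload["accuracy"],
        precision=payload["precision"],
        auc_roc=payload["auc_roc"],
        macro_f1=payload["macro_f1"],
        weighted_f1=payload["weighted_f1"],
        confusion=payload["confusion"],
        n_samples=payload.get("n_samples"),
        metadata=payload.get("metadata", {}),
    )


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for run metadata."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
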