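"""Synthetic multi-omics cohorts with known ground truth.

Emulates the structure of a two-block NSCLC case/control cohort:

* an expression block of positive, log-normal continuous values whose
  informative features carry a class mean shift on the log scale
  (``effect_size`` in units of the within-class log-SD, which is 1),
  with equicorrelated feature blocks induced by shared Gaussian factors;
* a methylation block of beta-distributed values in [0, 1] whose
  informative CpGs are alternately hyper- and hypomethylated in the
  cancer class, shifted by ``effect_size`` within-class beta SDs
  (clipped to keep means inside (0, 1));
* a sparse variant table with driver-gene mutations enriched in the
  cancer class.

Everything is deterministic given the spec's seed; the returned
manifest records the informative feature IDs and shift directions so
recovery experiments can score themselves against the truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    LabelVector,
    OmicsKind,
    OmicsMatrix,
    VariantTable,
)

__all__ = ["SyntheticSpec", "generate_cohort", "generate_separable_toy"]

#: Dispersion (a+b) of the beta noise around each CpG's class mean.
_BETA_CONCENTRATION = 8.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Defaults give a 150 cancer + 150 control cohort with 200 expression
    features (20 informative) and 300 methylation features (30
    informative) at a 1.5-SD class shift — the scale of the two omics
    blocks after the real pipeline's top-200/top-300 feature selection.
    """

    n_cancer: int = 150
    n_control: int = 150
    p_expression: int = 200
    p_methylation: int = 300
    n_informative_expression: int = 20
    n_informative_methylation: int = 30
    effect_size: float = 1.5
    block_correlation: float = 0.3
    block_size: int = 10
    n_driver_genes: int = 10
    driver_mutation_rate_cancer: float = 0.30
    driver_mutation_rate_control: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 1 or self.n_control < 1:
            raise ValueError("both classes need at least one sample")
        if self.n_informative_expression > self.p_expression:
            raise ValueError("n_informative_expression exceeds p_expression")
        if self.n_informative_methylation > self.p_methylation:
            raise ValueError("n_informative_methylation exceeds p_methylation")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        for r in (
            self.driver_mutation_rate_cancer,
            self.driver_mutation_rate_control,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must be in [0, 1]")


def _expression_block(
    spec: SyntheticSpec, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[int], np.ndarray]:
    n = y.size
    p = spec.p_expression
    rho = spec.block_correlation
    n_blocks = int(np.ceil(p / spec.block_size))
    factors = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    block_of = np.arange(p) // spec.block_size
    z = np.sqrt(rho) * factors[:, block_of] + np.sqrt(1.0 - rho) * eps
    informative = sorted(
        rng.choice(p, size=spec.n_informative_expression, replace=False)
    )
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(informative))])
    for idx, s in zip(informative, signs):
        z[y == 1, idx] += s * spec.effect_size
    base_log_mean = rng.uniform(1.0, 3.0, size=p)
    values = np.exp(base_log_mean[None, :] + z)
    return values, [int(i) for i in informative], signs


def _methylation_block(
    spec: SyntheticSpec, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[int], np.ndarray]:
    n = y.size
    p = spec.p_methylation
    s0 = _BETA_CONCENTRATION
    base_mean = rng.uniform(0.05, 0.95, size=p)
    informative = sorted(
        rng.choice(p, size=spec.n_informative_methylation, replace=False)
    )
    # differentially methylated CpGs sit at intermediate methylation,
    # where a class shift of a few beta-SDs stays inside (0, 1)
    base_mean[informative] = rng.uniform(0.35, 0.65, size=len(informative))
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(informative))])
    mean = np.tile(base_mean, (n, 1))
    for idx, s in zip(informative, signs):
        m = base_mean[idx]
        sd = np.sqrt(m * (1.0 - m) / (1.0 + s0))
        shifted = np.clip(m + s * spec.effect_size * sd, 0.02, 0.98)
        mean[y == 1, idx] = shifted
    a = mean * s0
    b = (1.0 - mean) * s0
    values = rng.beta(a, b)
    return values, [int(i) for i in informative], signs


def _variant_block(
    spec: SyntheticSpec,
    y: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> VariantTable:
    genes = [f"DRV{g + 1:02d}" for g in range(spec.n_driver_genes)]
    alterations = ["SNV", "indel", "fusion"]
    rows = []
    for i, sid in enumerate(sample_ids):
        rate = (
            spec.driver_mutation_rate_cancer
            if y[i] == 1
            else spec.driver_mutation_rate_control
        )
        hits = rng.random(len(genes)) < rate
        for g, hit in zip(genes, hits):
            if hit:
                alt = alterations[int(rng.integers(len(alterations)))]
                rows.append((sid, g, alt, "synthetic"))
    return VariantTable(
        pd.DataFrame(rows, columns=["sample_id", "gene", "alteration", "detail"])
    )


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[OmicsMatrix, OmicsMatrix, VariantTable, LabelVector, dict]:
    """Draw one cohort; returns (expression, methylation, variants, labels, manifest)."""
    rng = np.random.default_rng(spec.seed)
    y = np.concatenate(
        [np.ones(spec.n_cancer, int), np.zeros(spec.n_control, int)]
    )
    sample_ids = [f"S{i + 1:04d}" for i in range(y.size)]
    labels = LabelVector(sample_ids, y)

    expr_values, expr_inf_idx, expr_signs = _expression_block(spec, y, rng)
    expr_ids = [f"GENE{j + 1:04d}" for j in range(spec.p_expression)]
    expression = OmicsMatrix(
        expr_values, sample_ids, expr_ids, OmicsKind.EXPRESSION
    )

    meth_values, meth_inf_idx, meth_signs = _methylation_block(spec, y, rng)
    meth_ids = [f"cg{j + 1:06d}" for j in range(spec.p_methylation)]
    methylation = OmicsMatrix(
        meth_values, sample_ids, meth_ids, OmicsKind.METHYLATION
    )

    variants = _variant_block(spec, y, sample_ids, rng)

    manifest = {
        "spec": asdict(spec),
        "informative_expression": [expr_ids[i] for i in expr_inf_idx],
        "informative_expression_direction": [
            "up" if s > 0 else "down" for s in expr_signs
        ],
        "informative_methylation": [meth_ids[i] for i in meth_inf_idx],
        "informative_methylation_direction": [
            "hyper" if s > 0 else "hypo" for s in meth_signs
        ],
        "driver_genes": [f"DRV{g + 1:02d}" for g in range(spec.n_driver_genes)],
    }
    return expression, methylation, variants, labels, manifest


def generate_separable_toy(
    n: int, seed: int = 0
) -> tuple[OmicsMatrix, OmicsMatrix, VariantTable, LabelVector, dict]:
    """A small, nearly separable two-omics cohort for convergence tests.

    Balanced n/2 + n/2 cohort, 200 features per omics with 2 informative
    features each at a 3-SD shift. ``n`` must be even and at least 20.
    """
    if n % 2 != 0:
        raise ValueError("toy cohort size n must be even")
    if n < 20:
        raise ValueError("toy cohort needs n >= 20")
    spec = SyntheticSpec(
        n_cancer=n // 2,
        n_control=n // 2,
        p_expression=200,
        p_methylation=200,
        n_informative_expression=2,
        n_informative_methylation=2,
        effect_size=3.0,
        block_correlation=0.0,
        seed=seed,
    )
    return generate_cohort(spec)
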