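import numpy as np
import pytest

import omicsgraphnet as og


@pytest.fixture(scope="session")
def toy_cohort():
    """Small nearly separable two-omics cohort (n=60, 2x200 features)."""
    expr, meth, variants, labels, manifest = og.generate_separable_toy(
        60, seed=7
    )
    cohort = og.align_cohort([expr, meth], labels, variants)
    return cohort, manifest


@pytest.fixture(scope="session")
def tiny_trained(toy_cohort):
    """A quickly trained pipeline on the toy cohort, shared across tests."""
    cohort, _ = toy_cohort
    split = og.split_dataset(cohort.labels, seed=7)
    config = og.PipelineConfig(
        train=og.TrainConfig(pretrain_epochs=60, finetune_epochs=60, seed=7)
    )
    return og.run_pipeline(cohort, split, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
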