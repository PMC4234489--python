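import logging

import numpy as np
import pytest

from cohub.datatypes import ExpressionMatrix, PhenotypeTable
from cohub.simulate import SyntheticConfig, generate_synthetic_study

# silence expected per-stage chatter (drop counts, fallback notices) in tests
logging.getLogger("cohub").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_study():
    """One generator-default study shared by read-only tests."""
    return generate_synthetic_study(SyntheticConfig(seed=11))


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(10)],
        sample_ids=[f"s{j}" for j in range(8)],
        platform=["P1"] * 8,
        values=rng.standard_normal((10, 8)),
    )


@pytest.fixture()
def tiny_phenotypes():
    status = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    grade = np.array([1.0, 0.0, 1.0, 0.0, np.nan, np.nan, np.nan, np.nan])
    return PhenotypeTable(
        sample_ids=[f"s{j}" for j in range(8)],
        status=status,
        grade=grade,
        type=grade.copy(),
        stage=grade.copy(),
    )


def small_study(seed: int = 0, **overrides):
    """A fast, down-scaled synthetic study for pipeline-level tests."""
    params = dict(
        n_genes=120,
        module_sizes=[40, 40],
        n_hubs_per_module=3,
        n_samples_per_platform=[60, 60],
        trait_effects={"grade": (0, 2.0), "type": (1, 2.0)},
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)
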