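import warnings

import numpy as np
import pandas as pd
import pytest

from gliosig import CohortConfig, ExpressionMatrix, generate_cohort
from gliosig.io_formats import GliosigWarning


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """A compact cohort for unit tests: same structure, smaller everything."""
    defaults = dict(
        n_genes=400,
        n_samples=100,
        block_size=80,
        n_inflammation_genes=100,
        n_region_up_genes=70,
        n_signature=20,
        n_block_inflammation_extra=20,
        n_block_region_extra=10,
        n_inflammation_region_extra=5,
        n_controls=30,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=7))


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        {
            "s1": [1.0, 3.0, 5.0],
            "s2": [2.0, 2.0, 5.5],
            "s3": [3.0, 1.0, 6.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(data)


@pytest.fixture(autouse=True)
def _quiet_package_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GliosigWarning)
        yield


def case_samples(metadata: pd.DataFrame) -> list[str]:
    return metadata.loc[metadata["diagnostic_label"] == "case", "sample_id"].tolist()


def rng_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(master).integers(0, 2**31 - 1, size=n)]
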