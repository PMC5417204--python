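import numpy as np
import pytest

from nirscreen.scenarios import (
    SEPARABLE_NOISE,
    monotherapy_formulation,
    two_api_formulation,
)
from nirscreen.synthetic_data import (
    BrandPlan,
    ClassPlan,
    LibraryConfig,
    default_grid,
    generate_library,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_library_config(seed=7, qa_batches=2, qa_samples=8, falsified_samples=2):
    """Tiny two-batch library for fast IO/CLI tests."""
    plan = BrandPlan(
        formulation=monotherapy_formulation("TOY"),
        quality_assured=ClassPlan(batches=qa_batches, samples=qa_samples),
        falsified=ClassPlan(batches=1, samples=falsified_samples),
        wrong_shift_nm=60.0,
    )
    return LibraryConfig(brands=[plan], noise=SEPARABLE_NOISE, seed=seed)


@pytest.fixture
def small_library():
    return generate_library(small_library_config())


@pytest.fixture(scope="session")
def combo_formulation():
    return two_api_formulation()
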