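import numpy as np
import pandas as pd
import pytest

from b12status.indicators import Cb12Constants
from b12status.survey import SurveyDesign
from b12status.synthetic import SyntheticConfig, generate_population, split_cycles


@pytest.fixture(scope="session")
def constants() -> Cb12Constants:
    return Cb12Constants.packaged_default()


@pytest.fixture(scope="session")
def default_population():
    """One default-condition population (15 strata x 2 PSU x 120, seed 1)."""
    return generate_population(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def split_population(default_population):
    return split_cycles(default_population, 2.0 / 3.0)


@pytest.fixture(scope="session")
def small_population():
    """Quicker fixture for bootstrap-heavy tests (600 records)."""
    return generate_population(
        SyntheticConfig(n_strata=6, n_per_psu=50, prevalence_inadequate=0.10, seed=3)
    )


def equal_weight_design(n: int, n_psus: int = 2) -> SurveyDesign:
    """Single-stratum design with records dealt round-robin over PSUs."""
    return SurveyDesign(
        np.repeat("S1", n),
        np.array([f"P{i % n_psus + 1}" for i in range(n)]),
        np.ones(n),
    )


def weighted_median(values, weights) -> float:
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cum = np.cumsum(w) / np.sum(w)
    return float(v[np.searchsorted(cum, 0.5)])
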