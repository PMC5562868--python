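import numpy as np
import pytest

from metabotype import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """A scaled-down cohort: same structure, fast to analyse."""
    base = dict(
        n_per_group={"WT6": 8, "KO6": 8, "WT18": 8, "KO18": 8},
        n_qc=6,
        n_features=120,
        n_genotype_features=15,
        genotype_effect=1.8,
        n_age_features=40,
        age_effect=2.0,
        noise_feature_fraction=0.15,
        seed=42,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def null_cohort():
    """No genotype or age effect: intensities carry no group signal."""
    return generate_cohort(small_config(genotype_effect=1.0, age_effect=1.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
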