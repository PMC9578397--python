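import numpy as np
import pytest

from bdqpk.model import CovariateEffect, final_model
from bdqpk.pk import CovariateModel, PKParameters
from bdqpk.simulate import StudyDesignSpec, generate_dataset


@pytest.fixture(scope="session")
def final_cov_model() -> CovariateModel:
    return CovariateModel()


@pytest.fixture(scope="session")
def typical_params() -> PKParameters:
    """Typical subject at the reference GGT (28.9 U/L), AA/AG genotype."""
    return PKParameters(ka=0.447, cl=4.54, v=227.0)


@pytest.fixture(scope="session")
def reference_dataset():
    """One seeded dataset with the study design (99 subjects, 246 samples)."""
    spec = StudyDesignSpec()
    records, table, truth = generate_dataset(spec, seed=20201001)
    return records, table, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset (24 subjects) for fast estimation tests."""
    spec = StudyDesignSpec(n_subjects=24)
    records, table, truth = generate_dataset(spec, seed=7)
    return records, table, truth


def neutral_start():
    """Final-model structure with neutral (non-truth) initial estimates."""
    m0 = final_model()
    m0.theta = {"ka": 0.3, "cl": 3.0, "v": 150.0}
    m0.effects = [
        CovariateEffect("cl", "GGT", "power", 0.0, 28.9),
        CovariateEffect("cl", "RS319952_GG", "additive", 0.0),
    ]
    m0.omega2 = {"cl": 0.15, "v": 0.4}
    m0.sigma_prop = 0.25
    return m0
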