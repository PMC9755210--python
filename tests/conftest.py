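import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aripk.model import PopPKModel
from aripk.population import CohortSpec, OmegaSpec, SigmaSpec, generate_synthetic_study
from aripk.reference import reference_model

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def study84(ref_model):
    """One default-design synthetic study (84 subjects, sparse sampling)."""
    return generate_synthetic_study(CohortSpec(), ref_model, seed=1)


@pytest.fixture(scope="session")
def small_study(ref_model):
    """Small rich-sampling study for fast estimation tests."""
    spec = CohortSpec(n_subjects=20, samples_probs=(0.0, 0.0, 1.0, 0.0, 0.0),
                      lloq_ari=0.0, lloq_dari=0.0)
    return generate_synthetic_study(spec, ref_model, seed=7)


@pytest.fixture(scope="session")
def truth_results(study84, ref_model):
    """Results object for the generating (correct) model, no fitting."""
    return PopPKModel(study84, ref_model).evaluate()


@pytest.fixture()
def noiseless_model(ref_model):
    return ref_model.replace(
        omega=OmegaSpec({"vd_f": 0.0, "cl_f": 0.0, "clm_fm": 0.0}),
        sigma=SigmaSpec(0.0, 0.0),
    )
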