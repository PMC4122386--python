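import numpy as np
import pytest
from hypothesis import settings

from oacce import Therapy, evaluate_arm, generate_reference_paramset, run_base_case

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_params():
    """The reference parameter set (printed anchors + documented placeholders)."""
    return generate_reference_paramset()


@pytest.fixture(scope="session")
def base_result(ref_params):
    """Deterministic base-case CE analysis, apixaban vs VKA."""
    return run_base_case(ref_params)


@pytest.fixture(scope="session")
def apix_outcome(ref_params):
    return evaluate_arm(ref_params, Therapy.APIXABAN, keep_trace=True)


@pytest.fixture(scope="session")
def vka_outcome(ref_params):
    return evaluate_arm(ref_params, Therapy.VKA, keep_trace=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140805)
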