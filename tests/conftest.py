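import numpy as np
import pytest

import dioxhop as dh
from dioxhop.engine import EngineParams, run_ensemble
from dioxhop.sampling import SamplingParams


@pytest.fixture(scope="session")
def model():
    return dh.build_model()


@pytest.fixture(scope="session")
def reference_q(model):
    """Launch-region geometry used for point evaluations."""
    q = np.zeros(model.d)
    q[0] = 1.60
    q[1] = np.radians(135.8)
    q[2] = np.pi
    return q


@pytest.fixture(scope="session")
def ensemble(model):
    """A reusable default-model surrogate ensemble.

    40 trajectories on an 800 fs horizon: large enough for yield and
    product-label statistics, small enough to keep the suite quick.
    """
    return run_ensemble(model, 40, EngineParams(t_max=800.0), 42, SamplingParams())


@pytest.fixture(scope="session")
def zero_soc_ensemble():
    """Ensemble with all spin-orbit couplings switched off."""
    m = dh.build_model(dict(soc_singlet_triplet=0.0, soc_intra_triplet=0.0))
    return run_ensemble(m, 10, EngineParams(t_max=400.0), 7, SamplingParams())
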