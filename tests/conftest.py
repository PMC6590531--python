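import numpy as np
import pytest

from diabsde import LinearCoefficients, ModelParams, NoiseSpec, StateVec


@pytest.fixture
def canonical() -> ModelParams:
    """Published reference model: slopes 0.02/0.01/0.05/0.007/0.002, K3=5."""
    return ModelParams()


@pytest.fixture
def noise_free(canonical) -> ModelParams:
    return ModelParams(coeffs=canonical.coeffs, noise=NoiseSpec(0.0),
                       x0=canonical.x0)


@pytest.fixture
def constant_M() -> np.ndarray:
    """Constant part M of the coefficient family A(t) = t*M."""
    return np.array([[-0.03, 0.02], [-0.007, -0.002]])
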