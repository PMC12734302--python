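import numpy as np
import pytest

from branchproc import EmpiricalLaw, GeometricLaw, NegativeBinomialLaw, PoissonLaw


@pytest.fixture
def hornet_law():
    """Subcritical three-point law (0.5, 0.3, 0.2): mean 0.7, variance 0.61."""
    return EmpiricalLaw(np.array([0.5, 0.3, 0.2]))


@pytest.fixture
def galton_law():
    """Supercritical surname law a0..a5 = 0.1, 0.3, 0.25, 0.15, 0.1, 0.1."""
    return EmpiricalLaw(np.array([0.1, 0.3, 0.25, 0.15, 0.1, 0.1]))


@pytest.fixture
def supercritical_three_point():
    """Three-point law (0.1, 0.4, 0.5): mean 1.5, extinction probability 0.2."""
    return EmpiricalLaw(np.array([0.1, 0.4, 0.5]))


@pytest.fixture(
    params=[
        EmpiricalLaw(np.array([0.5, 0.3, 0.2])),
        PoissonLaw(0.7),
        PoissonLaw(2.0),
        GeometricLaw(1.5),
        NegativeBinomialLaw(2.0, 0.6),
    ],
    ids=["empirical", "poisson0.7", "poisson2", "geometric1.5", "negbin"],
)
def any_law(request):
    """One representative of each offspring-law family."""
    return request.param
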