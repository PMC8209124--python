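import numpy as np
import pytest

from paceshape.siler import QuadratureConfig, SilerParams


@pytest.fixture(scope="session")
def theta_star() -> SilerParams:
    """Reference primate-like parameter set used across the suite."""
    return SilerParams(a0=-2.0, a1=1.0, c=0.01, b0=-5.0, b1=0.15)


@pytest.fixture(scope="session")
def const_hazard() -> SilerParams:
    """Effectively constant hazard 0.2/yr (infant and senescent terms ~e^-30)."""
    return SilerParams(a0=-30.0, a1=1.0, c=0.2, b0=-30.0, b1=0.1)


@pytest.fixture(scope="session")
def wide_quad() -> QuadratureConfig:
    """Quadrature settings for long-lived / low-mortality schedules."""
    return QuadratureConfig(max_upper=2000.0)


def random_params(rng: np.random.Generator) -> SilerParams:
    """A random valid parameter set in a demographically plausible range."""
    return SilerParams(
        a0=rng.uniform(-4.0, 1.0),
        a1=rng.uniform(0.3, 3.0),
        c=rng.uniform(0.001, 0.1),
        b0=rng.uniform(-7.0, -3.0),
        b1=rng.uniform(0.05, 0.3),
    )
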