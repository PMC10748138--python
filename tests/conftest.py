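import numpy as np
import pytest

from exufiber import RiccatiParams, morphology_field


@pytest.fixture
def unit_params() -> RiccatiParams:
    """Symmetric oscillator: roots +/- i, Omega = 1."""
    return RiccatiParams(a1=1.0, a2=0.0, a3=1.0, r=0.5, tau_r=0.0)


def random_oscillatory_params(rng: np.random.Generator) -> RiccatiParams:
    """Draw a parameter set with guaranteed Omega**2 > 0.1."""
    a1 = rng.uniform(0.5, 2.0)
    a2 = rng.uniform(-1.0, 1.0)
    omega_sq = rng.uniform(0.1, 2.0)
    a3 = (omega_sq + a2**2) / a1
    return RiccatiParams(
        a1=a1, a2=a2, a3=a3, r=rng.uniform(0.0, 0.9), tau_r=rng.uniform(-1.0, 1.0)
    )


def canonical_trace(omega: float, r: float, n_periods: int = 6, samples_per_period: int = 256):
    """Morphology time trace at fixed Omega over n_periods, with its dt."""
    period = np.pi / omega
    t = np.linspace(0.0, n_periods * period, n_periods * samples_per_period, endpoint=False)
    fld = morphology_field(np.array([omega]), t, r)
    return fld.values[0], t[1] - t[0]
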