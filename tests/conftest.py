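import numpy as np
import pytest

import spherebidomain as sb
from spherebidomain import scenarios as sc


@pytest.fixture(scope="session")
def default_model():
    """Default configuration with solved coefficients (mu_max=10)."""
    cfg = sb.default_config()
    par = sb.default_parameters()
    src = sb.default_sources()
    return cfg, par, src, sb.coefficients(cfg, par, src)


@pytest.fixture(scope="session")
def axisym_model():
    """Polar-axis electrode pair (azimuthally symmetric limiting case)."""
    s = sb.scenario("axisymmetric")
    return s, sb.coefficients(s.config, s.params, s.sources)


@pytest.fixture(scope="session")
def small_current_grid(default_model):
    """Reduced current-density grid shared by the Biot-Savart tests."""
    cfg, par, src, co = default_model
    return sb.sample_grid(cfg, par, src, co, extent=3e-3, dims=(16, 16, 7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160909)
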