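import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fsrskit as fk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def irf():
    """Sub-50-fs-class Gaussian IRF at time zero."""
    return fk.IRFModel(t0=0.0, sigma=0.021)


@pytest.fixture(scope="session")
def ta_preset():
    return fk.preset("curcumin_dmso_ta")


@pytest.fixture(scope="session")
def chloroform_preset():
    return fk.preset("curcumin_chloroform_ta")


@pytest.fixture(scope="session")
def fsrs_preset():
    return fk.preset("curcumin_dmso_fsrs")


@pytest.fixture(scope="session")
def fsrs_surface(fsrs_preset):
    """Noise-free FSRS surface, reused read-only across tests."""
    return fk.generate_surface(fsrs_preset)


@pytest.fixture()
def small_surface():
    """A tiny two-band Raman surface with known row values."""
    axis = np.arange(640.0, 700.0, 4.0)
    delays = np.array([-1.0, 0.0, 1.0, 2.0, 5.0])
    g = lambda c, w: np.exp(-4 * np.log(2) * ((axis - c) / w) ** 2)
    profile = 1.0 * g(657.0, 14.0) + 0.5 * g(678.0, 14.0)
    course = np.array([0.2, 0.5, 1.0, 0.8, 0.4])
    values = profile[:, None] * course[None, :]
    return fk.DelaySpectraSurface(axis, delays, values, "raman_shift_cm")


def numeric_conv_exp(t, tau, irf_model):
    """Independent oracle: quadrature of (unit-area Gaussian) ⊗ (step·exp).

    Uses the substitution c(t) = ∫_0^∞ G(t − t0 − s) e^(−s/τ) ds with a
    smooth integrand, evaluated by adaptive quadrature.
    """
    from scipy.integrate import quad

    sigma = irf_model.sigma
    x = float(t) - irf_model.t0

    def integrand(s):
        g = np.exp(-0.5 * ((x - s) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        return g * np.exp(-s / tau)

    upper = max(x + 12 * sigma, 0.0)
    if upper == 0.0:
        return 0.0
    val, _ = quad(integrand, 0.0, upper, epsabs=1e-13, epsrel=1e-13, limit=400)
    return val
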