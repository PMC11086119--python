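import numpy as np
import pytest

from lactowave.model import CCParameters, evaluate_permittivity, default_frequency_grid
from lactowave.cohort import simulate_instrument_noise


@pytest.fixture
def grid():
    return default_frequency_grid()


@pytest.fixture
def debye_params():
    """Pure Debye water-like dispersion (alpha=1, no conductivity)."""
    return CCParameters(eps_inf=5.0, delta_eps=70.0, tau=8.0, alpha=1.0)


@pytest.fixture
def milk_params():
    """Milk-like baseline with broadening and ionic conductivity."""
    return CCParameters(eps_inf=5.5, delta_eps=68.0, tau=9.0,
                        alpha=0.985, sigma_dc=0.9)


@pytest.fixture
def milk_spectrum(milk_params, grid):
    return evaluate_permittivity(milk_params, grid)


@pytest.fixture
def noisy_spectrum_factory(grid):
    """Factory producing seeded 5%-noise spectra from given parameters."""

    def make(params, seed=0, rel_sd=0.05):
        clean = evaluate_permittivity(params, grid)
        return simulate_instrument_noise(clean, rel_sd, seed)

    return make
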