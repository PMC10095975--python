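import numpy as np
import pytest

from sucrokin import (
    EffluxLaw,
    FluxParameters,
    InvertaseParameters,
    MetabolicState,
    ParameterScenario,
)


@pytest.fixture
def invertase():
    return InvertaseParameters(v_max=5.0, k_m=2.0, k_i_glc=5.0, k_i_frc=5.0)


@pytest.fixture
def fluxes():
    return FluxParameters(
        r_in=0.5,
        efflux_glc=EffluxLaw.michaelis_menten(v_max=1.5, k_m=2.0),
        efflux_frc=EffluxLaw.michaelis_menten(v_max=1.5, k_m=2.0),
    )


@pytest.fixture
def scenario(invertase, fluxes):
    return ParameterScenario(
        name="22C_whole_cell",
        invertase=invertase,
        fluxes=fluxes,
        temperature_label="22C",
        compartment_label="whole_cell",
    )


@pytest.fixture
def scan_scenario(invertase):
    """Efflux-free scenario matching the default scan mode."""
    return ParameterScenario(
        name="scan", invertase=invertase, fluxes=FluxParameters(r_in=0.5)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_states(rng, n, low=1e-2, high=1e2):
    """Concentration triples log-uniform in [low, high] mM."""
    x = np.exp(rng.uniform(np.log(low), np.log(high), size=(n, 3)))
    return [MetabolicState(*row) for row in x]
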