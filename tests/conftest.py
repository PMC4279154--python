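import numpy as np
import pytest

import salixnmr as sx
from salixnmr.simulate import SimulatorConfig


@pytest.fixture(scope="session")
def library():
    return sx.builtin_willow_library()


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, solvent-free synthesis: oracle conditions for exact fits."""
    return SimulatorConfig(noise_sd=0.0, solvent_residuals=False)


@pytest.fixture(scope="session")
def quiet_matrix():
    """Matrix with no additives and no standing: pure composition spectra."""
    return sx.MatrixState(total_ca_mm=0.0, edta_mm=0.0, standing_time_h=0.0)


@pytest.fixture(scope="session")
def cohort():
    """Default 72-spectrum study: 2 genotypes x 2 tissues x 3 positions
    x 2 biological x 3 technical replicates."""
    spectra, metadata, truth = sx.simulate_cohort(sx.CohortDesign(seed=1))
    return spectra, metadata, truth
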