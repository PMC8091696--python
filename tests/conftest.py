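import numpy as np
import pytest

from hepavisc.rheology import RheoModel, RheoParams
from hepavisc.swe_dispersion import PipelineConfig, preprocess
from hepavisc.wavefield_sim import simulate_planar_wave

#: Healthy-liver (stage S0) Voigt parameters measured by shear-wave
#: elastography: mu = 0.86 kPa, eta = 0.77 Pa*s.
S0_SWE = RheoParams(RheoModel.VOIGT, mu=860.0, eta=0.77)

#: Stage S0 parameters measured by bench rheometry: 1.12 kPa, 5.40 Pa*s.
S0_DMA = RheoParams(RheoModel.VOIGT, mu=1120.0, eta=5.40)

RHO = 1000.0


@pytest.fixture(scope="session")
def s0_swe_params():
    return S0_SWE


@pytest.fixture(scope="session")
def s0_dma_params():
    return S0_DMA


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_s0_movie():
    """Noiseless default-acquisition movie of the S0 SWE medium."""
    return simulate_planar_wave(S0_SWE, rho=RHO, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_s0_preprocessed(clean_s0_movie, pipeline_config):
    """The same movie after the full preprocessing chain (stages 2-4)."""
    return preprocess(clean_s0_movie, pipeline_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
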