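import warnings

import numpy as np
import pytest

from dyadsync import PipelineConfig, SynthConfig, generate_dyad
from dyadsync.io import DEFAULT_CLUSTERS
from dyadsync.preprocess import preprocess_recording
from dyadsync.spectral import faa_for_recording
from dyadsync.synchrony import bin_faa

# mixed-model variance components legitimately hit the boundary on
# driver-free synthetic data; that is the scenario under test, not noise
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def coupled_dyad():
    """One dyad, two 60 s conditions, perfect coupling at a 4 s delay."""
    cfg = SynthConfig(
        n_channels=16,
        condition_schedule=(("A", 60.0), ("B", 60.0)),
        coupling_strength=1.0,
        coupling_delay_s=4.0,
        seed=11,
    )
    return generate_dyad(cfg, dyad_id="dyadA")


@pytest.fixture(scope="session")
def coupled_bins(coupled_dyad, small_config):
    """Binned FAA for both partners of the coupled dyad."""
    out = []
    for rec in (coupled_dyad.recording_p1, coupled_dyad.recording_p2):
        clean, _ = preprocess_recording(rec, small_config)
        faa = faa_for_recording(clean, small_config, DEFAULT_CLUSTERS)
        out.append(bin_faa(faa, bin_epochs=small_config.bin_epochs))
    return tuple(out)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
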