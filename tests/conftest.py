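import numpy as np
import pytest

from aridforest import synth


@pytest.fixture(scope="session")
def climate_sim():
    """Default synthetic station network (3 stations, 1961–2009, gaps)."""
    return synth.simulate_climate(synth.ClimateSimSpec(seed=7))


@pytest.fixture(scope="session")
def noise_free_climate():
    """Noise-free network: satellite series are exact linear transforms."""
    spec = synth.ClimateSimSpec(
        noise_sd_t=0.0, noise_sd_p=0.0, intercepts_p=(4.0, 5.0), gap_fraction=0.0, seed=3
    )
    return spec, synth.simulate_climate(spec)


@pytest.fixture(scope="session")
def scene_sim():
    """Default two-date degraded scene, 64×64 for speed."""
    return synth.simulate_scene(
        synth.SceneSimSpec(shape=(64, 64), seed=11, signatures_t2=synth.DEGRADED_SIGNATURES)
    )


@pytest.fixture(scope="session")
def commune_sim():
    """113 communes in 5 planted clusters with true labels."""
    return synth.simulate_communes(synth.CommuneSimSpec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
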