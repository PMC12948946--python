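import numpy as np
import pytest

from sourscope.synthetic_data import GeneratorConfig, PlantedEffect, generate_study


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_participants=150, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def messy_config():
    """Study with missingness, planted effects, and density errors."""
    return GeneratorConfig(
        n_participants=250,
        seed=7,
        p_results=0.8,
        p_lab=0.9,
        missingness={"backslop_frequency": 0.3, "ph_home": 0.1, "cata": 0.1,
                     "tta": 0.05, "ferment_time_h": 0.2},
        effect_registry=[
            PlantedEffect("mean_shift", "tta", "grain_base", "rye", 1.0),
            PlantedEffect("aroma_association", "sour", "grain_base", "rye", 0.35),
        ],
    )


@pytest.fixture(scope="session")
def messy_study(messy_config):
    return generate_study(messy_config)


@pytest.fixture(scope="session")
def integrated(small_study):
    from sourscope.harmonize import integrate

    reg, res, lab, _ = small_study
    return integrate(reg, res, lab)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
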