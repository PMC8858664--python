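import numpy as np
import pytest

from neckservo import (
    FAST,
    LONG,
    STANDARD,
    PlantParams,
    RotationProfile,
    SuppressionParams,
    SwitchConfig,
    make_perturbation,
    simulate,
)

SIM_RATE = 2000.0  # profile rate matching the default integration step


@pytest.fixture(scope="session")
def plant():
    return PlantParams()


@pytest.fixture(scope="session")
def suppr():
    return SuppressionParams()


@pytest.fixture(scope="session")
def static_profiles():
    """The three static ramp-and-hold stimuli on the simulation grid."""
    return {
        "standard": make_perturbation(STANDARD, SIM_RATE, tail=0.4),
        "fast": make_perturbation(FAST, SIM_RATE, tail=0.4),
        "long": make_perturbation(LONG, SIM_RATE, tail=0.4),
    }


@pytest.fixture(scope="session")
def static_traces(static_profiles):
    """Full-model responses to the three static perturbations."""
    return {name: simulate(prof) for name, prof in static_profiles.items()}


def zero_profile(duration=1.0, rate=SIM_RATE):
    t = np.arange(int(round(duration * rate)) + 1) / rate
    z = np.zeros_like(t)
    return RotationProfile(t, z, z, z, rate)
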