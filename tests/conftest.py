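"""Shared fixtures: small, fast synthetic acquisitions.

Everything is generated at run time by the simulator; fixture scale
(128x128 sensor frames, handful of sub-pixel shifts) keeps single tests
in the seconds range while exercising the real processing chain.
"""

from __future__ import annotations

import numpy as np
import pytest

from uvholo.config import PipelineConfig
from uvholo.pipeline import preprocess_stack
from uvholo.simulate import (
    HologramSimulator,
    NoiseScene,
    Scatterer,
    SensorModel,
    make_pattern,
    simulate_stack,
)
from uvholo.superres import shift_and_add

Z2 = 400.0
N_SENSOR = 128
CENTER = N_SENSOR * 1.12 / 2  # um


@pytest.fixture(scope="session")
def quiet_sensor() -> SensorModel:
    return SensorModel.noiseless(bayer="mono")


@pytest.fixture(scope="session")
def single_particle_scene() -> list[Scatterer]:
    return [
        Scatterer(
            x=CENTER, y=CENTER, z2=Z2, diameter=300,
            strength=0.6 - 0.5j, nanolens_gain=5.0,
        )
    ]


def _quiet_sr(scene):
    """Noise-free mono acquisition -> normalized frames -> 4x SR."""
    pat = make_pattern(4, 0.28, 0, 0, 0)
    stack = simulate_stack(
        scene, pat, SensorModel.noiseless(bayer="mono"), NoiseScene.quiet(),
        seed=1, shape=(N_SENSOR, N_SENSOR),
    )
    pre = preprocess_stack(stack, PipelineConfig(), bayer=False)
    return shift_and_add(pre, factor=4)


@pytest.fixture(scope="session")
def particle_sr(single_particle_scene):
    """Super-resolved hologram of one nanolens-enhanced 300 nm bead."""
    return _quiet_sr(single_particle_scene)


@pytest.fixture(scope="session")
def dust_sr():
    """Super-resolved hologram of a 2.5 um dust speck (strong object)."""
    return _quiet_sr([Scatterer(x=CENTER, y=CENTER, z2=Z2, diameter=2500, strength=0.9 - 0.3j)])


@pytest.fixture(scope="session")
def quiet_simulator(single_particle_scene, quiet_sensor) -> HologramSimulator:
    return HologramSimulator(
        single_particle_scene, quiet_sensor, NoiseScene.quiet(), shape=(N_SENSOR, N_SENSOR)
    )


@pytest.fixture(scope="session")
def dust_simulator(quiet_sensor) -> HologramSimulator:
    """Noise-free acquisition of a strong 2.5 um dust speck — the kind
    of visible mark used for shift registration."""
    scene = [Scatterer(x=CENTER, y=CENTER, z2=Z2, diameter=2500, strength=0.9 - 0.3j)]
    return HologramSimulator(scene, quiet_sensor, NoiseScene.quiet(), shape=(N_SENSOR, N_SENSOR))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
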