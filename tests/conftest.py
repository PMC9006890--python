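import numpy as np
import pytest

from capsidkit import phantom_spec, make_phantom
from capsidkit.presets import PARTICLE_TYPES

#: the suite's global seed convention
SEED = 0

#: noise model used throughout ("stated dose" of the generator)
NOISE = {"dose": 2.0, "gaussian_sigma": 0.5}


@pytest.fixture(scope="session")
def coarse_volumes():
    """One 20-Angstrom phantom per maturation state (cheap, reused)."""
    return {
        t: make_phantom(phantom_spec(t), voxel_size=20.0, seed=1)
        for t in PARTICLE_TYPES
    }


@pytest.fixture(scope="session")
def lattice_7_12():
    from capsidkit.lattice import assign_spikes, build_lattice, decompose_symmetrons

    lat = decompose_symmetrons(build_lattice((7, 12)))
    assign_spikes(lat)
    return lat


@pytest.fixture(scope="session")
def fine_profiles():
    """Spherical radial profiles of the Empty/Full presets at 5-A voxels
    (the morphometry acceptance resolution; built once per session)."""
    from capsidkit.morphometry import radial_profile

    out = {}
    for t in ("Empty", "Full"):
        vol = make_phantom(phantom_spec(t), voxel_size=5.0, seed=1)
        out[t] = radial_profile(vol)
        del vol
    return out
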