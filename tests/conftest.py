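import numpy as np
import pytest

from suprafibre.constants import ROOM
from suprafibre.fibre import (DefectSpec, FibreSpec, PairPotentialParams,
                              generate_fibre)
from suprafibre.landscapes import (LandscapeSpec, Well, build_landscape,
                                   catalogue_field)


@pytest.fixture(scope="session")
def fibre1_field():
    return catalogue_field("fibre1_step1")


@pytest.fixture(scope="session")
def ideal_stack():
    """Defect-free 24-monomer stack, zero thermal noise, z-periodic."""
    return generate_fibre(FibreSpec(n_monomers=24, thermal_noise=0.0, seed=1))


@pytest.fixture(scope="session")
def two_break_fibre():
    spec = FibreSpec(n_monomers=24,
                     defects=(DefectSpec("break", 5, 8.0),
                              DefectSpec("break", 15, 8.0)),
                     thermal_noise=0.0, seed=1)
    return generate_fibre(spec)


@pytest.fixture(scope="session")
def gaussian_well():
    """Single deep Gaussian well: near-harmonic with curvature d/w²."""
    spec = LandscapeSpec(
        name="well", dim=1,
        wells=(Well((0.0,), 50.0, (1.0,)),),
        walls=((-4.0, 4.0),),
        states={"A": ((-1.0, 1.0),)})
    return build_landscape(spec, calibrate=False)


@pytest.fixture(scope="session")
def low_barrier_field():
    """Double well with a 2 kBT barrier, for kinetics cross-checks."""
    spec = LandscapeSpec(
        name="2kT", dim=1,
        wells=(Well((1.0,), 2 * ROOM.kT, (0.35,)),
               Well((2.5,), 0.8, (0.35,))),
        walls=((0.4, 3.1),),
        states={"A": ((0.6, 1.4),), "B": ((2.1, 3.0),)},
        designed_barriers={"A->B": 2 * ROOM.kT})
    return build_landscape(spec)
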