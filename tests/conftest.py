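import numpy as np
import pytest

from sfbrelax.hydrodynamics import friction_tensor
from sfbrelax.molecule_io import Probe, make_fixture
from sfbrelax.sfb_model import build_sfb, internal_modes

TEMPERATURE = 298.0
VISCOSITY = 1.0e-3
REFF = 2.0


@pytest.fixture(scope="session")
def tri_bead_system():
    """tri_bead structure + hessian + friction + SFB parameters at standard conditions."""
    structure, hessian = make_fixture("tri_bead")
    modes = internal_modes(hessian, structure)
    friction = friction_tensor(structure, modes.fields, REFF, VISCOSITY, "stick")
    params = build_sfb(structure, hessian, friction, TEMPERATURE)
    return {
        "structure": structure,
        "hessian": hessian,
        "modes": modes,
        "friction": friction,
        "params": params,
        "probe": Probe(0, (2,)),
        "temperature": TEMPERATURE,
        "viscosity": VISCOSITY,
        "reff": REFF,
    }


@pytest.fixture(scope="session")
def rigid_sphere_high_friction():
    """Spherical rigid rotor deep in the diffusive regime (xi / sqrt(I kT) > 1e3)."""
    from sfbrelax.constants import K_B

    inertia = 1e-45
    structure, _ = make_fixture("rigid_rotor", inertia=(inertia,) * 3)
    friction = friction_tensor(structure, None, REFF, 1.2e-2, "stick")
    params = build_sfb(structure, None, friction, TEMPERATURE)
    xi = friction.xi_rr[0, 0]
    d_rot = K_B * TEMPERATURE / xi
    return {
        "structure": structure,
        "friction": friction,
        "params": params,
        "inertia": inertia,
        "xi": xi,
        "D": d_rot,
        "tau": 1.0 / (6.0 * d_rot),
    }


@pytest.fixture(scope="session")
def bead_pair_system():
    """Stiff bead pair (underdamped internal mode) with friction blocks."""
    structure, hessian = make_fixture("bead_pair", k=100.0, d=1.5)
    modes = internal_modes(hessian, structure)
    friction = friction_tensor(structure, modes.fields, REFF, VISCOSITY, "stick")
    params = build_sfb(structure, hessian, friction, TEMPERATURE)
    return {
        "structure": structure,
        "hessian": hessian,
        "modes": modes,
        "friction": friction,
        "params": params,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
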