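import numpy as np
import pytest

from alphared.structure_io import Atom, Residue, Structure
from alphared.toys import ToyComplexSpec, generate_toy_complex


@pytest.fixture()
def toy():
    """Default hinge fixture: bound/unbound/model triple, seed 1."""
    return generate_toy_complex(ToyComplexSpec(seed=1))


@pytest.fixture()
def rigid_toy():
    """Fixture without hinge motion: unbound == bound, uniform-quality model."""
    return generate_toy_complex(ToyComplexSpec(hinge_angle_deg=0.0, seed=1))


def make_residue(chain, pos, aa="A", ca=(0.0, 0.0, 0.0), cb=None, bfactor=90.0):
    atoms = [Atom(name="CA", element="C", coords=np.array(ca, float), bfactor=bfactor)]
    if cb is not None:
        atoms.append(Atom(name="CB", element="C", coords=np.array(cb, float), bfactor=bfactor))
    return Residue(chain_id=chain, seq_pos=pos, aa=aa, atoms=atoms)


def two_chain_structure(ca_a, ca_b, bfactors_a=None, bfactors_b=None):
    """Minimal CA-only two-chain structure from coordinate lists."""
    bfactors_a = bfactors_a or [90.0] * len(ca_a)
    bfactors_b = bfactors_b or [90.0] * len(ca_b)
    chains = {
        "A": [make_residue("A", i + 1, ca=c, bfactor=b) for i, (c, b) in enumerate(zip(ca_a, bfactors_a))],
        "B": [make_residue("B", i + 1, ca=c, bfactor=b) for i, (c, b) in enumerate(zip(ca_b, bfactors_b))],
    }
    return Structure("twochain", chains)
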