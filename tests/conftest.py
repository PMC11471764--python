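import numpy as np
import pytest

from enmunfold.fixtures import ToySpec, make_toy
from enmunfold.network import build_gamma
from enmunfold.structure_io import CalphaStructure, ContactSet

from oracles import random_walk_coords


@pytest.fixture
def square_structure():
    """Four beads on a square, side 3.8 A: backbone 1-2-3-4, non-covalent
    contacts (1,3), (2,4) (diagonals, 5.37 A) and (1,4) at 7 A cutoff."""
    a = 3.8
    coords = np.array([[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0]], dtype=float)
    return CalphaStructure(
        residue_ids=np.arange(1, 5),
        coords=coords,
        b_factors=np.full(4, 10.0),
    )


@pytest.fixture
def lattice_toy():
    return make_toy(ToySpec("lattice-fold", 27, seed=3))


@pytest.fixture
def hinge_toy():
    return make_toy(ToySpec("hinge", 10, seed=5))


def random_toy_network(seed, max_n=12, max_contacts=10, c=2.0):
    """Random walk chain with a random subset of geometric contacts.

    Returns (n, backbone, contacts, net); used for oracle-equivalence runs.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, max_n + 1))
    coords = random_walk_coords(n, seed=int(rng.integers(2**31)))
    backbone = tuple((i, i + 1) for i in range(1, n))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    ii, jj = np.triu_indices(n, k=2)
    geom = [(int(a) + 1, int(b) + 1) for a, b in zip(ii, jj) if d[a, b] < 7.0]
    if len(geom) > max_contacts:
        keep = rng.choice(len(geom), size=max_contacts, replace=False)
        geom = [geom[k] for k in sorted(keep)]
    contacts = tuple(geom)
    net = build_gamma(
        ContactSet(backbone=backbone, noncovalent=contacts),
        c, n, kappa=1.0, coords0=coords,
    )
    return n, backbone, contacts, net
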