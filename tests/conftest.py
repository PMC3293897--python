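import numpy as np
import pytest

import helixscreen as hs


@pytest.fixture(scope="session")
def dimer():
    """Default planted dimer (single frame) + its parameter table."""
    return hs.make_toy_dimer()


@pytest.fixture(scope="session")
def ensemble(dimer):
    structure, _ = dimer
    return hs.jitter_ensemble(structure, 0.1, 20, seed=11)


@pytest.fixture(scope="session")
def model(dimer):
    structure, _ = dimer
    hot = [structure.residue("A", n) for n in (203, 204, 206, 207)]
    return hs.derive_interface_pharmacophore(structure, hot)


@pytest.fixture(scope="session")
def receptor_a(dimer):
    structure, _ = dimer
    return structure.subset(["A"])


@pytest.fixture(scope="session")
def library(model):
    return hs.make_ligand_library(hs.LibrarySpec(seed=3), model)


def make_point_atom(serial, element, xyz, charge=0.0, eps=0.0, rmin_half=1.9,
                    radius=1.7, name=None):
    a = hs.Atom(serial, name or f"{element}{serial}", element, np.asarray(xyz, float))
    a.charge, a.lj_epsilon, a.lj_rmin_half, a.radius = charge, eps, rmin_half, radius
    return a


def single_atom_structure(element="C", xyz=(0.0, 0.0, 0.0), charge=0.0,
                          eps=0.1, rmin_half=1.9, radius=1.7, chain="R"):
    atom = make_point_atom(1, element, xyz, charge, eps, rmin_half, radius)
    res = hs.Residue(chain, 1, "UNK", [atom])
    return hs.Structure({chain: [res]})


def single_atom_ligand(element="C", xyz=(0.0, 0.0, 0.0), charge=0.0,
                       eps=0.1, rmin_half=1.9, radius=1.7):
    atom = make_point_atom(1, element, xyz, charge, eps, rmin_half, radius)
    return hs.Ligand("probe", [atom], [], [np.array([xyz], dtype=float)])
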