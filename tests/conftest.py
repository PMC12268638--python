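import numpy as np
import pytest

from conformap.structure import AtomRecord, Selection, Structure
from conformap.synth import TwoLobeParams, make_two_lobe


def ca_structure(identifier, residues, chain="A"):
    """Structure from [(resnum, resname, (x, y, z)), ...] CA records."""
    atoms = [
        AtomRecord(chain, rn, "", name, "CA", "C", "", 1.0, 20.0,
                   tuple(float(c) for c in xyz))
        for rn, name, xyz in residues
    ]
    return Structure(identifier, atoms)


def sequence_structure(identifier, one_letter, chain="A", start=1, spacing=3.8):
    """CA-only chain whose residue names spell the given sequence."""
    three = {v: k for k, v in {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }.items()}
    residues = [
        (start + i, three[c], (spacing * i, 0.1 * (i % 7), 0.0))
        for i, c in enumerate(one_letter)
    ]
    return ca_structure(identifier, residues, chain)


@pytest.fixture(scope="session")
def two_lobe_closed():
    s, truth = make_two_lobe(TwoLobeParams(theta_open=0.0))
    return s


@pytest.fixture(scope="session")
def two_lobe_open():
    s, truth = make_two_lobe(TwoLobeParams(theta_open=30.0))
    return s


@pytest.fixture(scope="session")
def small_lobe_sel():
    return Selection(ranges=((1, 60),))


@pytest.fixture(scope="session")
def large_lobe_sel():
    return Selection(ranges=((61, 180),))


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(0, 10, 3)
    return R, t
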