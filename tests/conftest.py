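import numpy as np
import pytest

from dockppi.structio import AtomRecord, ChainStructure, DimerStructure, Residue
from dockppi.synthgen import make_toy_dimer


def chain_from_coords(chain_id, coords, res_names=None, atom_name="CA"):
    """Build a chain of single-atom residues from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    names = res_names or ["ALA"] * len(coords)
    return ChainStructure(
        chain_id,
        [
            Residue(i + 1, names[i], [AtomRecord(atom_name, "C", coords[i])])
            for i in range(len(coords))
        ],
    )


def dimer_from_coords(rec_coords, lig_coords, label=""):
    rec = chain_from_coords("A", rec_coords)
    lig = chain_from_coords("B", lig_coords)
    if len(lig.residues) > len(rec.residues):
        raise ValueError("receptor must be the larger chain in fixtures")
    return DimerStructure(receptor=rec, ligand=lig, label=label)


@pytest.fixture(scope="session")
def toy_dimer():
    """A clash-free two-helix native complex with a >= 20-residue interface."""
    return make_toy_dimer(40, 30, seed=11, label="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
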