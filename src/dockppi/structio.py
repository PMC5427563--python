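"""PDB structure I/O and the chain/residue/atom data model.

Only the ATOM/TER/END subset of the PDB format is handled: HETATM records,
waters and hydrogens are skipped on read (heavy-atom convention — all
downstream distance computations operate on heavy atoms only). Residues are
keyed by (chain_id, res_seq); insertion codes are rejected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np
from Bio.SeqUtils import seq1

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainStructure",
    "DimerStructure",
    "PDBParseError",
    "EmptyStructureError",
    "read_pdb",
    "write_pdb",
    "assign_roles",
]


class PDBParseError(ValueError):
    """Malformed PDB content; message names the offending line number."""


class EmptyStructureError(ValueError):
    """No usable ATOM records found."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: name, element and Cartesian coordinates in Angstroms."""

    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), float

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("coords must be a finite 3-vector")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        object.__setattr__(self, "coords", c)


@dataclass
class Residue:
    res_seq: int
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class ChainStructure:
    """A single protein chain: ordered residues with heavy atoms."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """One-letter sequence derived from residue names (X for unknowns)."""
        return "".join(
            seq1(r.res_name, undef_code="X") for r in self.residues
        )

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates in residue order; residues without CA are skipped."""
        out = [r.atom("CA").coords for r in self.residues if r.atom("CA")]
        return np.array(out) if out else np.empty((0, 3))

    def heavy_coords(self) -> np.ndarray:
        return np.vstack([r.coords for r in self.residues])

    def residue_of_atom(self) -> np.ndarray:
        """Index of the owning residue for every heavy atom (heavy_coords order)."""
        return np.concatenate(
            [np.full(len(r.atoms), i) for i, r in enumerate(self.residues)]
        )


@dataclass
class DimerStructure:
    """A two-chain complex with receptor/ligand roles already assigned.

    By convention the receptor is the larger chain (more residues).
    """

    receptor: ChainStructure
    ligand: ChainStructure
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.receptor) < len(self.ligand):
            raise ValueError("receptor must not be smaller than ligand")
        if self.receptor.chain_id == self.ligand.chain_id:
            raise ValueError("receptor and ligand chain ids must differ")


def _infer_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_pdb(source: Union[str, Path, TextIO]) -> list[ChainStructure]:
    """Parse ATOM records from PDB text into one ChainStructure per chain.

    HETATM, waters and hydrogens are skipped; altloc duplicates keep the
    first occurrence; insertion codes raise. Chains appear in file order.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()

    chains: dict[str, ChainStructure] = {}
    seen_atoms: set[tuple[str, int, str]] = set()
    for lineno, line in enumerate(io.StringIO(text), start=1):
        rec = line[:6]
        if rec != "ATOM  ":
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM record")
        try:
            atom_name = line[12:16].strip()
            altloc = line[16]
            res_name = line[17:20].strip()
            chain_id = line[21]
            res_seq = int(line[22:26])
            icode = line[26]
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from exc
        if icode != " ":
            raise PDBParseError(
                f"line {lineno}: insertion codes are not supported (found {icode!r})"
            )
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(atom_name)
        if element in ("H", "D"):
            continue
        if res_name == "HOH":
            continue
        key = (chain_id, res_seq, atom_name)
        if key in seen_atoms:  # altloc duplicate: keep first
            if altloc != " ":
                continue
            raise PDBParseError(f"line {lineno}: duplicate atom {key}")
        seen_atoms.add(key)

        chain = chains.setdefault(chain_id, ChainStructure(chain_id))
        if chain.residues and chain.residues[-1].res_seq == res_seq:
            residue = chain.residues[-1]
        else:
            residue = Residue(res_seq=res_seq, res_name=res_name)
            chain.residues.append(residue)
        residue.atoms.append(
            AtomRecord(atom_name=atom_name, element=element, coords=np.array([x, y, z]))
        )

    if not chains:
        raise EmptyStructureError("no ATOM records found")
    return list(chains.values())


def write_pdb(
    chains: Iterable[ChainStructure], destination: Union[str, Path, TextIO]
) -> None:
    """Write chains as fixed-width ATOM records with TER between chains and END."""
    chains = list(chains)
    if not chains:
        raise ValueError("no chains to write")

    lines: list[str] = []
    serial = 0
    for chain in chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                name = atom.atom_name
                # standard alignment: 1-3 char names start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name_field:<4s} {res.res_name:<3s} "
                    f"{chain.chain_id}{res.res_seq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        last = chain.residues[-1]
        lines.append(
            f"TER   {serial:5d}      {last.res_name:<3s} "
            f"{chain.chain_id}{last.res_seq:4d}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"

    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def assign_roles(
    chain_a: ChainStructure, chain_b: ChainStructure, label: str = ""
) -> DimerStructure:
    """Assign receptor/ligand roles: the larger monomer (more residues) is the
    receptor. Equal lengths tie-break on lexicographically smaller chain id.
    """
    if len(chain_a) == 0 or len(chain_b) == 0:
        raise ValueError("chains must be non-empty")
    if chain_a.chain_id == chain_b.chain_id:
        raise ValueError("chain ids must be distinct")
    if len(chain_a) > len(chain_b):
        receptor, ligand = chain_a, chain_b
    elif len(chain_b) > len(chain_a):
        receptor, ligand = chain_b, chain_a
    elif chain_a.chain_id < chain_b.chain_id:
        receptor, ligand = chain_a, chain_b
    else:
        receptor, ligand = chain_b, chain_a
    return DimerStructure(receptor=receptor, ligand=ligand, label=label)
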