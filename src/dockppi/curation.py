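"""Dataset curation rules for dimer benchmark and training sets.

Covers the construction rules for benchmark/training data: global-alignment
sequence identity, the 85% homo/hetero split, greedy longest-first clustering
at 80% identity (a transparent reimplementation of the CD-HIT-style
procedure), interface-redundancy removal at interface-MCC > 0.5, proteome
length filters (50-600 residues), the >= 20-interface-residue inclusion rule,
and ligand-swap negative generation (a seeded derangement of ligand
assignments among homodimers, producing putative non-interacting pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from dockppi.interface_metrics import interface_overlap_mcc, interface_residues
from dockppi.structio import DimerStructure

__all__ = [
    "CurationConfig",
    "pairwise_identity",
    "classify_dimer",
    "greedy_cluster",
    "remove_redundant_interfaces",
    "proteome_filter",
    "swap_ligands",
    "min_interface_filter",
    "read_fasta",
    "write_fasta",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO")


@dataclass(frozen=True)
class CurationConfig:
    homo_identity_min: float = 85.0  # percent
    cluster_identity: float = 80.0  # percent
    interface_mcc_max: float = 0.5
    min_interface_residues: int = 20
    min_length: int = 50
    max_length: int = 600

    def __post_init__(self) -> None:
        ok = (
            0 < self.homo_identity_min <= 100
            and 0 < self.cluster_identity <= 100
            and 0 < self.min_length < self.max_length
        )
        if not ok:
            raise ValueError("invalid curation configuration")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # end gaps penalized like internal ones (global identity definition)
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity: matches / alignment length x 100."""
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq.upper()) - _AA
        if bad:
            raise ValueError(f"invalid residue characters: {sorted(bad)}")
    alignment = _aligner().align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / length


def classify_dimer(dimer: DimerStructure, config: CurationConfig = CurationConfig()) -> str:
    """'homo' iff chain identity >= the 85% cut (boundary inclusive), else 'hetero'."""
    identity = pairwise_identity(dimer.receptor.sequence, dimer.ligand.sequence)
    return "homo" if identity >= config.homo_identity_min else "hetero"


def greedy_cluster(
    sequences: dict[str, str], identity_threshold: float = 80.0
) -> list[dict]:
    """Greedy longest-first clustering by representative identity.

    Sequences sorted by decreasing length (stable); each joins the first
    cluster whose representative it matches at >= threshold, else founds a
    new cluster with itself as representative.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: list[dict] = []
    for name in order:
        seq = sequences[name]
        for cluster in clusters:
            if pairwise_identity(seq, cluster["representative_seq"]) >= identity_threshold:
                cluster["members"].append(name)
                break
        else:
            clusters.append(
                {"representative": name, "representative_seq": seq, "members": [name]}
            )
    return clusters


def remove_redundant_interfaces(
    dimers_in_cluster: Sequence[DimerStructure],
    config: CurationConfig = CurationConfig(),
) -> list[DimerStructure]:
    """Greedy retention in input order; drop a dimer whose interface MCC
    against any already retained dimer exceeds the redundancy cut (0.5)."""
    retained: list[DimerStructure] = []
    for dimer in dimers_in_cluster:
        if all(
            interface_overlap_mcc(dimer, kept) <= config.interface_mcc_max
            for kept in retained
        ):
            retained.append(dimer)
    return retained


def proteome_filter(
    proteins: dict[str, str], config: CurationConfig = CurationConfig()
) -> dict[str, str]:
    """Keep proteins with 50 <= length <= 600 and deduplicate identical
    sequences (first occurrence kept)."""
    seen: set[str] = set()
    out: dict[str, str] = {}
    for name, seq in proteins.items():
        if not (config.min_length <= len(seq) <= config.max_length):
            continue
        if seq in seen:
            continue
        seen.add(seq)
        out[name] = seq
    return out


def swap_ligands(
    homo_dimers: Sequence[tuple[str, str]],
    seed: int,
    known_pairs: Iterable[tuple[str, str]] = (),
    max_tries: int = 10_000,
) -> list[tuple[str, str]]:
    """Ligand-swap negatives: a seeded random derangement of ligand assignments.

    Input is (receptor_id, ligand_id) per homodimer. No dimer keeps its own
    ligand, the ligand multiset is preserved, and any swap that reproduces a
    known positive pair is re-drawn. Returns the same number of pairs.
    """
    n = len(homo_dimers)
    if n < 2:
        raise ValueError("need >= 2 dimers for a derangement")
    forbidden = {frozenset(p) for p in known_pairs}
    receptors = [r for r, _ in homo_dimers]
    ligands = [l for _, l in homo_dimers]
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if np.any(perm == np.arange(n)):
            continue
        pairs = [(receptors[i], ligands[perm[i]]) for i in range(n)]
        if any(frozenset(p) in forbidden for p in pairs):
            continue
        return pairs
    raise RuntimeError("no valid derangement found within retry budget")


def min_interface_filter(
    dimers: Sequence[DimerStructure], config: CurationConfig = CurationConfig()
) -> list[DimerStructure]:
    """Keep dimers whose total interface (both chains, 10 Å rule) has at
    least `min_interface_residues` residues (boundary inclusive)."""
    return [
        d
        for d in dimers
        if interface_residues(d).total >= config.min_interface_residues
    ]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    lines = []
    for name, seq in sequences.items():
        lines.append(f">{name}")
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    Path(path).write_text("\n".join(lines) + "\n")
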