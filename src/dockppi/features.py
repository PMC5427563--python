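"""Binding-energy feature vectors for the interaction classifier.

The canonical feature schema mirrors the terms a docking refinement engine
reports per dimer model: global energy, attractive/repulsive van der Waals,
atomic contact energy, internal energy, hydrogen bonds, partial
electrostatics, disulfide bonds, π-stacking and aliphatic interactions.
Engine output is ingested through a TSV reader; `surrogate_features` computes
deterministic contact-derived stand-ins directly from a structure so the
pipeline runs end-to-end without an engine. Surrogates are never mixed with
engine values in one table.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from dockppi.structio import DimerStructure

__all__ = [
    "FEATURE_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "zscore_normalize",
    "surrogate_features",
]

FEATURE_COLUMNS: tuple[str, ...] = (
    "global_energy",
    "vdw_attractive",
    "vdw_repulsive",
    "atomic_contact_energy",
    "internal_energy",
    "hbond",
    "partial_electrostatics",
    "disulfide",
    "pi_stacking",
    "aliphatic",
)

_KEY_COLUMNS = ("pair_id", "model_rank")


def read_feature_table(path) -> pd.DataFrame:
    """Read and validate a tab-separated feature table.

    Required columns: pair_id, model_rank and the ten canonical energy terms;
    an optional integer `label` column in {0, 1}. Extra columns are preserved.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (*_KEY_COLUMNS, *FEATURE_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing required column(s): {missing}")
    for col in FEATURE_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(values)]
        if len(bad):
            raise ValueError(
                f"non-numeric or non-finite value in column {col!r}, row {bad[0]}"
            )
        df[col] = values.astype(float)
    dups = df.duplicated(subset=list(_KEY_COLUMNS))
    if dups.any():
        raise ValueError(
            f"duplicate (pair_id, model_rank) at row {df.index[dups][0]}"
        )
    if "label" in df.columns and not df["label"].isin([0, 1]).all():
        raise ValueError("label column must contain only 0/1")
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def zscore_normalize(
    table: pd.DataFrame, reference_stats: dict[str, tuple[float, float]] | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-column Z-score normalization of the canonical feature columns.

    With `reference_stats` (column -> (mean, sd), e.g. from the training
    split) those statistics are applied; otherwise they are estimated from
    the table and returned for reuse on held-out data. A zero-variance
    column maps to zeros with a warning.
    """
    if table.empty:
        raise ValueError("empty feature table")
    out = table.copy()
    if reference_stats is None:
        if len(table) < 2:
            raise ValueError("need >= 2 rows to estimate normalization stats")
        reference_stats = {}
        for col in FEATURE_COLUMNS:
            reference_stats[col] = (
                float(table[col].mean()),
                float(table[col].std(ddof=0)),
            )
    for col in FEATURE_COLUMNS:
        mean, sd = reference_stats[col]
        if sd == 0:
            warnings.warn(f"constant feature column {col!r}; normalized to zeros")
            out[col] = 0.0
        else:
            out[col] = (table[col] - mean) / sd
    return out, reference_stats


# ---------------------------------------------------------------------------
# structure-derived surrogate features

_POLAR = {"N", "O"}
_CHARGE = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}
_AROMATIC = {"PHE", "TYR", "TRP", "HIS"}
_ALIPHATIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PRO"}


def _pair_count(tree_a: cKDTree, coords_b: np.ndarray, r: float) -> int:
    if len(coords_b) == 0:
        return 0
    return int(tree_a.count_neighbors(cKDTree(coords_b), r))


def surrogate_features(dimer: DimerStructure) -> dict[str, float]:
    """Deterministic contact-derived energy-term stand-ins for one dimer.

    Documented formulas (heavy atoms, cross-interface pairs only):
      vdw_attractive        -0.1 x pairs in the 3.5-6.0 Å shell
      vdw_repulsive          0.5 x pairs closer than 3.0 Å
      atomic_contact_energy -0.1 x pairs closer than 5.0 Å
      hbond                 -0.2 x N/O-N/O pairs closer than 3.5 Å
      partial_electrostatics sum of charge products over charged-residue
                             (ASP/GLU -, LYS/ARG +) CB pairs within 6 Å
      disulfide             -1.0 x SG-SG pairs closer than 2.5 Å
      pi_stacking           -0.2 x aromatic-residue CB pairs within 7 Å
      aliphatic             -0.05 x aliphatic-residue CB pairs within 6 Å
      internal_energy        0 (rigid decoys carry no strain term)
      global_energy          sum of all terms above

    An empty interface yields the all-zero vector. Invariant under joint
    rigid transforms of the complex (all terms are distance-based).
    """
    rec, lig = dimer.receptor, dimer.ligand
    rc = rec.heavy_coords()
    lc = lig.heavy_coords()
    rec_tree = cKDTree(rc)

    def chain_atoms(chain, predicate):
        return np.array(
            [
                a.coords
                for res in chain.residues
                for a in res.atoms
                if predicate(res, a)
            ]
        ).reshape(-1, 3)

    n_attr = _pair_count(rec_tree, lc, 6.0) - _pair_count(rec_tree, lc, 3.5)
    n_rep = _pair_count(rec_tree, lc, 3.0)
    n_ace = _pair_count(rec_tree, lc, 5.0)

    rec_polar = chain_atoms(rec, lambda r, a: a.element in _POLAR)
    lig_polar = chain_atoms(lig, lambda r, a: a.element in _POLAR)
    n_hb = (
        _pair_count(cKDTree(rec_polar), lig_polar, 3.5) if len(rec_polar) else 0
    )

    elec = 0.0
    rec_charged = [
        (res, a)
        for res in rec.residues
        for a in res.atoms
        if res.res_name in _CHARGE and a.atom_name == "CB"
    ]
    lig_charged = [
        (res, a)
        for res in lig.residues
        for a in res.atoms
        if res.res_name in _CHARGE and a.atom_name == "CB"
    ]
    for res_r, atom_r in rec_charged:
        for res_l, atom_l in lig_charged:
            if np.linalg.norm(atom_r.coords - atom_l.coords) <= 6.0:
                elec += _CHARGE[res_r.res_name] * _CHARGE[res_l.res_name]

    rec_sg = chain_atoms(rec, lambda r, a: a.atom_name == "SG")
    lig_sg = chain_atoms(lig, lambda r, a: a.atom_name == "SG")
    n_ss = _pair_count(cKDTree(rec_sg), lig_sg, 2.5) if len(rec_sg) else 0

    rec_aro = chain_atoms(rec, lambda r, a: r.res_name in _AROMATIC and a.atom_name == "CB")
    lig_aro = chain_atoms(lig, lambda r, a: r.res_name in _AROMATIC and a.atom_name == "CB")
    n_pi = _pair_count(cKDTree(rec_aro), lig_aro, 7.0) if len(rec_aro) else 0

    rec_ali = chain_atoms(rec, lambda r, a: r.res_name in _ALIPHATIC and a.atom_name == "CB")
    lig_ali = chain_atoms(lig, lambda r, a: r.res_name in _ALIPHATIC and a.atom_name == "CB")
    n_ali = _pair_count(cKDTree(rec_ali), lig_ali, 6.0) if len(rec_ali) else 0

    terms = {
        "vdw_attractive": -0.1 * n_attr,
        "vdw_repulsive": 0.5 * n_rep,
        "atomic_contact_energy": -0.1 * n_ace,
        "internal_energy": 0.0,
        "hbond": -0.2 * n_hb,
        "partial_electrostatics": float(elec),
        "disulfide": -1.0 * n_ss,
        "pi_stacking": -0.2 * n_pi,
        "aliphatic": -0.05 * n_ali,
    }
    terms["global_energy"] = float(sum(terms.values()))
    return {col: float(terms[col]) for col in FEATURE_COLUMNS}
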