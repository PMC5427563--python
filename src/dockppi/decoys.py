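"""Decoy dimer generation.

Two generators are provided: controlled rigid perturbations of a native
complex (decoys with known deviation, for metric and spectrum fixtures), and
a naive exhaustive rigid-body sampler over a rotation set x translation grid
scored by interface contacts minus clashes. The sampler stands in for an
external FFT docking engine so that every downstream stage of the pipeline is
exercisable without one; it makes no claim to docking accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from dockppi.geometry import RigidTransform, apply_transform, rmsd
from dockppi.structio import ChainStructure, DimerStructure, write_pdb

__all__ = [
    "DecoyPose",
    "perturb_native",
    "generate_decoy_set",
    "naive_rigid_sample",
    "write_decoy_set",
]

#: two poses are duplicates if their ligand-Cα RMSD is below this (Å)
DEDUP_RMSD = 1.0
#: contact shell (Å) and clash cutoff (Å) for the naive sampler score
CONTACT_SHELL = (4.0, 6.0)
CLASH_CUTOFF = 2.5
#: weight of the continuous packing tie-break term in the sampler score
_PACKING_EPS = 1e-4


@dataclass(frozen=True)
class DecoyPose:
    """One rigid ligand pose: transform (receptor frame), score and rank."""

    transform: RigidTransform
    score: float
    rank: int


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    # uniform on the sphere via normalized Gaussian 3-vector
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _pose_transform_about_centroid(
    centroid: np.ndarray, rot_deg: float, axis: np.ndarray, shift: np.ndarray
) -> RigidTransform:
    R = Rotation.from_rotvec(np.deg2rad(rot_deg) * axis).as_matrix()
    # rotate about the centroid, then translate
    t = centroid - R @ centroid + shift
    return RigidTransform(R, t)


def perturb_native(
    native: DimerStructure, rot_deg: float, trans_ang: float, seed: int
) -> tuple[DecoyPose, DimerStructure]:
    """Rotate the ligand by `rot_deg` about a random axis through its centroid
    and translate it `trans_ang` Å in a random direction; receptor untouched.
    Deterministic under `seed`.
    """
    if rot_deg < 0 or trans_ang < 0:
        raise ValueError("perturbation magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    axis = _random_unit_vector(rng)
    shift = _random_unit_vector(rng) * trans_ang
    centroid = native.ligand.heavy_coords().mean(axis=0)
    transform = _pose_transform_about_centroid(centroid, rot_deg, axis, shift)
    decoy = DimerStructure(
        receptor=native.receptor,
        ligand=apply_transform(transform, native.ligand),
        label=f"{native.label}:perturb",
    )
    return DecoyPose(transform=transform, score=0.0, rank=1), decoy


def _contact_score(
    receptor_tree: cKDTree, ligand_coords: np.ndarray, clash_weight: float
) -> float:
    tree = cKDTree(ligand_coords)
    c_clash, c_lo, c_hi = receptor_tree.count_neighbors(
        tree, np.array([CLASH_CUTOFF, CONTACT_SHELL[0], CONTACT_SHELL[1]])
    )
    return float(c_hi - c_lo) - clash_weight * float(c_clash)


def generate_decoy_set(
    native: DimerStructure,
    n: int,
    magnitude_schedule: Sequence[tuple[float, float]],
    seed: int,
    clash_weight: float = 2.0,
) -> list[tuple[DecoyPose, DimerStructure]]:
    """n perturbation decoys cycling through a (rot_deg, trans_ang) schedule,
    ranked by the contact-minus-clash sampler score (ties broken by tighter
    packing, then generation order).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not magnitude_schedule:
        raise ValueError("empty magnitude schedule")
    receptor_tree = cKDTree(native.receptor.heavy_coords())
    rec_centroid = native.receptor.heavy_coords().mean(axis=0)
    entries = []
    for i in range(n):
        rot, trans = magnitude_schedule[i % len(magnitude_schedule)]
        _, decoy = perturb_native(native, rot, trans, seed=seed + i)
        lig = decoy.ligand.heavy_coords()
        score = _contact_score(receptor_tree, lig, clash_weight)
        score -= _PACKING_EPS * float(np.linalg.norm(lig.mean(axis=0) - rec_centroid))
        entries.append((score, i, decoy))
    entries.sort(key=lambda e: (-e[0], e[1]))
    out = []
    for rank, (score, i, decoy) in enumerate(entries, start=1):
        rot, trans = magnitude_schedule[i % len(magnitude_schedule)]
        pose = DecoyPose(
            transform=RigidTransform.identity(), score=score, rank=rank
        )
        out.append((pose, replace_label(decoy, f"{native.label}:decoy{i}")))
    return out


def replace_label(dimer: DimerStructure, label: str) -> DimerStructure:
    return DimerStructure(receptor=dimer.receptor, ligand=dimer.ligand, label=label)


def _canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and a canonical orthonormal frame of a coordinate cloud.

    The first axis is the leading principal direction, sign-fixed by the
    third moment of the projections. The second axis is a smooth moment-based
    in-plane direction (height-weighted perpendicular components), which
    stays well-defined even when the two minor principal axes are degenerate
    (e.g. for helical clouds); the third completes a right-handed frame. The
    frame co-rotates under any rigid transform of the input, making the
    sampler's translation grid pose-independent.
    """
    centroid = coords.mean(axis=0)
    X = coords - centroid
    _, S, Vt = np.linalg.svd(X, full_matrices=False)
    a1 = Vt[0]
    proj = X @ a1
    skew = np.sum(proj**3)
    if abs(skew) < 1e-9:
        skew = proj[np.argmax(np.abs(proj))]
    if skew < 0:
        a1 = -a1
        proj = -proj
    perp = X - np.outer(proj, a1)
    v = (proj[:, None] * perp).sum(axis=0)  # height-weighted radial moment
    if np.linalg.norm(v) < 1e-6:
        v = perp[np.argmax(np.einsum("ij,ij->i", perp, perp))]
    a2 = v - (v @ a1) * a1
    a2 /= np.linalg.norm(a2)
    a3 = np.cross(a1, a2)
    return centroid, np.vstack([a1, a2, a3])


def _rotation_set(n_rotations: int) -> list[np.ndarray]:
    """Deterministic quasi-uniform rotations: Fibonacci-sphere axes crossed
    with evenly spaced angles."""
    rots = [np.eye(3)]
    if n_rotations == 1:
        return rots
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = n_rotations - 1
    for i in range(k):
        z = 1.0 - 2.0 * (i + 0.5) / k
        r = np.sqrt(max(0.0, 1.0 - z * z))
        axis = np.array([r * np.cos(golden * i), r * np.sin(golden * i), z])
        angle = 2.0 * np.pi * ((i % 4) + 1) / 5.0
        rots.append(Rotation.from_rotvec(angle * axis).as_matrix())
    return rots


def naive_rigid_sample(
    receptor: ChainStructure,
    ligand: ChainStructure,
    n_rotations: int = 8,
    grid_step: float = 3.0,
    clash_weight: float = 2.0,
    n_keep: int = 10,
) -> list[tuple[DecoyPose, DimerStructure]]:
    """Exhaustive coarse rigid sampling of ligand poses around the receptor.

    Rotations from a deterministic quasi-uniform set; ligand centroid swept
    over a cubic grid (spacing `grid_step`) laid out in the receptor's
    canonical principal-axes frame, restricted to the shell where contacts
    are geometrically possible. Score = heavy-atom pairs in the 4-6 Å shell
    minus `clash_weight` x pairs closer than 2.5 Å, with a small packing term
    breaking integer ties. Top poses are deduplicated (ligand-Cα RMSD < 1 Å)
    and returned ranked.
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    rec_coords = receptor.heavy_coords()
    lig_coords = ligand.heavy_coords()
    if len(rec_coords) < 3 or len(lig_coords) < 3:
        raise ValueError("degenerate input chains")

    rec_centroid, rec_axes = _canonical_frame(rec_coords)
    rec_local = (rec_coords - rec_centroid) @ rec_axes.T
    rec_tree = cKDTree(rec_local)
    lig_centroid, lig_axes = _canonical_frame(lig_coords)
    # ligand expressed in its own canonical frame so poses are input-pose-free
    lig_centered = (lig_coords - lig_centroid) @ lig_axes.T
    lig_radius = float(np.linalg.norm(lig_centered, axis=1).max())
    rec_radius = float(np.linalg.norm(rec_local, axis=1).max())
    reach = rec_radius + lig_radius + CONTACT_SHELL[1]

    n_steps = int(np.ceil(reach / grid_step))
    offsets = np.arange(-n_steps, n_steps + 1) * grid_step
    grid = np.array(np.meshgrid(offsets, offsets, offsets)).reshape(3, -1).T
    dist = np.linalg.norm(grid, axis=1)
    grid = grid[(dist <= reach) & (dist >= max(grid_step * 0.5, 1.0))]

    candidates: list[tuple[float, int, int, np.ndarray]] = []
    for ri, R in enumerate(_rotation_set(n_rotations)):
        rotated = lig_centered @ R.T
        for gi, center in enumerate(grid):
            d = float(np.linalg.norm(center))
            placed = rotated + center
            score = _contact_score(rec_tree, placed, clash_weight)
            score -= _PACKING_EPS * d
            if score > 0 or len(candidates) < n_keep * 5:
                candidates.append((score, ri, gi, center))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    kept: list[tuple[DecoyPose, DimerStructure]] = []
    kept_lig_ca: list[np.ndarray] = []
    ca_idx = [
        i
        for i, r in enumerate(ligand.residues)
        if r.atom("CA") is not None
    ]
    rotset = _rotation_set(n_rotations)
    for score, ri, gi, center in candidates:
        if len(kept) >= n_keep:
            break
        R_local = rotset[ri]
        # local-frame placement back to world coordinates
        R_world = rec_axes.T @ R_local @ lig_axes
        t_world = rec_axes.T @ center + rec_centroid - R_world @ lig_centroid
        transform = RigidTransform(R_world, t_world)
        new_ligand = apply_transform(transform, ligand)
        ca = new_ligand.ca_coords()
        if any(rmsd(ca, prev) < DEDUP_RMSD for prev in kept_lig_ca if len(prev) == len(ca)):
            continue
        kept_lig_ca.append(ca)
        pose = DecoyPose(transform=transform, score=float(score), rank=len(kept) + 1)
        dimer = DimerStructure(
            receptor=receptor, ligand=new_ligand, label=f"pose{len(kept) + 1}"
        )
        kept.append((pose, dimer))
    return kept


def write_decoy_set(
    decoys: Sequence[tuple[DecoyPose, DimerStructure]], outdir
) -> None:
    """Serialize a decoy set as numbered PDB files plus a TSV index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["rank\tscore\tfile"]
    for pose, dimer in decoys:
        fname = f"decoy_{pose.rank:04d}.pdb"
        write_pdb([dimer.receptor, dimer.ligand], outdir / fname)
        lines.append(f"{pose.rank}\t{pose.score:.6f}\t{fname}")
    (outdir / "index.tsv").write_text("\n".join(lines) + "\n")
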