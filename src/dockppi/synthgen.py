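"""Synthetic inputs for end-to-end pipeline testing.

Generates idealized helical toy monomers and rigid toy dimers with a
designed interface of at least 20 residues, class-conditional binding-energy
feature tables whose per-term medians are calibrated to the values observed
for interacting vs non-interacting pairs (attractive vdW -0.230 / 0.214,
repulsive vdW -0.187 / -0.195, hydrogen bond -0.068 / 0.418 on the Z-score
scale; remaining terms are package-chosen defaults in the same spirit),
synthetic GO-slim annotations with configurable co-annotation pass rates
(CC 82% for interacting vs 58% for random pairs by default), and a seeded
miniature-proteome scenario directory exercising every pipeline stage.

The toy geometry is deliberately biologically naive — ideal α-helical
Cα/Cβ traces — because the pipeline under test is geometry-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dockppi.bookkeeping import iter_pairs
from dockppi.decoys import generate_decoy_set, write_decoy_set
from dockppi.features import FEATURE_COLUMNS, write_feature_table
from dockppi.interface_metrics import interface_residues, irmsd
from dockppi.structio import (
    AtomRecord,
    ChainStructure,
    DimerStructure,
    Residue,
    assign_roles,
    write_pdb,
)

__all__ = [
    "SynthConfig",
    "make_toy_monomer",
    "make_toy_dimer",
    "synth_energy_features",
    "synth_annotations",
    "build_scenario",
]

_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL"
).split()

# ideal α-helix trace parameters
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue
_CA_RADIUS = 2.3  # Å
_CB_RADIUS = _CA_RADIUS + 1.53  # Cβ radially outward of Cα

#: class-conditional per-term medians (interacting, non_interacting)
DEFAULT_FEATURE_MEDIANS: dict[str, tuple[float, float]] = {
    "global_energy": (-0.45, 0.32),
    "vdw_attractive": (-0.230, 0.214),
    "vdw_repulsive": (-0.187, -0.195),
    "atomic_contact_energy": (-0.22, 0.18),
    "internal_energy": (-0.05, 0.07),
    "hbond": (-0.068, 0.418),
    "partial_electrostatics": (-0.08, 0.05),
    "disulfide": (0.0, 0.0),
    "pi_stacking": (-0.04, 0.03),
    "aliphatic": (-0.10, 0.06),
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic miniature proteome."""

    seed: int = 0
    n_proteins: int = 20
    length_range: tuple[int, int] = (50, 120)
    interface_target: int = 20
    n_true_pairs: int = 15
    n_decoy_pairs: int = 4  # true pairs that also get a decoy set on disk
    n_decoys: int = 12
    models_per_pair: int = 3
    feature_medians: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_MEDIANS))
    feature_scale_left: float = 0.35
    feature_scale_right: float = 0.45
    # per-aspect (interacting, random) co-annotation pass rates and coverage
    cc_pass_rates: tuple[float, float] = (0.82, 0.58)
    bp_pass_rates: tuple[float, float] = (0.93, 0.35)
    mf_pass_rates: tuple[float, float] = (0.48, 0.52)
    cc_coverage: float = 1.0
    bp_coverage: float = 1.0
    mf_coverage: float = 1.0
    n_go_terms: int = 12  # non-dominant slim terms per aspect

    def __post_init__(self) -> None:
        rates = [*self.cc_pass_rates, *self.bp_pass_rates, *self.mf_pass_rates,
                 self.cc_coverage, self.bp_coverage, self.mf_coverage]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("probabilities must be in [0, 1]")


def make_toy_monomer(n_residues: int, seed: int, chain_id: str = "A") -> ChainStructure:
    """Ideal α-helical Cα+Cβ trace with a random sequence; deterministic per seed."""
    if n_residues < 5:
        raise ValueError("toy monomer needs at least 5 residues")
    rng = np.random.default_rng(seed)
    chain = ChainStructure(chain_id)
    for i in range(n_residues):
        theta = math.radians(_HELIX_TWIST * i)
        z = _HELIX_RISE * i
        res_name = _AA3[rng.integers(len(_AA3))]
        atoms = [
            AtomRecord(
                "CA", "C",
                np.array([_CA_RADIUS * math.cos(theta), _CA_RADIUS * math.sin(theta), z]),
            )
        ]
        if res_name != "GLY":
            atoms.append(
                AtomRecord(
                    "CB", "C",
                    np.array(
                        [_CB_RADIUS * math.cos(theta), _CB_RADIUS * math.sin(theta), z]
                    ),
                )
            )
        chain.residues.append(Residue(res_seq=i + 1, res_name=res_name, atoms=atoms))
    return chain


def make_toy_dimer(
    receptor_len: int,
    ligand_len: int,
    seed: int,
    label: str = "",
    interface_target: int = 20,
) -> DimerStructure:
    """Two toy helices packed side by side into a native dimer.

    The second helix is placed parallel to the first at increasing axis
    separations until there is no heavy-atom clash (< 2.5 Å) while the 10 Å
    interface still holds at least `interface_target` residues in total.
    """
    if receptor_len < 20 or ligand_len < 20:
        raise ValueError("toy dimer chains must have >= 20 residues")
    chain_a = make_toy_monomer(receptor_len, seed=seed, chain_id="A")
    chain_b = make_toy_monomer(ligand_len, seed=seed + 1, chain_id="B")
    # center the shorter helix against the longer along z
    dz = _HELIX_RISE * (receptor_len - ligand_len) / 2.0
    from scipy.spatial import cKDTree

    a_coords = chain_a.heavy_coords()
    for dx in np.arange(9.4, 14.0, 0.4):
        shifted = ChainStructure(
            "B",
            [
                Residue(
                    r.res_seq,
                    r.res_name,
                    [
                        AtomRecord(a.atom_name, a.element, a.coords + np.array([dx, 0.0, dz]))
                        for a in r.atoms
                    ],
                )
                for r in chain_b.residues
            ],
        )
        min_dist = cKDTree(a_coords).query(shifted.heavy_coords(), k=1)[0].min()
        if min_dist < 2.5:
            continue
        dimer = assign_roles(chain_a, shifted, label=label)
        if interface_residues(dimer).total >= interface_target:
            return dimer
        break
    raise RuntimeError("could not build a clash-free dimer with the target interface")


def synth_energy_features(
    cls: str, n: int, config: SynthConfig = SynthConfig(), seed: int = 0
) -> pd.DataFrame:
    """Class-conditional energy-feature draws with calibrated medians.

    Each term is an asymmetric two-sided exponential around the configured
    class median: a fair coin picks the side, then an exponential deviate
    with side-specific scale is subtracted/added, so the population median
    equals the configured value exactly.
    """
    if cls not in ("interacting", "non_interacting"):
        raise ValueError(f"unknown class {cls!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = 0 if cls == "interacting" else 1
    rng = np.random.default_rng(seed)
    data = {}
    for col in FEATURE_COLUMNS:
        median = config.feature_medians[col][idx]
        side = rng.random(n) < 0.5
        dev = np.where(
            side,
            -rng.exponential(config.feature_scale_left, n),
            rng.exponential(config.feature_scale_right, n),
        )
        data[col] = median + dev
    df = pd.DataFrame(data)
    df.insert(0, "model_rank", 1)
    df.insert(0, "pair_id", [f"{cls}_{i:06d}" for i in range(n)])
    df["label"] = 1 if cls == "interacting" else 0
    return df


def _dominant_term_prob(target_collision: float, n_terms: int) -> float:
    """Probability mass of the dominant term so that two independent draws
    collide with the target probability (the rest uniform over n_terms)."""
    # p0^2 + (1 - p0)^2 / m = target  ->  quadratic in p0
    m = n_terms
    a = 1.0 + 1.0 / m
    b = -2.0 / m
    c = 1.0 / m - target_collision
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("co-annotation target not reachable with this term count")
    p0 = (-b + math.sqrt(disc)) / (2 * a)
    return min(max(p0, 0.0), 1.0)


def synth_annotations(
    protein_ids: list[str],
    interacting_pairs: list[tuple[str, str]],
    config: SynthConfig = SynthConfig(),
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Synthetic GO-slim rows (protein_id, aspect, term_id).

    Each protein draws one slim term per aspect from a skewed term
    distribution whose two-draw collision probability equals the configured
    random-pair pass rate; designated interacting pairs are then re-drawn to
    share (or to differ, when the interacting rate is below the random rate)
    with the probability that yields the configured interacting pass rate.
    Per-aspect coverage controls the fraction of proteins annotated at all.
    """
    if len(set(protein_ids)) != len(protein_ids):
        raise ValueError("protein ids must be unique")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    aspect_cfg = {
        "CC": (config.cc_pass_rates, config.cc_coverage),
        "BP": (config.bp_pass_rates, config.bp_coverage),
        "MF": (config.mf_pass_rates, config.mf_coverage),
    }
    for aspect, ((rate_pos, rate_neg), coverage) in aspect_cfg.items():
        m = config.n_go_terms
        p0 = _dominant_term_prob(rate_neg, m)
        terms = [f"{aspect}:slim{t:02d}" for t in range(m + 1)]
        probs = np.array([p0] + [(1.0 - p0) / m] * m)

        assigned: dict[str, str | None] = {}
        for pid in protein_ids:
            if rng.random() >= coverage:
                assigned[pid] = None
            else:
                assigned[pid] = terms[rng.choice(len(terms), p=probs)]

        if rate_pos >= rate_neg:
            q = 0.0 if rate_neg == 1.0 else (rate_pos - rate_neg) / (1.0 - rate_neg)
            for a, b in interacting_pairs:
                if assigned.get(a) and assigned.get(b) and rng.random() < q:
                    assigned[b] = assigned[a]
        else:
            q = (rate_neg - rate_pos) / rate_neg
            for a, b in interacting_pairs:
                if assigned.get(a) and assigned.get(b) and rng.random() < q:
                    others = [t for t in terms if t != assigned[a]]
                    assigned[b] = others[rng.integers(len(others))]

        for pid in protein_ids:
            if assigned[pid] is not None:
                rows.append((pid, aspect, assigned[pid]))
    return rows


#: perturbation schedule for scenario decoy sets: exact native through far-off
DECOY_SCHEDULE = [(0.0, 0.0), (5.0, 1.0), (10.0, 3.0), (20.0, 6.0), (45.0, 12.0), (90.0, 25.0)]


def build_scenario(config: SynthConfig, outdir) -> dict:
    """Write a miniature end-to-end experiment directory and return its manifest.

    Layout: structures/ (monomer PDBs), decoys/<pair>/ (decoy PDBs + index
    TSV), features.tsv (labeled class-conditional energy features for every
    candidate pair x model rank), annotations.tsv, reference_edges.tsv (the
    planted interactions) and manifest.yaml with the ground truth.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(config.seed)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)

    lo, hi = config.length_range
    ids = [f"P{i:03d}" for i in range(config.n_proteins)]
    lengths = {pid: int(rng.integers(lo, hi + 1)) for pid in ids}
    for pid in ids:
        chain = make_toy_monomer(lengths[pid], seed=config.seed * 1000 + int(pid[1:]))
        write_pdb([chain], outdir / "structures" / f"{pid}.pdb")

    all_pairs = list(iter_pairs(ids))
    true_idx = rng.choice(len(all_pairs), size=config.n_true_pairs, replace=False)
    true_pairs = sorted(all_pairs[i] for i in sorted(true_idx))

    # decoy sets with known quality for a subset of the planted pairs
    decoy_quality: dict[str, list[float]] = {}
    for a, b in true_pairs[: config.n_decoy_pairs]:
        pair_seed = config.seed * 100 + int(a[1:]) + int(b[1:])
        native = make_toy_dimer(
            lengths[a], lengths[b], seed=pair_seed, label=f"{a}-{b}",
            interface_target=config.interface_target,
        )
        decoys = generate_decoy_set(
            native, n=config.n_decoys, magnitude_schedule=DECOY_SCHEDULE, seed=pair_seed
        )
        pair_dir = outdir / "decoys" / f"{a}-{b}"
        write_decoy_set(decoys, pair_dir)
        write_pdb([native.receptor, native.ligand], pair_dir / "native.pdb")
        decoy_quality[f"{a}-{b}"] = [
            round(irmsd(d, native), 4) for _, d in decoys
        ]

    # labeled energy features: models_per_pair rows per candidate pair
    true_set = set(true_pairs)
    frames = []
    for a, b in all_pairs:
        cls = "interacting" if (a, b) in true_set else "non_interacting"
        block = synth_energy_features(
            cls,
            config.models_per_pair,
            config,
            seed=int(rng.integers(2**31)),
        )
        block["pair_id"] = f"{a}-{b}"
        block["model_rank"] = range(1, config.models_per_pair + 1)
        frames.append(block)
    features = pd.concat(frames, ignore_index=True)
    write_feature_table(features, outdir / "features.tsv")

    rows = synth_annotations(ids, true_pairs, config, seed=config.seed + 7)
    (outdir / "annotations.tsv").write_text(
        "\n".join("\t".join(r) for r in rows) + "\n"
    )

    (outdir / "reference_edges.tsv").write_text(
        "protein_a\tprotein_b\n"
        + "\n".join(f"{a}\t{b}" for a, b in true_pairs)
        + "\n"
    )

    manifest = {
        "seed": config.seed,
        "n_proteins": config.n_proteins,
        "protein_lengths": {k: lengths[k] for k in sorted(lengths)},
        "true_pairs": [list(p) for p in true_pairs],
        "decoy_irmsd": {k: decoy_quality[k] for k in sorted(decoy_quality)},
        "models_per_pair": config.models_per_pair,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
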