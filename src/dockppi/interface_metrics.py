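"""Interface extraction and dimer-model quality metrics.

Interface residues follow the 10 Å any-heavy-atom rule: a residue is
interfacial if at least one of its heavy atoms lies within the cutoff of any
heavy atom of the partner chain. iRMSD is the interfacial Cα RMSD between
ligands after superposing receptors; PCS scores the overlap of model and
reference residue-residue contact maps with the Matthews correlation
coefficient (MCC). Docking success is judged against iRMSD/PCS acceptance
criteria (2.5 Å / 0.65 for experimental references, 8.5 Å / 0.30 for modeled
ones), and unsuccessful targets split into scoring failures (a good pose
exists in the sampled pool but is not ranked in the top k) and sampling
failures (no good pose anywhere in the pool).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from dockppi.geometry import superpose, rmsd
from dockppi.structio import DimerStructure

__all__ = [
    "InterfaceSet",
    "ContactMap",
    "ConfusionCounts",
    "ClassificationMetrics",
    "AcceptanceCriteria",
    "CRYSTAL_CRITERIA",
    "MODEL_CRITERIA",
    "SpectrumPoint",
    "interface_residues",
    "contact_map",
    "irmsd",
    "pcs",
    "interface_overlap_mcc",
    "classify_metrics",
    "success_rate",
    "failure_spectrum",
]


@dataclass(frozen=True)
class InterfaceSet:
    receptor_residues: frozenset[int]
    ligand_residues: frozenset[int]
    cutoff: float

    @property
    def total(self) -> int:
        return len(self.receptor_residues) + len(self.ligand_residues)


@dataclass(frozen=True)
class ContactMap:
    contacts: frozenset[tuple[int, int]]  # (receptor res_seq, ligand res_seq)
    n_receptor: int
    n_ligand: int
    cutoff: float

    @property
    def universe_size(self) -> int:
        return self.n_receptor * self.n_ligand


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class ClassificationMetrics:
    TPR: float
    FPR: float
    ACC: float
    MCC: float


@dataclass(frozen=True)
class AcceptanceCriteria:
    """Model-correctness thresholds: iRMSD <= irmsd_max AND PCS >= pcs_min."""

    irmsd_max: float
    pcs_min: float
    source_kind: str = "crystal"  # crystal | model

    def __post_init__(self) -> None:
        if self.irmsd_max <= 0 or not (0 < self.pcs_min <= 1):
            raise ValueError("invalid acceptance criteria")

    def accepts(self, irmsd_value: float, pcs_value: float) -> bool:
        return irmsd_value <= self.irmsd_max and pcs_value >= self.pcs_min


#: acceptance criteria for references that are experimental structures
CRYSTAL_CRITERIA = AcceptanceCriteria(irmsd_max=2.5, pcs_min=0.65, source_kind="crystal")
#: relaxed criteria for computer-generated reference models
MODEL_CRITERIA = AcceptanceCriteria(irmsd_max=8.5, pcs_min=0.30, source_kind="model")


@dataclass(frozen=True)
class SpectrumPoint:
    quality_threshold: float
    success_fraction: float
    scoring_failure_fraction: float
    sampling_failure_fraction: float

    def __post_init__(self) -> None:
        s = (
            self.success_fraction
            + self.scoring_failure_fraction
            + self.sampling_failure_fraction
        )
        if abs(s - 1.0) > 1e-12:
            raise ValueError("spectrum fractions must sum to 1")


# ---------------------------------------------------------------------------
# interface / contact extraction


def interface_residues(dimer: DimerStructure, cutoff: float = 10.0) -> InterfaceSet:
    """Residues of each chain with any heavy atom within `cutoff` of the partner.

    KD-tree accelerated; results identical to the brute-force all-pair scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rc = dimer.receptor.heavy_coords()
    lc = dimer.ligand.heavy_coords()
    pairs = cKDTree(rc).query_ball_tree(cKDTree(lc), r=cutoff)
    r_owner = dimer.receptor.residue_of_atom()
    l_owner = dimer.ligand.residue_of_atom()
    r_hit: set[int] = set()
    l_hit: set[int] = set()
    for i, neighbours in enumerate(pairs):
        if neighbours:
            r_hit.add(int(r_owner[i]))
            l_hit.update(int(l_owner[j]) for j in neighbours)
    return InterfaceSet(
        receptor_residues=frozenset(
            dimer.receptor.residues[i].res_seq for i in r_hit
        ),
        ligand_residues=frozenset(dimer.ligand.residues[i].res_seq for i in l_hit),
        cutoff=cutoff,
    )


def contact_map(dimer: DimerStructure, cutoff: float = 5.0) -> ContactMap:
    """Residue-pair contacts: any heavy-atom pair within `cutoff` Angstroms."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rc = dimer.receptor.heavy_coords()
    lc = dimer.ligand.heavy_coords()
    pairs = cKDTree(rc).query_ball_tree(cKDTree(lc), r=cutoff)
    r_owner = dimer.receptor.residue_of_atom()
    l_owner = dimer.ligand.residue_of_atom()
    contacts: set[tuple[int, int]] = set()
    for i, neighbours in enumerate(pairs):
        ri = dimer.receptor.residues[int(r_owner[i])].res_seq
        for j in neighbours:
            contacts.add((ri, dimer.ligand.residues[int(l_owner[j])].res_seq))
    return ContactMap(
        contacts=frozenset(contacts),
        n_receptor=len(dimer.receptor),
        n_ligand=len(dimer.ligand),
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# quality metrics


def _matched_ca(chain_model, chain_ref, res_seqs=None):
    """Paired Cα coordinate arrays for residues shared by model and reference."""
    model_map = {r.res_seq: r for r in chain_model.residues}
    ref_map = {r.res_seq: r for r in chain_ref.residues}
    wanted = sorted(res_seqs) if res_seqs is not None else sorted(ref_map)
    missing = [s for s in wanted if s not in model_map]
    if missing:
        raise ValueError(f"residues missing from model chain: {missing}")
    m, f = [], []
    for s in wanted:
        ca_m = model_map[s].atom("CA")
        ca_f = ref_map[s].atom("CA")
        if ca_m is None or ca_f is None:
            raise ValueError(f"residue {s} lacks a CA atom")
        m.append(ca_m.coords)
        f.append(ca_f.coords)
    return np.array(m), np.array(f)


def irmsd(model: DimerStructure, reference: DimerStructure) -> float:
    """Interfacial Cα RMSD between ligands after receptor superposition.

    The interface is defined on the reference complex (10 Å rule); the metric
    is the Cα RMSD over the reference ligand's interface residues after the
    optimal superposition of model receptor onto reference receptor.
    """
    iface = interface_residues(reference, cutoff=10.0)
    if not iface.ligand_residues:
        raise ValueError("reference complex has an empty interface")
    rec_m, rec_f = _matched_ca(model.receptor, reference.receptor)
    transform, _ = superpose(rec_m, rec_f)
    lig_m, lig_f = _matched_ca(
        model.ligand, reference.ligand, res_seqs=iface.ligand_residues
    )
    return rmsd(transform.apply(lig_m), lig_f)


def pcs(
    model: DimerStructure, reference: DimerStructure, contact_cutoff: float = 5.0
) -> float:
    """Pairwise Contact Score: MCC between model and reference contact maps.

    Predicted positives are the model's residue-pair contacts, actual
    positives the reference's, over the full receptor x ligand pair universe.
    Ranges from about 0 (random) to 1 (perfect overlap).
    """
    ref_cm = contact_map(reference, cutoff=contact_cutoff)
    if not ref_cm.contacts:
        raise ValueError("reference complex has no contacts at this cutoff")
    mod_cm = contact_map(model, cutoff=contact_cutoff)
    universe = ref_cm.universe_size
    tp = len(mod_cm.contacts & ref_cm.contacts)
    fp = len(mod_cm.contacts - ref_cm.contacts)
    fn = len(ref_cm.contacts - mod_cm.contacts)
    tn = universe - tp - fp - fn
    return classify_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)).MCC


def interface_overlap_mcc(a: DimerStructure, b: DimerStructure) -> float:
    """MCC of per-residue interface membership between two dimers.

    Chains are paired by sequence position (receptor with receptor, ligand
    with ligand); the universe is all residue positions of both chains.
    Used for interface-redundancy removal (threshold 0.5).
    """
    if len(a.receptor) != len(b.receptor) or len(a.ligand) != len(b.ligand):
        raise ValueError("dimers are not pairable: chain lengths differ")
    ia = interface_residues(a)
    ib = interface_residues(b)

    def membership(dimer: DimerStructure, iface: InterfaceSet) -> list[bool]:
        out = [r.res_seq in iface.receptor_residues for r in dimer.receptor.residues]
        out += [r.res_seq in iface.ligand_residues for r in dimer.ligand.residues]
        return out

    ma = membership(a, ia)
    mb = membership(b, ib)
    tp = sum(x and y for x, y in zip(ma, mb))
    fp = sum(x and not y for x, y in zip(ma, mb))
    fn = sum(y and not x for x, y in zip(ma, mb))
    tn = len(ma) - tp - fp - fn
    return classify_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)).MCC


def classify_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """TPR, FPR, ACC and MCC from a confusion matrix.

    MCC uses the standard denominator √((TP+FP)(TP+FN)(TN+FP)(TN+FN)) and is
    defined as 0 when any factor vanishes.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    acc = (tp + tn) / c.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return ClassificationMetrics(TPR=tpr, FPR=fpr, ACC=acc, MCC=mcc)


# ---------------------------------------------------------------------------
# success rates and the sampling/scoring failure spectrum

#: one docking target: ranked candidate models plus the reference complex
RankedTarget = tuple[Sequence[DimerStructure], DimerStructure]


def success_rate(
    ranked_decoy_sets: Sequence[RankedTarget],
    criteria: AcceptanceCriteria,
    top_k: int = 10,
) -> float:
    """Fraction of targets with >= 1 correct model ranked within the top k.

    A model is correct when iRMSD <= criteria.irmsd_max and
    PCS >= criteria.pcs_min against the target's reference.
    """
    if not ranked_decoy_sets:
        raise ValueError("no targets provided")
    hits = 0
    for models, reference in ranked_decoy_sets:
        if not models:
            raise ValueError("target with no ranked models")
        for model in list(models)[:top_k]:
            if criteria.accepts(irmsd(model, reference), pcs(model, reference)):
                hits += 1
                break
    return hits / len(ranked_decoy_sets)


def failure_spectrum(
    ranked_decoy_sets: Sequence[RankedTarget],
    quality_fn: Callable[[DimerStructure, DimerStructure], float],
    thresholds: Sequence[float],
    top_k: int = 10,
    pool_k: int = 2000,
) -> list[SpectrumPoint]:
    """Success / scoring-failure / sampling-failure fractions per threshold.

    `quality_fn(model, reference)` must return a score where higher is
    better. At threshold t a target is a success if some top-k model scores
    >= t, a scoring failure if a model scoring >= t exists in the pool (first
    `pool_k` models) but not in the top k, and a sampling failure otherwise.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("no thresholds provided")
    if not ranked_decoy_sets:
        raise ValueError("no targets provided")
    per_target: list[tuple[float, float]] = []  # (best in top_k, best in pool)
    for models, reference in ranked_decoy_sets:
        pool = list(models)[:pool_k]
        if not pool:
            raise ValueError("target with no ranked models")
        scores = [quality_fn(m, reference) for m in pool]
        per_target.append((max(scores[:top_k]), max(scores)))

    n = len(per_target)
    points = []
    for t in thresholds:
        succ = sum(best_top >= t for best_top, _ in per_target)
        scoring = sum(
            best_top < t <= best_pool for best_top, best_pool in per_target
        )
        sampling = n - succ - scoring
        points.append(
            SpectrumPoint(
                quality_threshold=float(t),
                success_fraction=succ / n,
                scoring_failure_fraction=scoring / n,
                sampling_failure_fraction=sampling / n,
            )
        )
    return points


def write_spectrum_tsv(points: Sequence[SpectrumPoint], path) -> None:
    """Spectrum table: threshold and the three fractions, tab-separated."""
    lines = ["threshold\tsuccess\tscoring_failure\tsampling_failure"]
    for p in points:
        lines.append(
            f"{p.quality_threshold:g}\t{p.success_fraction:g}"
            f"\t{p.scoring_failure_fraction:g}\t{p.sampling_failure_fraction:g}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
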