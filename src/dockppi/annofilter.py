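"""GO-slim annotation loading and co-annotation filters.

Predicted interactions are filtered by Gene Ontology slim terms in the three
aspects — cellular component (CC), biological process (BP) and molecular
function (MF). A pair passes an aspect when the two proteins share at least
one slim term; pairs with an unannotated member are a distinct outcome whose
fate is set by policy (default: drop). The default cascade applies CC then
BP; MF is implemented but excluded by default because it does not
discriminate interacting from non-interacting pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "ASPECTS",
    "GOAnnotation",
    "load_annotations",
    "shares_term",
    "apply_filter_cascade",
]

ASPECTS = ("CC", "BP", "MF")


@dataclass
class GOAnnotation:
    protein_id: str
    cc_terms: set[str] = field(default_factory=set)
    bp_terms: set[str] = field(default_factory=set)
    mf_terms: set[str] = field(default_factory=set)

    def terms(self, aspect: str) -> set[str]:
        if aspect == "CC":
            return self.cc_terms
        if aspect == "BP":
            return self.bp_terms
        if aspect == "MF":
            return self.mf_terms
        raise ValueError(f"unknown GO aspect {aspect!r}")


def load_annotations(path) -> dict[str, GOAnnotation]:
    """Read a flat TSV mapping: protein_id <tab> aspect <tab> term_id.

    Lines are aggregated per protein; blank lines and #-comments skipped.
    """
    annotations: dict[str, GOAnnotation] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3 or not all(f.strip() for f in fields):
            raise ValueError(f"line {lineno}: expected protein_id<TAB>aspect<TAB>term_id")
        protein_id, aspect, term = (f.strip() for f in fields)
        if aspect not in ASPECTS:
            raise ValueError(f"line {lineno}: unknown GO aspect {aspect!r}")
        ann = annotations.setdefault(protein_id, GOAnnotation(protein_id))
        ann.terms(aspect).add(term)
    return annotations


def shares_term(a: GOAnnotation, b: GOAnnotation, aspect: str) -> Optional[bool]:
    """True/False for shared/disjoint non-empty term sets; None when either
    side has no annotation in this aspect ('unannotated' outcome)."""
    ta, tb = a.terms(aspect), b.terms(aspect)
    if not ta or not tb:
        return None
    return bool(ta & tb)


def apply_filter_cascade(
    pairs: Sequence[tuple[str, str]],
    annotations: dict[str, GOAnnotation],
    cascade: Sequence[str] = ("CC", "BP"),
    unannotated_policy: str = "drop",
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Sequentially filter pairs by shared GO-slim terms per aspect.

    `unannotated_policy` is 'drop' (a pair with an unannotated member fails
    the stage; default) or 'keep' (it passes untested). Proteins missing
    from the annotation map count as unannotated. Returns the retained
    pairs and per-stage count records (aspect, input, passed, failed,
    unannotated).
    """
    if unannotated_policy not in ("drop", "keep"):
        raise ValueError("unannotated_policy must be 'drop' or 'keep'")
    for aspect in cascade:
        if aspect not in ASPECTS:
            raise ValueError(f"unknown GO aspect {aspect!r}")
    empty = GOAnnotation("")
    current = list(pairs)
    stages: list[dict] = []
    for aspect in cascade:
        passed: list[tuple[str, str]] = []
        n_fail = n_unann = 0
        for a, b in current:
            outcome = shares_term(
                annotations.get(a, empty), annotations.get(b, empty), aspect
            )
            if outcome is None:
                n_unann += 1
                if unannotated_policy == "keep":
                    passed.append((a, b))
            elif outcome:
                passed.append((a, b))
            else:
                n_fail += 1
        stages.append(
            {
                "aspect": aspect,
                "input": len(current),
                "passed": len(passed),
                "failed": n_fail,
                "unannotated": n_unann,
            }
        )
        current = passed
    return current, stages
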