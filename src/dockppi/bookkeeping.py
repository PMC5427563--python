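"""Pair-enumeration bookkeeping for across-proteome docking campaigns.

All-against-all docking of a proteome of N proteins considers every
unordered distinct pair (N choose 2) — e.g. 2,300 proteins give 2,643,850
candidate PPIs — and each pair carries a fixed number of retained dimer
models. Pathway-scale analyses that allow homodimers count self-pairs too:
N(N+1)/2.
"""

from __future__ import annotations

from itertools import combinations, combinations_with_replacement
from typing import Iterable, Iterator

__all__ = ["candidate_pair_count", "model_count", "iter_pairs"]


def candidate_pair_count(n_proteins: int, include_self: bool = False) -> int:
    """Number of unordered protein pairs; with `include_self`, homodimer
    self-pairs are counted as well."""
    if n_proteins < 0:
        raise ValueError("n_proteins must be non-negative")
    pairs = n_proteins * (n_proteins - 1) // 2
    return pairs + n_proteins if include_self else pairs


def model_count(n_pairs: int, models_per_pair: int = 3) -> int:
    """Total dimer models retained across a campaign (default 3 per pair)."""
    if n_pairs < 0 or models_per_pair < 1:
        raise ValueError("invalid pair or model count")
    return n_pairs * models_per_pair


def iter_pairs(ids: Iterable[str], include_self: bool = False) -> Iterator[tuple[str, str]]:
    """Deterministic enumeration of unordered pairs in sorted id order."""
    ordered = sorted(ids)
    gen = combinations_with_replacement if include_self else combinations
    yield from gen(ordered, 2)
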