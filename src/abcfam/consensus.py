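"""Consensus-pattern derivation and information content for motif blocks.

Given an aligned block of equal-length motif subsequences (e.g. all Walker
A matches of a cohort, which share a fixed span by construction), this
module computes per-column residue profiles, WebLogo-style information
content, and a generalized extended-PROSITE pattern.

Generalization rule, per column with observed residue set S:

* |S| = 1            → exact element;
* otherwise, if the number of residues at frequency >= ``freq_floor``
  is at most ``class_threshold`` → bracket class over *all* of S;
* otherwise            → wildcard.

Classes always include every observed residue, so a derived pattern
matches 100% of the rows it was derived from (rare residues never drop
out of a class; they only stop counting toward the class-size test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patterns import (
    AMINO_ACIDS,
    CLASS,
    EXACT,
    WILDCARD,
    MotifPattern,
    PositionElement,
)

LOG2_20 = math.log2(20.0)


@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts of one alignment column."""

    counts: dict
    depth: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.depth:
            raise ValueError("counts must sum to depth")

    @property
    def frequencies(self) -> dict:
        return {r: c / self.depth for r, c in self.counts.items()}


def column_profiles(block: list[str]) -> list[ColumnProfile]:
    """One profile per column of a rectangular block."""
    if not block:
        return []
    widths = {len(row) for row in block}
    if len(widths) > 1:
        raise ValueError(f"ragged block: row lengths {sorted(widths)}")
    bad = set("".join(block)) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-standard letters in block: {sorted(bad)}")
    width = widths.pop()
    depth = len(block)
    profiles = []
    for j in range(width):
        counts: dict[str, int] = {}
        for row in block:
            counts[row[j]] = counts.get(row[j], 0) + 1
        profiles.append(ColumnProfile(counts, depth))
    return profiles


def information_content(profile: ColumnProfile, pseudocount: float = 0.0) -> float:
    """Column information content in bits: log2(20) − Shannon entropy.

    With ``pseudocount`` > 0 every residue receives that many extra
    counts before normalization (no small-sample correction beyond that).
    """
    if profile.depth < 1:
        raise ValueError("profile depth must be >= 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount > 0:
        total = profile.depth + 20 * pseudocount
        freqs = [
            (profile.counts.get(r, 0) + pseudocount) / total for r in AMINO_ACIDS
        ]
    else:
        freqs = [c / profile.depth for c in profile.counts.values()]
    entropy = -sum(p * math.log2(p) for p in freqs if p > 0)
    return LOG2_20 - entropy


def derive_consensus(
    block: list[str],
    class_threshold: int = 10,
    freq_floor: float = 0.05,
) -> MotifPattern:
    """Generalized extended-PROSITE pattern for an aligned block."""
    if not block:
        raise ValueError("cannot derive a consensus from an empty block")
    elements = []
    for profile in column_profiles(block):
        observed = frozenset(profile.counts)
        n_major = sum(1 for f in profile.frequencies.values() if f >= freq_floor)
        if len(observed) == 1:
            elements.append(PositionElement(EXACT, observed))
        elif n_major <= class_threshold and observed < AMINO_ACIDS:
            elements.append(PositionElement(CLASS, observed))
        else:
            elements.append(PositionElement(WILDCARD, frozenset()))
    pattern = MotifPattern(tuple(elements), source_text="", name=None)
    return MotifPattern(tuple(elements), source_text=pattern.render(), name=None)


def consensus_report(
    block: list[str],
    class_threshold: int = 10,
    freq_floor: float = 0.05,
    pseudocount: float = 0.0,
) -> tuple[MotifPattern, pd.DataFrame]:
    """Derived pattern plus a per-column information-content table."""
    pattern = derive_consensus(block, class_threshold, freq_floor)
    profiles = column_profiles(block)
    table = pd.DataFrame(
        {
            "column": np.arange(1, len(profiles) + 1),
            "information_bits": [
                information_content(p, pseudocount) for p in profiles
            ],
            "n_residues": [len(p.counts) for p in profiles],
        }
    )
    return pattern, table
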