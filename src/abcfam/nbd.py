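"""Nucleotide-binding domain (NBD) detection in ABC transporter proteins.

An NBD is located as an ordered Walker A → ATP-binding (C-loop) → Walker B
motif triplet subject to spacing constraints, assembled greedily from the
N-terminus. Detected NBDs are indexed by chain position (the first NBD
along the chain is index 1) and can be assigned a sequence class from the
residues at a small set of diagnostic motif positions.

The exact residue-to-class mapping is biological prior knowledge rather
than something the detection algorithm can derive, so the shipped default
:data:`DEFAULT_CLASS_RULE` is an editable heuristic: Class1 groups the
sterol/retinoid-style families (Protein White, Rim protein), Class2 the
translation-regulating Uup family, Class3 the efflux families (MRP, CFTR,
MDR, MdlB, ATM1, 3a0123).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .patterns import DEFAULT_HYDROPHOBIC, MotifMatch, MotifPattern, default_patterns, min_span, scan

UNASSIGNED = "unassigned"


def nbd_patterns(hydrophobic: frozenset = DEFAULT_HYDROPHOBIC) -> dict[str, MotifPattern]:
    """The three generalized NBD patterns keyed by triplet role."""
    shipped = default_patterns(hydrophobic)
    return {
        "walker_a": shipped["walker_a"],
        "c_loop": shipped["atp_binding"],
        "walker_b": shipped["walker_b"],
    }

MOTIF_NAMES = ("walker_a", "c_loop", "walker_b")


@dataclass(frozen=True)
class SpacingConfig:
    """Allowed gaps between NBD motifs, in residues.

    ``cloop_gap`` bounds ``c_loop.start − walker_a.end`` and
    ``walker_b_gap`` bounds ``walker_b.start − c_loop.end``. Defaults
    reflect typical ABC NBD geometry and keep false assemblies rare.
    """

    cloop_gap: tuple[int, int] = (30, 200)
    walker_b_gap: tuple[int, int] = (5, 80)


@dataclass(frozen=True)
class NbdHit:
    walker_a: MotifMatch
    c_loop: MotifMatch
    walker_b: MotifMatch
    position_index: int
    class_label: str = UNASSIGNED

    def __post_init__(self):
        if not (self.walker_a.start < self.c_loop.start < self.walker_b.start):
            raise ValueError("NBD motifs must appear in Walker A, C-loop, Walker B order")
        if self.position_index < 1:
            raise ValueError("position_index is 1-based")

    def motif(self, name: str) -> MotifMatch:
        if name not in MOTIF_NAMES:
            raise KeyError(f"unknown motif name {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class NbdClassRule:
    """Diagnostic-position class rule with nearest-exemplar fallback.

    ``diagnostic_positions`` are (motif_name, 1-based element index) pairs;
    ``residue_table`` maps the concatenated diagnostic residues to a class
    label. A string absent from the table falls back to the Hamming-nearest
    table entry; ties across different labels yield ``unassigned``.
    """

    diagnostic_positions: tuple
    residue_table: Mapping[str, str]

    def diagnostic_string(self, hit: NbdHit) -> str:
        chars = []
        for motif_name, index in self.diagnostic_positions:
            sub = hit.motif(motif_name).matched_subsequence
            if not (1 <= index <= len(sub)):
                raise IndexError(
                    f"diagnostic index {index} out of range for motif "
                    f"{motif_name!r} of span {len(sub)}"
                )
            chars.append(sub[index - 1])
        return "".join(chars)


DEFAULT_CLASS_RULE = NbdClassRule(
    diagnostic_positions=(
        ("walker_a", 8),
        ("c_loop", 6),
        ("c_loop", 8),
        ("c_loop", 12),
    ),
    residue_table={
        "SQRC": "Class1",  # Protein White / Rim protein style NBDs
        "TEKG": "Class2",  # Uup (translation regulation) style NBDs
        "SDLT": "Class3",  # efflux families (MRP/CFTR/MDR/MdlB/ATM1/3a0123)
    },
)


def find_nbds(
    sequence: str,
    patterns: Mapping[str, MotifPattern],
    spacing: SpacingConfig = SpacingConfig(),
    unknown: str = "reject",
) -> list[NbdHit]:
    """Greedy left-to-right assembly of non-overlapping NBD triplets.

    For each unconsumed Walker A match (in chain order) the earliest
    compatible C-loop and then the earliest compatible Walker B are taken;
    incomplete triplets are dropped. Returns hits with sequential
    ``position_index`` and class ``unassigned``.
    """
    for name in MOTIF_NAMES:
        if name not in patterns:
            raise KeyError(f"patterns mapping must provide {name!r}")
    a_matches = scan(sequence, patterns["walker_a"], unknown=unknown)
    c_matches = scan(sequence, patterns["c_loop"], unknown=unknown)
    b_matches = scan(sequence, patterns["walker_b"], unknown=unknown)

    hits: list[NbdHit] = []
    cursor = 0  # last residue consumed by an accepted triplet
    for a in a_matches:
        if a.start <= cursor:
            continue
        c = next(
            (
                m
                for m in c_matches
                if spacing.cloop_gap[0] <= m.start - a.end <= spacing.cloop_gap[1]
            ),
            None,
        )
        if c is None:
            continue
        b = next(
            (
                m
                for m in b_matches
                if spacing.walker_b_gap[0]
                <= m.start - c.end
                <= spacing.walker_b_gap[1]
            ),
            None,
        )
        if b is None:
            continue
        hits.append(NbdHit(a, c, b, position_index=len(hits) + 1))
        cursor = b.end
    return hits


def classify_nbd(hit: NbdHit, rule: NbdClassRule = DEFAULT_CLASS_RULE) -> str:
    """Class label for one NBD: table lookup, then nearest exemplar.

    The fallback uses Hamming distance over the diagnostic string; a tie
    between exemplars of different classes yields ``unassigned``.
    """
    key = rule.diagnostic_string(hit)
    table = rule.residue_table
    if key in table:
        return table[key]
    best_d = None
    best_labels: set[str] = set()
    for exemplar, label in table.items():
        if len(exemplar) != len(key):
            raise ValueError("exemplar length disagrees with diagnostic positions")
        d = sum(1 for a, b in zip(key, exemplar) if a != b)
        if best_d is None or d < best_d:
            best_d, best_labels = d, {label}
        elif d == best_d:
            best_labels.add(label)
    if len(best_labels) == 1:
        return next(iter(best_labels))
    return UNASSIGNED


def classify_all(
    hits: Iterable[NbdHit], rule: NbdClassRule = DEFAULT_CLASS_RULE
) -> list[NbdHit]:
    return [dataclasses.replace(h, class_label=classify_nbd(h, rule)) for h in hits]


def extract_motif_block(
    hits_by_protein: Mapping[str, Sequence[NbdHit]], motif_name: str
) -> list[str]:
    """Aligned block of equal-length motif subsequences.

    Rows are ordered by (protein id, NBD position index). All rows must
    come from the same fixed-span pattern; mixed spans raise.
    """
    rows: list[str] = []
    for protein_id in sorted(hits_by_protein):
        for hit in sorted(hits_by_protein[protein_id], key=lambda h: h.position_index):
            rows.append(hit.motif(motif_name).matched_subsequence)
    spans = {len(r) for r in rows}
    if len(spans) > 1:
        raise ValueError(f"mixed motif spans in block: {sorted(spans)}")
    return rows


def hits_to_frame(hits_by_protein: Mapping[str, Sequence[NbdHit]]) -> pd.DataFrame:
    """Flat TSV-ready table of NBD hits across a protein cohort."""
    records = []
    for protein_id in sorted(hits_by_protein):
        for h in hits_by_protein[protein_id]:
            records.append(
                {
                    "protein_id": protein_id,
                    "nbd_index": h.position_index,
                    "walkerA_start": h.walker_a.start,
                    "walkerA_end": h.walker_a.end,
                    "cloop_start": h.c_loop.start,
                    "cloop_end": h.c_loop.end,
                    "walkerB_start": h.walker_b.start,
                    "walkerB_end": h.walker_b.end,
                    "class": h.class_label,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "protein_id",
            "nbd_index",
            "walkerA_start",
            "walkerA_end",
            "cloop_start",
            "cloop_end",
            "walkerB_start",
            "walkerB_end",
            "class",
        ],
    )
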