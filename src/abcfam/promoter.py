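"""Promoter cis-regulatory element census over 1000-bp upstream regions.

Named motifs are given as IUPAC consensus strings (SCPD-style). The census
counts every (possibly overlapping) occurrence of every motif in each
promoter, optionally on both strands, and rolls up stress-related subsets
and per-family averages.

The shipped default dictionary (``data/scpd_motifs.tsv``) holds 39 named
yeast-style consensi with the eight stress-response regulators (GCR1,
GCN4, ADR1, STRE, HSTF, PHO4, GC/FAR, ABF1) flagged. The consensus strings
are editable external defaults — the census machinery is agnostic to them.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

DEFAULT_STRESS_NAMES = frozenset(
    {"GCR1", "GCN4", "ADR1", "STRE", "HSTF", "PHO4", "GC/FAR", "ABF1"}
)

_DNA_LETTERS = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def compile_iupac(consensus: str) -> re.Pattern:
    """Overlap-counting matcher for an IUPAC DNA consensus.

    Sequence ``N`` matches only a consensus ``N`` (which accepts
    anything); degenerate consensus letters expand to their IUPAC sets.
    """
    if not consensus:
        raise ValueError("empty consensus")
    parts = []
    for letter in consensus.upper():
        try:
            expansion = ambiguous_dna_values[letter]
        except KeyError:
            raise ValueError(f"illegal IUPAC letter {letter!r} in {consensus!r}") from None
        if letter == "N":
            expansion += "N"
        parts.append("[" + expansion + "]" if len(expansion) > 1 else expansion)
    return re.compile("(?=(" + "".join(parts) + "))")


def count_occurrences(sequence: str, matcher: re.Pattern) -> int:
    return sum(1 for _ in matcher.finditer(sequence))


@dataclass(frozen=True)
class MotifEntry:
    consensus: str
    stress: bool


@dataclass
class MotifDictionary:
    entries: dict

    def __post_init__(self):
        for name, entry in self.entries.items():
            if not entry.consensus:
                raise ValueError(f"motif {name!r} has an empty consensus")
            compile_iupac(entry.consensus)  # validates letters

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    @property
    def stress_names(self) -> list[str]:
        return [n for n, e in self.entries.items() if e.stress]

    def matchers(self) -> dict[str, re.Pattern]:
        return {n: compile_iupac(e.consensus) for n, e in self.entries.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifDictionary":
        entries: dict[str, MotifEntry] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                name, consensus, stress = row[0], row[1], row[2]
                if name in entries:
                    raise ValueError(f"duplicate motif name {name!r}")
                entries[name] = MotifEntry(consensus.strip().upper(), stress.strip() == "1")
        return cls(entries)

    @classmethod
    def default(cls) -> "MotifDictionary":
        path = resources.files("abcfam").joinpath("data/scpd_motifs.tsv")
        return cls.from_tsv(Path(path))


@dataclass
class CensusTable:
    """Per-gene × per-motif occurrence counts with stress rollups."""

    counts: pd.DataFrame  # genes × motif names
    dictionary: MotifDictionary
    both_strands: bool

    @property
    def per_gene_total(self) -> pd.Series:
        return self.counts.sum(axis=1).rename("total_motifs")

    @property
    def per_gene_types(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1).rename("distinct_types")

    @property
    def per_name_total(self) -> pd.Series:
        return self.counts.sum(axis=0).rename("total")

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    @property
    def distinct_types_cohort(self) -> int:
        return int((self.counts.sum(axis=0) > 0).sum())

    @property
    def stress_total(self) -> int:
        stress = [n for n in self.dictionary.stress_names if n in self.counts.columns]
        return int(self.counts[stress].values.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "total_motifs", self.per_gene_total)
        out.insert(1, "distinct_types", self.per_gene_types)
        return out


def _load_promoters(promoters) -> dict:
    if isinstance(promoters, (str, Path)):
        return {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(promoters), "fasta")
        }
    if isinstance(promoters, Mapping):
        return {k: v.upper() for k, v in promoters.items()}
    return {gene_id: seq.upper() for gene_id, seq in promoters}


def census(
    promoters,
    dictionary: MotifDictionary,
    both_strands: bool = False,
    promoter_length: int = 1000,
) -> CensusTable:
    """Count motif occurrences per gene.

    ``promoters`` may be a FASTA path, a mapping id → sequence, or an
    iterable of (id, sequence) pairs. Sequences longer than
    ``promoter_length`` are truncated 3'-anchored (the upstream-proximal
    end is kept) with a warning; non-ACGTN letters raise, naming the
    record.
    """
    seqs = _load_promoters(promoters)
    matchers = dictionary.matchers()
    rows = {}
    for gene_id, seq in seqs.items():
        bad = set(seq) - _DNA_LETTERS
        if bad:
            raise ValueError(
                f"promoter {gene_id!r} contains non-DNA letters {sorted(bad)}"
            )
        if len(seq) > promoter_length:
            warnings.warn(
                f"promoter {gene_id!r} longer than {promoter_length} bp; "
                "keeping the 3'-anchored tail",
                stacklevel=2,
            )
            seq = seq[-promoter_length:]
        rc = reverse_complement(seq) if both_strands else None
        row = {}
        for name, matcher in matchers.items():
            n = count_occurrences(seq, matcher)
            if both_strands:
                n += count_occurrences(rc, matcher)
            row[name] = n
        rows[gene_id] = row
    counts = pd.DataFrame.from_dict(rows, orient="index", dtype="int64")
    counts = counts.reindex(columns=dictionary.names, fill_value=0).sort_index()
    return CensusTable(counts, dictionary, both_strands)


def summarize_by_family(
    table: CensusTable,
    family_map: Mapping[str, str],
    round_to_int: bool = True,
) -> pd.DataFrame:
    """Per-family mean motif counts and mean distinct motif types.

    Every gene in the census must be mapped to a family; means are
    reported rounded to integers by default (the customary display
    precision for these summaries).
    """
    missing = [g for g in table.counts.index if g not in family_map]
    if missing:
        raise KeyError(f"genes missing from family map: {missing}")
    frame = pd.DataFrame(
        {
            "family": [family_map[g] for g in table.counts.index],
            "total_motifs": table.per_gene_total.values,
            "distinct_types": table.per_gene_types.values,
        },
        index=table.counts.index,
    )
    means = frame.groupby("family").mean()
    means.columns = ["mean_motifs", "mean_types"]
    if round_to_int:
        means = means.round(0).astype(int)
    return means
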