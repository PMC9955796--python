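"""Physical descriptors of ABC transporter genes and proteins.

Molecular weight (average residue masses), isoelectric point (bisection on
the Henderson–Hasselbalch net-charge function), acid/base classification,
and intron counting from GFF3 gene models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd

from .patterns import AMINO_ACIDS

#: Average (isotope-abundance-weighted) residue masses, Da. A residue mass
#: is the free amino acid minus one water; a chain therefore weighs the sum
#: of its residue masses plus one water.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: pKa sets for the ionizable groups used by the net-charge function.
#: "expasy" follows the Bjellqvist-style table popularized by ProtParam;
#: "emboss" is the EMBOSS iep default. Editable: pass any mapping with the
#: same keys to :func:`isoelectric_point`.
PKA_SETS: dict[str, dict[str, float]] = {
    "expasy": {
        "Nterm": 7.5, "Cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass
class GeneRecord:
    """One cohort member with its per-gene descriptors."""

    id: str
    family: str
    arrangement: str
    intron_count: int
    pi: float
    mw_kda: float
    structural_type: int | str
    scaffold: str = ""
    full_transporter: bool = False

    def __post_init__(self):
        if self.intron_count < 0:
            raise ValueError("intron_count must be >= 0")
        if not (0 < self.pi < 14):
            raise ValueError("pI must lie in (0, 14)")
        if self.mw_kda <= 0:
            raise ValueError("molecular weight must be positive")


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid amino-acid letters: {sorted(bad)}")


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in daltons (residue masses + one water)."""
    _check_sequence(sequence)
    return sum(RESIDUE_MASSES[a] for a in sequence) + WATER_MASS


def net_charge(sequence: str, ph: float, pka_set: dict[str, float] | str = "expasy") -> float:
    """Henderson–Hasselbalch net charge of the chain at the given pH."""
    _check_sequence(sequence)
    pka = PKA_SETS[pka_set] if isinstance(pka_set, str) else pka_set
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for residue in _POSITIVE:
        n = sequence.count(residue)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka[residue]))
    for residue in _NEGATIVE:
        n = sequence.count(residue)
        if n:
            charge -= n / (1.0 + 10 ** (pka[residue] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka_set: dict[str, float] | str = "expasy",
    tolerance: float = 1e-4,
) -> float:
    """pH of zero net charge, found by bisection on [0, 14].

    The net-charge function is strictly decreasing in pH, so bisection
    always converges; the returned pI satisfies |net_charge(pI)| < 1e-3
    for ordinary sequences.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_pi(pi: float) -> str:
    """Acid/base class: pI > 7 basic, < 7 acidic, exactly 7 neutral."""
    if pi > 7:
        return "basic"
    if pi < 7:
        return "acidic"
    return "neutral"


# ---------------------------------------------------------------------------
# Intron counting from GFF3 gene models
# ---------------------------------------------------------------------------

def load_gff(source: str | Path) -> gffutils.FeatureDB:
    """In-memory gffutils database from a GFF3 file path or text."""
    text = str(source)
    if "\n" not in text and Path(text).exists():
        data, from_string = text, False
    else:
        data, from_string = text, True
    return gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def count_introns(db: gffutils.FeatureDB, gene_id: str) -> int:
    """Intron count of a gene model: exon count − 1.

    Multiple transcripts: the transcript with the largest summed exon
    length is used. A gene without exons raises.
    """
    gene = db[gene_id]
    transcripts = list(db.children(gene, featuretype="mRNA"))
    if transcripts:
        best, best_len = None, -1
        for tr in transcripts:
            exons = list(db.children(tr, featuretype="exon"))
            total = sum(e.end - e.start + 1 for e in exons)
            if total > best_len:
                best, best_len = exons, total
        exons = best or []
    else:
        exons = list(db.children(gene, featuretype="exon"))
    if not exons:
        raise ValueError(f"gene {gene_id!r} has no exons")
    return len(exons) - 1


def intron_table(source: str | Path) -> pd.Series:
    """Per-gene intron counts for every gene feature in a GFF3."""
    db = load_gff(source)
    counts = {g.id: count_introns(db, g.id) for g in db.features_of_type("gene")}
    return pd.Series(counts, name="intron_count").sort_index()
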