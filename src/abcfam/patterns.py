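"""Extended PROSITE-style motif patterns for protein sequences.

The pattern language covers what is needed to express nucleotide-binding
domain (NBD) consensus motifs of ABC transporters:

* single residue letters (``G``) — exact match;
* ``X`` — wildcard, one arbitrary standard residue;
* ``[GA]`` — residue class, any residue listed inside the brackets;
* ``Φ`` — the hydrophobic residue class, usable bare or inside brackets,
  where it expands to the configured hydrophobic set (``[ΦHY]`` is the
  union of the hydrophobic set with H and Y);
* ``(n)`` after any element — fixed repeat, e.g. ``X(3)`` or ``[Φ](4)``;
* hyphens between elements are optional separators (``XX`` ≡ ``X-X``).

Variable-length repeats ``(n,m)`` are recognized by the tokenizer but
rejected: every pattern here has a fixed span, so a match always occupies
exactly ``min_span(pattern)`` residues and overlapping matches are
well-defined and all reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default hydrophobic residue set used to expand Φ. The strongly
#: hydrophobic residues by the classical Kyte–Doolittle-style grouping;
#: configurable wherever patterns are parsed.
DEFAULT_HYDROPHOBIC = frozenset("ACFILMVW")

PHI = "Φ"  # Φ

WILDCARD = "wildcard"
EXACT = "exact"
CLASS = "class"


class PatternSyntaxError(ValueError):
    """Malformed pattern text; carries the offending 0-based position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class PositionElement:
    """One residue position of a pattern: exact, class, or wildcard."""

    kind: str
    residues: frozenset

    def __post_init__(self):
        if self.kind not in (WILDCARD, EXACT, CLASS):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == EXACT and len(self.residues) != 1:
            raise ValueError("exact element must hold exactly one residue")
        if self.kind == CLASS and not self.residues:
            raise ValueError("residue class must be non-empty")

    def matches(self, letter: str, wildcard_matches_unknown: bool = False) -> bool:
        if self.kind == WILDCARD:
            return letter in AMINO_ACIDS or wildcard_matches_unknown
        return letter in self.residues


@dataclass(frozen=True)
class MotifMatch:
    """A fixed-span match; coordinates are 1-based inclusive."""

    start: int
    end: int
    matched_subsequence: str

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.matched_subsequence):
            raise ValueError("match span disagrees with matched subsequence")


@dataclass(frozen=True)
class MotifPattern:
    elements: tuple
    source_text: str
    name: str | None = None

    def __len__(self) -> int:
        return len(self.elements)

    def render(self) -> str:
        """Canonical pattern text; parsing it back matches the same set.

        Consecutive wildcards are collapsed to ``X(n)``; classes are
        rendered as sorted bracket lists (Φ is not re-compressed, so the
        rendered text is independent of the hydrophobic configuration).
        """
        parts: list[str] = []
        i = 0
        elems = self.elements
        while i < len(elems):
            e = elems[i]
            if e.kind == WILDCARD:
                j = i
                while j < len(elems) and elems[j].kind == WILDCARD:
                    j += 1
                run = j - i
                parts.append("X" if run == 1 else f"X({run})")
                i = j
            elif e.kind == EXACT:
                parts.append(next(iter(e.residues)))
                i += 1
            else:
                parts.append("[" + "".join(sorted(e.residues)) + "]")
                i += 1
        return "-".join(parts)


def parse_pattern(
    text: str,
    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC,
    name: str | None = None,
) -> MotifPattern:
    """Compile pattern text into an ordered element list.

    Raises :class:`PatternSyntaxError` for unbalanced brackets, unknown
    characters, zero repeats, and variable-length repeats.
    """
    hydrophobic = frozenset(hydrophobic)
    if not hydrophobic <= AMINO_ACIDS:
        raise ValueError("hydrophobic set must be standard amino acids")
    elements: list[PositionElement] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "-":
            i += 1
            continue
        if ch == "[":
            close = text.find("]", i)
            if close < 0:
                raise PatternSyntaxError("unbalanced bracket", i)
            body = text[i + 1 : close]
            residues: set[str] = set()
            for k, c in enumerate(body):
                if c == PHI:
                    residues |= hydrophobic
                elif c in AMINO_ACIDS:
                    residues.add(c)
                else:
                    raise PatternSyntaxError(
                        f"unknown character {c!r} in residue class", i + 1 + k
                    )
            if not residues:
                raise PatternSyntaxError("empty residue class", i)
            element = PositionElement(CLASS, frozenset(residues))
            i = close + 1
        elif ch == "]":
            raise PatternSyntaxError("unbalanced bracket", i)
        elif ch == "X":
            element = PositionElement(WILDCARD, frozenset())
            i += 1
        elif ch == PHI:
            element = PositionElement(CLASS, hydrophobic)
            i += 1
        elif ch in AMINO_ACIDS:
            element = PositionElement(EXACT, frozenset(ch))
            i += 1
        else:
            raise PatternSyntaxError(f"unknown character {ch!r}", i)
        repeat = 1
        if i < n and text[i] == "(":
            close = text.find(")", i)
            if close < 0:
                raise PatternSyntaxError("unbalanced repeat parenthesis", i)
            body = text[i + 1 : close]
            if "," in body:
                raise PatternSyntaxError(
                    "variable-length repeats (n,m) are not supported", i
                )
            if not body.isdigit():
                raise PatternSyntaxError(f"bad repeat count {body!r}", i)
            repeat = int(body)
            if repeat == 0:
                raise PatternSyntaxError("zero repeat count", i)
            i = close + 1
        elements.extend([element] * repeat)
    return MotifPattern(tuple(elements), text, name)


def min_span(pattern: MotifPattern) -> int:
    """Number of residues any match of the pattern occupies."""
    return len(pattern.elements)


def scan(
    sequence: str,
    pattern: MotifPattern,
    unknown: str = "reject",
    wildcard_matches_unknown: bool = False,
) -> list[MotifMatch]:
    """All (possibly overlapping) matches, in ascending start order.

    Parameters
    ----------
    unknown:
        Policy for letters outside the 20-residue alphabet: ``"reject"``
        raises, ``"never-match"`` lets the scan proceed with such letters
        failing every class/exact element (wildcards only accept them when
        ``wildcard_matches_unknown`` is set).
    """
    if not pattern.elements:
        raise ValueError("cannot scan with an empty pattern")
    if unknown not in ("reject", "never-match"):
        raise ValueError(f"unknown-letter policy {unknown!r} not recognized")
    if unknown == "reject":
        bad = set(sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"sequence contains non-standard letters: {sorted(bad)}")
    span = len(pattern.elements)
    elems = pattern.elements
    out: list[MotifMatch] = []
    for s in range(len(sequence) - span + 1):
        ok = True
        for k in range(span):
            if not elems[k].matches(sequence[s + k], wildcard_matches_unknown):
                ok = False
                break
        if ok:
            out.append(MotifMatch(s + 1, s + span, sequence[s : s + span]))
    return out


# ---------------------------------------------------------------------------
# Shipped pattern set: the generalized NBD motifs derived from a 79-NBD
# fungal ABC-transporter cohort, plus the earlier literature consensi they
# generalize.
# ---------------------------------------------------------------------------

NOVEL_WALKER_A = "G-XX-[GA]-X-G-K-[ST]"
NOVEL_ATP_BINDING = "[LIVMFYC]-S-[SGQDEVAHL]-G-X(3)-[RKALV]-[LIVMYATC]-X-[LIVMF]-[AGCT]"
NOVEL_WALKER_B = "[ΦHY]-[ΦCY]-[ΦC]-[ΦCT]-[D]-[DEI]"
CLASSIC_WALKER_A = "G-X(4)-G-K-[ST]"
CLASSIC_ATP_BINDING = "[LIVMFY]-S-[SG]-G-X(3)-[RKA]-[LIVMYA]-X-[LIVMF]-[AG]"
CLASSIC_WALKER_B = "[Φ](4)-[D]"

DEFAULT_PATTERN_TEXTS: dict[str, str] = {
    "walker_a": NOVEL_WALKER_A,
    "atp_binding": NOVEL_ATP_BINDING,
    "walker_b": NOVEL_WALKER_B,
    "walker_a_classic": CLASSIC_WALKER_A,
    "atp_binding_classic": CLASSIC_ATP_BINDING,
    "walker_b_classic": CLASSIC_WALKER_B,
}


def default_patterns(
    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC,
) -> dict[str, MotifPattern]:
    """Compile the six shipped patterns with the given hydrophobic set."""
    return {
        name: parse_pattern(text, hydrophobic=hydrophobic, name=name)
        for name, text in DEFAULT_PATTERN_TEXTS.items()
    }


def load_patterns_tsv(
    path: str | Path, hydrophobic: frozenset = DEFAULT_HYDROPHOBIC
) -> dict[str, MotifPattern]:
    """Read a two-column TSV (motif_name, pattern_text)."""
    patterns: dict[str, MotifPattern] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            name, text = row[0].strip(), row[1].strip()
            patterns[name] = parse_pattern(text, hydrophobic=hydrophobic, name=name)
    return patterns


def shipped_patterns_path() -> Path:
    """Path of the editable pattern TSV shipped with the package."""
    return Path(resources.files("abcfam").joinpath("data/patterns.tsv"))
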