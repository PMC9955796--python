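"""Conserved-domain arrangement → structural type → functional role.

ABC proteins are annotated with an ordered string over the domain alphabet
A–E (A = ABC-membrane, B = ABC-ATPase, C = ABC2-membrane, D = ABC-tran-2,
E = acyl-transfer-3 superfamily domains). The arrangement order, together
with the NCBI-style multidomain family label, determines one of six
structural types; types 1–4 are transmembrane transporters, types 5–6
regulate translation.

The one genuinely ambiguous arrangement is ``A-B`` (half transporter),
which occurs both for ATM1 members that behave as full type-1 transporters
and for type-2 half transporters (ATM1, MdlB, 3a0123). ``A-B`` defaults to
type 2; an explicit full-transporter evidence flag promotes ATM1 members
to type 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .props import GeneRecord, classify_pi

DOMAIN_ALPHABET = frozenset("ABCDE")
UNCLASSIFIED = "unclassified"
TRANSPORT = "transport"
TRANSLATION = "translation"

FAMILIES = (
    "ATM1", "CFTR", "MdlB", "MDR", "MRP",
    "Protein White", "Rim protein", "Uup", "3a0123",
)


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    domains: tuple
    family: str | None = None
    full_transporter: bool = False

    def __post_init__(self):
        if not self.domains:
            raise ValueError("domain list must be non-empty")
        bad = set(self.domains) - DOMAIN_ALPHABET
        if bad:
            raise ValueError(f"labels outside the A–E alphabet: {sorted(bad)}")
        if "B" not in self.domains:
            raise ValueError("an ABC protein carries at least one ABC-ATPase (B) domain")


@dataclass(frozen=True)
class ArrangementRule:
    arrangement: str
    structural_type: int
    families: frozenset | None = None
    requires_full_transporter: bool = False

    def applies(self, arrangement: str, family: str | None, full_transporter: bool) -> bool:
        if arrangement != self.arrangement:
            return False
        if self.families is not None and family not in self.families:
            return False
        if self.requires_full_transporter and not full_transporter:
            return False
        return True


@dataclass(frozen=True)
class ArrangementRuleSet:
    """Ordered, deterministic rules; first applicable rule wins."""

    rules: tuple
    role_map: Mapping[int, str] = field(
        default_factory=lambda: {1: TRANSPORT, 2: TRANSPORT, 3: TRANSPORT,
                                 4: TRANSPORT, 5: TRANSLATION, 6: TRANSLATION}
    )


DEFAULT_RULES = ArrangementRuleSet(
    rules=(
        ArrangementRule("A-B-A-B", 1),
        ArrangementRule("A-B", 1, families=frozenset({"ATM1"}),
                        requires_full_transporter=True),
        ArrangementRule("A-B", 2),
        ArrangementRule("B-C-B", 3),
        ArrangementRule("B-E-B", 3),
        ArrangementRule("B-C-B-C", 4),
        ArrangementRule("B-C", 4),
        ArrangementRule("B-B", 5),
        ArrangementRule("B-B-B", 5),
        ArrangementRule("B-D-B", 6),
        ArrangementRule("B-B-D-B", 6),
    ),
)


def arrangement_string(annotation: DomainAnnotation | Sequence[str]) -> str:
    """Hyphen-joined domain labels, e.g. ``A-B-A-B``."""
    domains = annotation.domains if isinstance(annotation, DomainAnnotation) else tuple(annotation)
    if not domains:
        raise ValueError("empty domain list")
    bad = set(domains) - DOMAIN_ALPHABET
    if bad:
        raise ValueError(f"labels outside the A–E alphabet: {sorted(bad)}")
    return "-".join(domains)


def assign_structural_type(
    arrangement: str,
    family: str | None = None,
    full_transporter: bool = False,
    rules: ArrangementRuleSet = DEFAULT_RULES,
) -> int | str:
    """Structural type 1–6 for an arrangement string, or ``unclassified``."""
    labels = arrangement.split("-") if arrangement else []
    bad = set(labels) - DOMAIN_ALPHABET
    if bad:
        raise ValueError(f"labels outside the A–E alphabet: {sorted(bad)}")
    for rule in rules.rules:
        if rule.applies(arrangement, family, full_transporter):
            return rule.structural_type
    return UNCLASSIFIED


def functional_category(structural_type: int, rules: ArrangementRuleSet = DEFAULT_RULES) -> str:
    """``transport`` for types 1–4, ``translation`` for 5–6."""
    try:
        return rules.role_map[structural_type]
    except (KeyError, TypeError):
        raise ValueError(f"no functional category for type {structural_type!r}") from None


INTRON_BINS = ("0", "1", "2", "3", "4+")


def _intron_bin(count: int) -> str:
    return str(count) if count < 4 else "4+"


def cohort_summary(records: Iterable[GeneRecord]) -> dict:
    """Marginal summaries of a gene cohort.

    Returns per-family counts, per-structural-type counts, the percentage
    of proteins in types 1–2, the intron-count distribution (bins
    0/1/2/3/4+ with percentages), and acidic/basic/neutral pI counts.
    """
    records = list(records)
    total = len(records)
    family_counts = pd.Series(
        [r.family for r in records], dtype="object"
    ).value_counts().sort_index() if records else pd.Series(dtype="int64")
    type_counts = pd.Series(
        [r.structural_type for r in records], dtype="object"
    ).value_counts().sort_index() if records else pd.Series(dtype="int64")
    n_type12 = sum(1 for r in records if r.structural_type in (1, 2))
    intron_counts = pd.Series(
        [_intron_bin(r.intron_count) for r in records], dtype="object"
    ).value_counts().reindex(INTRON_BINS, fill_value=0)
    intron = pd.DataFrame(
        {
            "count": intron_counts,
            "pct": (100.0 * intron_counts / total).round(0) if total else 0.0,
        }
    )
    pi_classes = pd.Series(
        [classify_pi(r.pi) for r in records], dtype="object"
    ).value_counts().reindex(["acidic", "basic", "neutral"], fill_value=0)
    return {
        "total": total,
        "family_counts": family_counts,
        "type_counts": type_counts,
        "pct_types_1_2": (100.0 * n_type12 / total) if total else 0.0,
        "intron_distribution": intron,
        "pi_classes": pi_classes,
    }
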