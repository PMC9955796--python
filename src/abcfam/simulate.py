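"""Seeded synthetic-data generators with ground-truth ledgers.

Every pipeline stage can be exercised without downloads: the generators
emulate a 44-gene fungal ABC-transporter cohort — proteins with planted
Walker A / C-loop / Walker B triplets (79 NBDs in total), 1000-bp
promoters with planted cis-element sites, a four-condition read-count
matrix with pinned marker genes, Ct tables with planted log2 effects, and
a cohort registry reproducing the study-scale marginal counts (family
sizes, intron distribution, pI partition, structural-type counts).

All outputs are deterministic for a fixed seed, and each generator
returns a ledger holding the planted truth; downstream tests consume the
ledger, never re-derive truth from the outputs. Accidental (unplanted)
motif occurrences are screened out by default so planted-truth checks are
exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import architecture, expression, nbd, promoter, qpcr
from .patterns import AMINO_ACIDS, MotifPattern, PositionElement, WILDCARD
from .props import GeneRecord

AA_LIST = sorted(AMINO_ACIDS)
DNA = "ACGT"

CONDITIONS = ("MM", "C-hungry", "N-hungry", "PdPap")
TIMEPOINTS = (0.0, 6.0, 24.0, 48.0)
REFERENCE_GENES = ("actin", "alpha-tubulin", "beta-tubulin")


@dataclass
class SyntheticSpec:
    """Study conditions for the generators (defaults = cohort scale)."""

    cohort_size: int = 44
    promoter_length: int = 1000
    # NBD geometry (within the scanner's default spacing windows)
    cloop_gap: tuple = (40, 80)
    walker_b_gap: tuple = (10, 30)
    flank: tuple = (60, 120)
    linker: tuple = (40, 100)
    # expression screen
    mapped_reads: float = 1e6
    nb_dispersion: float = 50.0
    high_rpkm_range: tuple = (300.0, 2000.0)
    low_rpkm_range: tuple = (1.0, 60.0)
    high_threshold: float = 100.0
    # qPCR
    ct_noise_sd: float = 0.2
    ct_replicates: int = 3


# ---------------------------------------------------------------------------
# Cohort registry plan: 44 genes, nine families, Table-2-consistent
# arrangements. The per-protein split of ATM1/MdlB members between
# structural types 1 and 2 is fixed arbitrarily but consistently (sums
# 27/6) and is synthetic, not authoritative.
# ---------------------------------------------------------------------------

_FAMILY_BY_ID = {
    1: "MRP", 2: "Rim protein", 3: "Rim protein", 4: "CFTR", 5: "MRP",
    6: "MdlB", 7: "MRP", 8: "MRP", 9: "CFTR", 10: "MDR",
    11: "CFTR", 12: "MDR", 13: "MRP", 14: "MDR", 15: "MRP",
    16: "CFTR", 17: "MDR", 18: "MRP", 19: "Protein White", 20: "MDR",
    21: "MDR", 22: "CFTR", 23: "MDR", 24: "MRP", 25: "MDR",
    26: "CFTR", 27: "ATM1", 28: "ATM1", 29: "Uup", 30: "Protein White",
    31: "Uup", 32: "ATM1", 33: "MdlB", 34: "MdlB", 35: "Uup",
    36: "Uup", 37: "3a0123", 38: "ATM1", 39: "MdlB", 40: "Protein White",
    41: "Protein White", 42: "Uup", 43: "MdlB", 44: "MRP",
}

_ARRANGEMENT_BY_ID = {
    2: "B-C-B", 3: "B-E-B",
    19: "B-C-B-C", 30: "B-C", 40: "B-C", 41: "B-C",
    29: "B-B", 31: "B-B-B", 35: "B-D-B", 36: "B-D-B", 42: "B-B-D-B",
    27: "A-B", 28: "A-B", 32: "A-B", 38: "A-B",
    33: "A-B", 39: "A-B", 43: "A-B", 37: "A-B",
}

#: ATM1 members with full-transporter evidence (promoted to type 1).
_FULL_TRANSPORTER_IDS = frozenset({27, 32})

#: Intron counts: 5×0, 5×1, 13×2, 4×3 and 17 genes with more than four
#: introns (none with exactly four), spanning 0–15.
_INTRON_VALUES = (
    [0] * 5 + [1] * 5 + [2] * 13 + [3] * 4
    + [5, 5, 6, 6, 7, 7, 8, 8, 9, 9, 10, 11, 12, 13, 14, 15, 15]
)

_SCAFFOLD_COUNTS = {
    1: 3, 2: 2, 3: 3, 4: 2, 5: 2, 6: 7, 7: 3, 8: 2, 9: 3,
    10: 2, 11: 3, 12: 2, 13: 3, 14: 2, 15: 2, 16: 2, 17: 1,
}

#: NBD class by family, mirroring the alignment-class structure: Class1 ~
#: Protein White / Rim protein, Class2 ~ Uup, Class3 ~ efflux families.
NBD_CLASS_BY_FAMILY = {
    "Protein White": "Class1", "Rim protein": "Class1",
    "Uup": "Class2",
    "MRP": "Class3", "CFTR": "Class3", "MDR": "Class3",
    "MdlB": "Class3", "ATM1": "Class3", "3a0123": "Class3",
}

#: Diagnostic residues planted at (walker_a:8, c_loop:6, c_loop:8,
#: c_loop:12) so the default class rule recovers the class.
_CLASS_DIAGNOSTICS = {
    "Class1": ("S", "Q", "R", "C"),
    "Class2": ("T", "E", "K", "G"),
    "Class3": ("S", "D", "L", "T"),
}


def gene_ids(n: int = 44) -> list:
    return [f"ABC{i:02d}" for i in range(1, n + 1)]


@dataclass
class CohortRegistry:
    records: list
    gff3: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id, "family": r.family, "arrangement": r.arrangement,
                    "intron_count": r.intron_count, "pi": r.pi,
                    "mw_kda": r.mw_kda, "structural_type": r.structural_type,
                    "scaffold": r.scaffold,
                    "full_transporter": r.full_transporter,
                }
                for r in self.records
            ]
        ).set_index("id")


def gen_cohort_registry(spec: SyntheticSpec | None = None, seed: int = 0) -> CohortRegistry:
    """44 GeneRecords pinned to the cohort's marginal counts, plus GFF3."""
    spec = spec or SyntheticSpec()
    if spec.cohort_size != 44:
        raise ValueError("the registry plan is defined for a 44-gene cohort")
    rng = np.random.default_rng([seed, 11])
    ids = gene_ids()

    introns = list(_INTRON_VALUES)
    rng.shuffle(introns)
    acidic = np.round(np.linspace(5.48, 6.90, 27), 2)
    basic = np.round(np.linspace(7.15, 9.87, 17), 2)
    pis = np.concatenate([acidic, basic])
    rng.shuffle(pis)
    mws = np.round(np.linspace(55.33, 187.56, 44), 2)
    rng.shuffle(mws)
    scaffolds = [f"scaffold_{s}" for s, c in _SCAFFOLD_COUNTS.items() for _ in range(c)]
    rng.shuffle(scaffolds)

    records = []
    for k, gid in enumerate(ids):
        num = k + 1
        family = _FAMILY_BY_ID[num]
        arrangement = _ARRANGEMENT_BY_ID.get(num, "A-B-A-B")
        full = num in _FULL_TRANSPORTER_IDS
        stype = architecture.assign_structural_type(arrangement, family, full)
        records.append(
            GeneRecord(
                id=gid, family=family, arrangement=arrangement,
                intron_count=int(introns[k]), pi=float(pis[k]),
                mw_kda=float(mws[k]), structural_type=stype,
                scaffold=scaffolds[k], full_transporter=full,
            )
        )
    return CohortRegistry(records, _registry_gff3(records))


def _registry_gff3(records: Sequence[GeneRecord]) -> str:
    """GFF3 gene models whose exon counts encode the intron counts."""
    exon_len, intron_len, gap = 300, 100, 500
    cursor: dict[str, int] = {}
    lines = ["##gff-version 3"]
    for r in records:
        start = cursor.get(r.scaffold, 1)
        n_exons = r.intron_count + 1
        end = start + n_exons * exon_len + r.intron_count * intron_len - 1
        lines.append(
            f"{r.scaffold}\tabcfam_sim\tgene\t{start}\t{end}\t.\t+\t.\tID={r.id}"
        )
        lines.append(
            f"{r.scaffold}\tabcfam_sim\tmRNA\t{start}\t{end}\t.\t+\t.\t"
            f"ID={r.id}.t1;Parent={r.id}"
        )
        pos = start
        for e in range(n_exons):
            lines.append(
                f"{r.scaffold}\tabcfam_sim\texon\t{pos}\t{pos + exon_len - 1}\t.\t+\t.\t"
                f"ID={r.id}.t1.exon{e + 1};Parent={r.id}.t1"
            )
            pos += exon_len + intron_len
        cursor[r.scaffold] = end + gap
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Proteins with planted NBD triplets
# ---------------------------------------------------------------------------

@dataclass
class ProteinSet:
    sequences: dict
    ledger: pd.DataFrame  # one row per planted NBD

    def fasta(self) -> str:
        return "".join(f">{pid}\n{seq}\n" for pid, seq in self.sequences.items())


def _sample_from_pattern(
    pattern: MotifPattern, rng: np.random.Generator, overrides: Mapping[int, str] | None = None
) -> str:
    out = []
    for i, element in enumerate(pattern.elements, start=1):
        if overrides and i in overrides:
            residue = overrides[i]
            if element.kind != WILDCARD and residue not in element.residues:
                raise ValueError(f"override {residue!r} not allowed at position {i}")
            out.append(residue)
        elif element.kind == WILDCARD:
            out.append(AA_LIST[rng.integers(len(AA_LIST))])
        else:
            choices = sorted(element.residues)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _plant_protein(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    n_nbds: int,
    class_label: str,
    patterns: Mapping[str, MotifPattern],
) -> tuple[str, list]:
    """One protein with `n_nbds` planted triplets; returns (seq, planted).

    ``planted`` rows are dicts with 1-based starts per motif role.
    """
    diag = _CLASS_DIAGNOSTICS[class_label]
    wa_overrides = {8: diag[0]}
    cl_overrides = {6: diag[1], 8: diag[2], 12: diag[3]}
    parts: list[str] = []
    planted: list[dict] = []
    protected: list[tuple[int, int, MotifPattern, set]] = []  # start0, end0, pattern, override idx
    pos = 0

    def background(n: int) -> None:
        nonlocal pos
        parts.append("".join(AA_LIST[i] for i in rng.integers(len(AA_LIST), size=n)))
        pos += n

    def plant(pattern: MotifPattern, overrides: Mapping[int, str]) -> int:
        nonlocal pos
        seq = _sample_from_pattern(pattern, rng, overrides)
        start0 = pos
        parts.append(seq)
        pos += len(seq)
        protected.append((start0, start0 + len(seq) - 1, pattern, set(overrides)))
        return start0 + 1  # 1-based

    background(int(rng.integers(spec.flank[0], spec.flank[1] + 1)))
    for k in range(n_nbds):
        if k:
            background(int(rng.integers(spec.linker[0], spec.linker[1] + 1)))
        wa_start = plant(patterns["walker_a"], wa_overrides)
        background(int(rng.integers(spec.cloop_gap[0], spec.cloop_gap[1] + 1)))
        cl_start = plant(patterns["c_loop"], cl_overrides)
        background(int(rng.integers(spec.walker_b_gap[0], spec.walker_b_gap[1] + 1)))
        wb_start = plant(patterns["walker_b"], {})
        planted.append(
            {
                "nbd_index": k + 1,
                "walker_a_start": wa_start,
                "walker_a_end": wa_start + len(patterns["walker_a"].elements) - 1,
                "cloop_start": cl_start,
                "cloop_end": cl_start + len(patterns["c_loop"].elements) - 1,
                "walker_b_start": wb_start,
                "walker_b_end": wb_start + len(patterns["walker_b"].elements) - 1,
            }
        )
    background(int(rng.integers(spec.flank[0], spec.flank[1] + 1)))
    seq = _screen_protein("".join(parts), planted, protected, patterns, rng)
    return seq, planted


def _screen_protein(
    seq: str,
    planted: list,
    protected: list,
    patterns: Mapping[str, MotifPattern],
    rng: np.random.Generator,
    max_passes: int = 60,
) -> str:
    """Mutate away accidental motif matches so planted truth is exact."""
    expected = {
        ("walker_a", p["walker_a_start"]) for p in planted
    } | {("c_loop", p["cloop_start"]) for p in planted} | {
        ("walker_b", p["walker_b_start"]) for p in planted
    }
    # map: 0-based index -> (allowed residues under planted motif, frozen?)
    allowed = {}
    for start0, end0, pattern, override_idx in protected:
        for i, element in enumerate(pattern.elements):
            idx = start0 + i
            if (i + 1) in override_idx:
                allowed[idx] = None  # frozen: diagnostic residue
            elif element.kind == WILDCARD:
                allowed[idx] = AMINO_ACIDS
            else:
                allowed[idx] = element.residues

    chars = list(seq)
    for _ in range(max_passes):
        dirty = False
        text = "".join(chars)
        for role, pattern in patterns.items():
            from .patterns import scan as _scan

            for m in _scan(text, pattern):
                if (role, m.start) in expected:
                    continue
                if not _patch(chars, m, pattern, allowed, rng):
                    raise _Unpatchable()
                dirty = True
        if not dirty:
            return "".join(chars)
    raise _Unpatchable()


class _Unpatchable(Exception):
    pass


def _patch(chars, match, pattern, allowed, rng) -> bool:
    start0 = match.start - 1
    order = list(range(len(pattern.elements)))
    rng.shuffle(order)
    for k in order:
        element = pattern.elements[k]
        if element.kind == WILDCARD:
            continue  # cannot break a wildcard position
        idx = start0 + k
        site_allowed = allowed.get(idx, AMINO_ACIDS)
        if site_allowed is None:
            continue  # frozen diagnostic residue
        choices = sorted(set(site_allowed) - set(element.residues))
        if not choices:
            continue
        chars[idx] = choices[rng.integers(len(choices))]
        return True
    return False


def gen_proteins(
    spec: SyntheticSpec | None = None,
    registry: CohortRegistry | None = None,
    seed: int = 0,
) -> ProteinSet:
    """Cohort protein FASTA with one planted triplet per ABC-ATPase domain.

    The number of NBDs per protein equals the number of B domains in its
    arrangement string (79 across the default registry); diagnostic
    positions carry the family's class residues so classification is
    recoverable from sequence alone.
    """
    spec = spec or SyntheticSpec()
    registry = registry or gen_cohort_registry(spec, seed)
    patterns = nbd.nbd_patterns()
    rng = np.random.default_rng([seed, 23])
    sequences: dict[str, str] = {}
    rows = []
    for record in registry.records:
        n_nbds = record.arrangement.count("B")
        class_label = NBD_CLASS_BY_FAMILY[record.family]
        for attempt in range(50):
            try:
                seq, planted = _plant_protein(spec, rng, n_nbds, class_label, patterns)
                break
            except _Unpatchable:
                continue
        else:
            raise RuntimeError(f"could not generate a clean protein for {record.id}")
        sequences[record.id] = seq
        for p in planted:
            rows.append({"protein_id": record.id, **p, "class_label": class_label})
    ledger = pd.DataFrame(rows)
    return ProteinSet(sequences, ledger)


# ---------------------------------------------------------------------------
# Promoters with planted cis-element sites
# ---------------------------------------------------------------------------

@dataclass
class PromoterSet:
    sequences: dict
    ledger: pd.DataFrame  # genes × motif names planted counts
    sites: pd.DataFrame  # one row per planted site
    dictionary: promoter.MotifDictionary

    def fasta(self) -> str:
        return "".join(f">{gid}\n{seq}\n" for gid, seq in self.sequences.items())


_STRESS_PRIORITY = ("GCN4", "GCR1", "ADR1", "STRE", "HSTF", "PHO4", "GC/FAR", "ABF1")
_STRESS_WEIGHTS = {"GCN4": 8.0, "GCR1": 5.0, "ADR1": 3.0}


def _promoter_plan(registry: CohortRegistry, dictionary: promoter.MotifDictionary) -> pd.DataFrame:
    """Deterministic per-gene, per-motif planted-count plan.

    Reproduces the cohort-scale census shape: 794 sites of 39 types, 541
    on stress-flagged motifs, per-gene totals 9–32 with the ATM1 family
    averaging 21 (most) and Rim protein 13 (fewest), per-gene distinct
    types 5–14 with Uup the most diverse.
    """
    by_family: dict[str, list[str]] = {}
    for r in registry.records:
        by_family.setdefault(r.family, []).append(r.id)
    for fam in by_family:
        by_family[fam].sort()

    totals: dict[str, int] = {}
    for gid, t in zip(by_family["ATM1"], (20, 21, 21, 22)):
        totals[gid] = t
    for gid in by_family["Rim protein"]:
        totals[gid] = 13
    totals["ABC01"] = 32  # the most motifs — an MRP gene
    totals["ABC09"] = 9   # the fewest
    rest = sorted(g for g in gene_ids() if g not in totals)
    for i, gid in enumerate(rest):
        totals[gid] = 17 if i < 5 else 18
    assert sum(totals.values()) == 794

    types: dict[str, int] = {}
    for gid, t in zip(by_family["Uup"], (9, 10, 11, 11, 14)):
        types[gid] = t
    for gid in by_family["Rim protein"]:
        types[gid] = 7
    types["ABC09"] = 5
    for gid in gene_ids():
        types.setdefault(gid, 8)

    # stress totals per gene: ~68% of sites, adjusted to sum exactly 541
    stress_n = {g: int(round(0.681 * totals[g])) for g in gene_ids()}
    diff = 541 - sum(stress_n.values())
    step = 1 if diff > 0 else -1
    ids_cycle = gene_ids()
    i = 0
    while diff != 0:
        g = ids_cycle[i % len(ids_cycle)]
        new = stress_n[g] + step
        if 2 <= new <= totals[g] - 2:
            stress_n[g] = new
            diff -= step
        i += 1

    stress_names = [n for n in _STRESS_PRIORITY if n in dictionary.entries]
    other_names = [n for n in dictionary.names if n not in set(stress_names)]
    counts = pd.DataFrame(0, index=gene_ids(), columns=dictionary.names, dtype="int64")
    cover_cycle_stress = 0
    cover_cycle_other = 0
    for gid in gene_ids():
        t_g, total_g, s_g = types[gid], totals[gid], stress_n[gid]
        k_s = max(1, min(8, t_g - 1, int(round(t_g * s_g / total_g))))
        while (t_g - k_s) > (total_g - s_g) and k_s < min(8, t_g - 1):
            k_s += 1
        k_s = min(k_s, s_g)
        # stress kinds: the high-priority names plus one coverage pick
        chosen = list(stress_names[: max(0, k_s - 1)])
        while len(chosen) < k_s:
            cand = stress_names[cover_cycle_stress % len(stress_names)]
            cover_cycle_stress += 1
            if cand not in chosen:
                chosen.append(cand)
        # distribute stress sites: 1 each + weighted remainder
        weights = np.array([_STRESS_WEIGHTS.get(n, 1.0) for n in chosen])
        alloc = np.ones(len(chosen), dtype=int)
        remainder = s_g - len(chosen)
        if remainder > 0:
            shares = weights / weights.sum() * remainder
            extra = np.floor(shares).astype(int)
            short = remainder - extra.sum()
            for j in np.argsort(-(shares - extra))[:short]:
                extra[j] += 1
            alloc += extra
        for name, c in zip(chosen, alloc):
            counts.loc[gid, name] = int(c)
        # non-stress kinds: global cycle for coverage, round-robin counts
        k_n = t_g - k_s
        chosen_o: list[str] = []
        while len(chosen_o) < k_n:
            cand = other_names[cover_cycle_other % len(other_names)]
            cover_cycle_other += 1
            if cand not in chosen_o:
                chosen_o.append(cand)
        n_other = total_g - s_g
        if chosen_o:
            base, extra_n = divmod(n_other, len(chosen_o))
            for j, name in enumerate(chosen_o):
                counts.loc[gid, name] = base + (1 if j < extra_n else 0)
    assert int(counts.values.sum()) == 794
    assert int((counts.sum(axis=0) > 0).sum()) == len(dictionary.names)
    stress_cols = [n for n in dictionary.stress_names]
    assert int(counts[stress_cols].values.sum()) == 541
    return counts


def _sample_site(consensus: str, rng: np.random.Generator) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values

    out = []
    for letter in consensus:
        expansion = ambiguous_dna_values[letter]
        out.append(expansion[rng.integers(len(expansion))])
    return "".join(out)


def _screen_promoter(
    chars: list,
    planted_spans: list,
    expected: set,
    matchers: Mapping[str, "re.Pattern"],
    dictionary: promoter.MotifDictionary,
    rng: np.random.Generator,
    max_passes: int = 80,
) -> bool:
    from Bio.Data.IUPACData import ambiguous_dna_values

    occupied = np.zeros(len(chars), dtype=bool)
    for s, e in planted_spans:
        occupied[s : e + 1] = True
    for _ in range(max_passes):
        dirty = False
        text = "".join(chars)
        for name, matcher in matchers.items():
            consensus = dictionary.entries[name].consensus
            for m in matcher.finditer(text):
                if (name, m.start()) in expected:
                    continue
                patched = False
                order = list(range(len(consensus)))
                rng.shuffle(order)
                for k in order:
                    idx = m.start() + k
                    if occupied[idx]:
                        continue
                    expansion = set(ambiguous_dna_values[consensus[k]])
                    choices = sorted(set(DNA) - expansion)
                    if not choices:
                        continue
                    chars[idx] = choices[rng.integers(len(choices))]
                    patched = True
                    break
                if not patched:
                    return False
                dirty = True
        if not dirty:
            return True
    return False


def gen_promoters(
    spec: SyntheticSpec | None = None,
    registry: CohortRegistry | None = None,
    dictionary: promoter.MotifDictionary | None = None,
    seed: int = 0,
) -> PromoterSet:
    """1000-bp promoters with planted, screened forward-strand sites."""
    spec = spec or SyntheticSpec()
    registry = registry or gen_cohort_registry(spec, seed)
    dictionary = dictionary or promoter.MotifDictionary.default()
    plan = _promoter_plan(registry, dictionary)
    matchers = dictionary.matchers()
    rng = np.random.default_rng([seed, 37])
    length = spec.promoter_length
    sequences: dict[str, str] = {}
    site_rows = []
    for gid in plan.index:
        wanted = [(name, int(c)) for name, c in plan.loc[gid].items() if c > 0]
        for attempt in range(60):
            chars = [DNA[i] for i in rng.integers(4, size=length)]
            placements = []  # (name, start0, site)
            intervals: list[tuple[int, int]] = []
            ok = True
            for name, count in wanted:
                consensus = dictionary.entries[name].consensus
                for _ in range(count):
                    site = _sample_site(consensus, rng)
                    placed = False
                    for _try in range(300):
                        start0 = int(rng.integers(0, length - len(site) + 1))
                        end0 = start0 + len(site) - 1
                        if all(end0 < s - 2 or start0 > e + 2 for s, e in intervals):
                            intervals.append((start0, end0))
                            placements.append((name, start0, site))
                            placed = True
                            break
                    if not placed:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            for name, start0, site in placements:
                chars[start0 : start0 + len(site)] = list(site)
            expected = {(name, start0) for name, start0, _ in placements}
            if _screen_promoter(chars, intervals, expected, matchers, dictionary, rng):
                sequences[gid] = "".join(chars)
                for name, start0, site in placements:
                    site_rows.append(
                        {"gene": gid, "motif": name, "start": start0 + 1,
                         "strand": "+", "site": site}
                    )
                break
        else:
            raise RuntimeError(f"could not build a clean promoter for {gid}")
    sites = pd.DataFrame(site_rows)
    return PromoterSet(sequences, plan.copy(), sites, dictionary)


# ---------------------------------------------------------------------------
# Read-count matrix with pinned marker genes
# ---------------------------------------------------------------------------

#: Genes designed highly expressed in all four conditions (13 transport +
#: 4 translation-regulating Uup members, incl. the two pinned markers).
HIGH_ALL_CONDITIONS = (
    "ABC37", "ABC32", "ABC38", "ABC04", "ABC11", "ABC34", "ABC21", "ABC23",
    "ABC01", "ABC05", "ABC15", "ABC19", "ABC30",  # transport
    "ABC29", "ABC35", "ABC31", "ABC42",  # translation (Uup)
)

#: Transport genes high in exactly one condition (17 transport genes high
#: in >= 1 condition in total).
HIGH_ONE_CONDITION = {
    "ABC06": "C-hungry", "ABC10": "N-hungry", "ABC24": "PdPap", "ABC40": "MM",
}

#: RPKM values pinned exactly (length 1000 bp, 1e6 mapped reads → the
#: count equals the RPKM value).
PINNED_RPKM = {
    "ABC31": {"MM": 8537, "C-hungry": 21000, "N-hungry": 32000, "PdPap": 59214},
    "ABC42": {"MM": 3957, "C-hungry": 6200, "N-hungry": 11790, "PdPap": 8400},
}


@dataclass
class SimCounts:
    matrix: expression.CountMatrix
    ledger: pd.DataFrame  # per gene: category, designed flags, target RPKM
    high_rule: dict


def gen_counts(
    spec: SyntheticSpec | None = None,
    registry: CohortRegistry | None = None,
    seed: int = 0,
    null: bool = False,
) -> SimCounts:
    """Negative-binomial count matrix over four culture conditions.

    High/low design is ledgered; sampled cells are screened so that the
    absolute RPKM >= ``spec.high_threshold`` rule reproduces the design
    exactly. ``null=True`` gives every gene one shared expected RPKM in
    all conditions (no condition effects).
    """
    spec = spec or SyntheticSpec()
    registry = registry or gen_cohort_registry(spec, seed)
    rng = np.random.default_rng([seed, 53])
    ids = [r.id for r in registry.records]
    category = {
        r.id: architecture.functional_category(r.structural_type)
        for r in registry.records
    }
    lengths = pd.Series(
        {gid: 1000 if gid in PINNED_RPKM else int(rng.integers(900, 4501)) for gid in ids}
    )
    n_total = spec.mapped_reads
    r_disp = spec.nb_dispersion

    target = pd.DataFrame(0.0, index=ids, columns=list(CONDITIONS))
    designed_high = pd.DataFrame(False, index=ids, columns=list(CONDITIONS))
    for gid in ids:
        if null:
            level = float(rng.uniform(*spec.low_rpkm_range))
            target.loc[gid] = level
            continue
        if gid in PINNED_RPKM:
            for cond, v in PINNED_RPKM[gid].items():
                target.loc[gid, cond] = float(v)
                designed_high.loc[gid, cond] = True
            continue
        if gid in HIGH_ALL_CONDITIONS:
            for cond in CONDITIONS:
                target.loc[gid, cond] = float(rng.uniform(*spec.high_rpkm_range))
                designed_high.loc[gid, cond] = True
        elif gid in HIGH_ONE_CONDITION:
            high_cond = HIGH_ONE_CONDITION[gid]
            for cond in CONDITIONS:
                if cond == high_cond:
                    target.loc[gid, cond] = float(rng.uniform(*spec.high_rpkm_range))
                    designed_high.loc[gid, cond] = True
                else:
                    target.loc[gid, cond] = float(rng.uniform(*spec.low_rpkm_range))
        else:
            for cond in CONDITIONS:
                target.loc[gid, cond] = float(rng.uniform(*spec.low_rpkm_range))

    counts = pd.DataFrame(0, index=ids, columns=list(CONDITIONS), dtype="int64")
    for gid in ids:
        for cond in CONDITIONS:
            if not null and gid in PINNED_RPKM:
                counts.loc[gid, cond] = int(PINNED_RPKM[gid][cond])
                continue
            mu = target.loc[gid, cond] * n_total * lengths[gid] / 1e9
            p = r_disp / (r_disp + mu)
            for _ in range(200):  # screen: sampled cell stays on its design side
                c = int(rng.negative_binomial(r_disp, p))
                sampled_rpkm = c * 1e9 / (n_total * lengths[gid])
                if null:
                    break
                if designed_high.loc[gid, cond]:
                    if spec.high_threshold <= sampled_rpkm < 3900:
                        break
                elif sampled_rpkm < spec.high_threshold:
                    break
            counts.loc[gid, cond] = c

    matrix = expression.CountMatrix(
        counts=counts,
        lengths=lengths,
        mapped_totals=pd.Series(n_total, index=list(CONDITIONS)),
    )
    ledger = pd.DataFrame(
        {
            "category": pd.Series(category),
            "designed_high_any": designed_high.any(axis=1),
        }
    ).join(target.add_prefix("target_rpkm_")).join(designed_high.add_prefix("high_"))
    return SimCounts(matrix, ledger, {"kind": "absolute", "threshold": spec.high_threshold})


# ---------------------------------------------------------------------------
# Ct tables with planted log2 effects
# ---------------------------------------------------------------------------

#: Planted −ΔΔCt trajectories (relative to the same condition at 0 h).
#: Peak magnitudes mirror the study's printed fold changes.
DEFAULT_CT_EFFECTS: dict = {
    "ABC01": {"treatment": {6.0: 1.0, 24.0: 2.0, 48.0: 3.13},
              "control": {6.0: -0.3, 24.0: -0.5, 48.0: -0.8}},
    "ABC02": {"treatment": {6.0: -0.8, 24.0: 0.0, 48.0: 0.29},
              "control": {24.0: 1.5, 48.0: 2.0}},
    "ABC04": {"treatment": {6.0: 2.54, 24.0: 1.2, 48.0: 0.6},
              "control": {6.0: 1.0, 24.0: 1.2, 48.0: 1.5}},
    "ABC05": {"treatment": {6.0: 4.92, 24.0: 2.5, 48.0: 1.0},
              "control": {6.0: -0.3, 24.0: -0.5, 48.0: -0.7}},
    "ABC30": {"treatment": {6.0: 0.59, 24.0: -1.0, 48.0: -1.83},
              "control": {48.0: 1.0}},
    "ABC31": {"treatment": {6.0: 5.09, 24.0: 2.0, 48.0: 1.0},
              "control": {6.0: -0.4, 24.0: -0.6, 48.0: -0.9}},
}

_REF_BASE_CT = {"actin": 18.2, "alpha-tubulin": 20.1, "beta-tubulin": 21.7}


@dataclass
class SimCt:
    table: qpcr.CtTable
    ledger: pd.DataFrame  # planted effects per (gene, condition, timepoint)


def gen_ct(
    spec: SyntheticSpec | None = None,
    seed: int = 0,
    effects: Mapping | None = None,
    conditions: tuple = ("control", "treatment"),
    timepoints: tuple = TIMEPOINTS,
) -> SimCt:
    """Two-condition × four-timepoint × triplicate Ct table.

    Reference genes are constant up to well noise; each target gene's Ct
    is offset by its planted −ΔΔCt trajectory so the ddCt pipeline should
    recover the planted log2 effects.
    """
    spec = spec or SyntheticSpec()
    effects = DEFAULT_CT_EFFECTS if effects is None else effects
    rng = np.random.default_rng([seed, 71])
    sd = spec.ct_noise_sd
    ref_mean_base = float(np.mean(list(_REF_BASE_CT.values())))
    rows = []
    ledger_rows = []
    baselines = {
        gene: float(rng.uniform(4.0, 8.0)) for gene in sorted(effects)
    }
    for gene in sorted(effects):
        for condition in conditions:
            for tp in timepoints:
                effect = effects[gene].get(condition, {}).get(tp, 0.0)
                ledger_rows.append(
                    {"gene": gene, "condition": condition,
                     "timepoint": tp, "effect": effect}
                )
                for rep in range(1, spec.ct_replicates + 1):
                    ct = (
                        ref_mean_base + baselines[gene] - effect
                        + rng.normal(0.0, sd)
                    )
                    rows.append(
                        {"gene": gene, "condition": condition, "timepoint": tp,
                         "replicate": rep, "ct": round(float(ct), 3)}
                    )
    for ref, base in _REF_BASE_CT.items():
        for condition in conditions:
            for tp in timepoints:
                for rep in range(1, spec.ct_replicates + 1):
                    rows.append(
                        {"gene": ref, "condition": condition, "timepoint": tp,
                         "replicate": rep,
                         "ct": round(float(base + rng.normal(0.0, sd)), 3)}
                    )
    table = qpcr.CtTable(
        pd.DataFrame(rows), reference_genes=REFERENCE_GENES, calibrator_timepoint=0.0
    )
    return SimCt(table, pd.DataFrame(ledger_rows))


# ---------------------------------------------------------------------------
# One-stop writer
# ---------------------------------------------------------------------------

def simulate_all(outdir: str | Path, spec: SyntheticSpec | None = None, seed: int = 0) -> None:
    """Write every synthetic input plus ledgers under ``outdir``."""
    spec = spec or SyntheticSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = gen_cohort_registry(spec, seed)
    proteins = gen_proteins(spec, registry, seed)
    promoters = gen_promoters(spec, registry, seed=seed)
    counts = gen_counts(spec, registry, seed)
    ct = gen_ct(spec, seed)

    registry.to_frame().to_csv(outdir / "registry.tsv", sep="\t")
    (outdir / "genes.gff3").write_text(registry.gff3)
    (outdir / "proteins.fa").write_text(proteins.fasta())
    proteins.ledger.to_csv(outdir / "nbd_ledger.tsv", sep="\t", index=False)
    (outdir / "promoters.fa").write_text(promoters.fasta())
    promoters.ledger.to_csv(outdir / "promoter_ledger.tsv", sep="\t")
    promoters.sites.to_csv(outdir / "promoter_sites.tsv", sep="\t", index=False)
    counts.matrix.counts.to_csv(outdir / "counts.tsv", sep="\t")
    counts.matrix.lengths.rename("length_bp").to_csv(outdir / "gene_lengths.tsv", sep="\t")
    counts.matrix.mapped_totals.rename("mapped_reads").to_csv(
        outdir / "mapped_totals.tsv", sep="\t"
    )
    counts.ledger.to_csv(outdir / "counts_ledger.tsv", sep="\t")
    ct.table.data.to_csv(outdir / "ct.csv", index=False)
    ct.ledger.to_csv(outdir / "ct_ledger.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps({"seed": seed, "cohort_size": spec.cohort_size}, indent=2)
    )
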