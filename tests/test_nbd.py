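"""NBD triplet assembly, classification, and block extraction."""

import pytest

from abcfam import nbd
from abcfam.patterns import parse_pattern

PATTERNS = nbd.nbd_patterns()

# handcrafted motif instances (P is inert for all three patterns)
WALKER_A = "GAAGAGKS"
C_LOOP = "LSSGPPPRLPLA"
WALKER_B = "LLLLDD"


def build_protein(gap1=35, gap2=10, n_triplets=1, linker=60):
    parts = ["P" * 40]
    for k in range(n_triplets):
        if k:
            parts.append("P" * linker)
        parts += [WALKER_A, "P" * gap1, C_LOOP, "P" * gap2, WALKER_B]
    parts.append("P" * 25)
    return "".join(parts)


class TestFindNbds:
    def test_single_triplet_coordinates(self):
        seq = build_protein()
        hits = nbd.find_nbds(seq, PATTERNS)
        assert len(hits) == 1
        h = hits[0]
        assert h.walker_a.start == 41
        assert h.walker_a.matched_subsequence == WALKER_A
        assert h.c_loop.start == 41 + 8 + 35
        assert h.walker_b.start == h.c_loop.end + 10 + 1
        assert h.position_index == 1

    def test_missing_walker_b_in_window_yields_nothing(self):
        seq = "P" * 40 + WALKER_A + "P" * 35 + C_LOOP + "P" * 200 + WALKER_B
        assert nbd.find_nbds(seq, PATTERNS) == []

    def test_cloop_outside_spacing_window_yields_nothing(self):
        seq = "P" * 40 + WALKER_A + "P" * 10 + C_LOOP + "P" * 10 + WALKER_B
        assert nbd.find_nbds(seq, PATTERNS) == []

    def test_two_triplets_indexed_in_chain_order(self):
        hits = nbd.find_nbds(build_protein(n_triplets=2), PATTERNS)
        assert [h.position_index for h in hits] == [1, 2]
        assert hits[0].walker_a.start < hits[1].walker_a.start

    def test_no_hits_on_inert_sequence(self):
        assert nbd.find_nbds("P" * 500, PATTERNS) == []

    def test_missing_pattern_key_raises(self):
        with pytest.raises(KeyError):
            nbd.find_nbds("P" * 100, {"walker_a": PATTERNS["walker_a"]})


class TestPlantedRecovery:
    def test_planted_triplets_recovered_exactly(self, proteins):
        """Generator ledger and scanner agree on every NBD coordinate."""
        ledger = proteins.ledger
        assert len(ledger) == 79
        for pid, seq in proteins.sequences.items():
            want = ledger[ledger.protein_id == pid]
            hits = nbd.find_nbds(seq, PATTERNS)
            assert len(hits) == len(want)
            for h, (_, row) in zip(hits, want.iterrows()):
                assert h.walker_a.start == row.walker_a_start
                assert h.c_loop.start == row.cloop_start
                assert h.walker_b.start == row.walker_b_start

    def test_position_index_follows_walker_a_order(self, proteins):
        for pid, seq in proteins.sequences.items():
            hits = nbd.find_nbds(seq, PATTERNS)
            starts = [h.walker_a.start for h in hits]
            assert starts == sorted(starts)
            assert [h.position_index for h in hits] == list(range(1, len(hits) + 1))

    def test_classes_recovered_from_planted_diagnostics(self, proteins):
        ledger = proteins.ledger
        for pid, seq in proteins.sequences.items():
            hits = nbd.classify_all(nbd.find_nbds(seq, PATTERNS))
            want = ledger[ledger.protein_id == pid]["class_label"].tolist()
            assert [h.class_label for h in hits] == want


def _hit(diag="SQRC"):
    """An NbdHit whose diagnostic string is `diag` under the default rule."""
    wa = "GAAGAGK" + diag[0]
    cl = "LSSGP" + diag[1] + "P" + diag[2] + "LPL" + diag[3]
    seq = "P" * 40 + wa + "P" * 35 + cl + "P" * 10 + WALKER_B + "P" * 20
    hits = nbd.find_nbds(seq, PATTERNS)
    assert len(hits) == 1
    return hits[0]


class TestClassify:
    def test_exact_table_lookup(self):
        assert nbd.classify_nbd(_hit("SQRC")) == "Class1"
        assert nbd.classify_nbd(_hit("TEKG")) == "Class2"
        assert nbd.classify_nbd(_hit("SDLT")) == "Class3"

    def test_hamming_one_falls_back_to_nearest_exemplar(self):
        # one substitution away from the Class3 exemplar SDLT only
        label = nbd.classify_nbd(_hit("SDLC"))
        exemplars = nbd.DEFAULT_CLASS_RULE.residue_table
        dists = {
            k: sum(a != b for a, b in zip("SDLC", k)) for k in exemplars
        }
        assert min(dists.values()) == 1 and list(dists.values()).count(1) == 1
        assert label == "Class3"

    def test_equidistant_tie_is_unassigned(self):
        rule = nbd.NbdClassRule(
            diagnostic_positions=(("walker_a", 8),),
            residue_table={"S": "Class1", "T": "Class2"},
        )
        # diagnostic 'S' is distance 0 from Class1: exact lookup
        assert nbd.classify_nbd(_hit("SQRC"), rule) == "Class1"
        rule_tie = nbd.NbdClassRule(
            diagnostic_positions=(("walker_a", 8),),
            residue_table={"A": "Class1", "G": "Class2"},
        )
        assert nbd.classify_nbd(_hit("SQRC"), rule_tie) == nbd.UNASSIGNED

    def test_out_of_range_diagnostic_index_raises(self):
        rule = nbd.NbdClassRule(
            diagnostic_positions=(("walker_a", 9),), residue_table={"S": "Class1"}
        )
        with pytest.raises(IndexError):
            nbd.classify_nbd(_hit(), rule)


class TestMotifBlock:
    def test_block_shape_and_ordering(self, proteins):
        pats = PATTERNS
        hits = {
            pid: nbd.find_nbds(seq, pats) for pid, seq in proteins.sequences.items()
        }
        block = nbd.extract_motif_block(hits, "walker_a")
        assert len(block) == 79
        assert all(len(row) == 8 for row in block)

    def test_rows_rematch_source_pattern(self, proteins):
        hits = {
            pid: nbd.find_nbds(seq, PATTERNS)
            for pid, seq in list(proteins.sequences.items())[:10]
        }
        block = nbd.extract_motif_block(hits, "walker_b")
        from abcfam.patterns import scan

        for row in block:
            assert any(m.start == 1 for m in scan(row, PATTERNS["walker_b"]))

    def test_empty_hit_list_gives_empty_block(self):
        assert nbd.extract_motif_block({}, "walker_a") == []

    def test_mixed_spans_rejected(self):
        h1 = _hit()
        import dataclasses
        from abcfam.patterns import MotifMatch

        h2 = dataclasses.replace(h1, walker_a=MotifMatch(1, 9, "GAAGAGKST"),
                                 position_index=2)
        with pytest.raises(ValueError):
            nbd.extract_motif_block({"p1": [h1], "p2": [h2]}, "walker_a")
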