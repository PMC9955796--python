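"""RPKM normalization, clustering vs brute-force oracle, high flags."""

import numpy as np
import pandas as pd
import pytest

from abcfam import expression as ex
from _oracles import brute_force_complete_linkage


def _matrix(counts, lengths, totals):
    return ex.CountMatrix(
        counts=pd.DataFrame(counts),
        lengths=pd.Series(lengths),
        mapped_totals=pd.Series(totals),
    )


class TestRpkm:
    def test_formula(self):
        m = _matrix({"s1": {"g1": 10}}, {"g1": 1000}, {"s1": 1e6})
        assert ex.rpkm(m).loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_counts_zero_rpkm(self):
        m = _matrix({"s1": {"g1": 0}}, {"g1": 500}, {"s1": 1e6})
        assert ex.rpkm(m).loc["g1", "s1"] == 0.0

    def test_joint_scale_invariance(self):
        a = _matrix({"s1": {"g1": 10}}, {"g1": 1000}, {"s1": 1e6})
        b = _matrix({"s1": {"g1": 20}}, {"g1": 1000}, {"s1": 2e6})
        assert ex.rpkm(a).loc["g1", "s1"] == pytest.approx(ex.rpkm(b).loc["g1", "s1"])

    def test_linearity_and_inverse_proportionality(self):
        rng = np.random.default_rng(2)
        c = rng.integers(1, 1000, size=(5, 3))
        lengths = rng.integers(200, 4000, size=5)
        totals = rng.integers(int(1e5), int(1e7), size=3).astype(float)
        m = _matrix(
            pd.DataFrame(c, index=list("abcde"), columns=list("xyz")),
            pd.Series(lengths, index=list("abcde")),
            pd.Series(totals, index=list("xyz")),
        )
        r = ex.rpkm(m)
        m2 = _matrix(m.counts * 3, m.lengths, m.mapped_totals)
        assert np.allclose(ex.rpkm(m2), r * 3)
        m3 = _matrix(m.counts, m.lengths * 2, m.mapped_totals)
        assert np.allclose(ex.rpkm(m3), r / 2)

    def test_invalid_lengths_and_totals(self):
        with pytest.raises(ValueError):
            _matrix({"s1": {"g1": 1}}, {"g1": 0}, {"s1": 1e6})
        with pytest.raises(ValueError):
            _matrix({"s1": {"g1": 1}}, {"g1": 100}, {"s1": 0})
        with pytest.raises(ValueError):
            _matrix({"s1": {"g1": -1}}, {"g1": 100}, {"s1": 1e6})


class TestLog2:
    def test_exact_values(self):
        assert ex.log2_matrix(pd.DataFrame({"c": [8.0]}), offset=0.0).iloc[0, 0] == 3.0
        assert ex.log2_matrix(pd.DataFrame({"c": [0.0]}), offset=1.0).iloc[0, 0] == 0.0

    def test_zero_with_nonpositive_offset_rejected(self):
        with pytest.raises(ValueError):
            ex.log2_matrix(pd.DataFrame({"c": [0.0]}), offset=0.0)

    def test_monotone(self):
        m = pd.DataFrame({"c": [1.0, 2.0, 5.0]})
        out = ex.log2_matrix(m)["c"]
        assert out.is_monotonic_increasing


class TestClustering:
    def test_identical_pair_merges_first_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [5.0, 5.0], [1.0, 2.0]], index=list("abc"))
        d = ex.cluster_genes(m)
        a, b, h = d.merges[0]
        assert h == 0.0
        assert {a, b} == {0, 2}

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(8)
        d = ex.cluster_genes(pd.DataFrame(rng.normal(size=(12, 4))))
        heights = [h for _, _, h in d.merges]
        assert heights == sorted(heights)

    def test_complete_linkage_height_is_max_pairwise_distance(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(7, 3))
        d = ex.cluster_genes(pd.DataFrame(values))
        members = d.members()
        label_to_row = {i: i for i in range(7)}
        for i, (a, b, h) in enumerate(d.merges):
            dist = max(
                np.linalg.norm(values[x] - values[y])
                for x in members[a]
                for y in members[b]
            )
            assert h == pytest.approx(dist)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        values = rng.normal(size=(8, 4))
        d = ex.cluster_genes(pd.DataFrame(values))
        ours = [
            (frozenset(d.members()[a]), frozenset(d.members()[b]), h)
            for a, b, h in d.merges
        ]
        oracle = brute_force_complete_linkage(values)
        for (oa, ob, oh), (ma, mb, mh) in zip(oracle, ours):
            assert {oa, ob} == {ma, mb}
            assert oh == pytest.approx(mh)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ex.cluster_genes(pd.DataFrame([[1.0, np.nan], [0.0, 1.0]]))

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            ex.cluster_genes(pd.DataFrame([[1.0, 2.0]]))

    def test_newick_text_contains_all_leaves(self):
        m = pd.DataFrame(np.eye(4), index=list("wxyz"))
        text = ex.cluster_genes(m).to_newick()
        assert text.endswith(";")
        for leaf in "wxyz":
            assert leaf in text


class TestFlags:
    def test_absolute_threshold_boundary(self):
        expr = pd.DataFrame({"c1": [99.9, 100.0]}, index=["g1", "g2"])
        flags = ex.flag_high(expr, {"kind": "absolute", "threshold": 100.0})
        assert not flags.loc["g1", "c1"]
        assert flags.loc["g2", "c1"]

    def test_all_zero_matrix_no_flags(self):
        expr = pd.DataFrame(0.0, index=["g1", "g2"], columns=["c1"])
        flags = ex.flag_high(expr, {"kind": "absolute", "threshold": 1.0})
        assert not flags.values.any()

    def test_quantile_rule_flags_top_quartile(self):
        expr = pd.DataFrame({"c1": np.arange(8.0)})
        flags = ex.flag_high(expr, {"kind": "quantile", "q": 0.75})
        assert flags["c1"].sum() == 2

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            ex.flag_high(pd.DataFrame({"c": [1.0]}), {"kind": "zscore"})

    def test_cohort_rollup_matches_design(self, sim_counts):
        expr = ex.rpkm(sim_counts.matrix)
        flags = ex.flag_high(expr, sim_counts.high_rule)
        rollup = ex.high_rollup(flags, dict(sim_counts.ledger["category"]))
        assert rollup.to_dict() == {"transport": 17, "translation": 4}

    def test_flags_match_ledger_exactly(self, sim_counts):
        expr = ex.rpkm(sim_counts.matrix)
        flags = ex.flag_high(expr, sim_counts.high_rule)
        designed = sim_counts.ledger[[f"high_{c}" for c in flags.columns]]
        designed.columns = flags.columns
        assert flags.equals(designed)


class TestPinnedMarkers:
    def test_pinned_rpkm_values(self, sim_counts):
        expr = ex.rpkm(sim_counts.matrix)
        assert expr.loc["ABC31", "PdPap"] == pytest.approx(59214.0)
        assert expr.loc["ABC31", "MM"] == pytest.approx(8537.0)
        assert expr.loc["ABC42", "N-hungry"] == pytest.approx(11790.0)
        assert expr.loc["ABC42", "MM"] == pytest.approx(3957.0)

    def test_markers_rank_top_two(self, sim_counts):
        expr = ex.rpkm(sim_counts.matrix)
        ranked = ex.rank_genes(expr)
        assert list(ranked.index[:2]) == ["ABC31", "ABC42"]
        # the two markers lead in every single condition as well
        for cond in expr.columns:
            top2 = set(expr[cond].nlargest(2).index)
            assert top2 == {"ABC31", "ABC42"}
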