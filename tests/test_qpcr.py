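"""2^-ddCt quantification: normalization, fold changes, t-tests."""

import numpy as np
import pandas as pd
import pytest

from abcfam import qpcr, simulate


def _table(records, refs=("ref1",)):
    return qpcr.CtTable(pd.DataFrame(records), reference_genes=refs)


def _rows(gene, condition, tp, cts):
    return [
        {"gene": gene, "condition": condition, "timepoint": tp,
         "replicate": i + 1, "ct": ct}
        for i, ct in enumerate(cts)
    ]


class TestNormalize:
    def test_single_reference(self):
        t = _table(
            _rows("tgt", "control", 0.0, [25.0]) + _rows("ref1", "control", 0.0, [20.0])
        )
        norm = qpcr.normalize_ct(t)
        assert norm["delta_ct"].iloc[0] == pytest.approx(5.0)

    def test_three_references_arithmetic_mean(self):
        records = _rows("tgt", "control", 0.0, [26.0])
        for ref, ct in zip(("r1", "r2", "r3"), (20.0, 21.0, 22.0)):
            records += _rows(ref, "control", 0.0, [ct])
        t = _table(records, refs=("r1", "r2", "r3"))
        assert qpcr.normalize_ct(t)["delta_ct"].iloc[0] == pytest.approx(5.0)

    def test_global_shift_invariance(self):
        base = _rows("tgt", "control", 0.0, [25.0, 25.2]) + _rows(
            "ref1", "control", 0.0, [20.0, 20.1]
        )
        shifted = [dict(r, ct=r["ct"] + 2.0) for r in base]
        d1 = qpcr.normalize_ct(_table(base))["delta_ct"]
        d2 = qpcr.normalize_ct(_table(shifted))["delta_ct"]
        assert np.allclose(d1, d2)

    def test_missing_reference_names_sample(self):
        records = (
            _rows("tgt", "control", 0.0, [25.0])
            + _rows("ref1", "control", 0.0, [20.0])
            + _rows("tgt", "treatment", 6.0, [24.0])
        )
        with pytest.raises(ValueError, match="treatment"):
            qpcr.normalize_ct(_table(records))

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            _table(_rows("ref1", "control", 0.0, [0.0]))


def _planted_table(effect, tp=6.0, noise=0.0, n=3, seed=0):
    """Treatment series with a planted −ΔΔCt at `tp` relative to 0 h."""
    rng = np.random.default_rng(seed)
    records = []
    for t, eff in ((0.0, 0.0), (tp, effect)):
        for cond in ("control", "treatment"):
            e = eff if cond == "treatment" else 0.0
            records += _rows(
                "tgt", cond, t,
                [25.0 - e + rng.normal(0, noise) for _ in range(n)],
            )
            records += _rows("ref1", cond, t, [20.0 + rng.normal(0, noise) for _ in range(n)])
    return _table(records)


class TestFoldChange:
    def test_planted_offset_recovered_exactly_without_noise(self):
        t = _planted_table(5.09)
        r = qpcr.fold_change(t, "tgt", "treatment", 6.0)
        assert r.log2_fold_change == pytest.approx(5.09)
        assert r.fold == pytest.approx(2 ** 5.09)
        assert r.fold == pytest.approx(34.06, abs=0.01)

    def test_calibrator_fold_is_exactly_one(self):
        t = _planted_table(2.0, noise=0.1, seed=3)
        r = qpcr.fold_change(t, "tgt", "treatment", 0.0)
        assert r.fold == 1.0
        assert r.log2_fold_change == 0.0

    def test_symmetric_offsets(self):
        up = qpcr.fold_change(_planted_table(1.0), "tgt", "treatment", 6.0)
        down = qpcr.fold_change(_planted_table(-1.0), "tgt", "treatment", 6.0)
        assert up.fold == pytest.approx(2.0)
        assert down.fold == pytest.approx(0.5)

    def test_absent_calibrator_raises(self):
        t = _planted_table(1.0)
        with pytest.raises(ValueError):
            qpcr.fold_change(t, "tgt", "treatment", 6.0, calibrator=("treatment", 99.0))

    def test_reference_invariance_downstream(self):
        t1 = _planted_table(2.54)
        shifted = t1.data.copy()
        mask = (shifted["condition"] == "treatment") & (shifted["timepoint"] == 6.0)
        shifted.loc[mask, "ct"] += 3.0  # whole-sample shift: targets AND refs
        t2 = qpcr.CtTable(shifted, reference_genes=("ref1",))
        r1 = qpcr.fold_change(t1, "tgt", "treatment", 6.0)
        r2 = qpcr.fold_change(t2, "tgt", "treatment", 6.0)
        assert r1.log2_fold_change == pytest.approx(r2.log2_fold_change)


class TestTTest:
    def test_identical_groups(self):
        t, p = qpcr.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        t, p = qpcr.t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.001

    def test_agrees_with_independent_oracle(self):
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(loc=0.5, size=5)
            t, p = qpcr.t_test(a, b)
            t_o, p_o, _ = sm_ttest(a, b, usevar="pooled")
            assert t == pytest.approx(t_o, abs=1e-6)
            assert p == pytest.approx(p_o, abs=1e-6)

    def test_zero_variance_conventions(self):
        assert qpcr.t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = qpcr.t_test([3.0, 3.0], [2.0, 2.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            qpcr.t_test([1.0], [1.0, 2.0])

    def test_stars_mapping(self):
        assert qpcr.stars(0.2) == ""
        assert qpcr.stars(0.04) == "*"
        assert qpcr.stars(0.004) == "**"


class TestPipelineTables:
    def test_fold_change_table_covers_design(self, sim_ct):
        out = qpcr.fold_change_table(sim_ct.table)
        genes = sim_ct.table.target_genes
        assert len(out) == len(genes) * 2 * 4  # conditions x timepoints
        cal = out[(out.timepoint == 0.0)]
        assert np.allclose(cal["fold"], 1.0)

    def test_differential_series_sign_matches_planted(self, sim_ct):
        diff = qpcr.differential_series(sim_ct.table, "ABC31")
        at6 = diff[diff.timepoint == 6.0].iloc[0]
        assert at6["differential"] > 4.0  # planted +5.09 vs control −0.4
        assert at6["stars"] in ("*", "**")

    def test_recovered_effects_close_to_ledger(self, sim_ct):
        out = qpcr.fold_change_table(sim_ct.table)
        merged = out.merge(
            sim_ct.ledger, on=["gene", "condition", "timepoint"], how="left"
        )
        # replicate noise is 0.2 cycles; the estimator SE is ~0.13
        assert (merged["log2_fold_change"] - merged["effect"]).abs().max() < 0.8


class TestParameterRecovery:
    def test_planted_effects_recovered_within_3se(self):
        """Mean recovered −ΔΔCt across 500 sims is within 3·SE of truth."""
        spec = simulate.SyntheticSpec()
        for planted in (-1.83, 0.0, 2.54, 3.13, 4.92, 5.09):
            estimates = np.empty(120)
            for i in range(estimates.size):
                t = _planted_table(planted, noise=spec.ct_noise_sd, seed=1000 + i)
                estimates[i] = qpcr.fold_change(
                    t, "tgt", "treatment", 6.0
                ).log2_fold_change
            se = estimates.std(ddof=1) / np.sqrt(estimates.size)
            assert abs(estimates.mean() - planted) < 3 * se + 1e-12
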