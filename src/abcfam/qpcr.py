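"""Relative RT-qPCR quantification by the 2^−ΔΔCt method.

ΔCt normalizes a target gene's Ct to the arithmetic mean of the reference
genes' Ct within the same sample (equivalent to the geometric mean of the
reference quantities). ΔΔCt subtracts the mean ΔCt of a calibrator sample
— by default the same condition's 0 h timepoint, so control and treatment
form separate time series. Fold change is 2^−ΔΔCt.

Significance between control and treatment is an independent-samples
t-test on the per-replicate ΔCt values at the same timepoint (calibrator
subtraction is a within-series constant and would correlate replicates,
so it is left out of the test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("gene", "condition", "timepoint", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format Ct records with designated reference genes."""

    data: pd.DataFrame
    reference_genes: tuple
    calibrator_timepoint: float = 0.0

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        self.reference_genes = tuple(self.reference_genes)
        present = set(self.data["gene"])
        absent = [g for g in self.reference_genes if g not in present]
        if absent:
            raise ValueError(f"reference genes absent from table: {absent}")

    @property
    def target_genes(self) -> list:
        refs = set(self.reference_genes)
        return sorted(g for g in self.data["gene"].unique() if g not in refs)

    @property
    def conditions(self) -> list:
        return sorted(self.data["condition"].unique())

    @property
    def timepoints(self) -> list:
        return sorted(self.data["timepoint"].unique())

    @classmethod
    def from_csv(cls, path, reference_genes, calibrator_timepoint: float = 0.0):
        return cls(pd.read_csv(path), tuple(reference_genes), calibrator_timepoint)


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    condition: str
    timepoint: float
    log2_fold_change: float  # mean −ΔΔCt over replicates
    sd: float  # SD of −ΔΔCt over replicates
    fold: float  # 2^(mean −ΔΔCt)
    p_value: float | None  # vs control at the same timepoint

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold change must be positive")


def normalize_ct(table: CtTable) -> pd.DataFrame:
    """Per-sample ΔCt = Ct(target) − mean Ct(reference genes).

    A sample is one (condition, timepoint, replicate) well set; a sample
    lacking any reference gene raises, naming the sample.
    """
    data = table.data
    refs = data[data["gene"].isin(table.reference_genes)]
    sample_cols = ["condition", "timepoint", "replicate"]
    ref_counts = refs.groupby(sample_cols)["gene"].nunique()
    ref_mean = refs.groupby(sample_cols)["ct"].mean().rename("ref_ct")
    targets = data[~data["gene"].isin(table.reference_genes)].copy()
    for key in targets[sample_cols].itertuples(index=False, name=None):
        if key not in ref_mean.index or ref_counts.get(key, 0) < len(
            table.reference_genes
        ):
            raise ValueError(f"sample {key} lacks reference-gene measurements")
    targets = targets.merge(ref_mean.reset_index(), on=sample_cols, how="left")
    targets["delta_ct"] = targets["ct"] - targets["ref_ct"]
    return targets


def fold_change(
    table: CtTable,
    gene: str,
    condition: str,
    timepoint: float,
    calibrator: tuple | None = None,
    control_condition: str = "control",
) -> FoldChangeResult:
    """2^−ΔΔCt for one (gene, condition, timepoint).

    ``calibrator`` is a (condition, timepoint) pair; the default is the
    same condition at the table's calibrator timepoint (0 h). ΔΔCt is
    computed per replicate against the calibrator's mean ΔCt; the SD is
    the replicate SD of −ΔΔCt. The p value compares per-replicate ΔCt
    against the control condition at the same timepoint (None when the
    queried condition is the control itself or no control data exist).
    """
    if calibrator is None:
        calibrator = (condition, table.calibrator_timepoint)
    norm = normalize_ct(table)
    rows = norm[(norm["gene"] == gene)]
    sample = rows[(rows["condition"] == condition) & (rows["timepoint"] == timepoint)]
    if sample.empty:
        raise ValueError(f"no Ct data for {gene!r} at ({condition}, {timepoint})")
    cal = rows[(rows["condition"] == calibrator[0]) & (rows["timepoint"] == calibrator[1])]
    if cal.empty:
        raise ValueError(f"calibrator sample {calibrator} absent for {gene!r}")
    minus_ddct = -(sample["delta_ct"].values - cal["delta_ct"].mean())
    # identical to mean(minus_ddct) but exact (0, fold 1) at the calibrator
    mean = float(cal["delta_ct"].mean() - sample["delta_ct"].mean())
    sd = float(np.std(minus_ddct, ddof=1)) if len(minus_ddct) > 1 else 0.0
    p: float | None = None
    if condition != control_condition:
        ctrl = rows[
            (rows["condition"] == control_condition)
            & (rows["timepoint"] == timepoint)
        ]
        if len(ctrl) >= 2 and len(sample) >= 2:
            _, p = t_test(sample["delta_ct"].values, ctrl["delta_ct"].values)
    return FoldChangeResult(
        gene=gene,
        condition=condition,
        timepoint=float(timepoint),
        log2_fold_change=mean,
        sd=sd,
        fold=float(2.0 ** mean),
        p_value=p,
    )


def fold_change_table(table: CtTable, control_condition: str = "control") -> pd.DataFrame:
    """FoldChangeResult rows for every target × condition × timepoint."""
    records = []
    for gene in table.target_genes:
        for condition in table.conditions:
            for tp in table.timepoints:
                r = fold_change(
                    table, gene, condition, tp, control_condition=control_condition
                )
                records.append(
                    {
                        "gene": r.gene,
                        "condition": r.condition,
                        "timepoint": r.timepoint,
                        "log2_fold_change": r.log2_fold_change,
                        "sd": r.sd,
                        "fold": r.fold,
                        "p_value": r.p_value,
                        "stars": stars(r.p_value) if r.p_value is not None else "",
                    }
                )
    return pd.DataFrame.from_records(records)


def differential_series(
    table: CtTable,
    gene: str,
    treatment_condition: str = "treatment",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Treatment − control log2 expression difference per timepoint."""
    rows = []
    for tp in table.timepoints:
        tr = fold_change(table, gene, treatment_condition, tp,
                         control_condition=control_condition)
        ct = fold_change(table, gene, control_condition, tp,
                         control_condition=control_condition)
        rows.append(
            {
                "timepoint": tp,
                "log2_treatment": tr.log2_fold_change,
                "log2_control": ct.log2_fold_change,
                "differential": tr.log2_fold_change - ct.log2_fold_change,
                "p_value": tr.p_value,
                "stars": stars(tr.p_value) if tr.p_value is not None else "",
            }
        )
    return pd.DataFrame(rows)


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided independent-samples t-test (pooled by default).

    Degenerate input (zero variance in both groups) follows the
    convention: equal means → (0, 1); unequal means → (±inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.copysign(math.inf, np.mean(a) - np.mean(b)), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def stars(p: float) -> str:
    """Fig-style significance stars: * p<0.05, ** p<0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
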