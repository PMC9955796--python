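"""RPKM expression screen: normalization, log transform, clustering, flags.

RPKM[g, s] = C[g, s] · 10⁹ / (N[s] · L[g]) with C the read-count matrix,
L per-gene transcript lengths (bp) and N per-sample mapped-read totals
(supplied, not recomputed from C). Genes are clustered by Euclidean
distance with complete linkage on the log2 matrix, and "highly expressed"
genes are flagged per condition by a configurable rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class CountMatrix:
    """Integer read counts (genes × samples) with lengths and totals."""

    counts: pd.DataFrame
    lengths: pd.Series  # bp, per gene
    mapped_totals: pd.Series  # per sample

    def __post_init__(self):
        self.lengths = self.lengths.reindex(self.counts.index)
        self.mapped_totals = self.mapped_totals.reindex(self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive transcript length")
        if self.mapped_totals.isna().any() or (self.mapped_totals <= 0).any():
            raise ValueError("every sample needs a positive mapped-read total")


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    c = counts.counts.astype(float)
    return c.mul(1e9).div(counts.mapped_totals, axis=1).div(counts.lengths, axis=0)


def log2_matrix(expr: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log2(RPKM + offset); an offset of 1 maps zero RPKM to 0."""
    if (expr.values < 0).any():
        raise ValueError("expression values must be non-negative")
    if offset <= 0 and (expr.values == 0).any():
        raise ValueError("offset must be positive when zero values are present")
    return np.log2(expr + offset)


@dataclass
class Dendrogram:
    """Complete-linkage merge history in scipy linkage numbering.

    Leaves are 0..n−1; merge i creates cluster n+i. ``merges`` rows are
    (cluster_a, cluster_b, height); heights are non-decreasing under
    complete linkage.
    """

    merges: list
    n_leaves: int
    leaf_order: list
    labels: list

    @property
    def linkage_matrix(self) -> np.ndarray:
        sizes = {}
        z = np.zeros((len(self.merges), 4))
        for i, (a, b, h) in enumerate(self.merges):
            size = sizes.get(a, 1) + sizes.get(b, 1)
            sizes[self.n_leaves + i] = size
            z[i] = [a, b, h, size]
        return z

    def members(self) -> dict:
        """Cluster id → frozenset of leaf labels, for every cluster."""
        out = {i: frozenset([self.labels[i]]) for i in range(self.n_leaves)}
        for i, (a, b, _) in enumerate(self.merges):
            out[self.n_leaves + i] = out[a] | out[b]
        return out

    def to_newick(self) -> str:
        """Nested-parenthesis text with merge heights as node annotations."""
        names = {i: self.labels[i] for i in range(self.n_leaves)}
        for i, (a, b, h) in enumerate(self.merges):
            names[self.n_leaves + i] = f"({names[a]},{names[b]}):{h:.6g}"
        return names[self.n_leaves + len(self.merges) - 1] + ";"


def cluster_genes(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering, Euclidean metric, complete linkage."""
    if isinstance(matrix, pd.DataFrame):
        values = matrix.values.astype(float)
        labels = list(matrix.index)
    else:
        values = np.asarray(matrix, dtype=float)
        labels = list(range(values.shape[0]))
    if values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 genes")
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    z = hierarchy.linkage(values, method="complete", metric="euclidean")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    leaf_order = [int(i) for i in hierarchy.leaves_list(z)]
    return Dendrogram(merges, values.shape[0], leaf_order, labels)


DEFAULT_HIGH_RULE = {"kind": "quantile", "q": 0.75}


def flag_high(expr: pd.DataFrame, rule: Mapping = DEFAULT_HIGH_RULE) -> pd.DataFrame:
    """Boolean per-gene, per-condition high-expression flags.

    Rules: ``{"kind": "quantile", "q": 0.75}`` flags genes at or above the
    per-condition quantile; ``{"kind": "absolute", "threshold": t}`` flags
    values >= t.
    """
    kind = rule.get("kind")
    if kind == "quantile":
        cutoff = expr.quantile(rule["q"], axis=0)
        return expr.ge(cutoff, axis=1)
    if kind == "absolute":
        return expr >= rule["threshold"]
    raise ValueError(f"unknown high-expression rule {rule!r}")


def high_rollup(flags: pd.DataFrame, category_map: Mapping[str, str]) -> pd.Series:
    """Genes high in >= 1 condition, counted by functional category."""
    any_high = flags.any(axis=1)
    cats = pd.Series({g: category_map[g] for g in flags.index})
    return any_high.groupby(cats).sum().astype(int)


def rank_genes(expr: pd.DataFrame) -> pd.Series:
    """Genes ranked by their maximum expression across conditions."""
    return expr.max(axis=1).sort_values(ascending=False)
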