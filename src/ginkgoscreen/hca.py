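"""Hierarchical clustering of chromatographic flavonol profiles.

Each product is described by the percentage contribution of the rutin (%R),
quercetin (%Q) and kaempferol (%K) peak areas to its total chromatogram
area. Products are grouped by agglomerative clustering with Ward's
minimum-variance criterion on Euclidean distances after mean-centering the
three columns (centering leaves pairwise Euclidean distances unchanged but
matches the published preprocessing). Merge heights follow the distance
scale ("ward.D2" convention). Cutting the dendrogram at k = 4 separates
rutin-dominant products, quercetin-dominant ones, mixed
quercetin/kaempferol products, and low-flavonol products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "FLAVONOL_COLUMNS",
    "FlavonolTable",
    "Dendrogram",
    "Partition",
    "mean_center",
    "ward_linkage",
    "cut",
    "cluster_flavonols",
]

FLAVONOL_COLUMNS = ("%R", "%Q", "%K")


@dataclass
class FlavonolTable:
    """Per-product flavonol peak-area percentages (%R, %Q, %K).

    ``centered`` marks a mean-centered table, whose values may legitimately
    be negative; raw tables must lie in [0, 100].
    """

    product_ids: list[str]
    values: np.ndarray  # (n, 3), columns %R, %Q, %K
    centered: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(FLAVONOL_COLUMNS):
            raise ValueError(f"expected an (n, 3) table, got shape {v.shape}")
        if v.shape[0] != len(self.product_ids):
            raise ValueError("row count does not match number of product ids")
        if len(set(self.product_ids)) != len(self.product_ids):
            raise ValueError("product ids are not unique")
        if np.any(~np.isfinite(v)):
            raise ValueError("table contains missing or non-finite values")
        if not self.centered and (np.any(v < 0) or np.any(v > 100)):
            raise ValueError("percentages must lie in [0, 100]")
        self.values = v

    def __len__(self) -> int:
        return len(self.product_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.product_ids, columns=list(FLAVONOL_COLUMNS)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FlavonolTable":
        cols = [c for c in df.columns if c.upper().lstrip("%") in ("R", "Q", "K")]
        if len(cols) != 3:
            raise ValueError(f"could not identify %R/%Q/%K columns in {list(df.columns)}")
        return cls([str(i) for i in df.index], df[cols].to_numpy(dtype=float))


@dataclass
class Dendrogram:
    """The merge history of an agglomerative clustering.

    ``linkage_matrix`` is in SciPy linkage format: one row
    (cluster_a, cluster_b, height, new_size) per merge, n - 1 rows for n
    leaves, heights non-decreasing (guaranteed for Ward).
    """

    linkage_matrix: np.ndarray
    product_ids: list[str]

    def __post_init__(self) -> None:
        z = np.asarray(self.linkage_matrix, dtype=float)
        n = len(self.product_ids)
        if z.shape != (n - 1, 4):
            raise ValueError(f"expected {n - 1} merges for {n} items, got {z.shape[0]}")
        self.linkage_matrix = z

    @property
    def n_leaves(self) -> int:
        return len(self.product_ids)

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [(int(a), int(b), float(h), int(s)) for a, b, h, s in self.linkage_matrix]


@dataclass
class Partition:
    """A flat k-cluster assignment with labels 1..k in first-seen order."""

    product_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.size != len(self.product_ids):
            raise ValueError("one label per product required")
        if set(lab.tolist()) != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}")
        self.labels = lab

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for pid, lab in zip(self.product_ids, self.labels):
            out[int(lab)].append(pid)
        return out

    def cluster_of(self, product_id: str) -> int:
        return int(self.labels[self.product_ids.index(product_id)])


def mean_center(table: FlavonolTable) -> FlavonolTable:
    """Subtract each column's mean. Pairwise Euclidean distances are
    unchanged by this translation."""
    if len(table) < 2:
        raise ValueError("mean centering needs at least two rows")
    centered = table.values - table.values.mean(axis=0, keepdims=True)
    return FlavonolTable(list(table.product_ids), centered, centered=True)


def ward_linkage(table: FlavonolTable) -> Dendrogram:
    """Ward minimum-variance agglomeration on Euclidean distances.

    At each step the pair of clusters whose merge least increases the total
    within-cluster sum of squares is joined; heights are reported on the
    distance scale.
    """
    if len(table) < 2:
        raise ValueError("clustering needs at least two rows")
    z = linkage(table.values, method="ward", metric="euclidean")
    return Dendrogram(z, list(table.product_ids))


def cut(dendrogram: Dendrogram, k: int) -> Partition:
    """Extract exactly k flat clusters by undoing the last k - 1 merges.

    Cluster labels are assigned 1..k by first-seen product order, so the
    labelling is deterministic.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    raw = fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust")
    if len(set(raw.tolist())) != k:
        raise ValueError(f"could not split the tree into exactly {k} clusters")
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return Partition(list(dendrogram.product_ids), labels, k)


def cluster_flavonols(
    table: FlavonolTable, k: int = 4, center: bool = True
) -> tuple[Dendrogram, Partition]:
    """Convenience: (optionally) mean-center, Ward-link and cut at k."""
    prepared = mean_center(table) if center else table
    dend = ward_linkage(prepared)
    return dend, cut(dend, k)
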