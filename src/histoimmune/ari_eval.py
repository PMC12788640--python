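"""Adjusted Rand index from a labeled contingency table.

The ARI quantifies chance-corrected agreement between two partitions of the
same cells.  The three-way report compares Annotation vs Clustering (high is
good: clusters recover biology), Batch vs Clustering (low is good: clusters
are not driven by batch), and Annotation vs Batch (low is good: cell types
are spread evenly across batches); that interpretation lives here in the
docs, not in code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContingencyTable", "AriReport", "build_contingency", "adjusted_rand_index", "normalization_report"]


@dataclass
class ContingencyTable:
    """Co-occurrence counts n_ij between two partitions, with marginals."""

    n: int
    n_ij: np.ndarray  # (r, s)
    a_i: np.ndarray  # row sums
    b_j: np.ndarray  # column sums

    def __post_init__(self):
        if self.n_ij.sum() != self.n:
            raise ValueError("contingency entries must sum to n")
        if not np.array_equal(self.n_ij.sum(axis=1), self.a_i):
            raise ValueError("row sums inconsistent")
        if not np.array_equal(self.n_ij.sum(axis=0), self.b_j):
            raise ValueError("column sums inconsistent")


@dataclass
class AriReport:
    ari_annotation_vs_clustering: float
    ari_batch_vs_clustering: float
    ari_annotation_vs_batch: float
    n_clusters: int

    def to_dict(self) -> dict:
        return {
            "A-C": self.ari_annotation_vs_clustering,
            "B-C": self.ari_batch_vs_clustering,
            "A-B": self.ari_annotation_vs_batch,
            "n_clusters": self.n_clusters,
        }


def build_contingency(labels_x, labels_y) -> ContingencyTable:
    """Count co-occurrences n_ij between two equal-length labelings."""
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    r, s = xi.max() + 1, yi.max() + 1
    n_ij = np.bincount(xi * s + yi, minlength=r * s).reshape(r, s)
    return ContingencyTable(n=x.size, n_ij=n_ij, a_i=n_ij.sum(axis=1), b_j=n_ij.sum(axis=0))


def _comb2(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v * (v - 1) / 2.0


def adjusted_rand_index(t: ContingencyTable) -> float:
    """Closed-form ARI from a contingency table.

    ARI = (sum C(n_ij,2) - E) / (max - E) with
    E = sum C(a_i,2) * sum C(b_j,2) / C(n,2) and
    max = (sum C(a_i,2) + sum C(b_j,2)) / 2.  When both partitions are a
    single cluster the denominator is 0 with perfect trivial agreement; that
    degenerate case is defined as 1.  Values can be negative (worse than
    chance) and are not clamped.
    """
    if t.n < 2:
        raise ValueError("ARI needs n >= 2")
    index = _comb2(t.n_ij).sum()
    sum_a = _comb2(t.a_i).sum()
    sum_b = _comb2(t.b_j).sum()
    expected = sum_a * sum_b / _comb2(t.n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions trivial (all-singletons or single-cluster): identical
        return 1.0
    return float((index - expected) / (max_index - expected))


def ari(labels_x, labels_y) -> float:
    """Convenience: ARI directly from two labelings."""
    return adjusted_rand_index(build_contingency(labels_x, labels_y))


def normalization_report(annotation, clustering, batch) -> AriReport:
    """The three pairwise ARIs used to judge a normalization strategy.

    ``clustering`` may be a ClusteringResult or a plain labeling; all three
    labelings must cover the same cells in the same order.
    """
    labels_c = getattr(clustering, "cluster_of", clustering)
    a = np.asarray(annotation)
    b = np.asarray(batch)
    c = np.asarray(labels_c)
    if not (len(a) == len(b) == len(c)):
        raise ValueError("annotation, clustering and batch must label the same cells")
    return AriReport(
        ari_annotation_vs_clustering=ari(a, c),
        ari_batch_vs_clustering=ari(b, c),
        ari_annotation_vs_batch=ari(a, b),
        n_clusters=int(len(np.unique(c))),
    )
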