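"""Single-cell quality control and the normalizations applied downstream.

QC keeps a cell iff 250 <= detected genes <= 2500 (closed interval) and its
mitochondrial fraction does not exceed 5% (removal is strict: exactly 5% is
retained).  Single-cell counts get global-scaling log normalization
(log1p of counts rescaled to a common library size, default 10,000); bulk
matrices get upper-quartile normalization over nonzero genes.  The
embedding/clustering step is deliberately pluggable — it only supplies a
partition to the adjusted-Rand-index evaluation, not a reference clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "QCReport",
    "ClusteringResult",
    "qc_filter",
    "log_normalize",
    "upper_quartile_normalize",
    "embed_and_cluster",
]


@dataclass(frozen=True)
class QCThresholds:
    min_features: int = 250
    max_features: int = 2500
    max_mito: float = 0.05

    def __post_init__(self):
        if not 0 <= self.min_features < self.max_features:
            raise ValueError("need 0 <= min_features < max_features")
        if not 0 < self.max_mito <= 1:
            raise ValueError("max_mito must be in (0, 1]")


@dataclass
class QCReport:
    n_before: int
    n_after: int
    per_sample_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    per_sample_mito_stats: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def retained_fraction(self) -> float:
        return self.n_after / self.n_before if self.n_before else 0.0

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "retained_fraction": self.retained_fraction,
            "per_sample_counts": {k: list(v) for k, v in self.per_sample_counts.items()},
            "per_sample_mito_stats": self.per_sample_mito_stats,
        }


@dataclass
class ClusteringResult:
    cell_ids: list[str]
    cluster_of: np.ndarray  # (n_cells,) int labels in [0, k)
    k: int
    method_tag: str

    def __post_init__(self):
        labels = np.asarray(self.cluster_of)
        if labels.shape[0] != len(self.cell_ids):
            raise ValueError("one label per cell required")
        if labels.size and (labels.min() < 0 or labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")


def _dense(x) -> np.ndarray:
    return x.toarray() if hasattr(x, "toarray") else np.asarray(x)


def _mito_fraction(adata: ad.AnnData) -> np.ndarray:
    """Per-cell mitochondrial fraction: planted scalar column or ^MT- genes."""
    if "mito_fraction" in adata.obs:
        return adata.obs["mito_fraction"].to_numpy(dtype=float)
    mt = np.array([str(g).startswith("MT-") for g in adata.var_names])
    if not mt.any():
        raise ValueError(
            "no mitochondrial information: provide obs['mito_fraction'] or gene names "
            "matching '^MT-' (a missing value is never treated as 0)"
        )
    x = _dense(adata.X)
    totals = x.sum(axis=1)
    return np.divide(x[:, mt].sum(axis=1), totals, out=np.zeros(len(totals)), where=totals > 0)


def qc_filter(adata: ad.AnnData, thr: QCThresholds = QCThresholds()) -> tuple[ad.AnnData, QCReport]:
    """Filter cells on detected-gene count and mitochondrial fraction.

    A cell survives iff ``min_features <= detected <= max_features`` (both
    bounds inclusive) and ``mito <= max_mito``.  Detected genes come from
    ``obs['n_genes_detected']`` when present, else are counted from the
    matrix.  Returns the filtered copy plus a report with per-sample
    before/after counts and post-filter mito summary statistics.
    """
    if "n_genes_detected" in adata.obs:
        detected = adata.obs["n_genes_detected"].to_numpy(dtype=int)
    else:
        detected = (_dense(adata.X) > 0).sum(axis=1)
    mito = _mito_fraction(adata)
    keep = (detected >= thr.min_features) & (detected <= thr.max_features) & (mito <= thr.max_mito)

    samples = (
        adata.obs["sample_id"].astype(str)
        if "sample_id" in adata.obs
        else pd.Series("all", index=adata.obs_names)
    )
    per_sample_counts: dict[str, tuple[int, int]] = {}
    per_sample_mito: dict[str, dict[str, float]] = {}
    for s in sorted(samples.unique()):
        in_s = (samples == s).to_numpy()
        kept = in_s & keep
        per_sample_counts[s] = (int(in_s.sum()), int(kept.sum()))
        m = mito[kept]
        if m.size:
            per_sample_mito[s] = {
                "mean": float(m.mean()),
                "median": float(np.median(m)),
                "sd": float(m.std(ddof=1)) if m.size > 1 else 0.0,
                "min": float(m.min()),
                "max": float(m.max()),
            }
    report = QCReport(
        n_before=adata.n_obs,
        n_after=int(keep.sum()),
        per_sample_counts=per_sample_counts,
        per_sample_mito_stats=per_sample_mito,
    )
    return adata[keep].copy(), report


def log_normalize(counts, scale_total: float = 1e4):
    """Global-scaling log normalization: log1p(count * scale_total / libsize).

    Accepts an AnnData (cells x genes; returns a copy with normalized X and
    the raw counts in ``layers['counts']``) or a 2-D array oriented cells x
    genes.  Errors on any all-zero cell, naming it.
    """
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    if isinstance(counts, ad.AnnData):
        x = _dense(counts.X).astype(float)
        lib = x.sum(axis=1)
        zero = np.flatnonzero(lib == 0)
        if zero.size:
            raise ValueError(f"all-zero cell(s): {list(counts.obs_names[zero[:5]])}")
        out = counts.copy()
        out.layers["counts"] = x
        out.X = np.log1p(x * (scale_total / lib)[:, None])
        return out
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    lib = x.sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"all-zero cell(s) at rows {zero[:5].tolist()}")
    return np.log1p(x * (scale_total / lib)[:, None])


def upper_quartile_normalize(bulk: pd.DataFrame, target: float | None = None) -> pd.DataFrame:
    """Scale each sample (column) so its upper quartile over nonzero genes hits target.

    The 75th percentile is computed over each sample's nonzero genes (the
    common convention).  With ``target=None`` the mean of the per-sample
    quartiles is used, so the output stays on the input scale.
    """
    x = bulk.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("bulk counts must be non-negative")
    q75 = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        nz = x[:, j][x[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"sample {bulk.columns[j]!r} is all zeros")
        q75[j] = np.percentile(nz, 75)
    if target is None:
        target = float(q75.mean())
    if target <= 0:
        raise ValueError("target must be positive")
    return bulk * (target / q75)


def embed_and_cluster(
    normalized: np.ndarray,
    n_pcs: int = 20,
    k: int = 8,
    seed: int = 0,
    cluster_fn=None,
    cell_ids: list[str] | None = None,
) -> ClusteringResult:
    """PCA embedding followed by k-means (default) or a pluggable clusterer.

    ``normalized`` is cells x genes.  ``cluster_fn(embedding, seed) -> labels``
    replaces k-means when supplied (e.g. a graph clustering); the partition is
    all the adjusted-Rand evaluation consumes.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    x = np.asarray(normalized, dtype=float)
    n_cells = x.shape[0]
    if n_pcs > min(x.shape):
        raise ValueError("n_pcs cannot exceed min(cells, genes)")
    if cluster_fn is None and k > n_cells:
        raise ValueError("k cannot exceed the number of cells")
    emb = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    if cluster_fn is not None:
        labels = np.asarray(cluster_fn(emb, seed))
        tag = "custom"
    else:
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(emb)
        tag = f"pca{n_pcs}+kmeans{k}"
    # relabel to a compact [0, k) range
    _, labels = np.unique(labels, return_inverse=True)
    ids = cell_ids if cell_ids is not None else [str(i) for i in range(n_cells)]
    return ClusteringResult(cell_ids=list(ids), cluster_of=labels, k=int(labels.max()) + 1, method_tag=tag)
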