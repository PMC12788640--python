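"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Stands in for a real HCC cohort: a cell-type signature reference with marker
genes, droplet-style single-cell counts with per-sample batch effects and
planted low-quality cells, slide tile bags where "immune-high" bags carry a
planted density of dark nucleus-like blobs, and survival cohorts with a
planted hazard ratio between groups.  Every generator takes an integer seed,
is bit-reproducible given it, and returns its own ground-truth bookkeeping
(violation flags, signal masks, realized fractions, group assignments) so
downstream recoveries can be tested against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .survival import SurvivalRecord

__all__ = [
    "SignatureReference",
    "SyntheticSlide",
    "make_reference",
    "simulate_cells",
    "simulate_slide_bag",
    "simulate_survival_cohort",
    "write_sc_dataset",
    "write_slide_bags",
    "write_survival_csv",
]

# canonical QC bounds used for the generator's own bookkeeping
QC_MIN_FEATURES = 250
QC_MAX_FEATURES = 2500
QC_MAX_MITO = 0.05


@dataclass
class SignatureReference:
    """Cell-type expression signatures at unit library size.

    ``mean_expr`` rows are expected count fractions per gene for one type
    (each row sums to 1); ``marker_mask`` flags the genes elevated in exactly
    one type.
    """

    gene_ids: list[str]
    cell_types: list[str]
    mean_expr: np.ndarray  # (T, G), rows sum to 1
    marker_mask: np.ndarray  # (T, G) bool

    def __post_init__(self):
        t, g = self.mean_expr.shape
        if t < 2 or g < 10:
            raise ValueError("reference needs >= 2 types and >= 10 genes")
        if not np.all(np.isfinite(self.mean_expr)) or np.any(self.mean_expr < 0):
            raise ValueError("mean expression must be finite and non-negative")
        if np.any(self.marker_mask.sum(axis=1) < 1):
            raise ValueError("every type needs at least one marker gene")


@dataclass
class SyntheticSlide:
    """One slide's tile bag with planted-signal bookkeeping."""

    slide_id: str
    tiles: np.ndarray  # (N, H, W, 3) uint8
    signal_mask: np.ndarray  # (N,) bool, planted immune tile
    immune_level: int

    def __post_init__(self):
        if self.tiles.dtype != np.uint8:
            raise ValueError("tiles must be uint8 rasters in [0, 255]")


def make_reference(
    n_types: int,
    n_genes: int,
    marker_frac: float = 0.05,
    seed: int = 0,
    fold_change: float = 8.0,
) -> SignatureReference:
    """Build a signature reference with disjoint marker genes per type.

    Baseline per-gene means are log-normal; each type's markers are multiplied
    by ``fold_change`` (> 1), and rows are renormalized to unit library size.
    """
    if n_types < 2:
        raise ValueError("deconvolution is undefined for fewer than 2 cell types")
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    if not 0 < marker_frac < 1:
        raise ValueError("marker_frac must be in (0, 1)")
    if fold_change <= 1:
        raise ValueError("marker fold change must exceed 1")
    n_markers = max(1, round(marker_frac * n_genes))
    if n_markers * n_types > n_genes:
        raise ValueError("not enough genes for disjoint marker sets")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    marker_mask = np.zeros((n_types, n_genes), dtype=bool)
    marker_genes = rng.choice(n_genes, size=n_markers * n_types, replace=False)
    for t in range(n_types):
        marker_mask[t, marker_genes[t * n_markers : (t + 1) * n_markers]] = True
    mean_expr = np.tile(baseline, (n_types, 1))
    mean_expr[marker_mask] *= fold_change
    mean_expr /= mean_expr.sum(axis=1, keepdims=True)
    return SignatureReference(
        gene_ids=[f"gene_{i:05d}" for i in range(n_genes)],
        cell_types=[f"type_{t}" for t in range(n_types)],
        mean_expr=mean_expr,
        marker_mask=marker_mask,
    )


def simulate_cells(
    ref: SignatureReference,
    cells_per_type: int,
    batch_ids: list[str],
    lowq_frac: float = 0.0,
    seed: int = 0,
    mean_library: float = 2000.0,
    library_sigma: float = 0.3,
    batch_effect: float = 1.0,
    dispersion: float = 10.0,
    mito_mode: str = "scalar",
) -> ad.AnnData:
    """Draw negative-binomial single-cell counts around the reference.

    Each cell's expected counts are its type's signature scaled by a
    log-normal library size and a per-batch multiplicative gene factor whose
    geometric SD is ``batch_effect`` (1.0 means no batch effect).  A
    ``lowq_frac`` share of cells is planted as low quality: mitochondrial
    fraction above 5%, or detected genes forced outside [250, 2500].

    Returns an AnnData (cells x genes) whose ``obs`` carries the generator's
    own bookkeeping: ``cell_type``, ``sample_id``, ``mito_fraction``,
    ``n_genes_detected``, ``planted_lowq`` (intent) and ``qc_ok`` (realized
    truth under the canonical bounds).
    """
    if cells_per_type < 1:
        raise ValueError("cells_per_type must be >= 1")
    if not 0 <= lowq_frac < 1:
        raise ValueError("lowq_frac must be in [0, 1)")
    if not batch_ids:
        raise ValueError("batch_ids must be non-empty")
    if mito_mode not in ("scalar", "genes"):
        raise ValueError("mito_mode must be 'scalar' or 'genes'")
    rng = np.random.default_rng(seed)
    n_types, n_genes = ref.mean_expr.shape
    n_cells = n_types * cells_per_type

    cell_type = np.repeat(np.arange(n_types), cells_per_type)
    batch = rng.integers(0, len(batch_ids), size=n_cells)
    lib = mean_library * rng.lognormal(0.0, library_sigma, size=n_cells)
    log_sigma = np.log(batch_effect) if batch_effect > 1 else 0.0
    batch_factors = (
        rng.lognormal(0.0, log_sigma, size=(len(batch_ids), n_genes))
        if log_sigma > 0
        else np.ones((len(batch_ids), n_genes))
    )

    mu = ref.mean_expr[cell_type] * batch_factors[batch]
    mu *= lib[:, None] / mu.sum(axis=1, keepdims=True)
    # gamma-Poisson mixture == negative binomial with gene-level dispersion
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    gene_ids = list(ref.gene_ids)
    if mito_mode == "genes":
        n_mt = max(3, n_genes // 100)
        mt_idx = np.arange(n_mt)
        gene_ids = [f"MT-{g}" if i < n_mt else g for i, g in enumerate(gene_ids)]
    mito = rng.uniform(0.0, 0.045, size=n_cells)  # healthy cells stay <= 5%

    n_lowq = int(round(lowq_frac * n_cells))
    planted = np.zeros(n_cells, dtype=bool)
    if n_lowq:
        idx = rng.choice(n_cells, size=n_lowq, replace=False)
        planted[idx] = True
        modes = ["mito", "low_genes"] + (["high_genes"] if n_genes > QC_MAX_FEATURES else [])
        for i in idx:
            mode = modes[rng.integers(0, len(modes))]
            if mode == "mito":
                mito[i] = rng.uniform(0.06, 0.30)
            elif mode == "low_genes":
                nz = np.flatnonzero(counts[i])
                keep = rng.integers(20, QC_MIN_FEATURES - 30)
                if nz.size > keep:
                    drop = rng.choice(nz, size=nz.size - keep, replace=False)
                    counts[i, drop] = 0
            else:  # force detected genes above the upper bound
                zeros = np.flatnonzero(counts[i] == 0)
                need = QC_MAX_FEATURES + 1 - (n_genes - zeros.size)
                if need > 0 and zeros.size >= need:
                    counts[i, rng.choice(zeros, size=need, replace=False)] = 1

    if mito_mode == "genes":
        totals = counts.sum(axis=1)
        mt_totals = np.round(totals * mito / (1 - mito)).astype(np.int64)
        counts[:, mt_idx] = 0
        shares = rng.dirichlet(np.full(n_mt, 5.0))
        for j in range(n_mt):
            counts[:, mt_idx[j]] = np.round(mt_totals * shares[j]).astype(np.int64)
        mito = counts[:, mt_idx].sum(axis=1) / np.maximum(counts.sum(axis=1), 1)

    n_detected = (counts > 0).sum(axis=1)
    qc_ok = (
        (n_detected >= QC_MIN_FEATURES)
        & (n_detected <= QC_MAX_FEATURES)
        & (mito <= QC_MAX_MITO)
    )

    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical([ref.cell_types[t] for t in cell_type]),
            "sample_id": pd.Categorical([batch_ids[b] for b in batch]),
            "mito_fraction": mito,
            "n_genes_detected": n_detected,
            "planted_lowq": planted,
            "qc_ok": qc_ok,
        },
        index=[f"cell_{i:06d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=gene_ids))
    adata.uns["qc_bounds"] = {
        "min_features": QC_MIN_FEATURES,
        "max_features": QC_MAX_FEATURES,
        "max_mito": QC_MAX_MITO,
    }
    return adata


def _draw_blobs(tile: np.ndarray, rng: np.random.Generator) -> None:
    """Stamp dark elliptical nucleus-like blobs onto a tile in place."""
    h, w, _ = tile.shape
    yy, xx = np.mgrid[0:h, 0:w]
    n_blobs = rng.integers(6, 14)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(4, h - 4), rng.uniform(4, w - 4)
        a, b = rng.uniform(2.5, 6.0), rng.uniform(2.0, 4.5)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        color = np.array([70, 50, 110]) + rng.normal(0, 8, size=3)  # hematoxylin-dark
        tile[mask] = np.clip(0.25 * tile[mask] + 0.75 * color, 0, 255)


def simulate_slide_bag(
    immune_level: int,
    n_tiles: int = 44,
    tile_size: int = 64,
    signal_density: dict[int, float] | None = None,
    seed: int = 0,
    slide_id: str | None = None,
) -> SyntheticSlide:
    """Generate one slide's tile bag with a planted signal-tile density.

    Background tiles are textured eosin-pink noise; signal tiles additionally
    contain dark elliptical blobs.  The number of signal tiles is a binomial
    draw at ``signal_density[immune_level]``, recorded in ``signal_mask``.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if tile_size < 16:
        raise ValueError("tile_size must be >= 16")
    if signal_density is None:
        signal_density = {0: 0.0, 1: 0.5}
    levels = sorted(signal_density)
    dens = [signal_density[c] for c in levels]
    if any(b < a for a, b in zip(dens, dens[1:])):
        raise ValueError("signal densities must be monotone non-decreasing in class")
    if immune_level not in signal_density:
        raise ValueError(f"no density for immune level {immune_level}")
    rng = np.random.default_rng(seed)
    mask = rng.random(n_tiles) < signal_density[immune_level]
    tiles = np.empty((n_tiles, tile_size, tile_size, 3), dtype=np.uint8)
    base = np.array([225.0, 200.0, 215.0])  # eosin-pink background
    for i in range(n_tiles):
        texture = gaussian_filter(rng.normal(0, 18, size=(tile_size, tile_size)), sigma=3)
        tile = base[None, None, :] + texture[:, :, None] + rng.normal(0, 4, size=(tile_size, tile_size, 3))
        tile = np.clip(tile, 0, 255)
        if mask[i]:
            _draw_blobs(tile, rng)
        tiles[i] = np.clip(tile, 0, 255).astype(np.uint8)
    return SyntheticSlide(
        slide_id=slide_id or f"slide_L{immune_level}_s{seed}",
        tiles=tiles,
        signal_mask=mask,
        immune_level=int(immune_level),
    )


def simulate_survival_cohort(
    n: int,
    hazard_ratio: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    baseline_hazard: float = 1.0 / 24.0,
) -> list[SurvivalRecord]:
    """Exponential survival cohort with a planted hazard ratio between groups.

    Half the cohort is "high" (hazard = baseline * hazard_ratio), half "low"
    (baseline, median ~16.6 months at the default rate).  With probability
    ``censor_rate`` a record is independently censored at a uniform fraction
    of its event time.
    """
    if n < 2:
        raise ValueError("need n >= 2 for two non-empty groups")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_high = n // 2
    groups = np.array(["high"] * n_high + ["low"] * (n - n_high))
    rates = np.where(groups == "high", baseline_hazard * hazard_ratio, baseline_hazard)
    times = rng.exponential(1.0 / rates)
    censored = rng.random(n) < censor_rate
    times = np.where(censored, times * rng.random(n), times)
    return [
        SurvivalRecord(
            patient_id=f"pt_{i:04d}",
            time=float(times[i]),
            event=int(not censored[i]),
            group=str(groups[i]),
        )
        for i in range(n)
    ]


# -- plain-text writers --------------------------------------------------------

def write_sc_dataset(adata: ad.AnnData, outdir) -> None:
    """Write counts as MTX with genes.tsv / barcodes.tsv and a metadata CSV."""
    from pathlib import Path

    import scipy.io
    import scipy.sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X if not hasattr(adata.X, "toarray") else adata.X.toarray()
    scipy.io.mmwrite(outdir / "matrix.mtx", scipy.sparse.csr_matrix(x.T))  # genes x cells
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(outdir / "cell_metadata.csv")


def write_slide_bags(slides: list[SyntheticSlide], outdir) -> pd.DataFrame:
    """Write tiles as PNGs plus a bag manifest CSV; returns the manifest."""
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    rows = []
    for slide in slides:
        tile_dir = outdir / slide.slide_id
        tile_dir.mkdir(parents=True, exist_ok=True)
        for i, tile in enumerate(slide.tiles):
            path = tile_dir / f"tile_{i:04d}.png"
            Image.fromarray(tile).save(path)
            rows.append(
                {
                    "slide_id": slide.slide_id,
                    "tile_path": str(path),
                    "signal_flag": int(slide.signal_mask[i]),
                    "label": slide.immune_level,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def write_survival_csv(records: list[SurvivalRecord], path) -> None:
    from .survival import records_to_frame

    records_to_frame(records).to_csv(path, index=False)
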