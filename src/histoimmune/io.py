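"""Plain-text readers for the package's on-disk formats.

Counterparts of the writers in ``synthetic_data``: MTX + TSV sidecars +
metadata CSV for single-cell counts, a manifest CSV over PNG tile
directories for slide bags, and a survival CSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .mil import TileBag
from .survival import SurvivalRecord

__all__ = ["read_sc_dataset", "read_bags_manifest", "read_survival_csv", "read_bulk_csv"]


def read_sc_dataset(indir) -> ad.AnnData:
    """Read MTX (genes x cells) + genes.tsv / barcodes.tsv + cell_metadata.csv."""
    import scipy.io

    indir = Path(indir)
    x = scipy.io.mmread(indir / "matrix.mtx").tocsr().T  # cells x genes
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=np.asarray(x.todense()),
        obs=pd.DataFrame(index=barcodes.to_numpy()),
        var=pd.DataFrame(index=genes.to_numpy()),
    )
    meta_path = indir / "cell_metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col=0)
        adata.obs = meta.loc[adata.obs_names]
    return adata


def read_bags_manifest(manifest_csv) -> tuple[list[TileBag], np.ndarray]:
    """Load tile bags listed in a manifest CSV (slide_id, tile_path, label)."""
    from PIL import Image

    manifest = pd.read_csv(manifest_csv)
    bags, labels = [], []
    for slide_id, rows in manifest.groupby("slide_id", sort=True):
        tiles = np.stack([np.asarray(Image.open(p).convert("RGB")) for p in rows["tile_path"]])
        label = int(rows["label"].iloc[0])
        bags.append(TileBag(slide_id=str(slide_id), instances=tiles, label=label))
        labels.append(label)
    return bags, np.asarray(labels)


def read_survival_csv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    group_col = "group" if "group" in df.columns else None
    return [
        SurvivalRecord(
            patient_id=str(r["patient_id"] if "patient_id" in df.columns else r["id"]),
            time=float(r["time"]),
            event=int(r["event"]),
            group=str(r[group_col]) if group_col else "low",
        )
        for _, r in df.iterrows()
    ]


def read_bulk_csv(path) -> pd.DataFrame:
    """Bulk expression CSV, genes as rows (index) and samples as columns."""
    return pd.read_csv(path, index_col=0)
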