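"""File I/O: TIFF stacks, 10x-style MTX triplets, provenance-stamped CSV."""

from __future__ import annotations

import hashlib
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile
import yaml

from . import __version__
from .imaging import MultiplexImage

__all__ = [
    "read_multiplex_tiff",
    "write_multiplex_tiff",
    "read_counts_mtx",
    "write_counts_mtx",
    "write_csv",
    "config_hash",
]


def write_multiplex_tiff(path: str | Path, img: MultiplexImage) -> None:
    """Write the stack channel-first plus a YAML sidecar with channel roles."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(img.pixels, 2, 0).astype(np.float32))
    sidecar = {"channel_roles": dict(img.channel_roles), "pixel_size": img.pixel_size}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_multiplex_tiff(path: str | Path, channel_roles: dict | None = None) -> MultiplexImage:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a channel stack")
    pixel_size = 1.0
    if channel_roles is None:
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise ValueError(f"{path}: no channel roles given and no sidecar found")
        meta = yaml.safe_load(sidecar.read_text())
        channel_roles = meta["channel_roles"]
        pixel_size = float(meta.get("pixel_size", 1.0))
    return MultiplexImage(np.moveaxis(stack, 0, 2), channel_roles, pixel_size)


def write_counts_mtx(outdir: str | Path, adata: ad.AnnData) -> None:
    """10x-style triplet: matrix.mtx (genes x cells), genes.tsv, barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(outdir / "matrix.mtx", X.T.tocoo())
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")
    adata.obs.to_csv(outdir / "barcodes.tsv", sep="\t")


def read_counts_mtx(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    try:
        X = scipy.io.mmread(indir / "matrix.mtx").T.tocsr()
    except Exception as exc:  # noqa: BLE001 - reader error must name the file
        raise ValueError(f"corrupt MTX file {indir / 'matrix.mtx'}: {exc}") from exc
    var = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(indir / "barcodes.tsv", sep="\t", index_col=0)
    for col in ("mito", "ribo", "hemoglobin"):
        if col in var.columns:
            var[col] = var[col].astype(bool)
    return ad.AnnData(X=X.astype(np.int32), obs=obs, var=var)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_csv(
    path: str | Path, df: pd.DataFrame, seed: int | None = None, cfg_hash: str = "", **kwargs
) -> None:
    """CSV with a provenance header comment (version, seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# routescape v{__version__} seed={seed} config={cfg_hash}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, float_format=kwargs.pop("float_format", "%.6g"), **kwargs)
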