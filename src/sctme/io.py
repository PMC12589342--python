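"""Readers and writers for the on-disk formats the pipeline exchanges.

Counts travel as 10x-style triplets (``matrix.mtx`` in MatrixMarket
coordinate format, genes x cells, plus ``features.tsv`` and
``barcodes.tsv``); annotations and per-specimen tables as headered TSV;
gene sets as GMT.  In memory everything is an :class:`anndata.AnnData`
(cells x genes) or a :class:`pandas.DataFrame`.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

ANNOTATION_COLUMNS = [
    "cell_id",
    "sample_id",
    "group",
    "cluster_id",
    "major_type",
    "mp_subtype",
    "macro_subtype",
]

TISSUE_GROUPS = ("NOR", "RUNX3_Neg", "RUNX3_Pos")


def write_counts_dir(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write an AnnData's raw counts as matrix.mtx + features.tsv + barcodes.tsv.

    The matrix is stored genes x cells (10x convention), integer-valued.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.csr_matrix(adata.X).T.astype(np.int64)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(mat), field="integer")
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    return outdir


def read_counts_dir(indir: str | Path) -> ad.AnnData:
    """Read a matrix.mtx/features.tsv/barcodes.tsv triplet into AnnData (cells x genes)."""
    indir = Path(indir)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing {name} in {indir}")
    mat = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix.mtx is {mat.shape} but features.tsv has {len(genes)} rows "
            f"and barcodes.tsv has {len(cells)} rows"
        )
    adata = ad.AnnData(X=mat.T.tocsr())
    adata.var_names = genes.to_numpy()
    adata.obs_names = cells.to_numpy()
    return adata


def write_annotation(annot: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-cell annotation table as TSV with the canonical column set."""
    path = Path(path)
    out = annot.copy()
    for col in ANNOTATION_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")
    return path


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(annot.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return annot


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping set name -> gene list."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        name, genes = fields[0], [g for g in fields[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")
    return path


def _data_path(name: str):
    return importlib.resources.files("sctme").joinpath("data", name)


def load_marker_yaml() -> dict[str, dict[str, list[str]]]:
    """Load the packaged hierarchical marker reference (levels major/mp/macro)."""
    with importlib.resources.as_file(_data_path("markers.yaml")) as p:
        return yaml.safe_load(p.read_text())


def load_m1m2_sets() -> dict[str, list[str]]:
    """Load the packaged M1/M2 macrophage polarization gene sets."""
    with importlib.resources.as_file(_data_path("m1m2.gmt")) as p:
        return read_gmt(p)


def load_toy_pathways() -> dict[str, list[str]]:
    """Load the packaged toy pathway collection used as a GO/KEGG stand-in."""
    with importlib.resources.as_file(_data_path("toy_pathways.gmt")) as p:
        return read_gmt(p)


def load_lr_pairs_table() -> pd.DataFrame:
    """Load the packaged mini ligand-receptor database."""
    with importlib.resources.as_file(_data_path("lr_pairs.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")
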