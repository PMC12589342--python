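"""Marker-driven hierarchical cell-type annotation.

Cells are normalized (counts-per-target then log1p), embedded by PCA,
clustered by graph community detection (Leiden; k-means available as a
fallback), and each cluster is assigned the cell type whose markers it
expresses most highly: the score of (cluster, type) is the mean, over
the type's markers, of the gene's z-scored (across cells) mean
expression in the cluster.  The procedure runs at three nested levels -
13 major types on all cells, 5 mononuclear-phagocyte subtypes on the
MPs subset, 6 macrophage states on the Macrophages subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from .io import load_marker_yaml

__all__ = [
    "MarkerReference",
    "load_marker_reference",
    "normalize_log",
    "cluster_cells",
    "score_cluster_types",
    "assign_types",
    "annotate_hierarchy",
    "top_markers",
    "AnnotateParams",
]

LEVEL_SIZES = {"major": 13, "mp": 5, "macro": 6}
MACRO_ANCHORS = ("AZU1", "CXCL10", "FABP4", "SELENOP", "SPP1", "STMN1")
LEVEL_COLUMN = {"major": "major_type", "mp": "mp_subtype", "macro": "macro_subtype"}


@dataclass(frozen=True)
class MarkerReference:
    """Marker lists for one annotation level (``major``, ``mp`` or ``macro``)."""

    level: str
    entries: dict[str, list[str]]

    def __post_init__(self):
        if self.level not in LEVEL_SIZES:
            raise ValueError(f"unknown level {self.level!r}")
        if len(self.entries) != LEVEL_SIZES[self.level]:
            raise ValueError(
                f"level {self.level} requires exactly {LEVEL_SIZES[self.level]} "
                f"types, got {len(self.entries)}"
            )
        for t, genes in self.entries.items():
            if not genes:
                raise ValueError(f"type {t} has an empty marker list")
        if self.level == "macro":
            all_genes = {g for genes in self.entries.values() for g in genes}
            missing = set(MACRO_ANCHORS) - all_genes
            if missing:
                raise ValueError(
                    f"macro reference missing anchor genes: {sorted(missing)}"
                )


def load_marker_reference(level: str, path: str | None = None) -> MarkerReference:
    """Load the packaged (or a user-supplied YAML) marker reference."""
    import yaml

    if path is None:
        data = load_marker_yaml()
    else:
        data = yaml.safe_load(open(path).read())
    if level not in data:
        raise ValueError(f"marker file has no level {level!r}")
    return MarkerReference(level=level, entries=dict(data[level]))


# ---------------------------------------------------------------------------


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalize to ``target_sum`` counts per cell, then log1p.

    All-zero cells cannot be scaled; they are dropped with a warning.
    Returns a new AnnData; the input is left untouched.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} all-zero cells from normalization"
        )
    out = adata[keep].copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def cluster_cells(
    norm: ad.AnnData,
    n_components: int = 15,
    resolution_or_k: float = 2.0,
    seed: int = 0,
    method: str = "leiden",
    n_neighbors: int = 15,
    n_hvg: int | None = 200,
    scale: bool = False,
) -> np.ndarray:
    """Partition cells by Leiden community detection on a PCA-kNN graph.

    The matrix is reduced to the ``n_hvg`` most highly variable genes
    (skipped when the matrix is already that small), optionally z-scaled,
    then embedded by PCA.  ``resolution_or_k`` is the Leiden resolution,
    or the number of clusters when ``method="kmeans"``.  Over-clustering
    is benign downstream - several clusters may map to one cell type -
    so the default resolution errs on the fine side.  Deterministic for
    a fixed seed.
    """
    if norm.n_obs < 2:
        raise ValueError("clustering needs at least 2 cells")
    work = norm.copy()
    X = work.X.toarray() if sp.issparse(work.X) else np.asarray(work.X)
    if np.allclose(X.var(axis=0), 0):
        # no structure at all; a single cluster is the only sensible partition
        return np.zeros(work.n_obs, dtype=int)
    if n_hvg is not None and work.n_vars > n_hvg:
        sc.pp.highly_variable_genes(work, n_top_genes=n_hvg)
        work = work[:, work.var.highly_variable].copy()
    if scale:
        sc.pp.scale(work, max_value=10)
    max_comps = min(work.n_obs - 1, work.n_vars - 1)
    if n_components > max_comps:
        warnings.warn(
            f"n_components reduced from {n_components} to {max_comps} "
            "(fewer cells/genes than requested components)"
        )
        n_components = max_comps
    sc.tl.pca(work, n_comps=n_components, svd_solver="arpack", random_state=seed)
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(
            n_clusters=int(resolution_or_k), random_state=seed, n_init=10
        ).fit(work.obsm["X_pca"])
        return km.labels_.astype(int)
    if method != "leiden":
        raise ValueError(f"unknown clustering method {method!r}")
    sc.pp.neighbors(
        work, n_neighbors=min(n_neighbors, work.n_obs - 1), random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            work,
            resolution=float(resolution_or_k),
            random_state=seed,
            flavor="leidenalg",
        )
    return work.obs["leiden"].astype(int).to_numpy()


def score_cluster_types(
    norm: ad.AnnData, labels: np.ndarray, ref: "MarkerReference | dict[str, list[str]]"
) -> pd.DataFrame:
    """Mean z-scored marker expression per (cluster, type).

    Genes are z-scored across all cells (zero-variance genes score 0);
    the (cluster, type) entry averages the cluster means of the type's
    markers.  Markers absent from the matrix are dropped with a warning;
    a type with no present marker raises.  ``ref`` may be a
    :class:`MarkerReference` or a bare type -> markers mapping.
    """
    labels = np.asarray(labels)
    if len(labels) != norm.n_obs:
        raise ValueError("labels length does not match cell count")
    X = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mean) / sd, 0.0)
    gene_idx = {g: i for i, g in enumerate(norm.var_names)}
    clusters = np.unique(labels)
    entries = ref.entries if isinstance(ref, MarkerReference) else dict(ref)
    rows = {}
    for t, genes in entries.items():
        present = [g for g in genes if g in gene_idx]
        absent = [g for g in genes if g not in gene_idx]
        if absent:
            warnings.warn(f"type {t}: dropping absent markers {absent}")
        if not present:
            raise ValueError(f"type {t} has no markers present in the matrix")
        cols = [gene_idx[g] for g in present]
        rows[t] = [Z[labels == c][:, cols].mean() for c in clusters]
    return pd.DataFrame(rows, index=clusters)


def assign_types(score_table: pd.DataFrame) -> pd.DataFrame:
    """Argmax type per cluster; exact ties broken lexicographically and flagged.

    Returns a table indexed by cluster with columns ``type``, ``score``
    and ``tie``.
    """
    ordered = score_table[sorted(score_table.columns)]
    out = []
    for cluster, row in ordered.iterrows():
        best = row.max()
        winners = [t for t in ordered.columns if row[t] == best]
        out.append(
            {"cluster": cluster, "type": winners[0], "score": best,
             "tie": len(winners) > 1}
        )
    return pd.DataFrame(out).set_index("cluster")


@dataclass(frozen=True)
class AnnotateParams:
    """Tunable knobs of one annotation level."""

    target_sum: float = 1e4
    n_components: int = 15
    resolution: float = 2.0
    n_neighbors: int = 15
    n_hvg: int | None = 200
    scale: bool = False
    method: str = "leiden"
    seed: int = 0


def _annotate_level(
    adata: ad.AnnData, ref: MarkerReference, params: AnnotateParams
) -> tuple[pd.Series, pd.Series]:
    """Run normalize -> cluster -> score -> assign; per-cell type and cluster id."""
    norm = normalize_log(adata, target_sum=params.target_sum)
    labels = cluster_cells(
        norm,
        n_components=params.n_components,
        resolution_or_k=params.resolution,
        seed=params.seed,
        method=params.method,
        n_neighbors=params.n_neighbors,
        n_hvg=params.n_hvg,
        scale=params.scale,
    )
    scores = score_cluster_types(norm, labels, ref)
    mapping = assign_types(scores)
    types = pd.Series(
        [mapping.loc[c, "type"] for c in labels], index=norm.obs_names
    )
    clusters = pd.Series(labels, index=norm.obs_names)
    return types, clusters


def annotate_hierarchy(
    adata: ad.AnnData,
    metadata: pd.DataFrame,
    refs: dict[str, MarkerReference] | None = None,
    params: AnnotateParams | dict[str, AnnotateParams] | None = None,
    mp_type: str = "MPs",
    macrophage_type: str = "Macrophages",
) -> pd.DataFrame:
    """Three-level annotation: all cells -> MPs subset -> Macrophages subset.

    ``metadata`` must carry ``sample_id`` and ``group`` per cell (index =
    cell ids).  Returns a CellAnnotation table; ``mp_subtype`` is filled
    only for MPs, ``macro_subtype`` only for Macrophages.  Empty subsets
    skip their level with a warning.
    """
    if refs is None:
        refs = {lvl: load_marker_reference(lvl) for lvl in ("major", "mp", "macro")}
    if params is None:
        params = AnnotateParams()
    if isinstance(params, AnnotateParams):
        params = {lvl: params for lvl in ("major", "mp", "macro")}

    meta = metadata.copy()
    if "cell_id" in meta.columns:
        meta = meta.set_index("cell_id")
    missing = set(adata.obs_names) - set(meta.index)
    if missing:
        raise ValueError(f"{len(missing)} cells missing from metadata")
    meta = meta.loc[adata.obs_names]

    annot = pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "sample_id": meta["sample_id"].to_numpy(),
            "group": meta["group"].to_numpy(),
        },
        index=adata.obs_names,
    )
    annot["cluster_id"] = -1
    annot["major_type"] = ""
    annot["mp_subtype"] = ""
    annot["macro_subtype"] = ""

    major_types, major_clusters = _annotate_level(adata, refs["major"], params["major"])
    annot.loc[major_types.index, "major_type"] = major_types
    annot.loc[major_clusters.index, "cluster_id"] = major_clusters

    mp_cells = annot.index[annot["major_type"] == mp_type]
    if len(mp_cells) >= 2:
        sub_types, _ = _annotate_level(
            adata[mp_cells].copy(), refs["mp"], params["mp"]
        )
        annot.loc[sub_types.index, "mp_subtype"] = sub_types
    else:
        warnings.warn(f"no {mp_type} cells; skipping MP-subtype annotation")

    macro_cells = annot.index[annot["mp_subtype"] == macrophage_type]
    if len(macro_cells) >= 2:
        sub_types, _ = _annotate_level(
            adata[macro_cells].copy(), refs["macro"], params["macro"]
        )
        annot.loc[sub_types.index, "macro_subtype"] = sub_types
    else:
        warnings.warn(
            f"no {macrophage_type} cells; skipping macrophage-state annotation"
        )
    return annot.reset_index(drop=True)


def top_markers(
    norm: ad.AnnData,
    labels,
    n: int = 30,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Top one-vs-rest marker genes per type, ranked by log2 fold change.

    For each type, genes are ranked by ``log2((mean_in + c)/(mean_rest + c))``
    on the normalized scale; Wilcoxon rank-sum p-values (vs rest) and BH
    q-values accompany the ranking.
    """
    from .de import wilcoxon_de

    labels = pd.Series(np.asarray(labels), index=norm.obs_names)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("top_markers needs at least 2 types")
    n = min(n, norm.n_vars)
    frames = []
    for t in types:
        cells_a = labels.index[labels == t]
        cells_b = labels.index[labels != t]
        de = wilcoxon_de(norm, cells_a, cells_b, pseudocount=pseudocount)
        de = de.sort_values("log2fc", ascending=False).head(n)
        de.insert(0, "type", t)
        de["rank"] = np.arange(1, len(de) + 1)
        frames.append(de)
    return pd.concat(frames, ignore_index=True)
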