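"""Wilcoxon differential expression and hypergeometric over-representation.

DE between two cell groups uses the two-sided Wilcoxon rank-sum test
per gene (exact for tiny tie-free samples, normal approximation with
tie correction otherwise; the continuity correction is disabled so
identical groups give exactly p = 1) with a pseudocount log2 fold
change on normalized means and Benjamini-Hochberg adjustment.
Over-representation of a query gene list in a gene-set collection uses
the upper-tail hypergeometric test against a declared gene universe.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

__all__ = [
    "wilcoxon_de",
    "bh_adjust",
    "volcano_classify",
    "hypergeom_ora",
]


def _dense(norm: ad.AnnData, cells) -> np.ndarray:
    sub = norm[list(cells)]
    X = sub.X
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def wilcoxon_de(
    norm: ad.AnnData,
    cells_a,
    cells_b,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene rank-sum comparison of group a vs group b.

    ``norm`` holds log1p-normalized expression; means are reported on
    the pre-log normalized scale (expm1 of the stored values, the usual
    single-cell convention, so planted fold changes survive the log).
    Returns gene/mean_a/mean_b/log2fc/p/q with ``direction`` initialized
    to ``ns`` (fill it with :func:`volcano_classify`).  ``log2fc`` is
    ``log2((mean_a + c) / (mean_b + c))``.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    A = _dense(norm, cells_a)
    B = _dense(norm, cells_b)
    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.mannwhitneyu(
            A, B, axis=0, alternative="two-sided", use_continuity=False
        )
    p = np.asarray(res.pvalue, dtype=float)
    # constant genes carry no rank information: p = 1 by convention
    pooled_const = (A.std(axis=0) == 0) & (B.std(axis=0) == 0) & (mean_a == mean_b)
    p = np.where(pooled_const | np.isnan(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "gene": norm.var_names,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": p,
            "q": bh_adjust(p),
            "direction": "ns",
        }
    )
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def volcano_classify(
    results: pd.DataFrame, lfc_cut: float = 1.0, q_cut: float = 0.05
) -> pd.DataFrame:
    """Fill ``direction``: up/down when |log2fc| >= cut and q < q_cut, else ns."""
    out = results.copy()
    up = (out["log2fc"] >= lfc_cut) & (out["q"] < q_cut)
    down = (out["log2fc"] <= -lfc_cut) & (out["q"] < q_cut)
    out["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def hypergeom_ora(
    query,
    collection: dict[str, list[str]],
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Sets are intersected with the universe; the query must be a subset
    of the universe.  Returns one row per set (set/k/K/n/N/p/q), BH
    adjusted across sets and sorted by p.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("query gene list is empty")
    if not universe:
        raise ValueError("universe is empty")
    stray = query - universe
    if stray:
        raise ValueError(
            f"{len(stray)} query genes outside the universe, e.g. "
            f"{sorted(stray)[:3]}"
        )
    N_u, n = len(universe), len(query)
    rows = []
    for name, genes in collection.items():
        members = set(genes) & universe
        K = len(members)
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N_u, K, n)
        p = float(scipy.stats.hypergeom.sf(k - 1, N_u, K, n)) if K else 1.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N_u,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p"] = out["p"].clip(lower=np.finfo(float).tiny, upper=1.0)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)
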