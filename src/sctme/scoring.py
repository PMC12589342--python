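"""Gene-set module scores (M1/M2 macrophage programs) and group comparisons.

A module score for a cell is the mean normalized expression of the set
genes minus the mean of control genes drawn, per set gene, from the
same average-expression bin — the standard control-matched "module
score" convention of single-cell work.  Scores are summarized per
tissue group or macrophage state as mean/sd/n with a z-score of the
group means, compared by Student/Welch t-test (two groups) or one-way
ANOVA (three or more), and annotated with the usual significance stars
(* P<0.05, ** P<0.01, *** P<0.001, strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import load_m1m2_sets

__all__ = [
    "GeneSet",
    "module_score",
    "summarize_scores",
    "m1_m2_report",
    "stars",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")


def stars(p: float) -> str:
    """Significance label for a p-value; boundaries are strict (<)."""
    if np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def module_score(
    norm: ad.AnnData,
    gene_set: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Control-matched per-cell score of a gene set.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-size bins; each set gene contributes ``n_ctrl``
    control genes sampled (without replacement where possible) from its
    bin, excluding set genes.  Score = mean(set) - mean(controls).
    Missing set genes are dropped with a warning; a fully absent set
    raises.  Reproducible from ``seed``.
    """
    gene_idx = {g: i for i, g in enumerate(norm.var_names)}
    present = [g for g in gene_set.genes if g in gene_idx]
    absent = [g for g in gene_set.genes if g not in gene_idx]
    if absent:
        warnings.warn(f"gene set {gene_set.name}: dropping absent genes {absent}")
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")

    X = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X, dtype=float)
    gene_mean = X.mean(axis=0)
    order = np.argsort(gene_mean, kind="stable")
    n_bins_eff = min(n_bins, norm.n_vars)
    bin_of = np.empty(norm.n_vars, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins_eff)):
        bin_of[chunk] = b

    rng = np.random.default_rng(seed)
    set_idx = np.array([gene_idx[g] for g in present])
    set_mask = np.zeros(norm.n_vars, dtype=bool)
    set_mask[set_idx] = True
    ctrl: list[np.ndarray] = []
    for gi in set_idx:
        # widen to neighboring expression bins if the home bin holds only
        # set genes, so controls always come from non-set genes
        width = 0
        pool = np.array([], dtype=int)
        while len(pool) == 0 and width < n_bins_eff:
            in_bins = np.abs(bin_of - bin_of[gi]) <= width
            pool = np.flatnonzero(in_bins & ~set_mask)
            width += 1
        if len(pool) == 0:  # the set covers the whole matrix
            pool = np.flatnonzero(bin_of == bin_of[gi])
        take = min(n_ctrl, len(pool))
        ctrl.append(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.unique(np.concatenate(ctrl))
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def summarize_scores(
    scores: np.ndarray,
    labels,
    test: str = "welch",
) -> pd.DataFrame:
    """Per-group score summary with a shared cross-group test.

    Two groups are compared by a t-test (``test='welch'`` for unequal
    variances, ``'student'`` for the pooled-variance form), three or
    more by one-way ANOVA.  The z-score column standardizes the group
    means across groups (all 0 when the means do not vary).  Groups
    with fewer than 2 cells are excluded from testing with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = pd.Series(np.asarray(labels))
    if len(labels) != len(scores):
        raise ValueError("labels and scores lengths differ")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("summarize_scores needs at least 2 groups")
    per_group = {g: scores[(labels == g).to_numpy()] for g in groups}
    testable = {g: v for g, v in per_group.items() if len(v) >= 2}
    dropped = sorted(set(groups) - set(testable))
    if dropped:
        warnings.warn(f"groups with n < 2 excluded from testing: {dropped}")
    if len(testable) >= 3:
        p = float(scipy.stats.f_oneway(*testable.values()).pvalue)
    elif len(testable) == 2:
        a, b = testable.values()
        p = float(
            scipy.stats.ttest_ind(a, b, equal_var=(test == "student")).pvalue
        )
    else:
        p = float("nan")

    means = np.array([per_group[g].mean() for g in groups])
    msd = means.std()
    z = (means - means.mean()) / msd if msd > 0 else np.zeros_like(means)
    return pd.DataFrame(
        {
            "entity": groups,
            "mean": means,
            "sd": [per_group[g].std(ddof=1) if len(per_group[g]) > 1 else np.nan
                   for g in groups],
            "n": [len(per_group[g]) for g in groups],
            "z": z,
            "p": p,
            "star": stars(p),
        }
    )


def m1_m2_report(
    norm: ad.AnnData,
    annotation: pd.DataFrame,
    gene_sets: dict[str, list[str]] | None = None,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """M1 and M2 score summaries over tissue groups and macrophage states.

    Scores are computed on the annotated macrophage cells (non-empty
    ``macro_subtype``) and summarized twice: grouped by tissue group and
    grouped by macrophage state.  Returns a tidy table with columns
    set/grouping/entity/mean/sd/n/z/p/star.
    """
    if gene_sets is None:
        gene_sets = load_m1m2_sets()
    annot = annotation.set_index("cell_id") if "cell_id" in annotation.columns \
        else annotation
    macro = annot.index[
        annot["macro_subtype"].notna() & (annot["macro_subtype"].astype(str) != "")
    ]
    macro = [c for c in macro if c in set(norm.obs_names)]
    if not macro:
        raise ValueError(
            "no cells carry a macrophage-state label; run annotate_hierarchy first"
        )
    sub = norm[macro].copy()
    frames = []
    for set_name, genes in gene_sets.items():
        score = module_score(
            sub, GeneSet(set_name, tuple(genes)), n_bins=n_bins, n_ctrl=n_ctrl,
            seed=seed,
        )
        for grouping, column in (("group", "group"), ("macro_subtype", "macro_subtype")):
            summary = summarize_scores(score, annot.loc[macro, column])
            summary.insert(0, "grouping", grouping)
            summary.insert(0, "set", set_name)
            frames.append(summary)
    return pd.concat(frames, ignore_index=True)
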