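"""Ligand-receptor interaction screening with a permutation null.

A pair's interaction score between a sender and a receiver population
is the product of the ligand's mean normalized expression in senders
and the receptor's mean in receivers; multi-gene complexes contribute
their least-expressed member (so one silent subunit nullifies the
complex).  Significance comes from jointly shuffling the
sender/receiver labels: p = (1 + #{permuted >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import load_lr_pairs_table

__all__ = ["LRPair", "LRResult", "lr_score", "permutation_test", "load_lr_pairs"]


@dataclass(frozen=True)
class LRPair:
    name: str
    ligand: tuple[str, ...]
    receptor: tuple[str, ...]

    def __post_init__(self):
        if not self.ligand or not self.receptor:
            raise ValueError(f"pair {self.name!r} has an empty complex")


@dataclass(frozen=True)
class LRResult:
    pair: str
    sender: str
    receiver: str
    score: float
    p: float
    n_perm: int


def load_lr_pairs(path=None) -> list[LRPair]:
    """Load LR pairs from TSV (packaged mini database by default)."""
    table = load_lr_pairs_table() if path is None else pd.read_csv(
        path, sep="\t", comment="#"
    )
    pairs = []
    for row in table.itertuples(index=False):
        pairs.append(
            LRPair(
                name=str(row.pair),
                ligand=tuple(str(row.ligand_genes).split(",")),
                receptor=tuple(str(row.receptor_genes).split(",")),
            )
        )
    return pairs


def _complex_mean(X: np.ndarray, cols: list[int]) -> float:
    """Min-over-members of per-gene mean expression (CellPhoneDB-style)."""
    return float(min(X[:, c].mean() for c in cols))


def lr_score(
    norm: ad.AnnData,
    sender_cells,
    receiver_cells,
    pair: LRPair,
) -> float | None:
    """Interaction score; ``None`` (with a warning) if any gene is absent."""
    sender_cells, receiver_cells = list(sender_cells), list(receiver_cells)
    if not sender_cells or not receiver_cells:
        raise ValueError("sender and receiver populations must be non-empty")
    gene_idx = {g: i for i, g in enumerate(norm.var_names)}
    missing = [g for g in (*pair.ligand, *pair.receptor) if g not in gene_idx]
    if missing:
        warnings.warn(f"pair {pair.name}: genes absent, skipping ({missing})")
        return None
    X = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X, dtype=float)
    obs_idx = {c: i for i, c in enumerate(norm.obs_names)}
    s = np.array([obs_idx[c] for c in sender_cells])
    r = np.array([obs_idx[c] for c in receiver_cells])
    lig = _complex_mean(X[s], [gene_idx[g] for g in pair.ligand])
    rec = _complex_mean(X[r], [gene_idx[g] for g in pair.receptor])
    return lig * rec


def permutation_test(
    norm: ad.AnnData,
    sender_cells,
    receiver_cells,
    pairs: list[LRPair],
    n_perm: int = 999,
    seed: int = 0,
    sender_name: str = "sender",
    receiver_name: str = "receiver",
) -> list[LRResult]:
    """Permutation p-values for LR pairs between two cell populations.

    Labels are shuffled jointly over the union of sender and receiver
    cells, preserving the two population sizes; pairs with absent genes
    are skipped (warned inside :func:`lr_score`).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sender_cells, receiver_cells = list(sender_cells), list(receiver_cells)
    if not sender_cells or not receiver_cells:
        raise ValueError("sender and receiver populations must be non-empty")
    gene_idx = {g: i for i, g in enumerate(norm.var_names)}
    kept: list[LRPair] = []
    for p in pairs:
        missing = [g for g in (*p.ligand, *p.receptor) if g not in gene_idx]
        if missing:
            warnings.warn(f"pair {p.name}: genes absent, skipping ({missing})")
        else:
            kept.append(p)
    if not kept:
        return []

    # one dense slice of the genes in play, over the pooled cells
    involved = sorted({gene_idx[g] for p in kept for g in (*p.ligand, *p.receptor)})
    col_of = {gi: c for c, gi in enumerate(involved)}
    pool_cells = sender_cells + receiver_cells
    sub = norm[pool_cells, :][:, involved]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    n_s = len(sender_cells)

    def score_split(s_rows: np.ndarray, r_rows: np.ndarray, p: LRPair) -> float:
        lig = min(X[s_rows, col_of[gene_idx[g]]].mean() for g in p.ligand)
        rec = min(X[r_rows, col_of[gene_idx[g]]].mean() for g in p.receptor)
        return float(lig * rec)

    s_rows = np.arange(n_s)
    r_rows = np.arange(n_s, len(pool_cells))
    obs = {p.name: score_split(s_rows, r_rows, p) for p in kept}

    rng = np.random.default_rng(seed)
    exceed = {p.name: 0 for p in kept}
    for _ in range(n_perm):
        perm = rng.permutation(len(pool_cells))
        ps, pr = perm[:n_s], perm[n_s:]
        for p in kept:
            if score_split(ps, pr, p) >= obs[p.name]:
                exceed[p.name] += 1
    return [
        LRResult(
            pair=p.name,
            sender=sender_name,
            receiver=receiver_name,
            score=obs[p.name],
            p=(1 + exceed[p.name]) / (n_perm + 1),
            n_perm=n_perm,
        )
        for p in kept
    ]


def results_table(results: list[LRResult]) -> pd.DataFrame:
    cols = ["pair", "sender", "receiver", "score", "p", "n_perm"]
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)
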