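"""Ro/e tissue-preference statistics over cell types x tissue groups.

For a contingency table of cell counts O(i,j) (cell type i, tissue
group j), the expected count under independence is the chi-squared
expectation E(i,j) = row_i * col_j / N, and the enrichment ratio is
R(i,j) = O(i,j)/E(i,j).  R > 1 marks a tissue preference of the type,
R < 1 a depletion; the call uses a strict inequality, so R exactly 1 is
not a preference.  Entries in a zero row or column have no defined
expectation and are reported as missing rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["RoeTable", "contingency", "roe", "preference_calls"]


@dataclass
class RoeTable:
    """Observed, expected and Ro/e tables plus a global chi-squared p-value.

    The chi-squared p-value is reported for context only; preference
    calls are made per entry from R alone, without multiplicity
    correction.
    """

    observed: pd.DataFrame
    expected: pd.DataFrame
    ratio: pd.DataFrame
    N: int
    chi2_p: float


def contingency(
    annotation: pd.DataFrame,
    type_field: str = "major_type",
    group_field: str = "group",
) -> pd.DataFrame:
    """Cross-tabulate cells into a types x groups count table.

    Cells with a null/empty type or group are excluded (their number is
    reported via a warning-free return attribute ``attrs['n_excluded']``).
    Categories declared as pandas Categoricals are retained even at zero
    count.
    """
    if annotation.empty:
        raise ValueError("annotation table is empty")
    for fld in (type_field, group_field):
        if fld not in annotation.columns:
            raise ValueError(f"annotation lacks column {fld!r}")
    t = annotation[type_field]
    g = annotation[group_field]
    valid = t.notna() & g.notna() & (t.astype(str) != "") & (g.astype(str) != "")
    table = pd.crosstab(t[valid], g[valid], dropna=False)
    table.index.name = type_field
    table.columns.name = group_field
    table.attrs["n_excluded"] = int((~valid).sum())
    return table


def roe(observed: pd.DataFrame) -> RoeTable:
    """Compute E = row*col/N and R = O/E for a count table.

    Rows or columns with zero totals yield undefined (NaN) expected
    counts and ratios for their entries.
    """
    O = observed.to_numpy(dtype=float)
    if O.min() < 0:
        raise ValueError("counts must be non-negative")
    N = O.sum()
    if N <= 0:
        raise ValueError("contingency table has no cells")
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    E = row @ col / N
    defined = (row > 0) & (col > 0)
    E = np.where(defined, E, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = O / E
    nz = observed.loc[observed.sum(axis=1) > 0, observed.sum(axis=0) > 0]
    if nz.shape[0] > 1 and nz.shape[1] > 1:
        chi2_p = float(scipy.stats.chi2_contingency(nz.to_numpy()).pvalue)
    else:
        chi2_p = float("nan")
    idx, cols = observed.index, observed.columns
    return RoeTable(
        observed=observed.copy(),
        expected=pd.DataFrame(E, index=idx, columns=cols),
        ratio=pd.DataFrame(R, index=idx, columns=cols),
        N=int(round(N)),
        chi2_p=chi2_p,
    )


def preference_calls(
    roe_table: RoeTable, threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boolean preference table (R > threshold, strict) and a tidy listing.

    The long table has one row per (type, group) with O, E, Ro/e and the
    call, sorted by Ro/e descending; undefined entries keep NaN and are
    never called preferred.
    """
    R = roe_table.ratio
    preferred = R.gt(threshold) & R.notna()
    long = pd.DataFrame(
        [
            {
                "type": i,
                "group": j,
                "O": roe_table.observed.loc[i, j],
                "E": roe_table.expected.loc[i, j],
                "roe": R.loc[i, j],
            }
            for i in R.index
            for j in R.columns
        ]
    )
    long["preferred"] = (long["roe"] > threshold) & long["roe"].notna()
    long = long.sort_values("roe", ascending=False, na_position="last").reset_index(
        drop=True
    )
    return preferred, long
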