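"""Semiquantitative RUNX3 immunohistochemistry scoring.

Two components are rated on 0-2 point scales and summed into a 0-4
composite: the percentage of positively stained cells (<10% -> 0,
10-50% -> 1, >50% -> 2) and the staining intensity (no/weak -> 0,
moderate -> 1, strong -> 2).  Specimens with a composite of 0-2 form
the RUNX3-negative group, 3-4 the RUNX3-positive group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IHCSpecimen",
    "rate_percentage",
    "rate_intensity",
    "score_and_group",
    "read_specimens",
    "write_specimens",
]

INTENSITY_POINTS = {"none": 0, "weak": 0, "moderate": 1, "strong": 2}
NEGATIVE_MAX_SCORE = 2  # composite 0-2 -> RUNX3_Neg, 3-4 -> RUNX3_Pos


@dataclass(frozen=True)
class IHCSpecimen:
    """One scored specimen; ``group`` follows the composite-score rule."""

    specimen_id: str
    percent_positive: float
    intensity: str
    percent_points: int
    intensity_points: int
    overall_score: int
    group: str


def rate_percentage(percent_positive: float) -> int:
    """Points for the percentage of positively stained cells.

    Bins: <10% -> 0; 10-50% (both ends included) -> 1; >50% -> 2.
    """
    if percent_positive is None or pd.isna(percent_positive):
        raise ValueError("percent_positive is missing")
    p = float(percent_positive)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent_positive {p} outside [0, 100]")
    if p < 10.0:
        return 0
    if p <= 50.0:
        return 1
    return 2


def rate_intensity(intensity: str) -> int:
    """Points for staining intensity: none/weak 0, moderate 1, strong 2."""
    key = str(intensity).strip().lower()
    if key not in INTENSITY_POINTS:
        raise ValueError(
            f"unknown staining intensity {intensity!r}; "
            f"expected one of {sorted(set(INTENSITY_POINTS))}"
        )
    return INTENSITY_POINTS[key]


def score_and_group(
    specimens: Iterable[tuple[str, float, str]] | pd.DataFrame,
) -> list[IHCSpecimen]:
    """Complete composite scores and Pos/Neg grouping for a cohort.

    Accepts ``(specimen_id, percent_positive, intensity)`` tuples or a
    DataFrame with those columns.  Validation failures are re-raised
    with the offending specimen id.
    """
    if isinstance(specimens, pd.DataFrame):
        records: Sequence[tuple[str, float, str]] = list(
            specimens[["specimen_id", "percent_positive", "intensity"]]
            .itertuples(index=False, name=None)
        )
    else:
        records = list(specimens)
    out = []
    for spec_id, percent, intensity in records:
        try:
            pp = rate_percentage(percent)
            ip = rate_intensity(intensity)
        except ValueError as exc:
            raise ValueError(f"specimen {spec_id}: {exc}") from exc
        overall = pp + ip
        group = "RUNX3_Neg" if overall <= NEGATIVE_MAX_SCORE else "RUNX3_Pos"
        out.append(
            IHCSpecimen(
                specimen_id=str(spec_id),
                percent_positive=float(percent),
                intensity=str(intensity).strip().lower(),
                percent_points=pp,
                intensity_points=ip,
                overall_score=overall,
                group=group,
            )
        )
    return out


def read_specimens(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"specimen_id", "percent_positive", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    return df


def write_specimens(specimens: Sequence[IHCSpecimen], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([s.__dict__ for s in specimens]).to_csv(path, sep="\t", index=False)
    return path
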