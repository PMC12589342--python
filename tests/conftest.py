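"""Shared fixtures: expensive scenario pipelines run once per session."""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from sctme import annotate, simulate

SCENARIO_LEVEL = {"major13": "major", "mp5": "mp", "macro6": "macro"}
SCENARIO_COLUMN = {
    "major13": "major_type",
    "mp5": "mp_subtype",
    "macro6": "macro_subtype",
}

_cache: dict[str, SimpleNamespace] = {}


def _run_scenario(scenario: str) -> SimpleNamespace:
    """Simulate a scenario at study scale and run the annotation pipeline."""
    if scenario not in _cache:
        cfg = simulate.default_config(scenario, seed=1)
        ds = simulate.simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = annotate.normalize_log(ds.adata)
            labels = annotate.cluster_cells(norm, seed=1)
        ref = annotate.load_marker_reference(SCENARIO_LEVEL[scenario])
        scores = annotate.score_cluster_types(norm, labels, ref)
        mapping = annotate.assign_types(scores)
        assigned = np.array([mapping.loc[c, "type"] for c in labels])
        _cache[scenario] = SimpleNamespace(
            cfg=cfg,
            dataset=ds,
            norm=norm,
            cluster_labels=labels,
            assigned=assigned,
            truth=ds.truth[SCENARIO_COLUMN[scenario]].to_numpy(),
        )
    return _cache[scenario]


@pytest.fixture(scope="session")
def scenario_run():
    """Callable fixture: scenario name -> pipeline results at 5,000 cells."""
    return _run_scenario


@pytest.fixture(scope="session")
def small_dataset():
    """A small flat two-type dataset for cheap unit tests."""
    cfg = simulate.SimulationConfig(
        n_genes=60,
        populations=(
            simulate.Population(("A",), ("MA1", "MA2", "MA3"), 8.0),
            simulate.Population(("B",), ("MB1", "MB2", "MB3"), 8.0),
        ),
        group_proportions={
            "g1": {"A": 0.5, "B": 0.5},
            "g2": {"A": 0.5, "B": 0.5},
        },
        samples=(("s1", "g1"), ("s2", "g2")),
        n_cells_per_sample=150,
        seed=7,
        level_names=("major_type",),
    )
    return simulate.simulate_dataset(cfg)
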