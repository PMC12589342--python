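"""Synthetic single-cell cohorts with planted hierarchical cell types.

The generator emulates a lung-cancer cohort of tumor and adjacent-normal
samples in three tissue groups (``NOR``, ``RUNX3_Neg``, ``RUNX3_Pos``).
Cell types are planted as a tree (major type -> mononuclear-phagocyte
subtype -> macrophage state); each population overexpresses a small set
of marker genes by a fixed fold over a log-normal gene baseline, counts
are negative-binomial with a shared dispersion and a per-cell log-normal
library-size factor.  Group-specific composition shifts encode the
qualitative tissue-preference directions the downstream Ro/e statistic
is expected to recover (fibroblasts the only type enriched in
``RUNX3_Pos``; macrophages depleted / monocytes enriched in
``RUNX3_Neg``; the six macrophage states with their characteristic
enrichment signs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import TISSUE_GROUPS, load_marker_yaml

__all__ = [
    "ConfigError",
    "Population",
    "SimulationConfig",
    "SyntheticDataset",
    "default_config",
    "simulate_dataset",
    "planted_roe",
]

LEVEL_COLUMNS = ("major_type", "mp_subtype", "macro_subtype")

DEFAULT_SAMPLES = [
    ("NOR1", "NOR"),
    ("NOR2", "NOR"),
    ("NOR3", "NOR"),
    ("NEG1", "RUNX3_Neg"),
    ("NEG2", "RUNX3_Neg"),
    ("NEG3", "RUNX3_Neg"),
    ("POS1", "RUNX3_Pos"),
    ("POS2", "RUNX3_Pos"),
    ("POS3", "RUNX3_Pos"),
    ("POS4", "RUNX3_Pos"),
]

# Planted per-group composition, (NOR, RUNX3_Neg, RUNX3_Pos).  Magnitudes are
# free choices; only the sign of each type's deviation from its cohort-wide
# (cell-count-weighted) mean is meaningful, and it encodes the qualitative
# enrichment directions described above.
MAJOR13_PROPORTIONS = {
    "CancerCells": (0.02, 0.20, 0.08),
    "AT2": (0.16, 0.03, 0.06),
    "ClubCells": (0.04, 0.08, 0.04),
    "CiliatedCells": (0.04, 0.08, 0.04),
    "ECs": (0.13, 0.04, 0.06),
    "Fibroblasts": (0.03, 0.10, 0.32),
    "PlasmaCells": (0.03, 0.07, 0.03),
    "BCells": (0.04, 0.08, 0.04),
    "TCells": (0.22, 0.10, 0.14),
    "Neutrophils": (0.03, 0.06, 0.03),
    "MastCells": (0.02, 0.04, 0.02),
    "MPs": (0.22, 0.08, 0.12),
    "pDCs": (0.02, 0.04, 0.02),
}

MP5_PROPORTIONS = {
    "Macrophages": (0.58, 0.35, 0.59),
    "Monocytes": (0.25, 0.39, 0.18),
    "MatureDCs": (0.04, 0.09, 0.08),
    "cDC1": (0.08, 0.03, 0.04),
    "cDC2": (0.05, 0.14, 0.11),
}

MACRO6_PROPORTIONS = {
    "Macrophages_AZU1": (0.08, 0.03, 0.12),
    "Macrophages_CXCL10": (0.08, 0.16, 0.14),
    "Macrophages_FABP4": (0.54, 0.22, 0.23),
    "Macrophages_SELENOP": (0.12, 0.20, 0.19),
    "Macrophages_SPP1": (0.12, 0.24, 0.20),
    "Macrophages_STMN1": (0.06, 0.15, 0.12),
}

SCENARIOS = ("major13", "mp5", "macro6", "full")


class ConfigError(ValueError):
    """Raised when a :class:`SimulationConfig` violates its invariants."""


@dataclass(frozen=True)
class Population:
    """One planted cell population.

    ``path`` places the population in the type tree, e.g. ``("MPs",)``,
    ``("MPs", "Macrophages")`` or ``("MPs", "Macrophages",
    "Macrophages_SPP1")``.  ``markers`` are genes overexpressed by
    ``fold`` in cells of this population (and, for internal nodes, in
    all descendant populations).
    """

    path: tuple[str, ...]
    markers: tuple[str, ...]
    fold: float = 8.0

    @property
    def name(self) -> str:
        return self.path[-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic cohort."""

    n_genes: int
    populations: tuple[Population, ...]
    group_proportions: dict[str, dict[str, float]]
    samples: tuple[tuple[str, str], ...] = tuple(DEFAULT_SAMPLES)
    n_cells_per_sample: int = 500
    nb_dispersion: float = 10.0
    baseline_log_mean: float = -0.5
    baseline_log_sd: float = 1.0
    marker_baseline: float = 1.0
    library_size_sd: float = 0.3
    seed: int = 0
    exact_proportions: bool = True
    level_names: tuple[str, ...] = ("major_type",)
    fixed_levels: dict[str, str] = field(default_factory=dict)

    # -- structure helpers -------------------------------------------------
    def children(self, parent: tuple[str, ...]) -> list[Population]:
        return [p for p in self.populations if p.path[:-1] == parent]

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_cells_per_sample <= 0:
            raise ConfigError("n_cells_per_sample must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.library_size_sd < 0:
            raise ConfigError("library_size_sd must be non-negative")
        if not self.populations:
            raise ConfigError("at least one population is required")
        paths = [p.path for p in self.populations]
        if len(set(paths)) != len(paths):
            raise ConfigError("duplicate population paths")
        path_set = set(paths)
        for p in self.populations:
            if len(p.path) > 1 and p.path[:-1] not in path_set:
                raise ConfigError(f"population {p.path} has no parent in the tree")
            if not p.markers:
                raise ConfigError(f"population {p.name} has an empty marker list")
            if p.fold < 1:
                raise ConfigError(f"population {p.name} has marker fold < 1")
        seen: dict[str, str] = {}
        for p in self.populations:
            for g in p.markers:
                if g in seen:
                    raise ConfigError(
                        f"marker {g} appears in both {seen[g]} and {p.name}"
                    )
                seen[g] = p.name
        if self.n_genes < len(seen):
            raise ConfigError(
                f"n_genes={self.n_genes} smaller than the {len(seen)} marker genes"
            )
        if max(len(p.path) for p in self.populations) > len(self.level_names):
            raise ConfigError("tree deeper than level_names")
        groups = {g for _, g in self.samples}
        for group in groups:
            if group not in self.group_proportions:
                raise ConfigError(f"no proportions for group {group}")
            props = self.group_proportions[group]
            # each sibling block must be a probability vector
            parents = {p.path[:-1] for p in self.populations}
            for parent in parents:
                sibs = self.children(parent)
                if not sibs:
                    continue
                total = 0.0
                for s in sibs:
                    if s.name not in props:
                        raise ConfigError(
                            f"group {group} lacks a proportion for {s.name}"
                        )
                    v = props[s.name]
                    if not 0.0 <= v <= 1.0:
                        raise ConfigError(
                            f"proportion for {s.name} in {group} outside [0,1]"
                        )
                    total += v
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"proportions under {parent or 'root'} in group {group} "
                        f"sum to {total}, not 1"
                    )

    def gene_names(self) -> list[str]:
        markers = [g for p in self.populations for g in p.markers]
        n_bg = self.n_genes - len(markers)
        return markers + [f"BG{i:04d}" for i in range(1, n_bg + 1)]


@dataclass
class SyntheticDataset:
    """Simulated counts plus the ground-truth per-cell annotation."""

    adata: ad.AnnData
    truth: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# scenario construction


def _flat_populations(entries: dict[str, list[str]], fold: float) -> tuple[Population, ...]:
    return tuple(
        Population(path=(name,), markers=tuple(genes), fold=fold)
        for name, genes in entries.items()
    )


def _group_props(table: dict[str, tuple[float, float, float]]) -> dict[str, dict[str, float]]:
    return {
        group: {name: row[i] for name, row in table.items()}
        for i, group in enumerate(TISSUE_GROUPS)
    }


def default_config(scenario: str, *, marker_fold: float = 8.0, seed: int = 0,
                   n_cells_per_sample: int = 500) -> SimulationConfig:
    """Build the packaged scenario configurations.

    ``major13`` plants the 13 major cell types of the atlas, ``mp5`` the
    five mononuclear-phagocyte subtypes, ``macro6`` the six-gene
    macrophage classification, and ``full`` the complete three-level
    hierarchy (mp5 nested under MPs, macro6 under Macrophages).
    """
    markers = load_marker_yaml()
    if scenario == "major13":
        cfg = SimulationConfig(
            n_genes=1000,
            populations=_flat_populations(markers["major"], marker_fold),
            group_proportions=_group_props(MAJOR13_PROPORTIONS),
            level_names=("major_type",),
        )
    elif scenario == "mp5":
        cfg = SimulationConfig(
            n_genes=1000,
            populations=_flat_populations(markers["mp"], marker_fold),
            group_proportions=_group_props(MP5_PROPORTIONS),
            level_names=("mp_subtype",),
            fixed_levels={"major_type": "MPs"},
        )
    elif scenario == "macro6":
        cfg = SimulationConfig(
            n_genes=1000,
            populations=_flat_populations(markers["macro"], marker_fold),
            group_proportions=_group_props(MACRO6_PROPORTIONS),
            level_names=("macro_subtype",),
            fixed_levels={"major_type": "MPs", "mp_subtype": "Macrophages"},
        )
    elif scenario == "full":
        pops = list(_flat_populations(markers["major"], marker_fold))
        for name, genes in markers["mp"].items():
            pops.append(Population(("MPs", name), tuple(genes), marker_fold))
        for name, genes in markers["macro"].items():
            pops.append(
                Population(("MPs", "Macrophages", name), tuple(genes), marker_fold)
            )
        props = _group_props(MAJOR13_PROPORTIONS)
        for group, row in _group_props(MP5_PROPORTIONS).items():
            props[group].update(row)
        for group, row in _group_props(MACRO6_PROPORTIONS).items():
            props[group].update(row)
        cfg = SimulationConfig(
            n_genes=1000,
            populations=tuple(pops),
            group_proportions=props,
            level_names=LEVEL_COLUMNS,
        )
    else:
        raise ConfigError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    cfg = replace(cfg, seed=seed, n_cells_per_sample=n_cells_per_sample)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# simulation


def _allocate(n: int, probs: np.ndarray, rng: np.random.Generator,
              exact: bool) -> np.ndarray:
    """Counts per category summing to n: largest-remainder or multinomial."""
    probs = np.asarray(probs, dtype=float)
    if exact:
        raw = probs * n
        counts = np.floor(raw).astype(int)
        short = n - counts.sum()
        if short > 0:
            order = np.argsort(-(raw - counts), kind="stable")
            counts[order[:short]] += 1
        return counts
    return rng.multinomial(n, probs / probs.sum())


def _assign_paths(n: int, parent: tuple[str, ...], group: str,
                  config: SimulationConfig,
                  rng: np.random.Generator) -> list[tuple[str, ...]]:
    sibs = config.children(parent)
    names = [p.name for p in sibs]
    probs = np.array([config.group_proportions[group][nm] for nm in names])
    counts = _allocate(n, probs, rng, config.exact_proportions)
    out: list[tuple[str, ...]] = []
    for pop, c in zip(sibs, counts):
        if c == 0:
            continue
        if config.children(pop.path):
            out.extend(_assign_paths(c, pop.path, group, config, rng))
        else:
            out.extend([pop.path] * int(c))
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one cohort from the generative model.

    Per cell: a type path sampled from its sample's group composition
    (exact largest-remainder allocation when ``exact_proportions``);
    per gene: a log-normal baseline mean (marker genes instead use the
    fixed ``marker_baseline``), multiplied by the marker fold of every
    population on the cell's path that claims the gene; counts
    negative-binomial with dispersion ``nb_dispersion`` (variance
    ``mu + mu^2/dispersion``) and a per-cell log-normal library factor.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                         size=config.n_genes)
    # planted markers emulate canonical marker genes, which are reliably
    # expressed transcripts: fixed moderate baseline instead of a lottery draw
    if config.marker_baseline > 0:
        n_markers = sum(len(p.markers) for p in config.populations)
        base[:n_markers] = config.marker_baseline

    # fold multiplier per population path, accumulated along ancestry
    pop_by_path = {p.path: p for p in config.populations}
    factors: dict[tuple[str, ...], np.ndarray] = {}

    def factor_for(path: tuple[str, ...]) -> np.ndarray:
        if path not in factors:
            vec = np.ones(config.n_genes) if len(path) == 1 else factor_for(path[:-1]).copy()
            if len(path) > 1:
                vec = vec.copy()
            pop = pop_by_path[path]
            for g in pop.markers:
                vec[gene_index[g]] *= pop.fold
            factors[path] = vec
        return factors[path]

    cell_paths: list[tuple[str, ...]] = []
    cell_ids: list[str] = []
    sample_ids: list[str] = []
    groups: list[str] = []
    for sample_id, group in config.samples:
        paths = _assign_paths(config.n_cells_per_sample, (), group, config, rng)
        cell_paths.extend(paths)
        cell_ids.extend(
            f"{sample_id}-{i + 1:05d}" for i in range(config.n_cells_per_sample)
        )
        sample_ids.extend([sample_id] * config.n_cells_per_sample)
        groups.extend([group] * config.n_cells_per_sample)

    n_cells = len(cell_paths)
    lib = rng.lognormal(0.0, config.library_size_sd, size=n_cells) \
        if config.library_size_sd > 0 else np.ones(n_cells)

    theta = config.nb_dispersion
    X = np.empty((n_cells, config.n_genes), dtype=np.int64)
    path_arr = np.array([("/".join(p)) for p in cell_paths])
    for path in sorted({tuple(p) for p in cell_paths}):
        mask = path_arr == "/".join(path)
        mu = np.outer(lib[mask], base * factor_for(path))
        X[mask] = rng.negative_binomial(theta, theta / (theta + mu))

    truth = pd.DataFrame({"cell_id": cell_ids, "sample_id": sample_ids,
                          "group": groups})
    for col in LEVEL_COLUMNS:
        truth[col] = config.fixed_levels.get(col, "")
    for depth, col in enumerate(config.level_names):
        vals = [p[depth] if len(p) > depth else "" for p in cell_paths]
        # keep fixed ancestor labels where the path does not reach this depth
        truth[col] = [
            v if v else truth[col].iloc[i] for i, v in enumerate(vals)
        ]

    adata = ad.AnnData(X=sp.csr_matrix(X))
    adata.obs_names = cell_ids
    adata.var_names = genes
    for col in ("sample_id", "group", *LEVEL_COLUMNS):
        adata.obs[col] = truth[col].to_numpy()
    return SyntheticDataset(adata=adata, truth=truth, config=config)


# ---------------------------------------------------------------------------
# truth oracle


def planted_roe(config: SimulationConfig, depth: int = 1) -> pd.DataFrame:
    """Ro/e each (type, group) would attain at infinite sample size.

    Plugs the planted composition directly into the observed/expected
    formula: O(i,j) = n_j * P(type i | group j), E(i,j) =
    row_total * col_total / N.  ``depth`` selects the tree level
    (1 = top level); deeper levels are conditioned on their subtree,
    mirroring how the pipeline recomputes Ro/e on a subset of cells.
    """
    config.validate()
    pops = [p for p in config.populations if len(p.path) == depth]
    if not pops:
        raise ConfigError(f"no populations at depth {depth}")
    group_cells: dict[str, float] = {}
    for _, group in config.samples:
        group_cells[group] = group_cells.get(group, 0.0) + config.n_cells_per_sample
    groups = list(group_cells)

    O = np.zeros((len(pops), len(groups)))
    for i, pop in enumerate(pops):
        for j, group in enumerate(groups):
            p = 1.0
            for d in range(depth):
                p *= config.group_proportions[group][pop.path[d]]
            O[i, j] = group_cells[group] * p
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    N = O.sum()
    E = row @ col / N
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(E > 0, O / E, np.nan)
    return pd.DataFrame(R, index=[p.name for p in pops], columns=groups)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write counts triplet plus truth.tsv to a directory."""
    from .io import write_counts_dir

    outdir = write_counts_dir(dataset.adata, outdir)
    cols = ["cell_id", "sample_id", "group", *LEVEL_COLUMNS]
    dataset.truth[cols].to_csv(outdir / "truth.tsv", sep="\t", index=False)
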