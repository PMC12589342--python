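"""End-to-end orchestration: simulate/load -> annotate -> Ro/e -> scores -> DE -> ORA -> LR.

A run is driven by a :class:`RunConfig` (either a packaged synthetic
scenario or real input paths, never both), executes the stages in
dependency order, writes every product as TSV under one output
directory, and finishes with a JSON manifest listing each file with a
sha256 content hash.  All randomness flows from the config seed, so a
repeated run is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import de as de_mod
from . import lr as lr_mod
from . import roe as roe_mod
from . import scoring, simulate
from .io import (
    TISSUE_GROUPS,
    load_toy_pathways,
    read_counts_dir,
    write_annotation,
)

__all__ = ["RunConfig", "validate_inputs", "run_all"]

ROE_LEVELS = [("major", "major_type"), ("mp", "mp_subtype"), ("macro", "macro_subtype")]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``scenario`` (synthetic) or ``counts_dir``+``metadata``
    (real input) must be set.
    """

    outdir: str
    scenario: str | None = None
    counts_dir: str | None = None
    metadata: str | None = None
    ihc_table: str | None = None
    seed: int = 0
    n_cells_per_sample: int = 500
    marker_fold: float = 8.0
    resolution: float = 2.0
    n_components: int = 15
    target_sum: float = 1e4
    roe_threshold: float = 1.0
    lfc_cut: float = 1.0
    q_cut: float = 0.05
    n_perm: int = 199
    de_groups: tuple[str, str] = ("RUNX3_Pos", "RUNX3_Neg")
    lr_sender: str = "CancerCells"
    lr_sender_group: str | None = "RUNX3_Pos"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "de_groups" in raw:
            raw["de_groups"] = tuple(raw["de_groups"])
        return cls(**raw)

    def validate(self) -> None:
        synthetic = self.scenario is not None
        real = self.counts_dir is not None or self.metadata is not None
        if synthetic and real:
            raise ValueError("set either a simulation scenario or real input paths, not both")
        if not synthetic and not (self.counts_dir and self.metadata):
            raise ValueError("real input needs both counts_dir and metadata")


def validate_inputs(counts_dir: str | Path, metadata: str | Path | None = None) -> list[str]:
    """Pre-flight checks on a counts triplet (+ optional metadata table).

    Returns a list of human-readable violations; empty means clean.
    """
    report: list[str] = []
    counts_dir = Path(counts_dir)
    names = {}
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        path = counts_dir / name
        if not path.exists():
            report.append(f"{path}: missing")
        names[name] = path
    dims = None
    if names["matrix.mtx"].exists():
        with names["matrix.mtx"].open() as fh:
            header = fh.readline()
            if not header.startswith("%%MatrixMarket matrix coordinate"):
                report.append(f"{names['matrix.mtx']}: not a MatrixMarket coordinate file")
            else:
                line = fh.readline()
                while line.startswith("%"):
                    line = fh.readline()
                try:
                    n_genes, n_cells, _ = (int(x) for x in line.split())
                    dims = (n_genes, n_cells)
                except ValueError:
                    report.append(f"{names['matrix.mtx']}: malformed size line {line!r}")
    counts = {}
    for name in ("features.tsv", "barcodes.tsv"):
        if names[name].exists():
            counts[name] = sum(1 for _ in names[name].open())
    if dims is not None:
        if "features.tsv" in counts and counts["features.tsv"] != dims[0]:
            report.append(
                f"features.tsv has {counts['features.tsv']} rows but matrix.mtx "
                f"declares {dims[0]} genes"
            )
        if "barcodes.tsv" in counts and counts["barcodes.tsv"] != dims[1]:
            report.append(
                f"barcodes.tsv has {counts['barcodes.tsv']} rows but matrix.mtx "
                f"declares {dims[1]} cells"
            )
    if metadata is not None:
        meta_path = Path(metadata)
        if not meta_path.exists():
            report.append(f"{meta_path}: missing")
        else:
            meta = pd.read_csv(meta_path, sep="\t")
            for col in ("cell_id", "sample_id", "group"):
                if col not in meta.columns:
                    report.append(f"{meta_path}: missing column {col!r}")
            if "group" in meta.columns:
                bad = sorted(set(meta["group"].astype(str)) - set(TISSUE_GROUPS))
                if bad:
                    report.append(
                        f"{meta_path}: unknown group labels {bad}; allowed: "
                        f"{list(TISSUE_GROUPS)}"
                    )
            if names["barcodes.tsv"].exists() and "cell_id" in meta.columns:
                barcodes = pd.read_csv(names["barcodes.tsv"], sep="\t", header=None)[0]
                uncovered = set(barcodes.astype(str)) - set(meta["cell_id"].astype(str))
                if uncovered:
                    report.append(
                        f"{meta_path}: {len(uncovered)} barcodes lack metadata rows"
                    )
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    from . import __version__

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: list[str] = []
    log: dict[str, dict] = {}

    def stage(name):
        stages.append(name)
        log[name] = {}
        return log[name]

    # --- inputs -----------------------------------------------------------
    if config.scenario is not None:
        info = stage("simulate")
        cfg = simulate.default_config(
            config.scenario,
            marker_fold=config.marker_fold,
            seed=config.seed,
            n_cells_per_sample=config.n_cells_per_sample,
        )
        dataset = simulate.simulate_dataset(cfg)
        simulate.write_dataset(dataset, outdir / "counts")
        adata, meta = dataset.adata, dataset.truth
        info["n_cells"] = int(adata.n_obs)
        info["n_genes"] = int(adata.n_vars)
    else:
        info = stage("load")
        problems = validate_inputs(config.counts_dir, config.metadata)
        if problems:
            raise ValueError("input validation failed:\n" + "\n".join(problems))
        adata = read_counts_dir(config.counts_dir)
        meta = pd.read_csv(config.metadata, sep="\t")
        info["n_cells"] = int(adata.n_obs)
        info["n_genes"] = int(adata.n_vars)

    if config.ihc_table is not None:
        from .ihc import read_specimens, score_and_group, write_specimens

        stage("ihc_score")["table"] = str(config.ihc_table)
        scored = score_and_group(read_specimens(config.ihc_table))
        write_specimens(scored, outdir / "ihc_scored.tsv")

    # --- annotation -------------------------------------------------------
    info = stage("annotate")
    params = ann.AnnotateParams(
        target_sum=config.target_sum,
        n_components=config.n_components,
        resolution=config.resolution,
        seed=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        annot = ann.annotate_hierarchy(adata, meta, params=params)
    write_annotation(annot, outdir / "annot.tsv")
    info["n_major_types"] = int(annot["major_type"].nunique())
    info["n_mp_cells"] = int((annot["mp_subtype"] != "").sum())

    norm = ann.normalize_log(adata, target_sum=config.target_sum)
    annot_idx = annot.set_index("cell_id")

    # --- Ro/e per level ---------------------------------------------------
    info = stage("roe")
    for level, column in ROE_LEVELS:
        present = annot[column].astype(str) != ""
        if present.sum() == 0:
            continue
        obs = roe_mod.contingency(annot[present], column, "group")
        table = roe_mod.roe(obs)
        _, long = roe_mod.preference_calls(table, threshold=config.roe_threshold)
        wide = table.ratio.round(6)
        wide.to_csv(outdir / f"roe_wide_{level}.tsv", sep="\t")
        long.round(6).to_csv(outdir / f"roe_long_{level}.tsv", sep="\t", index=False)
        info[f"chi2_p_{level}"] = table.chi2_p

    # --- M1/M2 scores -----------------------------------------------------
    if (annot["macro_subtype"].astype(str) != "").any():
        stage("score_modules")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = scoring.m1_m2_report(norm, annot, seed=config.seed)
        report.round(6).to_csv(outdir / "m1m2.tsv", sep="\t", index=False)

    # --- DE + enrichment --------------------------------------------------
    group_a, group_b = config.de_groups
    mp_cells = annot_idx.index[annot_idx["major_type"] == "MPs"]
    cells_a = [c for c in mp_cells if annot_idx.loc[c, "group"] == group_a]
    cells_b = [c for c in mp_cells if annot_idx.loc[c, "group"] == group_b]
    norm_cells = set(norm.obs_names)
    cells_a = [c for c in cells_a if c in norm_cells]
    cells_b = [c for c in cells_b if c in norm_cells]
    if len(cells_a) >= 2 and len(cells_b) >= 2:
        info = stage("de")
        de = de_mod.wilcoxon_de(norm, cells_a, cells_b)
        de = de_mod.volcano_classify(de, lfc_cut=config.lfc_cut, q_cut=config.q_cut)
        de.round(6).to_csv(outdir / "de.tsv", sep="\t", index=False)
        info["n_up"] = int((de["direction"] == "up").sum())
        info["n_down"] = int((de["direction"] == "down").sum())

        detected = np.asarray((adata.X > 0).sum(axis=0)).ravel() > 0
        universe = list(np.asarray(adata.var_names)[detected])
        query = [g for g in de.loc[de["direction"] == "up", "gene"] if g in universe]
        if query:
            stage("enrich")
            enrichment = de_mod.hypergeom_ora(query, load_toy_pathways(), universe)
            enrichment.round(6).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # --- ligand-receptor --------------------------------------------------
    senders = annot_idx.index[annot_idx["major_type"] == config.lr_sender]
    if config.lr_sender_group is not None:
        senders = [
            c for c in senders if annot_idx.loc[c, "group"] == config.lr_sender_group
        ]
    senders = [c for c in senders if c in norm_cells]
    receivers = [c for c in mp_cells if c in norm_cells]
    if senders and receivers:
        info = stage("lr")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = lr_mod.permutation_test(
                norm,
                senders,
                receivers,
                lr_mod.load_lr_pairs(),
                n_perm=config.n_perm,
                seed=config.seed,
                sender_name=config.lr_sender,
                receiver_name="MPs",
            )
        lr_mod.results_table(results).round(6).to_csv(
            outdir / "lr.tsv", sep="\t", index=False
        )
        info["n_pairs_scored"] = len(results)

    # --- manifest ---------------------------------------------------------
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "stages": stages,
        "stage_log": log,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
        "wall_time_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
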