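"""Generator contracts: composition, markers, determinism, planted Ro/e."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sctme import simulate
from sctme.simulate import ConfigError, Population, SimulationConfig


def _two_type_config(**overrides):
    base = dict(
        n_genes=40,
        populations=(
            Population(("A",), ("MA1", "MA2"), 8.0),
            Population(("B",), ("MB1", "MB2"), 8.0),
        ),
        group_proportions={"g1": {"A": 0.5, "B": 0.5}},
        samples=(("s1", "g1"),),
        n_cells_per_sample=100,
        seed=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigError, match="unknown scenario"):
            simulate.default_config("major14")

    def test_proportions_must_sum_to_one(self):
        cfg = _two_type_config(group_proportions={"g1": {"A": 0.6, "B": 0.6}})
        with pytest.raises(ConfigError, match="sum to"):
            cfg.validate()

    def test_marker_unique_across_populations(self):
        cfg = _two_type_config(
            populations=(
                Population(("A",), ("M1",), 8.0),
                Population(("B",), ("M1",), 8.0),
            )
        )
        with pytest.raises(ConfigError, match="appears in both"):
            cfg.validate()

    def test_orphan_population_rejected(self):
        cfg = _two_type_config(
            populations=(
                Population(("A",), ("MA1",), 8.0),
                Population(("X", "Y"), ("MB1",), 8.0),
            ),
            level_names=("major_type", "mp_subtype"),
        )
        with pytest.raises(ConfigError, match="no parent"):
            cfg.validate()


class TestDefaultScenarios:
    def test_major13_population_names(self):
        cfg = simulate.default_config("major13")
        names = {p.name for p in cfg.populations}
        assert names == {
            "CancerCells", "AT2", "ClubCells", "CiliatedCells", "ECs",
            "Fibroblasts", "PlasmaCells", "BCells", "TCells", "Neutrophils",
            "MastCells", "MPs", "pDCs",
        }

    def test_macro6_anchor_genes(self):
        cfg = simulate.default_config("macro6")
        markers = {g for p in cfg.populations for g in p.markers}
        assert {"AZU1", "CXCL10", "FABP4", "SELENOP", "SPP1", "STMN1"} <= markers

    @pytest.mark.parametrize("scenario,n", [("major13", 13), ("mp5", 5), ("macro6", 6)])
    def test_population_counts_and_proportion_sums(self, scenario, n):
        cfg = simulate.default_config(scenario)
        assert len(cfg.populations) == n
        for group, props in cfg.group_proportions.items():
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)


class TestSimulateDataset:
    def test_exact_allocation(self):
        ds = simulate.simulate_dataset(_two_type_config(exact_proportions=True))
        counts = ds.truth["major_type"].value_counts()
        assert counts["A"] == 50 and counts["B"] == 50

    def test_determinism_same_seed(self):
        cfg = _two_type_config(seed=11)
        a = simulate.simulate_dataset(cfg)
        b = simulate.simulate_dataset(cfg)
        assert (a.adata.X != b.adata.X).nnz == 0
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_counts_nonnegative_integers_and_truth_covers_cells(self):
        ds = simulate.simulate_dataset(_two_type_config())
        X = ds.adata.X.toarray()
        assert (X >= 0).all() and np.allclose(X, np.round(X))
        assert list(ds.truth["cell_id"]) == list(ds.adata.obs_names)

    def test_marker_fold_recovered(self):
        """Planted fold 8 shows up in the in/out-of-population mean ratio."""
        cfg = _two_type_config(n_cells_per_sample=2000, seed=5)
        ds = simulate.simulate_dataset(cfg)
        X = ds.adata.X.toarray()
        in_a = (ds.truth["major_type"] == "A").to_numpy()
        gi = list(ds.adata.var_names).index("MA1")
        ratio = X[in_a, gi].mean() / X[~in_a, gi].mean()
        assert 6.0 <= ratio <= 10.0

    def test_group_frequencies_converge_multinomial(self):
        cfg = simulate.default_config("major13", seed=0)
        # stochastic sampling branch; 5,000 cells per group
        from dataclasses import replace

        cfg = replace(cfg, exact_proportions=False, n_cells_per_sample=5000,
                      samples=(("a", "NOR"), ("b", "RUNX3_Neg"), ("c", "RUNX3_Pos")))
        ds = simulate.simulate_dataset(cfg)
        for group, props in cfg.group_proportions.items():
            sub = ds.truth[ds.truth["group"] == group]
            freq = sub["major_type"].value_counts(normalize=True)
            l1 = sum(abs(freq.get(t, 0.0) - p) for t, p in props.items())
            assert l1 < 0.05

    def test_non_marker_genes_population_independent(self, small_dataset):
        """Background genes should not differ between planted populations."""
        ds = small_dataset
        X = ds.adata.X.toarray()
        in_a = (ds.truth["major_type"] == "A").to_numpy()
        bg = [i for i, g in enumerate(ds.adata.var_names) if g.startswith("BG")]
        pvals = scipy.stats.mannwhitneyu(
            X[in_a][:, bg], X[~in_a][:, bg], axis=0
        ).pvalue
        assert (pvals > 0.01).mean() >= 0.95


class TestPlantedRoe:
    def test_identical_groups_give_unity(self):
        cfg = _two_type_config(
            group_proportions={"g1": {"A": 0.3, "B": 0.7}, "g2": {"A": 0.3, "B": 0.7}},
            samples=(("s1", "g1"), ("s2", "g2")),
        )
        r = simulate.planted_roe(cfg)
        assert np.allclose(r.to_numpy(), 1.0)

    def test_hand_computed_two_group_case(self):
        # A at 0.6 vs 0.2 with equal group sizes: pooled 0.4 -> Ro/e = 1.5
        cfg = _two_type_config(
            group_proportions={"g1": {"A": 0.6, "B": 0.4}, "g2": {"A": 0.2, "B": 0.8}},
            samples=(("s1", "g1"), ("s2", "g2")),
        )
        r = simulate.planted_roe(cfg)
        assert r.loc["A", "g1"] == pytest.approx(1.5)
        assert r.loc["A", "g2"] == pytest.approx(0.5)

    def test_invariant_to_cohort_scaling(self):
        cfg = _two_type_config(
            group_proportions={"g1": {"A": 0.6, "B": 0.4}, "g2": {"A": 0.2, "B": 0.8}},
            samples=(("s1", "g1"), ("s2", "g2")),
        )
        big = simulate.planted_roe(
            simulate.SimulationConfig(
                **{**cfg.__dict__, "n_cells_per_sample": cfg.n_cells_per_sample * 10}
            )
        )
        pd.testing.assert_frame_equal(simulate.planted_roe(cfg), big)

    def test_truth_labels_reproduce_planted_signs(self, scenario_run):
        """Ro/e on simulated truth matches the infinite-sample sign pattern."""
        from sctme import roe

        run = scenario_run("major13")
        planted = simulate.planted_roe(run.cfg)
        table = roe.roe(roe.contingency(run.dataset.truth, "major_type", "group"))
        observed_signs = table.ratio > 1
        planted_signs = planted.loc[table.ratio.index, table.ratio.columns] > 1
        assert (observed_signs == planted_signs).all().all()
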