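"""Annotation stages: normalization, clustering, marker scoring, hierarchy."""

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from sctme import annotate, simulate


def _adata(X, genes=None, cells=None):
    X = np.asarray(X, dtype=float)
    a = ad.AnnData(X=sp.csr_matrix(X))
    a.var_names = genes or [f"g{i}" for i in range(X.shape[1])]
    a.obs_names = cells or [f"c{i}" for i in range(X.shape[0])]
    return a


class TestNormalizeLog:
    def test_hand_computed_values(self):
        norm = annotate.normalize_log(_adata([[2, 2]]), target_sum=4)
        assert np.allclose(norm.X.toarray(), np.log(3))

    def test_cell_totals_equal_target_pre_log(self):
        rng = np.random.default_rng(0)
        a = _adata(rng.integers(0, 20, size=(30, 15)) + 1)
        norm = annotate.normalize_log(a, target_sum=100)
        totals = np.expm1(norm.X.toarray()).sum(axis=1)
        assert np.allclose(totals, 100)

    def test_zero_gene_stays_zero_and_zero_cell_dropped(self):
        X = np.array([[5, 0, 3], [0, 0, 0], [2, 0, 2]])
        with pytest.warns(UserWarning, match="all-zero cells"):
            norm = annotate.normalize_log(_adata(X))
        assert norm.n_obs == 2
        assert np.allclose(norm.X.toarray()[:, 1], 0)


class TestClusterCells:
    def test_two_separated_populations_fully_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(1.0, size=(200, 30)).astype(float)
        X[:100, :5] += 50  # population 1 marker block
        X[100:, 5:10] += 50
        norm = annotate.normalize_log(_adata(X))
        labels = annotate.cluster_cells(norm, resolution_or_k=0.5, seed=0)
        truth = np.repeat([0, 1], 100)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_cells_one_cluster(self):
        norm = _adata(np.ones((20, 10)))
        labels = annotate.cluster_cells(norm, seed=0)
        assert len(np.unique(labels)) == 1

    def test_deterministic_given_seed(self, small_dataset):
        norm = annotate.normalize_log(small_dataset.adata)
        l1 = annotate.cluster_cells(norm, seed=4)
        l2 = annotate.cluster_cells(norm, seed=4)
        assert (l1 == l2).all()

    def test_components_reduced_with_warning(self):
        rng = np.random.default_rng(2)
        norm = _adata(rng.poisson(2.0, size=(10, 6)).astype(float))
        with pytest.warns(UserWarning, match="n_components reduced"):
            annotate.cluster_cells(norm, n_components=50, method="kmeans",
                                   resolution_or_k=2, seed=0)


class TestScoreAndAssign:
    def _block_adata(self):
        # two clusters with swapped marker blocks
        X = np.ones((40, 4))
        X[:20, 0:2] = 6.0  # cluster 0 expresses X markers
        X[20:, 2:4] = 6.0  # cluster 1 expresses Y markers
        return _adata(X, genes=["x1", "x2", "y1", "y2"])

    def test_block_matrix_scores_are_symmetric(self):
        ref = {"X": ["x1", "x2"], "Y": ["y1", "y2"]}
        labels = np.repeat([0, 1], 20)
        scores = annotate.score_cluster_types(self._block_adata(), labels, ref)
        assert scores.loc[0, "X"] == pytest.approx(scores.loc[1, "Y"])
        assert scores.loc[0, "Y"] == pytest.approx(scores.loc[1, "X"])
        mapping = annotate.assign_types(scores)
        assert mapping.loc[0, "type"] == "X" and mapping.loc[1, "type"] == "Y"

    def test_constant_matrix_scores_zero(self):
        ref = {"X": ["x1"], "Y": ["y1"]}
        norm = _adata(np.ones((10, 4)), genes=["x1", "x2", "y1", "y2"])
        scores = annotate.score_cluster_types(norm, np.zeros(10, dtype=int), ref)
        assert (scores.to_numpy() == 0).all()

    def test_missing_marker_warned_absent_type_raises(self):
        ref = {"X": ["x1", "nope"], "Y": ["gone"]}
        norm = self._block_adata()
        with pytest.raises(ValueError, match="type Y"):
            with pytest.warns(UserWarning, match="absent markers"):
                annotate.score_cluster_types(norm, np.repeat([0, 1], 20), ref)

    def test_tie_breaks_lexicographic_with_flag(self):
        scores = pd.DataFrame({"B": [0.5], "A": [0.5]}, index=[0])
        mapping = annotate.assign_types(scores)
        assert mapping.loc[0, "type"] == "A"
        assert bool(mapping.loc[0, "tie"])


class TestMarkerReference:
    def test_level_sizes_enforced(self):
        with pytest.raises(ValueError, match="exactly 13"):
            annotate.MarkerReference("major", {"A": ["g"]})

    def test_macro_anchors_required(self):
        entries = {f"T{i}": [f"g{i}"] for i in range(6)}
        with pytest.raises(ValueError, match="anchor genes"):
            annotate.MarkerReference("macro", entries)

    def test_packaged_references_load(self):
        for level, n in (("major", 13), ("mp", 5), ("macro", 6)):
            ref = annotate.load_marker_reference(level)
            assert len(ref.entries) == n


class TestHierarchy:
    @pytest.mark.parametrize(
        "scenario,expected", [("major13", 13), ("mp5", 5), ("macro6", 6)]
    )
    def test_scenario_recovery(self, scenario_run, scenario, expected):
        """All planted types recovered with near-perfect agreement to truth."""
        run = scenario_run(scenario)
        assert len(np.unique(run.assigned)) == expected
        assert adjusted_rand_score(run.truth, run.assigned) >= 0.9

    def test_order_permutation_equivariance(self, small_dataset):
        """Permuting the cells permutes the labels identically."""
        norm = annotate.normalize_log(small_dataset.adata)
        labels = annotate.cluster_cells(norm, seed=0, method="kmeans",
                                        resolution_or_k=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(norm.n_obs)
        labels_p = annotate.cluster_cells(norm[perm].copy(), seed=0,
                                          method="kmeans", resolution_or_k=2)
        # cluster ids may be renamed; the partitions must match exactly
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_no_mp_cells_skips_sublevels(self):
        """With no cells of the MP type, the deeper levels stay null."""
        cfg = simulate.default_config("major13", seed=3, n_cells_per_sample=50)
        ds = simulate.simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            annot = annotate.annotate_hierarchy(
                ds.adata,
                ds.truth[["cell_id", "sample_id", "group"]],
                params=annotate.AnnotateParams(seed=0),
                mp_type="DOES_NOT_EXIST",
            )
        assert (annot["mp_subtype"] == "").all()
        assert (annot["macro_subtype"] == "").all()
        assert (annot["major_type"] != "").all()


class TestTopMarkers:
    def test_planted_markers_rank_top(self, scenario_run):
        run = scenario_run("macro6")
        table = annotate.top_markers(run.norm, run.truth, n=10)
        for pop in run.cfg.populations:
            top = set(table.loc[table["type"] == pop.name, "gene"])
            assert set(pop.markers) <= top

    def test_full_ranking_when_n_exceeds_genes(self, small_dataset):
        norm = annotate.normalize_log(small_dataset.adata)
        table = annotate.top_markers(norm, small_dataset.truth["major_type"],
                                     n=10_000)
        assert (table.groupby("type").size() == norm.n_vars).all()

    def test_single_type_rejected(self, small_dataset):
        norm = annotate.normalize_log(small_dataset.adata)
        with pytest.raises(ValueError, match="at least 2 types"):
            annotate.top_markers(norm, ["A"] * norm.n_obs, n=5)
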