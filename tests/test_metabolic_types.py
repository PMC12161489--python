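import numpy as np
import pandas as pd
import pytest

import hypometab as hm
from hypometab.deregulation import DeregulationMatrix


def _blob_dereg(means=(0.2, 0.5, 0.8), n_per=40, n_pathways=10, sd=0.03,
                seed=0):
    """Deregulation matrix of three well-separated sample blobs."""
    rng = np.random.default_rng(seed)
    cols, vals = [], []
    for b, mu in enumerate(means):
        for i in range(n_per):
            cols.append(f"b{b}_s{i}")
            vals.append(np.clip(rng.normal(mu, sd, n_pathways), 0, 1))
    df = pd.DataFrame(np.array(vals).T,
                      index=[f"pw{j}" for j in range(n_pathways)],
                      columns=cols)
    return DeregulationMatrix(df)


class TestClusterTypes:
    def test_labels_ordered_by_mean_deregulation(self):
        dereg = _blob_dereg()
        assign = hm.cluster_types(dereg, seed=17)
        # blob at 0.2 -> M1, 0.5 -> M2, 0.8 -> M3, whatever kmeans' indices
        for b, label in enumerate(["M1", "M2", "M3"]):
            members = [s for s in dereg.sample_ids if s.startswith(f"b{b}_")]
            assert (assign.table.loc[members, "label"] == label).all()
        means = assign.type_means()
        assert means["M1"] <= means["M2"] <= means["M3"]

    def test_deterministic_given_seed(self):
        dereg = _blob_dereg(seed=3)
        a = hm.cluster_types(dereg, seed=17)
        b = hm.cluster_types(dereg, seed=17)
        assert a.table.equals(b.table)

    def test_sample_order_invariance(self):
        dereg = _blob_dereg(seed=5)
        shuffled = DeregulationMatrix(
            dereg.scores[list(reversed(dereg.sample_ids))])
        a = hm.cluster_types(dereg, seed=17)
        b = hm.cluster_types(shuffled, seed=17)
        assert (a.table["label"].sort_index()
                == b.table["label"].sort_index()).all()

    def test_k_larger_than_n_rejected(self):
        dereg = _blob_dereg(n_per=1)
        with pytest.raises(ValueError, match="exceeds"):
            hm.cluster_types(dereg, k=10)

    def test_ward_alternative(self):
        dereg = _blob_dereg(seed=7)
        assign = hm.cluster_types(dereg, method="ward")
        means = assign.type_means()
        assert means["M1"] <= means["M2"] <= means["M3"]


class TestPredictLabels:
    def test_centroid_recovers_its_own_label(self):
        dereg = _blob_dereg(seed=11)
        ref = hm.cluster_types(dereg, seed=17)
        panel = DeregulationMatrix(ref.centroids.rename(
            columns={c: f"new_{c}" for c in ref.centroids.columns}))
        pred = hm.predict_labels(panel, ref)
        assert pred.table["label"].tolist() == list(ref.centroids.columns)
        assert (pred.table["margin"] > 0).all()

    def test_no_shared_pathways_rejected(self):
        dereg = _blob_dereg(seed=11)
        ref = hm.cluster_types(dereg, seed=17)
        panel = DeregulationMatrix(
            dereg.scores.rename(index=lambda s: f"other_{s}"))
        with pytest.raises(ValueError, match="no shared pathways"):
            hm.predict_labels(panel, ref)

    def test_cell_line_panel_maps_to_m2_m3(self, default_cohort):
        """A panel drawn only from the M2/M3 generative components should
        overwhelmingly receive M2 or M3 labels.

        Pathway scores are anchored on the cohort they are computed in,
        so tumor cohort and panel are scored jointly (the configurable
        joint-scoring mode) before nearest-centroid transfer.
        """
        from hypometab.deregulation import DeregulationMatrix
        panel_cohort = hm.generate_cohort(
            n_samples=150, type_props=(0.0, 0.5, 0.5), seed=99)
        panel_cols = [f"CL_{s}" for s in panel_cohort.expr.sample_ids]
        panel_expr = panel_cohort.expr.values.set_axis(panel_cols, axis=1)
        joint = hm.ExpressionMatrix(pd.concat(
            [default_cohort.expr.values, panel_expr], axis=1))
        dereg = hm.score_collection(joint, default_cohort.gene_sets)
        ref_dereg = DeregulationMatrix(
            dereg.scores[default_cohort.expr.sample_ids])
        panel_dereg = DeregulationMatrix(dereg.scores[panel_cols])
        ref = hm.cluster_types(ref_dereg, seed=17)
        pred = hm.predict_labels(panel_dereg, ref)
        frac = (pred.table["label"] != "M1").mean()
        assert frac >= 0.9


class TestSummarizeHsByType:
    def test_planted_m3_has_highest_hs(self, default_cohort):
        scores = hm.score_signature(default_cohort.expr)
        assign = hm.ClusterAssignment(
            default_cohort.truth.label.to_frame().assign(mean_dereg=0.0))
        summary, comparison = hm.summarize_hs_by_type(scores, assign)
        assert summary.loc["M3", "mean_hs"] > summary.loc["M1", "mean_hs"]
        assert summary.loc["M3", "mean_hs"] > summary.loc["M2", "mean_hs"]
        assert comparison.test == "kruskal-wallis"
        assert comparison.p < 0.05
        assert comparison.posthoc is not None

    def test_empty_intersection_rejected(self, default_cohort):
        scores = hm.score_signature(default_cohort.expr)
        assign = hm.ClusterAssignment(pd.DataFrame(
            {"label": ["M1"], "mean_dereg": [0.0]}, index=["unknown"]))
        with pytest.raises(ValueError, match="no shared samples"):
            hm.summarize_hs_by_type(scores, assign)

    def test_sparse_type_rejected(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(10)]
        scores = hm.ScoreTable(pd.DataFrame(
            {"hs": rng.integers(-8, 9, 10), "group": "low",
             "n_genes_found": 8}, index=ids))
        assign = hm.ClusterAssignment(pd.DataFrame(
            {"label": ["M1"] * 8 + ["M2"] * 2, "mean_dereg": 0.0}, index=ids))
        with pytest.raises(ValueError, match="3 required"):
            hm.summarize_hs_by_type(scores, assign)
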