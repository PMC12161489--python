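import numpy as np
import pandas as pd
import pytest
import hypometab as hm
from hypometab.associations import pearson_screen


def _score_table(values, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    hs = np.asarray(values)
    return hm.ScoreTable(pd.DataFrame(
        {"hs": hs, "group": np.where(hs > 0, "high", "low"),
         "n_genes_found": 8},
        index=pd.Index(ids, name="sample_id")))


class TestCorrelate:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        hs = rng.integers(-8, 9, 300)
        scores = _score_table(hs)
        feats = pd.DataFrame([hs.astype(float)], index=["self"],
                             columns=scores.sample_ids)
        fp = hm.correlate(scores, feats)
        rec = fp.records.iloc[0]
        assert rec["r"] == pytest.approx(1.0)
        assert rec["p"] < 1e-10

    def test_constant_feature_excluded(self):
        rng = np.random.default_rng(1)
        scores = _score_table(rng.integers(-8, 9, 50))
        feats = pd.DataFrame(
            [np.ones(50), rng.normal(size=50)], index=["const", "ok"],
            columns=scores.sample_ids)
        fp = hm.correlate(scores, feats)
        const = fp.records.set_index("feature").loc["const"]
        assert np.isnan(const["r"])
        assert not const["significant"]
        counts = hm.count_significant(fp)
        assert counts.loc["all"].sum() <= 1

    def test_scale_and_sign_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = rng.normal(size=(3, 100))
        r1, _ = pearson_screen(x, y)
        r2, _ = pearson_screen(3.0 * x + 7.0, y)
        r3, _ = pearson_screen(-2.0 * x, y)
        assert np.allclose(r1, r2)
        assert np.allclose(r1, -r3)

    def test_per_stratum_n_sums_to_overall(self, default_cohort):
        scores = hm.score_signature(default_cohort.expr)
        assign = hm.ClusterAssignment(
            default_cohort.truth.label.to_frame().assign(mean_dereg=0.0))
        fp = hm.correlate(scores, default_cohort.truth.pathway_latent,
                          groups=assign)
        per_feature = fp.records[fp.records["stratum"] != "all"]
        n_all = fp.stratum("all")["n"].iloc[0]
        assert per_feature.groupby("feature")["n"].sum().eq(n_all).all()

    def test_bh_is_monotone(self):
        rng = np.random.default_rng(3)
        hs = rng.integers(-8, 9, 120)
        feats = pd.DataFrame(
            0.3 * hs + rng.normal(size=(40, 120)),
            index=[f"f{i}" for i in range(40)])
        scores = _score_table(hs)
        feats.columns = scores.sample_ids
        none = hm.count_significant(hm.correlate(scores, feats)).loc["all"]
        bh = hm.count_significant(
            hm.correlate(scores, feats, multiplicity="bh")).loc["all"]
        assert bh.sum() <= none.sum()

    def test_no_shared_samples_rejected(self):
        scores = _score_table([1, -1, 3])
        feats = pd.DataFrame([[1.0, 2, 3]], index=["f"],
                             columns=["x1", "x2", "x3"])
        with pytest.raises(ValueError, match="no shared samples"):
            hm.correlate(scores, feats)

    def test_small_stratum_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        scores = _score_table(rng.integers(-8, 9, 20))
        feats = pd.DataFrame(rng.normal(size=(3, 20)),
                             index=list("abc"), columns=scores.sample_ids)
        labels = ["M1"] * 18 + ["M2"] * 2
        assign = hm.ClusterAssignment(pd.DataFrame(
            {"label": labels, "mean_dereg": 0.0}, index=scores.sample_ids))
        import logging
        with caplog.at_level(logging.WARNING, logger="hypometab"):
            fp = hm.correlate(scores, feats, groups=assign)
        assert "M2" not in fp.strata
        assert any("skipped" in r.message for r in caplog.records)


class TestCountSignificant:
    def test_counts_forced_by_definition(self):
        rec = pd.DataFrame({
            "stratum": ["all"] * 5,
            "feature": list("abcde"),
            "r": [0.5, 0.4, 0.3, -0.5, 0.01],
            "p": [0.001, 0.01, 0.04, 0.001, 0.9],
            "n": 100,
            "significant": [True, True, True, True, False],
            "sign": ["+", "+", "+", "-", "+"],
        })
        counts = hm.count_significant(hm.CorrelationFingerprint(rec))
        assert counts.loc["all", "n_positive"] == 3
        assert counts.loc["all", "n_negative"] == 1

    def test_sign_flip_excluded_under_consistency(self):
        def fp(sign):
            rec = pd.DataFrame({
                "stratum": ["all"], "feature": ["f"], "r": [0.5 if sign == "+" else -0.5],
                "p": [0.001], "n": 100, "significant": [True], "sign": [sign]})
            return hm.CorrelationFingerprint(rec)
        counts = hm.count_significant(fp("+"), require_consistency=fp("-"))
        assert counts.loc["all"].sum() == 0

    def test_breadth_ordering_and_ties(self):
        rec = []
        for stratum, n_sig in [("M1", 5), ("M2", 3), ("M3", 3)]:
            for i in range(6):
                rec.append({
                    "stratum": stratum, "feature": f"f{i}", "r": 0.5,
                    "p": 0.01 if i < n_sig else 0.5, "n": 50,
                    "significant": i < n_sig, "sign": "+"})
        fp = hm.CorrelationFingerprint(pd.DataFrame(rec))
        breadth = hm.fingerprint_breadth(fp)
        assert list(breadth.index) == ["M1", "M2", "M3"]
        assert not breadth.loc["M1", "tied"]
        assert breadth.loc["M2", "tied"] and breadth.loc["M3", "tied"]


class TestCompareGroups:
    def test_identical_groups_null_center(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=30)
        res = hm.compare_groups({"a": vals, "b": vals.copy()})
        assert res.p > 0.99

    def test_separated_normals_use_t_test(self):
        rng = np.random.default_rng(6)
        res = hm.compare_groups({
            "a": rng.normal(0, 1, 30), "b": rng.normal(2, 1, 30)})
        assert res.test == "t-test"
        assert res.p < 0.001

    def test_skewed_data_use_mann_whitney(self):
        rng = np.random.default_rng(7)
        res = hm.compare_groups({
            "a": rng.exponential(1, 50), "b": rng.exponential(1, 50)})
        assert res.test == "mann-whitney"

    def test_three_groups_use_kruskal_with_dunn(self):
        rng = np.random.default_rng(8)
        res = hm.compare_groups({
            "a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20),
            "c": rng.normal(3, 1, 20)})
        assert res.test == "kruskal-wallis"
        assert len(res.posthoc) == 3
        ph = res.posthoc.set_index(["group_a", "group_b"])
        assert ph.loc[("a", "c"), "p_adj"] < 0.05
        assert ph.loc[("a", "b"), "p_adj"] > 0.05

    def test_kruskal_null_calibration(self):
        """Three groups from one distribution: rejection rate ~ alpha."""
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 500
        for _ in range(reps):
            res = hm.compare_groups({
                "a": rng.normal(size=20), "b": rng.normal(size=20),
                "c": rng.normal(size=20)})
            rejections += res.p < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="3 required"):
            hm.compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
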