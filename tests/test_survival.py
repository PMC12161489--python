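import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import hypometab as hm


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        curve = hm.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(curve.times, [1, 2, 3, 4])
        assert np.allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_no_events_flat_at_one(self):
        curve = hm.km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0      # no event times: S stays 1

    def test_mixed_censoring_hand_table(self):
        # (1,event) (2,cens) (3,event) (4,cens) (5,event) (6,event):
        # S = 5/6, 5/6*3/4, *1/2, *0
        curve = hm.km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1])
        assert np.allclose(curve.times, [1, 3, 5, 6])
        assert np.allclose(curve.survival, [5 / 6, 0.625, 0.3125, 0.0])
        assert np.allclose(curve.at_risk, [6, 4, 2, 1])

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.exponential(10, 50).round(2))
        curve = hm.km_estimate(t, np.ones(50))
        emp = 1 - np.searchsorted(np.sort(t), curve.times, side="right") / 50
        assert np.allclose(curve.survival, emp)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            hm.km_estimate([-1, 2], [1, 1])

    def test_survival_nonincreasing_from_one(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 100)
        e = rng.integers(0, 2, 100)
        curve = hm.km_estimate(t, e)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival[0] <= 1.0


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 1]
        chi2, p = hm.logrank(t + t, e + e, [0] * 5 + [1] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        g = rng.integers(0, 2, 80)
        a = hm.logrank(t, e, g)
        b = hm.logrank(t, e, 1 - g)
        assert a == pytest.approx(b)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        g = rng.integers(0, 2, 80)
        _, p1 = hm.logrank(t, e, g)
        _, p2 = hm.logrank(t * 42.0, e, g)
        assert p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty groups"):
            hm.logrank([1, 2, 3], [1, 1, 1], [0, 0, 0])


def _simulate_cox(n, beta, seed, censor_scale=40.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    lam = 0.05 * np.exp(beta * x)
    t_event = rng.exponential(1 / lam)
    t_cens = rng.uniform(0, censor_scale, n)
    return (np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int),
            pd.DataFrame({"x": x}))


class TestCoxPH:
    def test_matches_lifelines_on_tie_free_data(self):
        t, e, x = _simulate_cox(400, 0.7, seed=4)
        ours = hm.cox_ph(t, e, x)
        ref = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x["x"]}), "t", "e")
        assert ours.converged
        assert ours.table.loc["x", "coef"] == pytest.approx(
            float(ref.params_.iloc[0]), abs=1e-6)
        assert ours.table.loc["x", "se"] == pytest.approx(
            float(ref.standard_errors_.iloc[0]), rel=1e-4)

    def test_duplicated_dataset_preserves_estimate(self):
        t, e, x = _simulate_cox(150, 0.5, seed=5)
        a = hm.cox_ph(t, e, x)
        b = hm.cox_ph(np.r_[t, t], np.r_[e, e],
                      pd.concat([x, x], ignore_index=True))
        assert b.table.loc["x", "coef"] == pytest.approx(
            a.table.loc["x", "coef"], abs=1e-6)

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(6)
        covered = 0
        for seed in range(40):
            t, e, x = _simulate_cox(200, 0.5, seed=100 + seed)
            x["junk"] = rng.normal(size=len(t))
            res = hm.cox_ph(t, e, x)
            lo, hi = res.table.loc["junk", ["ci_low", "ci_high"]]
            covered += lo <= 1.0 <= hi
        assert covered >= 33     # ~95% coverage of 40

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            hm.cox_ph(np.arange(1, 30), np.zeros(29),
                      pd.DataFrame({"x": np.arange(29.0)}))

    def test_separation_flagged_not_crashed(self):
        # covariate perfectly ordered with survival: no finite optimum
        t = np.arange(1.0, 31.0)
        e = np.ones(30)
        x = pd.DataFrame({"x": np.arange(30.0)})
        res = hm.cox_ph(t, e, x)
        assert res.table.loc["x", "coef"] < 0   # longer life, higher x
        assert res.flags and "separation" in res.flags[0]


class TestEncodeCovariates:
    def test_reference_level_is_most_frequent(self, default_cohort):
        scores = hm.score_signature(default_cohort.expr)
        design = hm.encode_covariates(default_cohort.clinical, scores)
        assert "hs_high" in design.columns
        grade_ref = default_cohort.clinical.table["grade"].value_counts().index[0]
        assert f"grade_{grade_ref}" not in design.columns
        assert any(c.startswith("grade_") for c in design.columns)
        assert any(c.startswith("pam50_") for c in design.columns)

    def test_multivariate_fit_runs(self, default_cohort):
        scores = hm.score_signature(default_cohort.expr)
        design = hm.encode_covariates(default_cohort.clinical, scores)
        time, event = default_cohort.clinical.endpoint("os")
        res = hm.cox_ph(time.loc[design.index], event.loc[design.index], design)
        assert res.converged
        assert res.table.loc["hs_high", "hr"] > 1.0   # hypoxia is prognostic
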