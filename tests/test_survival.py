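import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from scipy.optimize import minimize_scalar

import integromics as ig
from integromics.model import survival_records_to_frame
from integromics.survival import (
    MedianSplitSurvival,
    cox_ph_fit,
    km_estimator,
    logrank_test,
    median_split,
)


def frame(times, events, markers=None, ages=None, stages=None):
    n = len(times)
    return pd.DataFrame(
        {
            "time": times,
            "event": events,
            "age": ages if ages is not None else [60.0] * n,
            "stage": stages if stages is not None else [1] * n,
            "marker": markers if markers is not None else np.arange(n, dtype=float),
        }
    )


class TestMedianSplit:
    def test_even_split(self):
        groups = median_split(frame([1] * 4, [1] * 4, markers=[1, 2, 3, 4]))
        assert list(groups) == ["Low", "Low", "High", "High"]

    def test_ties_go_low(self):
        groups = median_split(frame([1] * 4, [1] * 4, markers=[1, 2, 2, 4]))
        assert list(groups) == ["Low", "Low", "Low", "High"]

    def test_two_records_and_degenerate(self):
        groups = median_split(frame([1, 1], [1, 1], markers=[0.0, 1.0]))
        assert sorted(groups) == ["High", "Low"]
        with pytest.raises(ValueError, match="equal"):
            median_split(frame([1, 1], [1, 1], markers=[3.0, 3.0]))


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # events at t=1 (1 of 4 at risk) and t=2 (1 of 3) -> S(2) = 0.5
        df = frame([1, 2, 3, 4], [1, 1, 0, 0])
        curve = km_estimator(df)["all"]
        assert curve.survival_at(2.0) == pytest.approx(0.5)
        assert curve.survival_at(0.5) == 1.0
        np.testing.assert_allclose(curve.at_risk, [4, 3])

    def test_no_events_and_trailing_censor(self):
        no_events = km_estimator(frame([1, 2, 3], [0, 0, 0]))["all"]
        assert no_events.event_times.size == 0
        assert no_events.median is None
        assert no_events.survival_at(99) == 1.0

        base = km_estimator(frame([1, 2], [1, 1]))["all"]
        extra = km_estimator(frame([1, 2, 5], [1, 1, 0]))["all"]
        assert base.survival_at(2) != extra.survival_at(2)  # different n at risk
        # censoring strictly after the last event leaves the curve unchanged
        a = km_estimator(frame([1, 2, 3], [1, 1, 0]))["all"]
        b = km_estimator(frame([1, 2, 9], [1, 1, 0]))["all"]
        np.testing.assert_allclose(a.survival, b.survival)

    def test_median_first_time_below_half(self):
        df = frame([1, 2, 3, 4], [1, 1, 1, 1])
        curve = km_estimator(df)["all"]
        assert curve.median == 2.0

    def test_matches_lifelines_on_random_cohorts(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 60))
            times = rng.exponential(10, n).round(1) + 0.1
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            curve = km_estimator(frame(times, events))["all"]
            kmf = KaplanMeierFitter().fit(times, events)
            for t, s in zip(curve.event_times, curve.survival):
                assert s == pytest.approx(
                    float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-9
                )


class TestLogRank:
    def test_hand_fixture(self):
        # 4 subjects, one event in group 1 at t=1, 2 at risk per group
        df = frame([1, 5, 5, 5], [1, 0, 0, 0])
        groups = pd.Series(["g1", "g1", "g2", "g2"])
        chi2, p = logrank_test(df, groups)
        assert chi2 == pytest.approx(1.0)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_identical_groups_and_label_swap(self, rng):
        times = np.concatenate([rng.exponential(10, 20)] * 2)
        events = np.ones(40, dtype=int)
        df = frame(times, events)
        groups = pd.Series(["a"] * 20 + ["b"] * 20)
        chi2, _ = logrank_test(df, groups)
        swapped, _ = logrank_test(df, groups.map({"a": "b", "b": "a"}))
        assert chi2 == pytest.approx(swapped)
        same = frame([1, 2, 1, 2], [1, 1, 1, 1])
        chi2_same, p_same = logrank_test(same, pd.Series(["a", "a", "b", "b"]))
        assert chi2_same == pytest.approx(0.0)
        assert p_same == pytest.approx(1.0)

    def test_error_contracts(self):
        df = frame([1, 2], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            logrank_test(df, pd.Series(["a", "b"]))
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(frame([1, 2], [1, 1]), pd.Series(["a", "a"]))

    def test_matches_lifelines_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(10, 50)) * 2
            times = rng.exponential(10, n) + 0.01
            events = rng.integers(0, 2, n)
            groups = pd.Series(rng.choice(["a", "b"], n))
            if events.sum() == 0 or groups.nunique() < 2:
                continue
            df = frame(times, events)
            chi2, p = logrank_test(df, groups)
            ref = ll_logrank(
                times[groups == "a"], times[groups == "b"],
                events[groups == "a"], events[groups == "b"],
            )
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
            assert p == pytest.approx(ref.p_value, rel=1e-6)


class TestCox:
    def test_three_subject_grid_search_oracle(self):
        # no ties: partial likelihood L(b) maximized by scalar search; the
        # Low subject has the middle event so the maximizer is interior
        df = frame([1.0, 2.0, 3.0], [1, 1, 1], markers=[0.0, 1.0, 0.0])
        df["marker_group"] = ["High", "Low", "High"]
        fit = cox_ph_fit(df, covariates=["marker_group"])
        x = np.array([0.0, 1.0, 0.0])  # Low indicator, ordered by time

        def neg_log_pl(b):
            ll = 0.0
            for i in range(3):
                risk = np.exp(b * x[i:])
                ll += b * x[i] - np.log(risk.sum())
            return -ll

        opt = minimize_scalar(neg_log_pl, bounds=(-10, 10), method="bounded")
        assert fit.loc["marker_Low", "coef"] == pytest.approx(opt.x, abs=1e-4)

    def test_monotone_likelihood_flagged(self):
        # the Low subject fails first and leaves: likelihood increases in
        # beta without bound, which the fit must refuse rather than report
        df = frame([1.0, 2.0, 3.0], [1, 1, 1], markers=[1.0, 0.0, 0.0])
        df["marker_group"] = ["Low", "High", "High"]
        with pytest.raises(RuntimeError, match="monotone|converge"):
            cox_ph_fit(df, covariates=["marker_group"])

    def test_matches_lifelines_efron(self, rng):
        n = 300
        rec = ig.generate_survival_cohort(n=n, beta=0.6, censor_rate=0.3, seed=2)
        df = survival_records_to_frame(rec)
        df["marker_group"] = median_split(df)
        fit = cox_ph_fit(df, covariates=["marker_group", "age"])
        data = pd.DataFrame(
            {
                "time": df["time"],
                "event": df["event"],
                "low": (df["marker_group"] == "Low").astype(float),
                "age": df["age"],
            }
        )
        ref = CoxPHFitter().fit(data, "time", "event")
        assert fit.loc["marker_Low", "coef"] == pytest.approx(
            ref.summary.loc["low", "coef"], abs=1e-5
        )
        assert fit.loc["age", "coef"] == pytest.approx(
            ref.summary.loc["age", "coef"], abs=1e-5
        )

    def test_hr_parameter_recovery(self):
        rec = ig.generate_survival_cohort(
            n=2000, beta=np.log(2), censor_rate=0.3, seed=1
        )
        df = survival_records_to_frame(rec)
        df["marker_group"] = median_split(df)
        fit = cox_ph_fit(df)
        assert fit.loc["marker_Low", "HR"] == pytest.approx(2.0, rel=0.1)
        assert fit.loc["marker_Low", "ci_low"] < fit.loc["marker_Low", "HR"]
        assert fit.loc["marker_Low", "HR"] < fit.loc["marker_Low", "ci_high"]

    def test_null_coverage(self):
        # under beta=0, the 95% CI for the marker HR covers 1 in >=93% of runs
        covered = 0
        reps = 300
        for s in range(reps):
            rec = ig.generate_survival_cohort(
                n=120, beta=0.0, censor_rate=0.2, seed=50_000 + s
            )
            df = survival_records_to_frame(rec)
            df["marker_group"] = median_split(df)
            fit = cox_ph_fit(df, covariates=["marker_group"])
            lo, hi = fit.loc["marker_Low", ["ci_low", "ci_high"]]
            covered += lo <= 1.0 <= hi
        assert covered / reps >= 0.93

    def test_degenerate_covariate_and_tie_options(self):
        # Low/High alternate along the event order, so the fit is regular
        df = frame([1, 2, 3, 4], [1, 1, 1, 0], markers=[1, 3, 2, 4])
        df["marker_group"] = median_split(df)
        with pytest.raises(ValueError, match="degenerate"):
            cox_ph_fit(df, covariates=["marker_group", "stage"])
        with pytest.raises(ValueError, match="ties"):
            cox_ph_fit(df, covariates=["marker_group"], ties="exact")
        breslow = cox_ph_fit(df, covariates=["marker_group"], ties="breslow")
        assert np.isfinite(breslow.loc["marker_Low", "coef"])


class TestMedianSplitSurvivalEstimator:
    def test_full_fit(self):
        rec = ig.generate_survival_cohort(
            n=400, beta=np.log(2), censor_rate=0.3, seed=9
        )
        est = MedianSplitSurvival().fit(survival_records_to_frame(rec))
        assert set(est.km_curves_) == {"High", "Low"}
        assert est.logrank_p_ < 0.01
        assert est.cox_.loc["marker_Low", "HR"] > 1.3
        # Low group dies faster: its curve reaches the median earlier
        low, high = est.km_curves_["Low"], est.km_curves_["High"]
        if low.median is not None and high.median is not None:
            assert low.median < high.median
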