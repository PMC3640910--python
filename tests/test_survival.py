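"""Survival layer: KM vs brute force, Cox vs independent libraries,
case-processing arithmetic and endpoint semantics."""

import numpy as np
import pandas as pd
import pytest

from agnor.simulate import CohortEffectSpec, generate_cohort
from agnor.survival import (
    CaseProcessingSummary,
    case_processing_summary,
    cox_fit,
    endpoint_events,
    format_percent,
    km_estimate,
    round_half_up,
)


def km_brute_force(times, events):
    """Direct risk-set enumeration of the product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    rows = []
    for t in np.unique(times):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        c = int(np.sum((times == t) & (events == 0)))
        if d:
            s *= 1.0 - d / at_risk
        rows.append((t, at_risk, d, c, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "censored", "survival"])


class TestKaplanMeier:
    def test_three_events_by_hand(self):
        km = km_estimate([1, 2, 3])
        assert km["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km["at_risk"].tolist() == [3, 2, 1]

    def test_all_censored_flat_curve(self):
        km = km_estimate([5, 8, 13], events=[0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        times = np.round(rng.exponential(10, size=n), 1)  # rounding creates ties
        events = (rng.random(n) < 0.7).astype(int)
        got = km_estimate(times, events)
        want = km_brute_force(times, events)
        pd.testing.assert_frame_equal(
            got.astype(float), want.astype(float), check_exact=False, atol=1e-12
        )


@pytest.fixture(scope="module")
def cohort():
    spec = CohortEffectSpec(
        coefficients={"polym": 0.6, "pN": 0.4},
        baseline_hazard=0.001,
        admin_censor_months=240.0,
    )
    return generate_cohort(300, spec, seed=42)


class TestCoxFit:
    def test_matches_lifelines_efron(self, cohort):
        from lifelines import CoxPHFitter

        covs = ["polym", "pN", "G"]
        mine = cox_fit(cohort, covs, ties="efron")
        cph = CoxPHFitter().fit(
            cohort[covs + ["time_months", "event"]],
            duration_col="time_months",
            event_col="event",
        )
        np.testing.assert_allclose(mine.params.values, cph.params_.values, atol=1e-4)
        np.testing.assert_allclose(mine.bse.values, cph.standard_errors_.values, atol=1e-4)
        assert mine.llf == pytest.approx(cph.log_likelihood_, abs=1e-4)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_statsmodels_phreg(self, cohort, ties):
        from statsmodels.duration.hazard_regression import PHReg

        covs = ["polym", "G"]
        mine = cox_fit(cohort, covs, ties=ties)
        sm = PHReg(
            cohort["time_months"], cohort[covs], status=cohort["event"], ties=ties
        ).fit(disp=False)
        np.testing.assert_allclose(mine.params.values, sm.params, atol=1e-6)
        np.testing.assert_allclose(mine.bse.values, sm.bse, atol=1e-6)

    def test_hazard_ratio_is_exp_coef(self, cohort):
        res = cox_fit(cohort, ["polym"])
        assert res.hazard_ratios["polym"] == pytest.approx(np.exp(res.params["polym"]))
        assert 0.0 <= res.lr_pvalues["polym"] <= 1.0

    def test_constant_covariate_named_in_error(self, cohort):
        df = cohort.copy()
        df["flat"] = 0.0
        with pytest.raises(ValueError, match="flat"):
            cox_fit(df, ["polym", "flat"])

    def test_too_few_events_rejected(self, cohort):
        df = cohort.copy()
        df["event"] = 0
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["polym"])

    def test_listwise_deletion(self, cohort):
        df = cohort.copy()
        df.loc[df.index[:30], "polym"] = np.nan
        res = cox_fit(df, ["polym", "pN"])
        assert res.n == len(df) - 30

    def test_removing_covariate_never_increases_loglik(self, cohort):
        full = cox_fit(cohort, ["polym", "pN", "G"], compute_lr=False)
        reduced = cox_fit(cohort, ["polym", "pN"], compute_lr=False)
        assert full.llf >= reduced.llf - 1e-9
        assert reduced.llf >= reduced.llf_null - 1e-9


class TestEndpoints:
    def test_cause_specific_events_subset_of_overall(self, cohort):
        ov = endpoint_events(cohort, "overall")
        cs = endpoint_events(cohort, "cause_specific")
        assert (cs <= ov).all()
        assert cs.sum() < ov.sum()  # some deaths are from other causes

    def test_unknown_endpoint_rejected(self, cohort):
        with pytest.raises(ValueError, match="endpoint"):
            endpoint_events(cohort, "disease_free")


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(33.1967, 33.2), (61.4754, 61.5), (0.4098, 0.4), (94.672, 94.7), (2.45, 2.5)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_up(x) == expected

    @pytest.mark.parametrize(
        "x,expected", [(0.4098, ".4%"), (33.1967, "33.2%"), (100.0, "100.0%"), (0.0, "0.0%")]
    )
    def test_leading_zero_suppression(self, x, expected):
        assert format_percent(x) == expected


class TestCaseProcessing:
    def test_classification_on_constructed_cohort(self):
        df = pd.DataFrame(
            {
                "time_months": [10, 20, 30, 15, 2, 50],
                "event": [1, 1, 0, 0, 0, 0],
                "cause": ["breast_cancer", "other", "none", "none", "none", "none"],
                "pN": [1, 0, 2, 1, 0, np.nan],
            }
        )
        cp = case_processing_summary(df, "overall", covariates=["pN"])
        # one missing pN; the t=2 censored case precedes the earliest event (t=10)
        assert (cp.n_events, cp.n_censored, cp.n_missing, cp.n_early_censored) == (2, 2, 1, 1)
        assert cp.n_total == 6

        cs = case_processing_summary(df, "cause_specific", covariates=["pN"])
        assert cs.n_events == 1  # the other-cause death becomes censored
        assert cs.n_events + cs.n_censored + cs.n_unused == 6

    def test_no_exclusions_full_availability(self):
        df = pd.DataFrame(
            {"time_months": [5, 10, 15], "event": [1, 0, 1], "cause": ["breast_cancer"] * 3}
        )
        cp = case_processing_summary(df, "overall")
        assert cp.percent(cp.n_available) == 100.0

    def test_counts_partition_the_cohort(self):
        spec = CohortEffectSpec(baseline_hazard=0.004)
        df = generate_cohort(100, spec, seed=1)
        df.loc[df.index[:7], "G"] = np.nan
        cp = case_processing_summary(df, "overall", covariates=["G", "pN"])
        assert cp.n_events + cp.n_censored + cp.n_missing + cp.n_early_censored == 100

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            case_processing_summary(pd.DataFrame(), "overall")

    def test_report_frame_layout(self):
        cp = CaseProcessingSummary.from_counts(81, 150, 12, 1)
        frame = cp.to_frame()
        assert frame["N"].tolist() == [81, 150, 231, 12, 1, 13, 244]
        assert frame["percent"].tolist() == [
            "33.2%", "61.5%", "94.7%", "4.9%", ".4%", "5.3%", "100.0%",
        ]
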