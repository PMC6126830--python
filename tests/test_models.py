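"""Closed-form oracles and cross-library checks for the incidence, propensity
and Cox building blocks."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from pscox import (
    ModelError,
    fit_adjusted_cox,
    fit_cox,
    fit_propensity,
    incidence_rate,
)


class TestIncidence:
    def test_worked_rate_arithmetic(self):
        # 318 events over 50,237 person-years is 633 per 100,000 person-years
        assert round(incidence_rate(318, 50_237)) == 633
        # 412 events over 152,355 person-years is 270 per 100,000
        assert round(incidence_rate(412, 152_355)) == 270

    def test_scale_and_zero_events(self):
        assert incidence_rate(0, 100.0) == 0.0
        assert incidence_rate(5, 100.0, scale=1000.0) == 50.0

    def test_nonpositive_person_years_rejected(self):
        with pytest.raises(ModelError):
            incidence_rate(3, 0.0)
        with pytest.raises(ModelError):
            incidence_rate(3, -1.0)


class TestPropensity:
    def test_intercept_only_score_is_the_exposure_mean(self):
        df = pd.DataFrame({"D": [1, 1, 0, 0, 0, 0, 0, 1]})
        ps = fit_propensity(df, [])
        assert np.allclose(ps.scores, df["D"].mean(), atol=1e-8)
        assert ps.variant == "error_prone"

    def test_single_binary_covariate_matches_group_means(self):
        """With one binary covariate the MLE scores equal the within-stratum
        exposure proportions (saturated model)."""
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, size=2000)
        p = np.where(x == 1, 0.6, 0.25)
        d = (rng.random(2000) < p).astype(int)
        df = pd.DataFrame({"D": d, "x": x.astype(float)})
        ps = fit_propensity(df, ["x"])
        for level in (0, 1):
            stratum = df[df["x"] == level]
            assert np.allclose(
                ps.scores[stratum.index], stratum["D"].mean(), atol=1e-6
            )

    def test_mean_score_equals_exposure_prevalence(self):
        """Logistic MLE with an intercept balances the score: the average
        fitted probability equals the observed exposure rate."""
        rng = np.random.default_rng(8)
        n = 5000
        x = rng.normal(size=n)
        d = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))).astype(int)
        ps = fit_propensity(pd.DataFrame({"D": d, "x": x}), ["x"])
        assert abs(ps.scores.mean() - d.mean()) < 1e-8

    def test_coefficient_recovery_large_sample(self):
        rng = np.random.default_rng(12)
        n = 50_000
        x = rng.normal(size=n)
        z = rng.integers(0, 2, size=n).astype(float)
        lp = -1.0 + 0.7 * x - 0.4 * z
        d = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        ps = fit_propensity(pd.DataFrame({"D": d, "x": x, "z": z}), ["x", "z"])
        assert abs(ps.params["const"] - (-1.0)) < 0.05
        assert abs(ps.params["x"] - 0.7) < 0.05
        assert abs(ps.params["z"] - (-0.4)) < 0.07

    def test_gold_standard_variant_and_predict(self):
        rng = np.random.default_rng(3)
        n = 1000
        df = pd.DataFrame(
            {
                "D": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
                "m": rng.normal(size=n),
            }
        )
        ps = fit_propensity(df, ["x"], missing_covariates=["m"])
        assert ps.variant == "gold_standard"
        assert np.allclose(ps.predict(df, ["x", "m"]), ps.scores, atol=1e-10)

    def test_single_group_and_missing_values_rejected(self):
        with pytest.raises(ModelError, match="both exposure groups"):
            fit_propensity(pd.DataFrame({"D": [1, 1, 1]}), [])
        df = pd.DataFrame({"D": [0, 1, 0], "x": [1.0, np.nan, 2.0]})
        with pytest.raises(ModelError, match="missing values"):
            fit_propensity(df, ["x"])


def _exponential_cohort(rng, n, lam0, rate_ratio, censor_at=5.0):
    d = rng.integers(0, 2, size=n)
    lam = lam0 * np.where(d == 1, rate_ratio, 1.0)
    t = rng.exponential(1 / lam)
    event = (t <= censor_at).astype(int)
    return pd.DataFrame(
        {
            "D": d,
            "followup_years": np.minimum(t, censor_at),
            "event": event,
        }
    )


class TestCox:
    def test_recovers_exponential_rate_ratio(self):
        """With exponential event times the hazard ratio is the rate ratio;
        the Cox estimate must land within 2 SE of log(2)."""
        rng = np.random.default_rng(17)
        df = _exponential_cohort(rng, 20_000, lam0=0.05, rate_ratio=2.0)
        fit = fit_cox(df, ["D"])
        assert abs(fit.beta - np.log(2.0)) < 2 * fit.se_beta
        # the crude occurrence/exposure estimator agrees with the Cox HR
        grouped = df.groupby("D")
        rate = grouped["event"].sum() / grouped["followup_years"].sum()
        assert abs(np.log(rate[1] / rate[0]) - fit.beta) < 0.05

    def test_label_swap_flips_the_sign(self):
        rng = np.random.default_rng(23)
        df = _exponential_cohort(rng, 5000, lam0=0.05, rate_ratio=1.8)
        flipped = df.assign(D=1 - df["D"])
        a = fit_cox(df, ["D"])
        b = fit_cox(flipped, ["D"])
        assert np.isclose(a.beta, -b.beta, atol=1e-8)
        assert np.isclose(a.se_beta, b.se_beta, atol=1e-8)

    def test_time_rescaling_invariance(self):
        """The partial likelihood depends only on the event-time ordering, so
        scaling every follow-up time leaves the coefficient unchanged."""
        rng = np.random.default_rng(29)
        df = _exponential_cohort(rng, 3000, lam0=0.08, rate_ratio=1.5)
        scaled = df.assign(followup_years=df["followup_years"] * 7.3)
        a = fit_cox(df, ["D"])
        b = fit_cox(scaled, ["D"])
        assert np.isclose(a.beta, b.beta, atol=1e-8)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(31)
        df = _exponential_cohort(rng, 4000, lam0=0.06, rate_ratio=1.7)
        df["x"] = rng.normal(size=len(df))
        ours = fit_cox(df, ["D", "x"])
        cph = CoxPHFitter()
        cph.fit(df, duration_col="followup_years", event_col="event")
        assert abs(ours.beta - cph.params_["D"]) < 1e-4
        assert abs(ours.coefficient("x") - cph.params_["x"]) < 1e-4
        assert abs(ours.se_beta - cph.standard_errors_["D"]) < 1e-4

    def test_breslow_and_efron_agree_without_ties(self):
        rng = np.random.default_rng(37)
        df = _exponential_cohort(rng, 2000, lam0=0.05, rate_ratio=1.4)
        a = fit_cox(df, ["D"], ties="efron")
        b = fit_cox(df, ["D"], ties="breslow")
        assert np.isclose(a.beta, b.beta, atol=1e-6)

    def test_summary_quantities_are_consistent(self):
        rng = np.random.default_rng(41)
        df = _exponential_cohort(rng, 3000, lam0=0.05, rate_ratio=1.6)
        fit = fit_cox(df, ["D"])
        lo, hi = fit.hr_ci()
        assert lo < fit.hr < hi
        assert np.isclose(fit.hr, np.exp(fit.beta))
        assert 0 <= fit.p_value <= 1
        d = fit.to_dict()
        assert d["events"] == int(df["event"].sum())
        assert d["n"] == len(df)

    def test_input_validation(self):
        base = pd.DataFrame(
            {"D": [0, 1, 0, 1], "followup_years": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 1, 0]}
        )
        with pytest.raises(ModelError, match="positive"):
            fit_cox(base.assign(followup_years=[0.0, 2.0, 3.0, 4.0]), ["D"])
        with pytest.raises(ModelError, match="no events"):
            fit_cox(base.assign(event=0), ["D"])
        with pytest.raises(ModelError, match="ties"):
            fit_cox(base, ["D"], ties="exact")
        with pytest.raises(ModelError, match="exposure term"):
            fit_cox(base.assign(x=1.0), ["x"], exposure="D")


class TestAdjustedCox:
    def test_ps_adjustment_removes_measured_confounding(self):
        """A confounder that raises both exposure odds and the hazard biases
        the crude HR upward; conditioning on PS = Pr(D|x) restores the truth
        (here beta = 0) within Monte-Carlo error."""
        rng = np.random.default_rng(43)
        n = 20_000
        x = rng.integers(0, 2, size=n).astype(float)
        d = (rng.random(n) < np.where(x == 1, 0.6, 0.2)).astype(int)
        lam = 0.05 * np.exp(0.9 * x)  # outcome depends on x only
        t = rng.exponential(1 / lam)
        df = pd.DataFrame(
            {
                "D": d,
                "x": x,
                "followup_years": np.minimum(t, 5.0),
                "event": (t <= 5.0).astype(int),
            }
        )
        crude = fit_cox(df, ["D"])
        adjusted, ps = fit_adjusted_cox(df, ["x"])
        assert crude.beta > 0.15  # confounding is material
        assert abs(adjusted.beta) < 3 * adjusted.se_beta
        assert ps.variant == "error_prone"
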