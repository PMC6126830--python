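"""Hand-traced entry criteria, Charlson scoring, matching invariants and
follow-up arithmetic."""

import numpy as np
import pandas as pd
import pytest

from pscox import (
    CHARLSON_WEIGHTS,
    CohortCriteria,
    CohortError,
    MatchingError,
    build_cohort,
    compute_cci,
    compute_followup,
    expected_control_count,
    identify_copd_cohort,
    match_controls,
)
from pscox.simulate import SimulationConfig, simulate_population

from conftest import dx, person, rx


def qualifying_claims(pid, index="2004-02-01"):
    """Claims satisfying every entry criterion, index at first treated visit."""
    idx = pd.Timestamp(index)
    return (
        [
            dx(pid, idx - pd.Timedelta(days=40), "491"),
            dx(pid, idx - pd.Timedelta(days=10), "496"),
        ],
        [
            rx(pid, idx, "SAMA"),
            rx(pid, idx + pd.Timedelta(days=35), "SAMA"),
            rx(pid, idx + pd.Timedelta(days=70), "SAMA"),
        ],
    )


class TestEntryCriteria:
    def test_qualifying_person_included_with_first_treated_visit_as_index(
        self, hand_bundle_factory
    ):
        d, r = qualifying_claims(1)
        bundle = hand_bundle_factory([person(1)], d, r)
        cohort = identify_copd_cohort(bundle)
        assert cohort["person_id"].tolist() == [1]
        assert cohort.loc[0, "index_date"] == pd.Timestamp("2004-02-01")
        assert cohort.loc[0, "age_years"] == 72  # born 1932
        assert cohort.loc[0, "age_band"] == ">70"

    def test_washout_violation_excludes(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        r.append(rx(1, "2003-09-15", "SAMA"))
        bundle = hand_bundle_factory([person(1)], d, r)
        assert identify_copd_cohort(bundle).empty

    def test_rx_just_outside_washout_is_allowed(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        r.append(rx(1, "2003-01-20", "SAMA"))  # > 365 days before index
        bundle = hand_bundle_factory([person(1)], d, r)
        assert len(identify_copd_cohort(bundle)) == 1

    def test_age_50_exactly_excluded(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        bundle = hand_bundle_factory([person(1, birth_year=1954)], d, r)
        assert identify_copd_cohort(bundle).empty

    def test_single_diagnosis_date_excluded(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        bundle = hand_bundle_factory([person(1)], d[:1], r)
        assert identify_copd_cohort(bundle).empty

    def test_two_rx_claims_excluded(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        bundle = hand_bundle_factory([person(1)], d, r[:2])
        assert identify_copd_cohort(bundle).empty

    def test_prior_prostate_cancer_excluded(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        d.append(dx(1, "2003-05-01", "185"))
        bundle = hand_bundle_factory([person(1)], d, r)
        assert identify_copd_cohort(bundle).empty

    def test_empty_claims_yield_empty_cohort(self, hand_bundle_factory):
        bundle = hand_bundle_factory([person(1)], [], [])
        assert identify_copd_cohort(bundle).empty

    def test_criteria_are_idempotent(self, small_bundle):
        first = identify_copd_cohort(small_bundle)
        again = identify_copd_cohort(small_bundle)
        pd.testing.assert_frame_equal(first, again)


class TestCharlson:
    def test_no_claims_scores_zero(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        bundle = hand_bundle_factory([person(1)], d, r)
        cohort = identify_copd_cohort(bundle)
        scored = compute_cci(cohort, bundle)
        assert scored.loc[0, "cci_score"] == 0
        assert scored.loc[0, "myocardial_infarction"] == 0

    def test_single_condition_unit_and_charlson_weights(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        d.append(dx(1, "2003-03-01", "410"))  # myocardial infarction
        d.append(dx(1, "2003-03-02", "585"))  # renal disease
        bundle = hand_bundle_factory([person(1)], d, r)
        cohort = identify_copd_cohort(bundle)
        unit = compute_cci(cohort, bundle)
        assert unit.loc[0, "cci_score"] == 2  # 1 + 1
        classic = compute_cci(cohort, bundle, weights=CHARLSON_WEIGHTS)
        assert classic.loc[0, "cci_score"] == 3  # 1 + 2

    def test_post_index_claims_do_not_count(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        d.append(dx(1, "2004-02-01", "410"))  # on index: counts (half-open rule)
        d.append(dx(1, "2004-06-01", "428"))  # after index: ignored
        bundle = hand_bundle_factory([person(1)], d, r)
        scored = compute_cci(identify_copd_cohort(bundle), bundle)
        assert scored.loc[0, "myocardial_infarction"] == 1
        assert scored.loc[0, "congestive_heart_failure"] == 0

    def test_unknown_comorbidity_in_weights_rejected(self, hand_bundle_factory):
        d, r = qualifying_claims(1)
        bundle = hand_bundle_factory([person(1)], d, r)
        cohort = identify_copd_cohort(bundle)
        with pytest.raises(CohortError, match="gout"):
            compute_cci(cohort, bundle, weights={"gout": 1})

    def test_simulated_cohort_reproduces_reference_cci_means(self):
        """Under the default prevalence calibration the unweighted Charlson
        count averages ~1.7 (COPD) and ~1.2 (controls), SD ~1.5/1.3."""
        cfg = SimulationConfig(n_persons=20_000)
        bundle = simulate_population(cfg, seed=3)
        cohort = build_cohort(bundle, ratio=3, seed=3)
        for d, target, sd in ((1, 1.7, 1.5), (0, 1.2, 1.3)):
            sub = cohort[cohort["D"] == d]
            se = sd / np.sqrt(len(sub))
            assert abs(sub["cci_score"].mean() - target) < 3 * se + 0.05


class TestMatching:
    def _cases(self, n, band_age=75):
        return pd.DataFrame(
            {
                "person_id": range(1, n + 1),
                "D": 1,
                "index_date": pd.Timestamp("2004-03-01"),
                "age_years": float(band_age),
                "age_band": ">70",
            }
        )

    def _pool_bundle(self, hand_bundle_factory, n_pool, birth_year=1930):
        persons = [person(1000 + i, birth_year=birth_year) for i in range(n_pool)]
        return hand_bundle_factory(persons, [], [])

    def test_exhaustive_selection_without_repeats(self, hand_bundle_factory):
        cases = self._cases(2)
        bundle = self._pool_bundle(hand_bundle_factory, 6)
        controls = match_controls(cases, bundle, ratio=3, seed=0)
        assert len(controls) == 6
        assert controls["person_id"].is_unique
        assert set(controls["person_id"]) == {1000 + i for i in range(6)}
        assert (controls["age_band"] == ">70").all()

    def test_pool_exhaustion_is_an_error(self, hand_bundle_factory):
        cases = self._cases(2)
        bundle = self._pool_bundle(hand_bundle_factory, 5)
        with pytest.raises(MatchingError, match=">70"):
            match_controls(cases, bundle, ratio=3, seed=0)

    def test_zero_cases_zero_controls(self, hand_bundle_factory):
        bundle = self._pool_bundle(hand_bundle_factory, 3)
        controls = match_controls(self._cases(0).iloc[:0], bundle, ratio=3, seed=0)
        assert controls.empty

    def test_controls_inherit_index_and_exclude_copd_claimants(
        self, hand_bundle_factory
    ):
        cases = self._cases(1)
        persons = [person(1000 + i, birth_year=1930) for i in range(4)]
        diagnoses = [dx(1001, "2004-05-01", "491")]  # stray COPD dx -> ineligible
        bundle = hand_bundle_factory(persons, diagnoses, [])
        controls = match_controls(cases, bundle, ratio=3, seed=0)
        assert 1001 not in set(controls["person_id"])
        assert (controls["index_date"] == pd.Timestamp("2004-03-01")).all()

    def test_prior_cancer_controls_skipped(self, hand_bundle_factory):
        cases = self._cases(1)
        persons = [person(1000 + i, birth_year=1930) for i in range(4)]
        diagnoses = [dx(1002, "2004-01-15", "185")]  # cancer before inherited index
        bundle = hand_bundle_factory(persons, diagnoses, [])
        controls = match_controls(cases, bundle, ratio=3, seed=0)
        assert 1002 not in set(controls["person_id"])

    def test_determinism_and_count_identity(self, small_bundle):
        cases = identify_copd_cohort(small_bundle)
        a = match_controls(cases, small_bundle, ratio=3, seed=4)
        b = match_controls(cases, small_bundle, ratio=3, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == expected_control_count(len(cases), 3)
        assert not set(a["person_id"]) & set(cases["person_id"])
        # band agreement with the matched case
        case_band = cases.set_index("person_id")["age_band"]
        assert (
            a["age_band"].astype(str)
            == case_band.reindex(a["matched_case_id"]).astype(str).to_numpy()
        ).all()


class TestFollowup:
    def _cohort_row(self, index="2004-01-01"):
        return pd.DataFrame(
            {
                "person_id": [1],
                "D": [1],
                "index_date": [pd.Timestamp(index)],
                "age_years": [72.0],
                "age_band": [">70"],
            }
        )

    def test_full_followup_to_admin_end(self, hand_bundle_factory):
        bundle = hand_bundle_factory([person(1)], [], [])
        out = compute_followup(self._cohort_row(), bundle)
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "censor_reason"] == "admin_end"
        assert abs(out.loc[0, "followup_years"] - 5.0) < 2 / 365.25

    def test_event_time_and_flag(self, hand_bundle_factory):
        bundle = hand_bundle_factory(
            [person(1)], [dx(1, "2006-07-01", "185")], []
        )
        out = compute_followup(self._cohort_row("2004-07-01"), bundle)
        assert out.loc[0, "event"] == 1
        assert out.loc[0, "censor_reason"] == "event"
        assert abs(out.loc[0, "followup_years"] - 2.0) < 2 / 365.25

    def test_withdrawal_precedes_later_cancer(self, hand_bundle_factory):
        bundle = hand_bundle_factory(
            [person(1, enroll_end=pd.Timestamp("2005-01-01"))],
            [dx(1, "2006-01-01", "185")],
            [],
        )
        out = compute_followup(self._cohort_row(), bundle)
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "censor_reason"] == "death_or_withdrawal"
        assert abs(out.loc[0, "followup_years"] - 1.0) < 2 / 365.25

    def test_event_before_index_is_a_consistency_error(self, hand_bundle_factory):
        bundle = hand_bundle_factory(
            [person(1)], [dx(1, "2003-12-01", "185")], []
        )
        with pytest.raises(CohortError, match="exclude upstream"):
            compute_followup(self._cohort_row(), bundle)

    def test_person_time_accounting_identity(self, small_bundle):
        cohort = build_cohort(small_bundle, ratio=3, seed=4)
        total = cohort["followup_years"].sum()
        by_group = cohort.groupby("D")["followup_years"].sum()
        assert np.isclose(total, by_group.sum())
        assert (cohort["followup_years"] > 0).all()
        assert ((cohort["event"] == 1) == (cohort["censor_reason"] == "event")).all()
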