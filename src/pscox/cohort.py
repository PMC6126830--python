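"""Cohort construction from claims: entry criteria, Charlson index, matching
and follow-up.

The treated cohort comprises men older than 50 with at least two COPD
diagnoses (ICD-9-CM 491/492/496) before their first treated visit of the
accrual year, at least three pharmacotherapy claims in that year, a clean
one-year medication washout, and no prostate-cancer code before the index
date.  Controls are drawn 3:1 from COPD-free persons, matched on sex and age
band, and inherit the matched case's index date so that person-time starts
at a comparable origin (avoiding immortal-time bias).

Date conventions are half-open around the index date: a diagnosis claim on
the index date counts as pre-index for comorbidity ascertainment and for the
prior-cancer exclusion; outcome events are counted strictly after index so
follow-up time is always positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    ADMIN_END,
    ACCRUAL_END,
    COPD_DX_PREFIXES,
    DAYS_PER_YEAR,
    PROSTATE_CA_CODE,
    STUDY_START,
    ClaimsBundle,
    SimulationConfig,
    age_band,
)

#: inhaled classes plus oral bronchodilators all count as COPD pharmacotherapy
COPD_RX_CLASSES = ("SAMA", "SABA", "LAMA", "LABA", "LABA_ICS", "xanthine")

#: classic Charlson weights for the conditions tracked here (weight 1 unless
#: listed).  The unit map scores each condition 1, i.e. a comorbidity count.
CHARLSON_WEIGHTS: dict[str, int] = {
    "diabetes_with_complications": 2,
    "paraplegia_hemiplegia": 2,
    "renal_disease": 2,
    "moderate_severe_liver_disease": 2,
    "metastatic_carcinoma": 6,
    "aids_hiv": 6,
}
UNIT_WEIGHTS: dict[str, int] = {}

#: ICD-9-CM prefixes per comorbidity; a diagnosis claim matches when its code
#: starts with any listed prefix.
DEFAULT_CCI_CODE_MAP: dict[str, tuple[str, ...]] = {
    "myocardial_infarction": ("410", "412"),
    "congestive_heart_failure": ("428",),
    "peripheral_vascular_disease": ("443",),
    "cerebrovascular_disease": ("430", "431", "432", "433", "434", "435", "436", "437", "438"),
    "dementia": ("290",),
    "rheumatic_disease": ("714.0", "710.0"),
    "peptic_ulcer_disease": ("531", "532", "533", "534"),
    "mild_liver_disease": ("571",),
    "diabetes_without_complications": ("250.0", "250.1", "250.2", "250.3"),
    "diabetes_with_complications": ("250.4", "250.5", "250.6", "250.7"),
    "paraplegia_hemiplegia": ("342", "344"),
    "renal_disease": ("582", "583", "585", "586"),
    "moderate_severe_liver_disease": ("572",),
    "metastatic_carcinoma": ("196", "197", "198", "199"),
    "aids_hiv": ("042", "043", "044"),
}


class CohortError(ValueError):
    pass


class MatchingError(CohortError):
    """Raised when a matching stratum cannot supply enough controls."""


@dataclass
class CohortCriteria:
    """Entry criteria for the treated cohort."""

    min_age: int = 51
    sex: str = "M"
    min_dx_dates: int = 2
    dx_code_prefixes: Sequence[str] = COPD_DX_PREFIXES
    min_rx_claims: int = 3
    rx_classes: Sequence[str] = COPD_RX_CLASSES
    washout_days: int = 365
    exclusion_dx_prefix: str = PROSTATE_CA_CODE
    accrual_start: pd.Timestamp = STUDY_START
    accrual_end: pd.Timestamp = ACCRUAL_END
    admin_end: pd.Timestamp = ADMIN_END

    def __post_init__(self) -> None:
        self.accrual_start = pd.Timestamp(self.accrual_start)
        self.accrual_end = pd.Timestamp(self.accrual_end)
        self.admin_end = pd.Timestamp(self.admin_end)
        if self.accrual_start >= self.accrual_end:
            raise CohortError("accrual window start must precede its end")
        if self.min_dx_dates < 1 or self.min_rx_claims < 1:
            raise CohortError("claim-count criteria must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortCriteria":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _matches_prefix(codes: pd.Series, prefixes: Sequence[str]) -> pd.Series:
    codes = codes.astype(str)
    mask = pd.Series(False, index=codes.index)
    for prefix in prefixes:
        mask |= codes.str.startswith(prefix)
    return mask


def _age_at_index(birth_year: pd.Series, index_date: pd.Series) -> pd.Series:
    """Whole-year age at the index date under the mid-year (July 1) birthday
    convention: age = index year - birth year."""
    return index_date.dt.year - birth_year


def identify_copd_cohort(
    bundle: ClaimsBundle, criteria: CohortCriteria | None = None
) -> pd.DataFrame:
    """Apply the treated-cohort criteria; returns D=1 rows with index dates.

    The index date is the first pharmacotherapy claim inside the accrual
    window.  Empty claims tables yield an empty cohort.
    """
    criteria = criteria or CohortCriteria()
    persons = bundle.persons
    dx = bundle.diagnosis_claims
    rx = bundle.prescription_claims

    copd_rx = rx[rx["drug_class"].isin(criteria.rx_classes)]
    in_window = copd_rx[
        (copd_rx["date"] >= criteria.accrual_start)
        & (copd_rx["date"] <= criteria.accrual_end)
    ]
    if in_window.empty:
        return _empty_cohort()

    grouped = in_window.groupby("person_id")["date"]
    counts = grouped.size()
    index_dates = grouped.min()
    eligible = counts[counts >= criteria.min_rx_claims].index
    index_dates = index_dates.loc[eligible]

    frame = persons.set_index("person_id").loc[index_dates.index]
    frame = frame[frame["sex"] == criteria.sex]
    index_dates = index_dates.loc[frame.index]
    age = _age_at_index(frame["birth_year"], index_dates)
    keep = age >= criteria.min_age
    frame, index_dates, age = frame[keep], index_dates[keep], age[keep]

    # at least min_dx_dates distinct COPD diagnosis dates on or before index
    copd_dx = dx[_matches_prefix(dx["icd9_code"], criteria.dx_code_prefixes)]
    copd_dx = copd_dx[copd_dx["person_id"].isin(frame.index)].copy()
    copd_dx["index_date"] = copd_dx["person_id"].map(index_dates)
    pre_index = copd_dx[copd_dx["date"] <= copd_dx["index_date"]]
    dx_dates = pre_index.groupby("person_id")["date"].nunique()
    keep_ids = dx_dates[dx_dates >= criteria.min_dx_dates].index
    frame, index_dates, age = (
        frame.loc[keep_ids],
        index_dates.loc[keep_ids],
        age.loc[keep_ids],
    )

    # washout: no COPD pharmacotherapy in the year before the index date
    prior_rx = copd_rx[copd_rx["person_id"].isin(frame.index)].copy()
    prior_rx["index_date"] = prior_rx["person_id"].map(index_dates)
    washout_lo = prior_rx["index_date"] - pd.to_timedelta(
        criteria.washout_days, unit="D"
    )
    violators = prior_rx.loc[
        (prior_rx["date"] >= washout_lo) & (prior_rx["date"] < prior_rx["index_date"]),
        "person_id",
    ].unique()
    keep_ids = frame.index.difference(violators)
    frame, index_dates, age = (
        frame.loc[keep_ids],
        index_dates.loc[keep_ids],
        age.loc[keep_ids],
    )

    # exclusion: prostate-cancer code on or before index
    ca = dx[_matches_prefix(dx["icd9_code"], [criteria.exclusion_dx_prefix])]
    ca = ca[ca["person_id"].isin(frame.index)].copy()
    ca["index_date"] = ca["person_id"].map(index_dates)
    prior_ca = ca.loc[ca["date"] <= ca["index_date"], "person_id"].unique()
    keep_ids = frame.index.difference(prior_ca)
    frame, index_dates, age = (
        frame.loc[keep_ids],
        index_dates.loc[keep_ids],
        age.loc[keep_ids],
    )

    # must still be enrolled at index (positive follow-up)
    enrolled = frame["enroll_end"].isna() | (frame["enroll_end"] > index_dates)
    frame, index_dates, age = (
        frame[enrolled],
        index_dates[enrolled],
        age[enrolled],
    )

    out = pd.DataFrame(
        {
            "person_id": frame.index.to_numpy(),
            "D": 1,
            "index_date": index_dates.to_numpy(),
            "age_years": age.to_numpy(dtype=float),
        }
    ).sort_values("person_id", kind="mergesort")
    out["age_band"] = age_band(out["age_years"].to_numpy())
    return out.reset_index(drop=True)


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": pd.Series(dtype=int),
            "D": pd.Series(dtype=int),
            "index_date": pd.Series(dtype="datetime64[ns]"),
            "age_years": pd.Series(dtype=float),
            "age_band": pd.Series(dtype=object),
        }
    )


def compute_cci(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    code_map: Mapping[str, Sequence[str]] | None = None,
    weights: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Attach comorbidity flags and the Charlson score to a cohort table.

    A flag is set when at least one matching diagnosis claim falls on or
    before the subject's index date; the score is the weight-weighted sum of
    flags.  ``weights`` defaults to the unit map (a plain comorbidity
    count); pass :data:`CHARLSON_WEIGHTS` for the classic weighting.
    """
    code_map = dict(code_map or DEFAULT_CCI_CODE_MAP)
    weights = dict(UNIT_WEIGHTS if weights is None else weights)
    unknown = set(weights) - set(code_map)
    if unknown:
        raise CohortError(f"weights reference unknown comorbidities: {sorted(unknown)}")

    dx = bundle.diagnosis_claims
    dx = dx[dx["person_id"].isin(cohort["person_id"])]
    merged = dx.merge(cohort[["person_id", "index_date"]], on="person_id")
    pre = merged[merged["date"] <= merged["index_date"]]

    out = cohort.copy()
    score = np.zeros(len(out))
    for name, prefixes in code_map.items():
        hit_ids = pre.loc[_matches_prefix(pre["icd9_code"], prefixes), "person_id"]
        flag = out["person_id"].isin(set(hit_ids)).astype(int)
        out[name] = flag
        score += weights.get(name, 1) * flag.to_numpy()
    out["cci_score"] = score
    return out


def match_controls(
    cases: pd.DataFrame,
    bundle: ClaimsBundle,
    ratio: int = 3,
    seed: int = 0,
    criteria: CohortCriteria | None = None,
) -> pd.DataFrame:
    """Draw ``ratio`` sex/age-band-matched controls per case.

    The pool is every person with no COPD diagnosis or pharmacotherapy
    claim.  Within each (sex, age band) stratum the eligible pool is
    shuffled once (seeded) and assigned greedily in case order, without
    replacement, skipping candidates with a prostate-cancer code on or
    before the case's index date.  Controls inherit the case's index date.

    Raises :class:`MatchingError` listing the stratum and shortfall when a
    stratum is exhausted; no silent partial matching.
    """
    criteria = criteria or CohortCriteria()
    if ratio < 1:
        raise CohortError("matching ratio must be >= 1")
    if cases.empty:
        return _empty_cohort()

    persons = bundle.persons
    dx = bundle.diagnosis_claims
    rx = bundle.prescription_claims

    copd_dx_ids = set(
        dx.loc[_matches_prefix(dx["icd9_code"], criteria.dx_code_prefixes), "person_id"]
    )
    copd_rx_ids = set(rx.loc[rx["drug_class"].isin(criteria.rx_classes), "person_id"])
    excluded = copd_dx_ids | copd_rx_ids | set(cases["person_id"])

    pool = persons[
        (persons["sex"] == criteria.sex) & ~persons["person_id"].isin(excluded)
    ].copy()
    # all index dates fall in the accrual year, so banding at the accrual
    # year is exact for inherited index dates
    pool_age = criteria.accrual_start.year - pool["birth_year"]
    pool = pool[pool_age >= criteria.min_age]
    pool["age_years"] = pool_age[pool.index].astype(float)
    pool["age_band"] = age_band(pool["age_years"].to_numpy())

    ca = dx[_matches_prefix(dx["icd9_code"], [criteria.exclusion_dx_prefix])]
    first_ca = ca.groupby("person_id")["date"].min()

    rng = np.random.default_rng(seed)
    picked_rows: list[dict] = []
    for (sex, band), stratum_cases in cases.groupby(
        [pd.Series(criteria.sex, index=cases.index), "age_band"],
        observed=True,
        sort=True,
    ):
        stratum_pool = pool[pool["age_band"] == band]
        order = rng.permutation(len(stratum_pool))
        candidates = stratum_pool.iloc[order]
        cand_ids = candidates["person_id"].to_numpy()
        cand_ages = candidates["age_years"].to_numpy()
        cand_ca = first_ca.reindex(cand_ids).to_numpy()
        cand_end = candidates["enroll_end"].to_numpy()
        pos = 0
        for _, case in stratum_cases.iterrows():
            index_date = case["index_date"]
            taken = 0
            while taken < ratio:
                if pos >= len(cand_ids):
                    raise MatchingError(
                        f"stratum (sex={sex}, band={band}) exhausted: "
                        f"short by {ratio - taken} controls for case "
                        f"{case['person_id']}"
                    )
                cid, cage, cca = cand_ids[pos], cand_ages[pos], cand_ca[pos]
                cend = cand_end[pos]
                pos += 1
                if pd.notna(cca) and cca <= index_date:
                    continue  # prior prostate cancer at inherited index
                if pd.notna(cend) and cend <= index_date:
                    continue  # disenrolled before the inherited index
                picked_rows.append(
                    {
                        "person_id": int(cid),
                        "D": 0,
                        "index_date": index_date,
                        "age_years": float(cage),
                        "age_band": band,
                        "matched_case_id": int(case["person_id"]),
                    }
                )
                taken += 1

    controls = pd.DataFrame(picked_rows)
    controls["index_date"] = pd.to_datetime(controls["index_date"])
    return controls.reset_index(drop=True)


def expected_control_count(n_cases: int, ratio: int) -> int:
    """Control count implied by exact k:1 matching with no stratum exhaustion."""
    return int(n_cases) * int(ratio)


def compute_followup(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    admin_end: pd.Timestamp = ADMIN_END,
) -> pd.DataFrame:
    """Derive follow-up years, event flag and censoring reason.

    Follow-up ends at the earliest of: first prostate-cancer claim after
    index, enrollment end (death or withdrawal), administrative end.  An
    outcome claim on or before the index date is a data-consistency error --
    such subjects belong to the upstream exclusion.
    """
    admin_end = pd.Timestamp(admin_end)
    if (cohort["index_date"] > admin_end).any():
        raise CohortError("index dates after the administrative end of follow-up")

    dx = bundle.diagnosis_claims
    ca = dx[_matches_prefix(dx["icd9_code"], [PROSTATE_CA_CODE])]
    ca = ca[ca["person_id"].isin(cohort["person_id"])]
    merged = ca.merge(cohort[["person_id", "index_date"]], on="person_id")
    bad = merged[merged["date"] <= merged["index_date"]]
    if not bad.empty:
        raise CohortError(
            "prostate-cancer claim on or before index for person(s) "
            f"{sorted(bad['person_id'].unique())[:5]}; exclude upstream"
        )
    first_ca = merged.groupby("person_id")["date"].min()

    out = cohort.copy()
    enroll_end = pd.to_datetime(
        bundle.persons.set_index("person_id")["enroll_end"]
        .reindex(out["person_id"])
        .reset_index(drop=True)
    )
    ca_date = pd.to_datetime(
        first_ca.reindex(out["person_id"]).reset_index(drop=True)
    )
    index = pd.to_datetime(out["index_date"]).reset_index(drop=True)

    censor = enroll_end.fillna(admin_end).clip(upper=admin_end)
    event = ca_date.notna() & (ca_date <= censor)
    end = censor.where(~event, ca_date)

    out["followup_years"] = (
        (end - index).dt.total_seconds() / (DAYS_PER_YEAR * 86_400)
    ).to_numpy()
    out["event"] = event.astype(int).to_numpy()
    out["censor_reason"] = np.where(
        event,
        "event",
        np.where(censor < admin_end, "death_or_withdrawal", "admin_end"),
    )
    return out


def build_cohort(
    bundle: ClaimsBundle,
    criteria: CohortCriteria | None = None,
    ratio: int = 3,
    seed: int = 0,
    code_map: Mapping[str, Sequence[str]] | None = None,
    weights: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """End-to-end cohort assembly: criteria, matching, CCI, follow-up."""
    criteria = criteria or CohortCriteria()
    cases = identify_copd_cohort(bundle, criteria)
    controls = match_controls(cases, bundle, ratio=ratio, seed=seed, criteria=criteria)
    cohort = pd.concat([cases, controls], ignore_index=True)
    cohort = compute_cci(cohort, bundle, code_map=code_map, weights=weights)
    cohort = compute_followup(cohort, bundle, admin_end=criteria.admin_end)
    return cohort
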