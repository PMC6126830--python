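"""Medication-exposure classification and the within-COPD multivariable Cox
model.

Inhaled pharmacotherapy is grouped into five classes -- SAMA, SABA, LAMA,
LABA and LABA plus ICS.  A prescription claim *qualifies* when its supplied
duration exceeds 14 days; a person's inhaled class is the unique class with
at least ``min_claims`` qualifying claims inside the first treatment year
(the stationary-medication rule: no class change).  Short-acting claims of
14 days or less held by a regular long-acting user are on-demand rescue use
and do not count against them; the leniency is one-directional, so brief
long-acting claims held by a short-acting user mark a combination.  Persons
with two qualifying classes are combination users and are excluded from the
medication model, mirroring the cohort design this package emulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import HazardFit, fit_cox
from .simulate import INHALED_CLASSES, LONG_ACTING, SHORT_ACTING, COMEDICATIONS

#: maps a raw drug code/class string to an analysis label.  The synthetic
#: generator emits class labels directly; real ATC codes (e.g. statins
#: C10AA01..C10AA05) can be mapped through the same table.
DEFAULT_CLASS_MAP: dict[str, str] = {
    **{c: c for c in INHALED_CLASSES},
    **{c: c for c in COMEDICATIONS},
    "xanthine": "oral_bronchodilator",
    **{f"C10AA0{i}": "statin" for i in range(1, 6)},
}

#: Table layout of the multivariable model: five inhaled classes, four
#: co-medications, CCI and continuous age.
MEDICATION_MODEL_TERMS = [
    "SAMA",
    "SABA",
    "LAMA",
    "LABA",
    "LABA_ICS",
    "statin",
    "aspirin",
    "steroid_oral",
    "nsaid",
    "cci_score",
    "age_years",
]


class UnmappedDrugCodeWarning(UserWarning):
    pass


@dataclass
class MedicationRules:
    """Tunable classification thresholds."""

    min_days_per_claim: int = 14  # a claim qualifies iff days_supplied > this
    min_claims: int = 3  # stationary-medication rule
    first_year_days: int = 365
    #: alternative reading of the duration rule: accumulate days across a
    #: person's claims of a class and require the total to exceed the
    #: threshold instead of each claim individually
    accumulate_per_person: bool = False


def load_class_map(path: str | Path) -> dict[str, str]:
    return dict(yaml.safe_load(Path(path).read_text()) or {})


def classify_medication_exposure(
    rx_claims: pd.DataFrame,
    index_dates: pd.Series | None = None,
    class_map: Mapping[str, str] | None = None,
    rules: MedicationRules | None = None,
    end_dates: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign each person one inhaled class plus co-medication flags.

    Parameters
    ----------
    rx_claims : DataFrame with person_id, date, drug_class, days_supplied.
    index_dates : Series mapping person_id -> index date; when given, the
        stationary-medication window is the first year after index,
        otherwise all claims count.
    class_map : raw code -> analysis label; unmapped codes trigger a
        warning and land in the ``unclassified`` bucket (never dropped
        silently).
    end_dates : Series mapping person_id -> end of follow-up; co-medication
        flags then require a claim on or before that date.

    Returns one row per person appearing in the claims: ``inhaled_class``
    in {SAMA, SABA, LAMA, LABA, LABA_ICS, none, unclassified}, flags
    ``rescue_use`` and ``excluded_combination``, co-medication flags and
    ``qualifying_claims``.
    """
    rules = rules or MedicationRules()
    class_map = dict(class_map or DEFAULT_CLASS_MAP)

    claims = rx_claims.copy()
    claims["label"] = claims["drug_class"].map(class_map)
    unmapped = claims.loc[claims["label"].isna(), "drug_class"].unique()
    if len(unmapped):
        warnings.warn(
            f"unmapped drug codes routed to 'unclassified': {sorted(map(str, unmapped))}",
            UnmappedDrugCodeWarning,
            stacklevel=2,
        )
        claims.loc[claims["label"].isna(), "label"] = "unclassified"

    if index_dates is not None:
        idx = index_dates.reindex(claims["person_id"]).to_numpy()
        claims["in_window"] = (claims["date"].to_numpy() >= idx) & (
            claims["date"].to_numpy()
            <= idx + np.timedelta64(rules.first_year_days, "D")
        )
    else:
        claims["in_window"] = True

    inhaled = claims[claims["label"].isin(INHALED_CLASSES) & claims["in_window"]]
    if rules.accumulate_per_person:
        totals = inhaled.groupby(["person_id", "label"])["days_supplied"].sum()
        qualifying_pairs = totals[totals > rules.min_days_per_claim]
        claim_counts = inhaled.groupby(["person_id", "label"]).size()
        qual_counts = claim_counts.reindex(qualifying_pairs.index)
    else:
        qual = inhaled[inhaled["days_supplied"] > rules.min_days_per_claim]
        qual_counts = qual.groupby(["person_id", "label"]).size()

    persons = pd.Index(claims["person_id"].unique(), name="person_id").sort_values()
    profiles = pd.DataFrame(
        {
            "inhaled_class": "none",
            "rescue_use": False,
            "excluded_combination": False,
            "qualifying_claims": 0,
        },
        index=persons,
    )

    nonqual_short = inhaled[
        inhaled["label"].isin(SHORT_ACTING)
        & ~(inhaled["days_supplied"] > rules.min_days_per_claim)
    ]
    short_brief_ids = set(nonqual_short["person_id"])
    any_long_ids = set(inhaled.loc[inhaled["label"].isin(LONG_ACTING), "person_id"])

    by_person: dict = {}
    for (pid, label), count in qual_counts.items():
        by_person.setdefault(pid, {})[label] = int(count)

    labels_by_person = claims.groupby("person_id")["label"].agg(set)

    for pid in persons:
        classes = by_person.get(pid, {})
        if len(classes) >= 2:
            profiles.loc[pid, "excluded_combination"] = True
            profiles.loc[pid, "inhaled_class"] = "combination"
            continue
        if len(classes) == 1:
            (label, count), = classes.items()
            profiles.loc[pid, "qualifying_claims"] = count
            if count >= rules.min_claims:
                if label in SHORT_ACTING and pid in any_long_ids:
                    # brief long-acting claims are not excused for
                    # short-acting users: combination
                    profiles.loc[pid, "excluded_combination"] = True
                    profiles.loc[pid, "inhaled_class"] = "combination"
                    continue
                profiles.loc[pid, "inhaled_class"] = label
                if label in LONG_ACTING and pid in short_brief_ids:
                    profiles.loc[pid, "rescue_use"] = True
                continue
        # no qualifying class: unclassified if the person's only claims
        # were unmappable, else none
        if labels_by_person.get(pid, set()) == {"unclassified"}:
            profiles.loc[pid, "inhaled_class"] = "unclassified"

    # co-medication flags: at least one claim before end of follow-up
    comeds = claims[claims["label"].isin(COMEDICATIONS)]
    if end_dates is not None:
        ends = end_dates.reindex(comeds["person_id"]).to_numpy()
        comeds = comeds[comeds["date"].to_numpy() <= ends]
    for med in COMEDICATIONS:
        users = set(comeds.loc[comeds["label"] == med, "person_id"])
        profiles[med] = profiles.index.isin(users)

    return profiles.reset_index()


def fit_medication_cox(
    copd_cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    ties: str = "efron",
) -> tuple[pd.DataFrame, HazardFit]:
    """Multivariable Cox model of prostate-cancer risk within the treated
    cohort.

    Combination users are removed; the design holds one indicator per
    inhaled class (persons with no inhaled class are the implicit
    reference), the four co-medication flags, the Charlson score and
    continuous age.  Zero-variance terms are dropped with a warning.
    Returns the formatted HR table (one row per retained term, in the
    canonical order) and the underlying fit.
    """
    merged = copd_cohort.merge(profiles, on="person_id", how="inner")
    merged = merged[~merged["excluded_combination"]].copy()

    for cls in INHALED_CLASSES:
        merged[cls] = (merged["inhaled_class"] == cls).astype(float)
    for med in COMEDICATIONS:
        merged[med] = merged[med].astype(float)

    terms = []
    for term in MEDICATION_MODEL_TERMS:
        if merged[term].nunique() <= 1:
            warnings.warn(
                f"term {term!r} has no variation and was dropped", UserWarning,
                stacklevel=2,
            )
            continue
        terms.append(term)

    fit = fit_cox(
        merged,
        covariates=terms,
        duration="followup_years",
        event="event",
        exposure=terms[0],
        ties=ties,
    )
    z = fit.params / fit.bse
    from scipy import stats

    rows = []
    pretty = {
        "LABA_ICS": "LABA plus ICS",
        "steroid_oral": "Steroid",
        "nsaid": "NSAID",
        "statin": "Statin",
        "aspirin": "Aspirin",
        "cci_score": "CCI score",
        "age_years": "Age (continuous)",
    }
    for term in terms:
        beta = float(fit.params[term])
        se = float(fit.bse[term])
        rows.append(
            {
                "term": pretty.get(term, term),
                "hr": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p_value": float(2 * stats.norm.sf(abs(beta / se))),
            }
        )
    return pd.DataFrame(rows), fit
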