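"""Synthetic claims-database generator for a matched COPD / prostate-cancer cohort study.

The generator emulates the structure of a longitudinal insurance-claims
database (one row per diagnosis or prescription claim) together with a small
interview-survey sample in which lifestyle confounders -- smoking, alcohol
drinking and body-mass index -- are observed.  Those confounders drive both
the probability of being a treated COPD patient and the prostate-cancer
hazard, but are *hidden* from the main-study export, which is what makes the
two-stage propensity-score-calibration analysis non-trivial on these data.

Two entry points are provided:

``simulate_population``
    Full claims-level simulation: persons, ICD-9 diagnosis claims,
    prescription claims and a hidden-truth table.  Feed the result to
    :mod:`pscox.cohort` to exercise the whole pipeline end to end.

``simulate_cohort``
    A fast person-level shortcut that emits an analysis-ready main cohort
    and validation sample directly (no claims materialisation).  Used for
    repeated-replicate experiments such as parameter-recovery studies.

All randomness flows through named child streams spawned from a single seed,
so output is byte-reproducible and enlarging ``n_persons`` leaves the draws
for earlier persons unchanged within each stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

STUDY_START = pd.Timestamp("2004-01-01")
ACCRUAL_END = pd.Timestamp("2004-12-31")
ADMIN_END = pd.Timestamp("2008-12-31")

DAYS_PER_YEAR = 365.25

#: inhaled medication classes; ``xanthine`` stands for oral bronchodilator
#: therapy, so its users carry no inhaled class in the medication analysis.
INHALED_CLASSES = ("SAMA", "SABA", "LAMA", "LABA", "LABA_ICS")
SHORT_ACTING = ("SAMA", "SABA")
LONG_ACTING = ("LAMA", "LABA", "LABA_ICS")
COMEDICATIONS = ("statin", "aspirin", "steroid_oral", "nsaid")

#: ICD-9-CM prefixes identifying the exposure (chronic bronchitis, emphysema,
#: chronic airway obstruction) and the outcome (prostate cancer).
COPD_DX_PREFIXES = ("491", "492", "496")
PROSTATE_CA_CODE = "185"


class ConfigurationError(ValueError):
    """Raised when a simulation parameter is outside its admissible range."""


@dataclass(frozen=True)
class BinaryConfounder:
    """Bernoulli lifestyle confounder (e.g. smoking).

    ``on_exposure`` is the log-odds increment on COPD status, ``on_outcome``
    the log-hazard increment on prostate cancer, both per unit (0/1).
    """

    prevalence: float
    on_exposure: float
    on_outcome: float


@dataclass(frozen=True)
class ContinuousConfounder:
    """Truncated-normal confounder (BMI).  Effects are per unit, centred at
    ``mean`` so the reference subject has a zero contribution."""

    mean: float
    sd: float
    low: float
    high: float
    on_exposure: float
    on_outcome: float


@dataclass(frozen=True)
class Comorbidity:
    """A claims-detectable chronic condition contributing to the CCI.

    ``p_exposed`` / ``p_unexposed`` are target prevalences conditional on
    COPD status; internally persons receive the mixture-marginal prevalence
    and the implied log-odds-ratio enters the COPD model, which reproduces
    the conditional pair to a close approximation.
    """

    icd9: str
    p_exposed: float
    p_unexposed: float


def _default_confounders() -> dict:
    # Prevalences/means follow the validation-survey margins of the study
    # population: smoking 59.6 vs 51.2 %, alcohol 34.3 vs 38.9 %, BMI
    # 23.4 (3.7) vs 24.2 (3.9) in COPD vs non-COPD men.  Exposure effects are
    # the implied log-odds ratios; outcome effects are moderate positive for
    # smoking and small for alcohol/BMI.
    return {
        "smoking": BinaryConfounder(0.512, 0.341, 0.45),
        "alcohol": BinaryConfounder(0.389, -0.199, 0.05),
        "bmi": ContinuousConfounder(24.2, 3.8, 14.0, 45.0, -0.055, 0.010),
    }


def _default_comorbidities() -> dict:
    # Conditional prevalence pairs follow the main-cohort comorbidity table
    # of the study population (COPD vs matched non-COPD men over 50).
    return {
        "myocardial_infarction": Comorbidity("410", 0.023, 0.019),
        "congestive_heart_failure": Comorbidity("428", 0.163, 0.078),
        "peripheral_vascular_disease": Comorbidity("443", 0.070, 0.050),
        "cerebrovascular_disease": Comorbidity("433", 0.253, 0.183),
        "dementia": Comorbidity("290", 0.078, 0.044),
        "rheumatic_disease": Comorbidity("714.0", 0.040, 0.024),
        "peptic_ulcer_disease": Comorbidity("533", 0.401, 0.262),
        "mild_liver_disease": Comorbidity("571", 0.231, 0.168),
        "diabetes_without_complications": Comorbidity("250.0", 0.232, 0.216),
        "diabetes_with_complications": Comorbidity("250.4", 0.067, 0.066),
        "paraplegia_hemiplegia": Comorbidity("342", 0.018, 0.013),
        "renal_disease": Comorbidity("585", 0.082, 0.067),
        "moderate_severe_liver_disease": Comorbidity("572", 0.004, 0.003),
        "metastatic_carcinoma": Comorbidity("196", 0.006, 0.006),
        "aids_hiv": Comorbidity("042", 0.0007, 0.0002),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic claims study.

    Defaults are calibrated to the study conditions this package models: a
    main cohort of roughly 12,800 treated COPD men over 50 with 3:1 matched
    controls followed for up to five years, prostate-cancer incidence near
    630 vs 360 per 100,000 person-years, and a validation survey of roughly
    312 COPD / 804 non-COPD men carrying the lifestyle confounders.
    """

    n_persons: int = 63_870
    copd_prevalence: float = 0.2
    true_log_hr_copd: float = float(np.log(1.62))
    baseline_hazard: float = 0.00215  # events per person-year, reference subject
    cci_log_hr: float = 0.10  # outcome log-hazard per CCI point
    age_log_hr: float = 0.03  # outcome log-hazard per year above 65
    confounder_effects: Mapping[str, BinaryConfounder | ContinuousConfounder] = field(
        default_factory=_default_confounders
    )
    comorbidity_prevalences: Mapping[str, Comorbidity] = field(
        default_factory=_default_comorbidities
    )
    #: (lower age, upper age, probability) for the three matching bands
    age_bands: Sequence[tuple[int, int, float]] = (
        (51, 60, 0.185),
        (61, 70, 0.240),
        (71, 85, 0.575),
    )
    withdrawal_rate: float = 0.05  # combined death/withdrawal hazard per year
    admin_end: pd.Timestamp = ADMIN_END
    #: sampling fraction of the validation survey, per exposure group
    #: (COPD, non-COPD); defaults yield ~312 / ~804 at the default scale.
    validation_fraction: tuple[float, float] = (312 / 12_774, 804 / 51_096)
    #: fraction of COPD persons whose claims satisfy every cohort-entry
    #: criterion; the remainder violate one criterion at random.
    claims_compliance: float = 1.0
    #: probability a treated person uses each medication class
    inhaled_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "SAMA": 0.30,
            "SABA": 0.28,
            "LAMA": 0.06,
            "LABA": 0.03,
            "LABA_ICS": 0.18,
            "xanthine": 0.15,
        }
    )
    rescue_prob: float = 0.30  # long-acting users with an on-demand short-acting claim
    combination_prob: float = 0.05  # users accumulating a second qualifying class
    comedication_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "statin": 0.15,
            "aspirin": 0.12,
            "steroid_oral": 0.20,
            "nsaid": 0.25,
        }
    )
    #: extra outcome log-hazard attached to medication use among COPD
    #: persons; zero by default so the exposure effect is homogeneous.
    medication_effects: Mapping[str, float] = field(default_factory=dict)
    #: fraction of non-COPD persons carrying a stray (non-qualifying) COPD
    #: diagnosis claim, exercising the control-pool exclusion.
    stray_copd_dx_prob: float = 0.02
    cci_weights: Mapping[str, int] | None = None  # None -> unit weights
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        for name, value in [
            ("copd_prevalence", self.copd_prevalence),
            ("claims_compliance", self.claims_compliance),
            ("rescue_prob", self.rescue_prob),
            ("combination_prob", self.combination_prob),
            ("stray_copd_dx_prob", self.stray_copd_dx_prob),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        for name, value in [
            ("baseline_hazard", self.baseline_hazard),
            ("withdrawal_rate", self.withdrawal_rate),
        ]:
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        fractions = np.atleast_1d(np.asarray(self.validation_fraction, dtype=float))
        if np.any((fractions < 0) | (fractions > 1)):
            raise ConfigurationError("validation_fraction entries must lie in [0, 1]")
        for name, com in self.comorbidity_prevalences.items():
            for p in (com.p_exposed, com.p_unexposed):
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"comorbidity_prevalences[{name!r}] must lie in [0, 1]"
                    )
        for name, conf in self.confounder_effects.items():
            if isinstance(conf, BinaryConfounder) and not 0.0 <= conf.prevalence <= 1.0:
                raise ConfigurationError(
                    f"confounder_effects[{name!r}].prevalence must lie in [0, 1]"
                )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from YAML; nested confounder/comorbidity maps are
        given as plain dictionaries of the dataclass fields."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "confounder_effects" in raw:
            parsed = {}
            for name, spec in raw["confounder_effects"].items():
                kind = ContinuousConfounder if "mean" in spec else BinaryConfounder
                parsed[name] = kind(**spec)
            raw["confounder_effects"] = parsed
        if "comorbidity_prevalences" in raw:
            raw["comorbidity_prevalences"] = {
                name: Comorbidity(**spec)
                for name, spec in raw["comorbidity_prevalences"].items()
            }
        if "admin_end" in raw:
            raw["admin_end"] = pd.Timestamp(raw["admin_end"])
        return cls(**raw)


@dataclass
class ClaimsBundle:
    """Simulated claims database plus the ground truth hidden from it.

    ``persons``, ``diagnosis_claims`` and ``prescription_claims`` mimic the
    main administrative database; ``hidden_truth`` carries the lifestyle
    confounders, true exposure status and latent event/censoring dates and
    must never be merged into a main-study analysis table.
    """

    persons: pd.DataFrame
    diagnosis_claims: pd.DataFrame
    prescription_claims: pd.DataFrame
    hidden_truth: pd.DataFrame

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(outdir / "persons.csv", index=False)
        self.diagnosis_claims.to_csv(outdir / "diagnoses.csv", index=False)
        self.prescription_claims.to_csv(outdir / "prescriptions.csv", index=False)
        self.hidden_truth.to_csv(outdir / "truth.csv", index=False)

    @classmethod
    def read_csv(cls, indir: str | Path) -> "ClaimsBundle":
        indir = Path(indir)
        return cls(
            persons=pd.read_csv(indir / "persons.csv", parse_dates=["enroll_end"]),
            diagnosis_claims=pd.read_csv(
                indir / "diagnoses.csv", parse_dates=["date"], dtype={"icd9_code": str}
            ),
            prescription_claims=pd.read_csv(
                indir / "prescriptions.csv", parse_dates=["date"]
            ),
            hidden_truth=pd.read_csv(
                indir / "truth.csv",
                parse_dates=["index_date", "event_date", "withdrawal_date"],
            ),
        )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = (
        "ages",
        "confounders",
        "comorbidities",
        "exposure",
        "events",
        "censoring",
        "claims",
        "validation",
    )
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _solve_intercept(target: float, offsets: np.ndarray) -> float:
    """Intercept of a logistic model such that mean(expit(c + offsets))
    equals ``target``."""

    def gap(c: float) -> float:
        return float(expit(c + offsets).mean() - target)

    return brentq(gap, -30.0, 30.0, xtol=1e-10)


def _draw_population(config: SimulationConfig, streams: dict) -> pd.DataFrame:
    """Person-level latent frame: age, confounders, comorbidity flags,
    exposure status, event and censoring times (in years from study start)."""
    config.validate()
    n = config.n_persons
    pi = config.copd_prevalence

    # ages: three bands, uniform integer age within band
    bands = list(config.age_bands)
    probs = np.array([b[2] for b in bands], dtype=float)
    probs = probs / probs.sum()
    rng = streams["ages"]
    band_idx = rng.choice(len(bands), size=n, p=probs)
    lows = np.array([b[0] for b in bands])
    highs = np.array([b[1] for b in bands])
    age = rng.integers(lows[band_idx], highs[band_idx] + 1)

    frame = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "age_years": age.astype(float),
            "age_band": _band_labels(age, config.age_bands),
        }
    )

    # lifestyle confounders
    rng = streams["confounders"]
    exposure_lp = np.zeros(n)
    outcome_lp = np.zeros(n)
    for name, conf in config.confounder_effects.items():
        if isinstance(conf, BinaryConfounder):
            x = (rng.random(n) < conf.prevalence).astype(float)
            exposure_lp += conf.on_exposure * x
            outcome_lp += conf.on_outcome * x
        else:
            x = rng.normal(conf.mean, conf.sd, size=n)
            x = np.clip(x, conf.low, conf.high)
            exposure_lp += conf.on_exposure * (x - conf.mean)
            outcome_lp += conf.on_outcome * (x - conf.mean)
        frame[name] = x

    # comorbidities: marginal mixture prevalence; the implied log odds ratio
    # feeds the exposure model so conditional prevalences approximate the
    # configured (exposed, unexposed) pair
    rng = streams["comorbidities"]
    for name, com in config.comorbidity_prevalences.items():
        p_marg = pi * com.p_exposed + (1.0 - pi) * com.p_unexposed
        flag = (rng.random(n) < p_marg).astype(int)
        frame[name] = flag
        if 0.0 < com.p_exposed < 1.0 and 0.0 < com.p_unexposed < 1.0:
            delta = float(logit(com.p_exposed) - logit(com.p_unexposed))
            exposure_lp += delta * flag

    # exposure status
    rng = streams["exposure"]
    intercept = _solve_intercept(pi, exposure_lp)
    p_copd = expit(intercept + exposure_lp)
    frame["copd"] = (rng.random(n) < p_copd).astype(int)

    # event times: exponential with subject-specific rate
    rng = streams["events"]
    log_rate = (
        np.log(config.baseline_hazard)
        + config.true_log_hr_copd * frame["copd"].to_numpy()
        + outcome_lp
        + config.age_log_hr * (frame["age_years"].to_numpy() - 65.0)
        + config.cci_log_hr * _cci_from_flags(frame, config)
    )
    frame["cci_true"] = _cci_from_flags(frame, config)
    rate = np.exp(log_rate)
    frame["event_time_years"] = rng.exponential(1.0, size=n) / rate

    # censoring clock (death or withdrawal, treated identically)
    rng = streams["censoring"]
    if config.withdrawal_rate > 0:
        frame["withdrawal_time_years"] = rng.exponential(
            1.0 / config.withdrawal_rate, size=n
        )
    else:
        frame["withdrawal_time_years"] = np.inf
    return frame


def _band_labels(
    age: np.ndarray, bands: Sequence[tuple[int, int, float]]
) -> pd.Categorical:
    labels = [_band_name(lo, hi, i == len(bands) - 1) for i, (lo, hi, _) in enumerate(bands)]
    edges = [bands[0][0] - 1] + [hi for _, hi, _ in bands]
    edges[-1] = max(edges[-1], int(np.max(age)) if len(age) else edges[-1])
    return pd.cut(age, bins=edges, labels=labels)


def _band_name(lo: int, hi: int, last: bool) -> str:
    return f">{lo - 1}" if last else f"{lo}-{hi}"


def age_band(age: np.ndarray | pd.Series, config: SimulationConfig | None = None) -> pd.Categorical:
    """Age band labels used for matching ('51-60', '61-70', '>70')."""
    bands = (config or SimulationConfig()).age_bands
    return _band_labels(np.asarray(age), bands)


def _cci_from_flags(frame: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    weights = config.cci_weights or {}
    total = np.zeros(len(frame))
    for name in config.comorbidity_prevalences:
        total += weights.get(name, 1) * frame[name].to_numpy()
    return total


def simulate_population(
    config: SimulationConfig, seed: int | None = None
) -> ClaimsBundle:
    """Generate a claims-style study population.

    COPD persons receive qualifying treatment claims (two pre-treatment COPD
    diagnoses, at least three prescription claims in the accrual year, a
    clean one-year washout) unless selected as non-compliant; everyone
    accrues comorbidity diagnoses before accrual, a prostate-cancer claim at
    the latent event date (when inside the study window) and an enrollment
    end date when the censoring clock fires before the administrative end.
    """
    seed = config.seed if seed is None else seed
    streams = _streams(seed)
    latent = _draw_population(config, streams)
    rng = streams["claims"]
    n = len(latent)
    copd = latent["copd"].to_numpy().astype(bool)

    # index date: first treated visit, uniform over the accrual year but
    # early enough that the third monthly claim still falls inside it
    accrual_days = int((ACCRUAL_END - STUDY_START).days) + 1
    index_offset = rng.integers(0, accrual_days - 71, size=n)
    index_date = STUDY_START + pd.to_timedelta(index_offset, unit="D")
    latent["index_date"] = pd.Series(index_date).where(pd.Series(copd), pd.NaT)

    # dates are capped far beyond the study window to stay representable
    event_days = np.minimum(
        np.round(latent["event_time_years"].to_numpy() * DAYS_PER_YEAR), 36_500
    )
    latent["event_date"] = STUDY_START + pd.to_timedelta(event_days, unit="D")
    wd_days = np.minimum(
        np.round(latent["withdrawal_time_years"].to_numpy() * DAYS_PER_YEAR), 36_500
    )
    latent["withdrawal_date"] = STUDY_START + pd.to_timedelta(wd_days, unit="D")

    persons = pd.DataFrame(
        {
            "person_id": latent["person_id"],
            "sex": "M",
            "birth_year": (2004 - latent["age_years"]).astype(int),
            "enroll_end": latent["withdrawal_date"].where(
                latent["withdrawal_date"] <= config.admin_end, pd.NaT
            ),
        }
    )

    dx_frames: list[pd.DataFrame] = []
    rx_frames: list[pd.DataFrame] = []

    ids = latent["person_id"].to_numpy()

    # --- comorbidity diagnoses (everyone), dated before the accrual year ---
    for name, com in config.comorbidity_prevalences.items():
        mask = latent[name].to_numpy().astype(bool)
        if not mask.any():
            continue
        offsets = rng.integers(0, 150, size=int(mask.sum()))
        dx_frames.append(
            pd.DataFrame(
                {
                    "person_id": ids[mask],
                    "date": pd.Timestamp("2003-06-01")
                    + pd.to_timedelta(offsets, unit="D"),
                    "icd9_code": com.icd9,
                }
            )
        )

    # --- COPD diagnoses and pharmacotherapy for exposed persons ---
    n_copd = int(copd.sum())
    copd_ids = ids[copd]
    copd_index = pd.Series(index_date)[copd].reset_index(drop=True)

    compliant = rng.random(n_copd) < config.claims_compliance
    violation = rng.integers(0, 3, size=n_copd)  # 0: one dx, 1: washout rx, 2: two rx

    class_names = list(config.inhaled_class_probs)
    class_probs = np.array([config.inhaled_class_probs[c] for c in class_names], float)
    class_probs = class_probs / class_probs.sum()
    assigned = rng.choice(len(class_names), size=n_copd, p=class_probs)
    assigned_class = np.array(class_names, dtype=object)[assigned]

    # two pre-treatment diagnoses (index-45, index-15 days); the "single
    # diagnosis" violation drops the earlier one
    dx_count = np.where(compliant | (violation != 0), 2, 1)
    for lag in (45, 15):
        take = np.ones(n_copd, bool) if lag == 15 else (dx_count == 2)
        codes = rng.choice(COPD_DX_PREFIXES, size=int(take.sum()))
        dx_frames.append(
            pd.DataFrame(
                {
                    "person_id": copd_ids[take],
                    "date": copd_index[take].to_numpy() - np.timedelta64(lag, "D"),
                    "icd9_code": codes,
                }
            )
        )

    rx_count = np.where(compliant | (violation != 2), 3, 2)
    for k, lag in enumerate((0, 35, 70)):
        take = rx_count >= k + 1
        rx_frames.append(
            pd.DataFrame(
                {
                    "person_id": copd_ids[take],
                    "date": copd_index[take].to_numpy() + np.timedelta64(lag, "D"),
                    "drug_class": assigned_class[take],
                    "days_supplied": 30,
                }
            )
        )

    washout_violation = (~compliant) & (violation == 1)
    if washout_violation.any():
        rx_frames.append(
            pd.DataFrame(
                {
                    "person_id": copd_ids[washout_violation],
                    "date": copd_index[washout_violation].to_numpy()
                    - np.timedelta64(100, "D"),
                    "drug_class": assigned_class[washout_violation],
                    "days_supplied": 30,
                }
            )
        )

    # rescue short-acting claims for long-acting users
    long_acting = np.isin(assigned_class, LONG_ACTING)
    rescue = long_acting & (rng.random(n_copd) < config.rescue_prob)
    if rescue.any():
        rx_frames.append(
            pd.DataFrame(
                {
                    "person_id": copd_ids[rescue],
                    "date": copd_index[rescue].to_numpy() + np.timedelta64(100, "D"),
                    "drug_class": rng.choice(SHORT_ACTING, size=int(rescue.sum())),
                    "days_supplied": 7,
                }
            )
        )

    # combination users: a second qualifying inhaled class
    inhaled_user = np.isin(assigned_class, INHALED_CLASSES)
    combo = inhaled_user & (rng.random(n_copd) < config.combination_prob)
    if combo.any():
        second = np.array(
            [
                rng.choice([c for c in INHALED_CLASSES if c != cls])
                for cls in assigned_class[combo]
            ],
            dtype=object,
        )
        for lag in (120, 150, 180):
            rx_frames.append(
                pd.DataFrame(
                    {
                        "person_id": copd_ids[combo],
                        "date": copd_index[combo].to_numpy() + np.timedelta64(lag, "D"),
                        "drug_class": second,
                        "days_supplied": 30,
                    }
                )
            )

    # co-medications
    for med, prob in config.comedication_probs.items():
        users = rng.random(n_copd) < prob
        if users.any():
            rx_frames.append(
                pd.DataFrame(
                    {
                        "person_id": copd_ids[users],
                        "date": copd_index[users].to_numpy() + np.timedelta64(60, "D"),
                        "drug_class": med,
                        "days_supplied": 30,
                    }
                )
            )

    # optional medication effects re-draw the event clock for treated persons
    med_effects = dict(config.medication_effects)
    if med_effects:
        extra = np.array(
            [med_effects.get(cls, 0.0) for cls in assigned_class], dtype=float
        )
        if np.any(extra != 0.0):
            old = latent.loc[copd, "event_time_years"].to_numpy()
            latent.loc[copd, "event_time_years"] = old * np.exp(-extra)
            event_days = np.minimum(
                np.round(latent["event_time_years"].to_numpy() * DAYS_PER_YEAR), 36_500
            )
            latent["event_date"] = STUDY_START + pd.to_timedelta(event_days, unit="D")

    # stray COPD diagnoses among non-COPD persons
    stray = (~copd) & (rng.random(n) < config.stray_copd_dx_prob)
    if stray.any():
        offs = rng.integers(0, accrual_days, size=int(stray.sum()))
        dx_frames.append(
            pd.DataFrame(
                {
                    "person_id": ids[stray],
                    "date": STUDY_START + pd.to_timedelta(offs, unit="D"),
                    "icd9_code": rng.choice(COPD_DX_PREFIXES, size=int(stray.sum())),
                }
            )
        )

    # prostate-cancer diagnoses at the latent event date, when observable
    # (not pre-empted by withdrawal and inside the study window)
    observable = (latent["event_date"] <= config.admin_end) & (
        latent["event_date"] <= latent["withdrawal_date"]
    )
    if observable.any():
        dx_frames.append(
            pd.DataFrame(
                {
                    "person_id": ids[observable.to_numpy()],
                    "date": latent.loc[observable, "event_date"].to_numpy(),
                    "icd9_code": PROSTATE_CA_CODE,
                }
            )
        )

    diagnosis_claims = (
        pd.concat(dx_frames, ignore_index=True)
        .sort_values(["person_id", "date", "icd9_code"], kind="mergesort")
        .reset_index(drop=True)
    )
    prescription_claims = (
        pd.concat(rx_frames, ignore_index=True)
        .sort_values(["person_id", "date", "drug_class"], kind="mergesort")
        .reset_index(drop=True)
    )

    truth_cols = (
        ["person_id", "copd", "age_years", "age_band", "cci_true"]
        + list(config.confounder_effects)
        + list(config.comorbidity_prevalences)
        + [
            "index_date",
            "event_time_years",
            "event_date",
            "withdrawal_time_years",
            "withdrawal_date",
        ]
    )
    hidden_truth = latent[truth_cols].copy()
    return ClaimsBundle(persons, diagnosis_claims, prescription_claims, hidden_truth)


class SamplingError(ValueError):
    """Raised when the validation sample cannot contain both exposure groups."""


def export_validation_sample(
    bundle: ClaimsBundle,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw the interview-survey validation sample from the simulated
    population, revealing the lifestyle confounders.

    A stratified random subsample (by true COPD status) of the hidden-truth
    table; the returned frame carries the exposure indicator ``D``, the
    shared covariates (age band, CCI) and the confounders that the main
    export hides.  ``overlap_with_main`` is always True: the survey and the
    claims database are sampled from the same population.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    truth = bundle.hidden_truth
    fractions = np.atleast_1d(np.asarray(config.validation_fraction, dtype=float))
    if fractions.size == 1:
        f_exp = f_unexp = float(fractions[0])
    else:
        f_exp, f_unexp = float(fractions[0]), float(fractions[1])

    parts = []
    for d, frac in ((1, f_exp), (0, f_unexp)):
        group = truth.index[truth["copd"] == d].to_numpy()
        k = int(round(frac * len(group)))
        if k < 1:
            raise SamplingError(
                f"validation_fraction too small: no subjects with D={d} sampled"
            )
        take = rng.choice(group, size=k, replace=False)
        parts.append(truth.loc[np.sort(take)])
    sample = pd.concat(parts, ignore_index=True)

    out = pd.DataFrame(
        {
            "person_id": sample["person_id"],
            "D": sample["copd"].astype(int),
            "age_years": sample["age_years"],
            "age_band": sample["age_band"],
            "cci_score": sample["cci_true"],
        }
    )
    for name in config.confounder_effects:
        out[name] = sample[name].to_numpy()
    out["overlap_with_main"] = True
    return out


# ---------------------------------------------------------------------------
# fast, person-level simulation used by replicate experiments
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directly simulate an analysis-ready main cohort and validation sample.

    Skips claims materialisation: follow-up and event status are derived
    from the latent clocks, with administrative censoring at five years
    minus a uniform accrual offset.  The main table omits the lifestyle
    confounders; the validation table reveals them.
    """
    seed = config.seed if seed is None else seed
    streams = _streams(seed)
    latent = _draw_population(config, streams)
    n = len(latent)

    rng = streams["claims"]
    admin_horizon = 5.0 - rng.random(n)  # accrual spread over one year
    t_event = latent["event_time_years"].to_numpy()
    t_cens = np.minimum(latent["withdrawal_time_years"].to_numpy(), admin_horizon)
    followup = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    followup = np.maximum(followup, 0.5 / DAYS_PER_YEAR)  # same-day events count half a day

    main = pd.DataFrame(
        {
            "person_id": latent["person_id"],
            "D": latent["copd"].astype(int),
            "age_years": latent["age_years"],
            "age_band": latent["age_band"],
            "cci_score": latent["cci_true"],
            "followup_years": followup,
            "event": event,
        }
    )

    rng = streams["validation"]
    fractions = np.atleast_1d(np.asarray(config.validation_fraction, dtype=float))
    f_exp = float(fractions[0])
    f_unexp = float(fractions[-1])
    parts = []
    for d, frac in ((1, f_exp), (0, f_unexp)):
        group = latent.index[latent["copd"] == d].to_numpy()
        k = max(int(round(frac * len(group))), 1)
        take = np.sort(rng.choice(group, size=k, replace=False))
        parts.append(latent.loc[take])
    val = pd.concat(parts, ignore_index=True)
    validation = pd.DataFrame(
        {
            "person_id": val["person_id"],
            "D": val["copd"].astype(int),
            "age_years": val["age_years"],
            "age_band": val["age_band"],
            "cci_score": val["cci_true"],
        }
    )
    for name in config.confounder_effects:
        validation[name] = val[name].to_numpy()
    return main, validation


def simulate_medication_cohort(
    config: SimulationConfig,
    medication_log_hrs: Mapping[str, float],
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a treated (COPD-only) cohort with per-class medication
    effects on the outcome hazard, for medication-model recovery studies.

    Returns ``(cohort, profiles)``: the cohort carries follow-up/event
    status, age and CCI; the profiles table carries one inhaled class per
    person plus co-medication flags, matching the output schema of
    :func:`pscox.medication.classify_medication_exposure`.
    """
    seed = config.seed if seed is None else seed
    streams = _streams(seed)
    latent = _draw_population(config, streams)
    latent = latent[latent["copd"] == 1].reset_index(drop=True)
    n = len(latent)
    rng = streams["claims"]

    class_names = list(config.inhaled_class_probs)
    probs = np.array([config.inhaled_class_probs[c] for c in class_names], float)
    probs /= probs.sum()
    assigned = np.array(class_names, dtype=object)[rng.choice(len(class_names), n, p=probs)]
    inhaled = np.where(np.isin(assigned, INHALED_CLASSES), assigned, "none")

    extra = np.array([medication_log_hrs.get(c, 0.0) for c in inhaled], dtype=float)
    comed_flags = {}
    for med, prob in config.comedication_probs.items():
        flag = (rng.random(n) < prob).astype(int)
        comed_flags[med] = flag
        extra += medication_log_hrs.get(med, 0.0) * flag

    t_event = latent["event_time_years"].to_numpy() * np.exp(-extra)
    admin_horizon = 5.0 - rng.random(n)
    t_cens = np.minimum(latent["withdrawal_time_years"].to_numpy(), admin_horizon)
    followup = np.maximum(np.minimum(t_event, t_cens), 0.5 / DAYS_PER_YEAR)
    event = (t_event <= t_cens).astype(int)

    cohort = pd.DataFrame(
        {
            "person_id": latent["person_id"],
            "D": 1,
            "age_years": latent["age_years"],
            "age_band": latent["age_band"],
            "cci_score": latent["cci_true"],
            "followup_years": followup,
            "event": event,
        }
    )
    profiles = pd.DataFrame(
        {
            "person_id": latent["person_id"],
            "inhaled_class": inhaled,
            "rescue_use": False,
            "excluded_combination": False,
            "qualifying_claims": 3,
        }
    )
    for med, flag in comed_flags.items():
        profiles[med] = flag.astype(bool)
    return cohort, profiles
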