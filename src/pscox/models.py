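"""Incidence rates, propensity-score models and Cox proportional-hazards fits.

The exposure effect is summarised as a hazard ratio from a partial-likelihood
Cox fit; the adjusted model enters the propensity score Pr(D=1 | E) as a
continuous covariate, H(t | D, PS) = H0(t) exp(beta*D + beta_c*PS), which is
the form required by the downstream regression-calibration algebra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class ModelError(ValueError):
    pass


def incidence_rate(events: int, person_years: float, scale: float = 100_000.0) -> float:
    """Events per ``scale`` person-years."""
    if person_years <= 0:
        raise ModelError("person_years must be positive")
    return events / person_years * scale


def _design_matrix(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Expand covariates into a numeric design matrix; categorical or object
    columns become treatment-coded indicators (first level dropped)."""
    pieces = []
    for col in columns:
        s = df[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            dummies = dummies[sorted(dummies.columns)]
            pieces.append(dummies)
        else:
            pieces.append(s.astype(float).to_frame(col))
    if not pieces:
        return pd.DataFrame(index=df.index)
    return pd.concat(pieces, axis=1)


@dataclass
class PropensityModel:
    """Fitted logistic exposure model with per-subject scores in (0, 1)."""

    covariates: list[str]
    params: pd.Series
    scores: pd.Series
    variant: str  # "error_prone" (shared covariates only) or "gold_standard"
    n: int

    def predict(self, df: pd.DataFrame, columns: Sequence[str]) -> pd.Series:
        X = sm.add_constant(_design_matrix(df, columns), has_constant="add")
        X = X.reindex(columns=self.params.index, fill_value=0.0)
        lp = X.to_numpy() @ self.params.to_numpy()
        return pd.Series(1.0 / (1.0 + np.exp(-lp)), index=df.index)


def fit_propensity(
    df: pd.DataFrame,
    covariates: Sequence[str],
    missing_covariates: Sequence[str] = (),
    exposure: str = "D",
) -> PropensityModel:
    """Maximum-likelihood logistic regression of exposure on covariates.

    With ``missing_covariates`` supplied (the confounders observed only in
    the validation survey) the fit is tagged ``gold_standard``; otherwise it
    is the ``error_prone`` score based on shared covariates alone.
    """
    cols = list(covariates) + list(missing_covariates)
    sub = df[[exposure, *cols]] if cols else df[[exposure]]
    if sub.isna().any().any():
        missing = sub.columns[sub.isna().any()].tolist()
        raise ModelError(f"missing values in propensity covariates: {missing}")
    y = sub[exposure].astype(float)
    if y.nunique() < 2:
        raise ModelError("both exposure groups required to fit a propensity model")
    X = sm.add_constant(_design_matrix(sub, cols), has_constant="add")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise ModelError(
            "propensity fit failed (possible perfect separation); consider a "
            "penalised fit or coarser covariates"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise ModelError("propensity fit did not converge")
    scores = pd.Series(res.predict(X), index=df.index)
    variant = "gold_standard" if missing_covariates else "error_prone"
    return PropensityModel(
        covariates=cols,
        params=res.params,
        scores=scores,
        variant=variant,
        n=len(df),
    )


@dataclass
class HazardFit:
    """Cox partial-likelihood fit summarised around one exposure term."""

    params: pd.Series
    bse: pd.Series
    exposure: str
    ties: str
    n: int
    events: int
    covariance: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def beta(self) -> float:
        return float(self.params[self.exposure])

    @property
    def se_beta(self) -> float:
        return float(self.bse[self.exposure])

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    def hr_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return (
            float(np.exp(self.beta - z * self.se_beta)),
            float(np.exp(self.beta + z * self.se_beta)),
        )

    @property
    def p_value(self) -> float:
        z = self.beta / self.se_beta
        return float(2 * stats.norm.sf(abs(z)))

    def coefficient(self, term: str) -> float:
        return float(self.params[term])

    def to_dict(self) -> dict:
        lo, hi = self.hr_ci()
        return {
            "exposure": self.exposure,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(v) for k, v in self.bse.items()},
            "hr": self.hr,
            "hr_ci_95": [lo, hi],
            "p_value": self.p_value,
            "ties": self.ties,
            "n": self.n,
            "events": self.events,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_cox(
    df: pd.DataFrame,
    covariates: Sequence[str],
    duration: str = "followup_years",
    event: str = "event",
    exposure: str = "D",
    ties: str = "efron",
) -> HazardFit:
    """Cox proportional-hazards fit via the partial likelihood.

    ``covariates`` are the model terms (the exposure indicator must be one
    of them, or named via ``exposure``); ties are handled by Efron's method
    by default (``ties='breslow'`` for the alternative).
    """
    if ties not in ("efron", "breslow"):
        raise ModelError("ties must be 'efron' or 'breslow'")
    durations = df[duration].to_numpy(dtype=float)
    if np.any(durations <= 0):
        raise ModelError("all follow-up times must be positive")
    status = df[event].to_numpy(dtype=int)
    n_events = int(status.sum())
    if n_events == 0:
        raise ModelError("no events; the partial likelihood is undefined")
    X = _design_matrix(df, covariates)
    if exposure not in X.columns:
        raise ModelError(f"exposure term {exposure!r} not among model columns")
    model = sm.PHReg(durations, X.to_numpy(), status=status, ties=ties)
    res = model.fit(maxiter=200, tol=1e-9)
    if not np.all(np.isfinite(res.params)):
        raise ModelError("Cox fit did not converge to finite coefficients")
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return HazardFit(
        params=params,
        bse=bse,
        exposure=exposure,
        ties=ties,
        n=len(df),
        events=n_events,
        covariance=cov,
    )


def fit_adjusted_cox(
    df: pd.DataFrame,
    ps_covariates: Sequence[str],
    duration: str = "followup_years",
    event: str = "event",
    exposure: str = "D",
    ties: str = "efron",
) -> tuple[HazardFit, PropensityModel]:
    """Propensity-adjusted fit: logistic PS on ``ps_covariates`` followed by
    a Cox model with terms (exposure, PS)."""
    ps = fit_propensity(df, ps_covariates, exposure=exposure)
    work = df[[duration, event, exposure]].copy()
    work["PS"] = ps.scores
    fit = fit_cox(
        work,
        covariates=[exposure, "PS"],
        duration=duration,
        event=event,
        exposure=exposure,
        ties=ties,
    )
    return fit, ps
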