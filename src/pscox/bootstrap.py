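"""Percentile bootstrap confidence intervals and empirical p-values.

Resamples subjects with replacement from the empirical distribution,
re-applies the estimator B times (default B = 1000) and reads the 95%
interval off the order statistics (indices ceil(0.025 B) and
floor(0.975 B), i.e. the 25th and 975th of 1000 sorted replicates).

Replicate j's resample depends only on (seed, j), so results are stable
under any evaluation order and reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class BootstrapError(ValueError):
    pass


@dataclass
class BootstrapResult:
    """Sorted replicate estimates with percentile bounds.

    ``empirical_p`` tests H0: estimand = 0 via the sign proportion
    2 * min(#{est <= 0}, #{est >= 0}) / B, floored at 1/B (the smallest
    attainable value; 0.001 at B = 1000) and capped at 1.
    """

    B: int
    estimates: np.ndarray  # sorted, failures removed
    ci_low: float
    ci_high: float
    empirical_p: float
    failures: int
    seed: int | None
    alpha: float = 0.05

    @property
    def point_spread(self) -> float:
        return self.ci_high - self.ci_low


def _resample(data, rng: np.random.Generator):
    if isinstance(data, (tuple, list)):
        return tuple(_resample(d, rng) for d in data)
    n = len(data)
    idx = rng.integers(0, n, size=n)
    if isinstance(data, pd.DataFrame):
        return data.iloc[idx].reset_index(drop=True)
    return np.asarray(data)[idx]


def percentile_bootstrap(
    estimator: Callable,
    data,
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    add_one: bool = False,
    max_failure_rate: float = 0.05,
) -> BootstrapResult:
    """Percentile bootstrap of ``estimator`` over ``data``.

    ``data`` may be a DataFrame/array or a tuple of them; tuple elements
    (e.g. a main cohort and a validation sample) are resampled
    independently, each within itself and at its original size.  Replicates
    on which the estimator raises are counted as failures; more than
    ``max_failure_rate`` of them makes the interval untrustworthy and is an
    error.

    ``add_one`` switches the empirical p-value to (count+1)/(B+1).
    """
    if B < 40:
        raise BootstrapError(
            "B must be >= 40 for a non-degenerate 2.5% order statistic"
        )
    point = estimator(data)
    if not np.isfinite(point):
        raise BootstrapError("estimator is not finite on the original data")

    estimates = np.empty(B)
    failures = 0
    base = 0 if seed is None else int(seed)
    for j in range(B):
        rng = np.random.default_rng([base, j])
        try:
            estimates[j - failures] = float(estimator(_resample(data, rng)))
        except Exception:
            failures += 1
    if failures > max_failure_rate * B:
        raise BootstrapError(
            f"{failures}/{B} bootstrap replicates failed; interval untrustworthy"
        )
    kept = np.sort(estimates[: B - failures])
    b_eff = len(kept)

    lo_idx = max(math.ceil(alpha / 2 * B), 1)
    hi_idx = min(math.floor((1 - alpha / 2) * B), b_eff)
    ci_low = float(kept[lo_idx - 1])
    ci_high = float(kept[hi_idx - 1])

    n_le = int(np.sum(kept <= 0))
    n_ge = int(np.sum(kept >= 0))
    if add_one:
        p = 2 * (min(n_le, n_ge) + 1) / (b_eff + 1)
    else:
        p = max(2 * min(n_le, n_ge) / b_eff, 1 / b_eff)
    empirical_p = float(min(p, 1.0))

    return BootstrapResult(
        B=B,
        estimates=kept,
        ci_low=ci_low,
        ci_high=ci_high,
        empirical_p=empirical_p,
        failures=failures,
        seed=seed,
        alpha=alpha,
    )


def truncate_followup(
    cohort: pd.DataFrame,
    horizon_years: float,
    duration: str = "followup_years",
    event: str = "event",
) -> pd.DataFrame:
    """Censor every subject at ``horizon_years``; events beyond it are lost."""
    out = cohort.copy()
    beyond = out[duration] > horizon_years
    out.loc[beyond, event] = 0
    out.loc[beyond, duration] = horizon_years
    return out


def sensitivity_by_followup(
    cohort: pd.DataFrame,
    horizons: Sequence[float],
    ps_covariates: Sequence[str],
    B: int = 1000,
    seed: int | None = None,
    exposure: str = "D",
    duration: str = "followup_years",
    event: str = "event",
    ties: str = "efron",
) -> pd.DataFrame:
    """Adjusted hazard ratio with bootstrap CI at each follow-up horizon.

    For each horizon the cohort is truncated, the propensity score is refit
    on the truncated data, the adjusted Cox model is re-estimated, and the
    log-hazard ratio is bootstrapped.  Horizons with zero remaining events
    yield a flagged row rather than an error.
    """
    from .models import fit_adjusted_cox

    rows = []
    for h in horizons:
        truncated = truncate_followup(cohort, h, duration=duration, event=event)
        n_events = int(truncated[event].sum())
        label = f"{_fmt_years(h)} of follow-up"
        if n_events == 0:
            rows.append(
                {
                    "horizon_years": h,
                    "label": label,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "empirical_p": np.nan,
                    "events": 0,
                    "flag": "no events",
                }
            )
            continue

        def log_hr(df: pd.DataFrame) -> float:
            fit, _ = fit_adjusted_cox(
                df,
                ps_covariates,
                duration=duration,
                event=event,
                exposure=exposure,
                ties=ties,
            )
            return fit.beta

        point = log_hr(truncated)
        boot = percentile_bootstrap(log_hr, truncated, B=B, seed=seed)
        rows.append(
            {
                "horizon_years": h,
                "label": label,
                "hr": float(np.exp(point)),
                "ci_low": float(np.exp(boot.ci_low)),
                "ci_high": float(np.exp(boot.ci_high)),
                "empirical_p": boot.empirical_p,
                "events": n_events,
                "flag": "",
            }
        )
    return pd.DataFrame(rows)


def _fmt_years(h: float) -> str:
    if float(h).is_integer():
        n = int(h)
        return f"{n} year" + ("" if n == 1 else "s")
    return f"{h} years"
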