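"""Descriptive statistics and table/figure-data assembly.

Formats follow epidemiological reporting conventions: hazard ratios to two
decimals (half-up), incidence rates to the nearest integer per 100,000
person-years, chi-square comparisons without continuity correction.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationResult
from .models import HazardFit, incidence_rate


class ReportingError(ValueError):
    pass


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Classical Pearson chi-square test of independence on an r x k count
    table (no continuity correction).

    Returns (statistic, degrees of freedom, upper-tail p-value).
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or np.any(observed < 0):
        raise ReportingError("table must be a 2-D array of non-negative counts")
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise ReportingError("zero margin: expected counts undefined")
    expected = row @ col / total
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def proportion_pct(count: int, total: int, decimals: int = 1) -> float:
    """Prevalence as a percentage, rounded half-up to ``decimals``."""
    if total <= 0:
        raise ReportingError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100 * count / total).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _fmt_hr(hr: float, ci: tuple[float, float] | None) -> str:
    if ci is None:
        return f"{round_half_up(hr):.2f}"
    return f"{round_half_up(hr):.2f}({round_half_up(ci[0]):.2f}-{round_half_up(ci[1]):.2f})"


def build_table2(
    crude: HazardFit,
    adjusted: HazardFit,
    calibrated: CalibrationResult | None,
    incidences: Mapping[str, tuple[int, float]],
    totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble the headline comparison table: events, incidence and the
    three exposure hazard ratios (crude, PS-adjusted, two-stage calibrated).

    ``incidences`` maps group label ('exposed'/'unexposed') to
    (events, person_years); ``totals`` optionally maps the same labels to
    subject counts for the events/total row.
    """
    for key in ("exposed", "unexposed"):
        if key not in incidences:
            raise ReportingError(f"missing incidence input for row {key!r}")
    if crude is None or adjusted is None:
        raise ReportingError("missing hazard fit for the crude or adjusted row")

    e1, py1 = incidences["exposed"]
    e0, py0 = incidences["unexposed"]

    def events_cell(events: int, label: str) -> str:
        if totals and label in totals:
            return f"{events}/{totals[label]}"
        return f"{events}"

    rows = [
        {
            "row": "Yes/Total",
            "unexposed": events_cell(e0, "unexposed"),
            "exposed": events_cell(e1, "exposed"),
        }
    ]
    rows.append(
        {
            "row": "Incidence (100,000 person-years)",
            "unexposed": f"{incidence_rate(e0, py0):.0f}",
            "exposed": f"{incidence_rate(e1, py1):.0f}",
        }
    )
    rows.append(
        {
            "row": "Crude HR (95% CI)",
            "unexposed": "1.00",
            "exposed": _fmt_hr(crude.hr, crude.hr_ci()),
        }
    )
    rows.append(
        {
            "row": "Adjusted HR (95% CI)",
            "unexposed": "1.00",
            "exposed": _fmt_hr(adjusted.hr, adjusted.hr_ci()),
        }
    )
    if calibrated is not None:
        rows.append(
            {
                "row": "Two-stage method adjusted HR (95% CI)",
                "unexposed": "1.00",
                "exposed": _fmt_hr(calibrated.hr_star, calibrated.ci),
            }
        )
    return pd.DataFrame(rows)


def hazard_curves(
    cohort: pd.DataFrame,
    group_col: str = "D",
    groups: Sequence | None = None,
    duration: str = "followup_years",
    event: str = "event",
) -> pd.DataFrame:
    """Nelson-Aalen cumulative-hazard points per group, for plotting
    elsewhere.

    Returns a long table (group, time, cumulative_hazard); the curve for a
    group with no events is flat at zero.
    """
    from lifelines import NelsonAalenFitter

    available = list(pd.unique(cohort[group_col]))
    groups = available if groups is None else list(groups)
    unknown = [g for g in groups if g not in available]
    if unknown:
        raise ReportingError(f"unknown group label(s): {unknown}")

    frames = []
    for g in groups:
        sub = cohort[cohort[group_col] == g]
        naf = NelsonAalenFitter()
        naf.fit(sub[duration], event_observed=sub[event])
        curve = naf.cumulative_hazard_.reset_index()
        curve.columns = ["time", "cumulative_hazard"]
        curve.insert(0, "group", g)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)
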