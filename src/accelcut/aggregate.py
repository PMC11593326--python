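"""Daily and period summaries of labelled epochs, and cohort-level tables.

Conventions: weekend = Saturday/Sunday, weekday = Monday-Friday; the "total"
period averages over *all* valid days (not the mean of the two period means);
a child is "active" in a period when their mean daily MVPA over valid days in
that period is at least the guideline (default 60 min/day, inclusive at the
bound). The mean-based rule is the only one under which the same child can be
active on weekdays and inactive at the weekend, which is how compliance is
conventionally tabulated.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cutpoints import CutPointSet, SEDENTARY, LIGHT, MVPA, UNWORN, classify_series
from .epoch_io import CountSeries
from .wear import WearInterval, is_weekend
from . import stats as _stats

__all__ = [
    "DaySummary",
    "PeriodSummary",
    "day_summary",
    "day_summaries",
    "period_summary",
    "cohort_tables",
    "WEEKDAY",
    "WEEKEND",
    "TOTAL",
]

logger = logging.getLogger(__name__)

WEEKDAY = "weekday"
WEEKEND = "weekend"
TOTAL = "total"
PERIODS = (WEEKDAY, WEEKEND, TOTAL)


@dataclass(frozen=True)
class DaySummary:
    """Minutes per intensity class for one child-day under one cut-point set.

    Invariant: sb_min + light_min + mvpa_min == wear_min exactly (each is a
    whole number of epochs times epoch_len/60). Mean cpm are totals of counts
    over worn epochs divided by worn minutes, on each axis.
    """

    child_id: str
    date: datetime.date
    day_type: str  # weekday | weekend
    wear_min: float
    sb_min: float
    light_min: float
    mvpa_min: float
    mean_cpm_vertical: float
    mean_cpm_vm: float


@dataclass(frozen=True)
class PeriodSummary:
    """Unweighted means over one child's valid days in a period, one cut-point set."""

    child_id: str
    period: str  # weekday | weekend | total
    cutpoints: str  # CutPointSet.key
    n_days: int
    sb_min: float
    light_min: float
    mvpa_min: float
    mean_cpm_vertical: float
    mean_cpm_vm: float
    active: bool


def day_summary(
    series: CountSeries,
    labels: np.ndarray,
    date: datetime.date,
    cps: CutPointSet,
    min_wear_minutes: float | None = None,
) -> DaySummary:
    """Summarise one calendar day of labelled epochs.

    ``labels`` must come from ``classify_series`` with wear intervals applied
    (non-worn epochs unlabelled). If ``min_wear_minutes`` is given, a day
    below it is refused.
    """
    date64 = np.datetime64(pd.Timestamp(date).normalize())
    in_day = series.dates == date64
    if not in_day.any():
        raise ValueError(f"series contains no epochs on {date}")
    day_labels = labels[in_day]
    worn = day_labels != UNWORN
    per_epoch_min = series.epoch_len_s / 60
    wear_min = int(worn.sum()) * per_epoch_min
    if min_wear_minutes is not None and wear_min < min_wear_minutes:
        raise ValueError(
            f"{series.child_id} {date}: wear {wear_min:.1f} min is below the "
            f"valid-day minimum of {min_wear_minutes:g} min"
        )
    wear_minutes_safe = wear_min if wear_min > 0 else np.nan
    return DaySummary(
        child_id=series.child_id,
        date=date,
        day_type=WEEKEND if is_weekend(date) else WEEKDAY,
        wear_min=wear_min,
        sb_min=int((day_labels == SEDENTARY).sum()) * per_epoch_min,
        light_min=int((day_labels == LIGHT).sum()) * per_epoch_min,
        mvpa_min=int((day_labels == MVPA).sum()) * per_epoch_min,
        mean_cpm_vertical=float(series.axis1[in_day][worn].sum()) / wear_minutes_safe,
        mean_cpm_vm=float(series.vm[in_day][worn].sum()) / wear_minutes_safe,
    )


def day_summaries(
    series: CountSeries,
    cps: CutPointSet,
    wear_intervals: list[WearInterval],
    valid_map: dict[datetime.date, bool] | None = None,
) -> list[DaySummary]:
    """Summaries for every valid day of a series (all days if no map given)."""
    labels = classify_series(series, cps, wear_intervals)
    days = pd.DatetimeIndex(series.timestamps.normalize().unique())
    out = []
    for d in days:
        date = d.date()
        if valid_map is not None and not valid_map.get(date, False):
            continue
        out.append(day_summary(series, labels, date, cps))
    return out


def period_summary(
    summaries: list[DaySummary],
    period: str,
    cps: CutPointSet,
    guideline_minutes: float = 60.0,
) -> PeriodSummary | None:
    """Mean daily minutes over a child's valid days in a period.

    Returns None (with a log entry) when the child has no valid day in the
    period, so the child is simply omitted from that period's tables.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}")
    if period == TOTAL:
        sel = summaries
    else:
        sel = [s for s in summaries if s.day_type == period]
    if not sel:
        child = summaries[0].child_id if summaries else "<unknown>"
        logger.info("child %s: no valid days in period %s; omitted", child, period)
        return None
    mvpa = float(np.mean([s.mvpa_min for s in sel]))
    return PeriodSummary(
        child_id=sel[0].child_id,
        period=period,
        cutpoints=cps.key,
        n_days=len(sel),
        sb_min=float(np.mean([s.sb_min for s in sel])),
        light_min=float(np.mean([s.light_min for s in sel])),
        mvpa_min=mvpa,
        mean_cpm_vertical=float(np.mean([s.mean_cpm_vertical for s in sel])),
        mean_cpm_vm=float(np.mean([s.mean_cpm_vm for s in sel])),
        active=mvpa >= guideline_minutes,
    )


def cohort_tables(
    period_summaries: list[PeriodSummary],
    metadata: pd.DataFrame,
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level descriptive and compliance tables.

    Parameters
    ----------
    period_summaries
        Flat list across children, periods and cut-point sets.
    metadata
        Columns ``child_id`` and ``sex`` (M/F).

    Returns
    -------
    intensity : per cut-point set x period x sex — n, and mean / SE / CI
        bounds of daily sedentary, light and MVPA minutes (t-based CI).
    active : per cut-point set x period — counts and % active overall and by
        sex, plus the two-sided Pearson chi-square p for the sex difference
        in active proportions (NaN when a margin is empty).
    """
    sex_of = dict(zip(metadata["child_id"], metadata["sex"]))
    df = pd.DataFrame([vars(s) for s in period_summaries])
    if df.empty:
        raise ValueError("no period summaries to tabulate")
    df["sex"] = df["child_id"].map(sex_of)

    intensity_rows = []
    for (key, period, sex), grp in df.groupby(["cutpoints", "period", "sex"],
                                              sort=True):
        row = {"cutpoints": key, "period": period, "sex": sex, "n": len(grp)}
        for var, col in (("sb", "sb_min"), ("light", "light_min"),
                         ("mvpa", "mvpa_min")):
            vals = grp[col].values
            if len(vals) >= 2:
                m, se, lo, hi = _stats.mean_ci(vals, level=ci_level)
            else:
                m, se, lo, hi = float(vals[0]), np.nan, np.nan, np.nan
            row.update({f"{var}_mean": m, f"{var}_se": se,
                        f"{var}_ci_lo": lo, f"{var}_ci_hi": hi})
        intensity_rows.append(row)
    intensity = pd.DataFrame(intensity_rows)

    active_rows = []
    for (key, period), grp in df.groupby(["cutpoints", "period"], sort=True):
        n = len(grp)
        act = grp["active"]
        males = grp["sex"] == "M"
        n_m, n_f = int(males.sum()), int((~males).sum())
        a_m = int((act & males).sum())
        a_f = int((act & ~males).sum())
        table = (a_m, n_m - a_m, a_f, n_f - a_f)
        _, p = _stats.chi2_2x2(table)
        active_rows.append(
            {
                "cutpoints": key,
                "period": period,
                "n": n,
                "n_active": int(act.sum()),
                "pct_active": round(100 * act.sum() / n, 2),
                "n_male": n_m,
                "n_active_male": a_m,
                "pct_active_male": round(100 * a_m / n_m, 2) if n_m else np.nan,
                "n_female": n_f,
                "n_active_female": a_f,
                "pct_active_female": round(100 * a_f / n_f, 2) if n_f else np.nan,
                "p_sex_difference": p,
            }
        )
        if act.sum() == 0:
            logger.info(
                "cut-points %s, period %s: 0 of %d children classified active",
                key, period, n,
            )
    return intensity, pd.DataFrame(active_rows)
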