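"""Wear-time rules: non-wear run removal and valid-day / valid-child screening.

Non-wear is a sufficiently long run of consecutive zero-count epochs; the
default threshold of 20 minutes follows the standard wear-time literature for
young children (a literal 20-*epoch* reading at 5 s would be 100 s and would
misclassify ordinary stillness). The zero test uses the vertical axis by
default, the axis all published preschool cut-point sets calibrate; an
all-axes-zero test is selectable. Runs are evaluated within calendar days: a
run crossing midnight is split at the boundary and each part is tested
against the threshold on its own.

A day is valid when it retains at least ``min_wear_minutes`` (default 600,
i.e. 10 h) of wear after non-wear removal, and a child is retained when their
valid days meet the per-period minima.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epoch_io import CountSeries

__all__ = [
    "WearInterval",
    "ValidDayRule",
    "detect_nonwear",
    "wear_minutes_per_day",
    "valid_days",
    "filter_children",
]

WORN = "worn"
NON_WORN = "non-worn"


@dataclass(frozen=True)
class WearInterval:
    """A maximal same-status run of epochs within one calendar day.

    ``start_epoch``/``end_epoch`` are half-open global epoch indices into the
    series. The intervals for a day partition that day's epochs and statuses
    alternate within the day.
    """

    day: datetime.date
    start_epoch: int
    end_epoch: int
    status: str

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch


@dataclass(frozen=True)
class ValidDayRule:
    """Screening thresholds for days and children.

    min_wear_minutes : minimum daily wear (default 600 = 10 h).
    min_zero_run_minutes : zero-run length flagged as non-wear (default 20).
    min_valid_weekdays / min_valid_weekend_days : per-child minima for
        retention (defaults 1 and 1; the source protocols rarely state this,
        so it is configuration, not a fixed rule).
    """

    min_wear_minutes: float = 600.0
    min_zero_run_minutes: float = 20.0
    min_valid_weekdays: int = 1
    min_valid_weekend_days: int = 1

    def __post_init__(self) -> None:
        for name in ("min_wear_minutes", "min_zero_run_minutes",
                     "min_valid_weekdays", "min_valid_weekend_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def detect_nonwear(
    series: CountSeries,
    min_zero_run_minutes: float = 20.0,
    zero_test: str = "vertical",
) -> list[WearInterval]:
    """Flag long zero-count runs as non-wear.

    Every maximal run of consecutive zero epochs lasting at least
    ``min_zero_run_minutes`` (inclusive: "20 or more") is non-worn; all other
    epochs are worn. Runs are clipped at midnight before the length test.

    Parameters
    ----------
    zero_test
        ``"vertical"`` (default): an epoch is zero when axis1 is zero.
        ``"all_axes"``: zero on all three axes.
    """
    if zero_test == "vertical":
        zero = series.axis1 == 0
    elif zero_test == "all_axes":
        zero = (series.axis1 == 0) & (series.axis2 == 0) & (series.axis3 == 0)
    else:
        raise ValueError(f"unknown zero_test {zero_test!r}")

    n = series.n_epochs
    if n == 0:
        return []
    min_epochs = int(np.ceil(min_zero_run_minutes * 60 / series.epoch_len_s))
    dates = series.dates

    nonwear = np.zeros(n, dtype=bool)
    # maximal zero-runs within each day: break runs where the date changes
    boundary = np.empty(n, dtype=bool)
    boundary[0] = True
    boundary[1:] = (zero[1:] != zero[:-1]) | (dates[1:] != dates[:-1])
    starts = np.flatnonzero(boundary)
    ends = np.append(starts[1:], n)
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) >= min_epochs:
            nonwear[s:e] = True

    intervals: list[WearInterval] = []
    boundary[1:] = (nonwear[1:] != nonwear[:-1]) | (dates[1:] != dates[:-1])
    starts = np.flatnonzero(boundary)
    ends = np.append(starts[1:], n)
    ts = series.timestamps
    for s, e in zip(starts, ends):
        intervals.append(
            WearInterval(
                day=ts[s].date(),
                start_epoch=int(s),
                end_epoch=int(e),
                status=NON_WORN if nonwear[s] else WORN,
            )
        )
    return intervals


def worn_mask(series: CountSeries, intervals: list[WearInterval]) -> np.ndarray:
    """Boolean per-epoch mask: True where the device was worn."""
    mask = np.zeros(series.n_epochs, dtype=bool)
    for iv in intervals:
        if iv.status == WORN:
            mask[iv.start_epoch:iv.end_epoch] = True
    return mask


def wear_minutes_per_day(
    series: CountSeries, intervals: list[WearInterval]
) -> dict[datetime.date, float]:
    """Worn minutes per calendar day (epochs x epoch length / 60)."""
    minutes: dict[datetime.date, float] = {}
    ts = series.timestamps
    if series.n_epochs:
        for d in pd.DatetimeIndex(ts.normalize().unique()):
            minutes[d.date()] = 0.0
    for iv in intervals:
        if iv.status == WORN:
            minutes[iv.day] = minutes.get(iv.day, 0.0) + iv.n_epochs * series.epoch_len_s / 60
    return minutes


def valid_days(
    wear_map: dict[datetime.date, float], rule: ValidDayRule
) -> dict[datetime.date, bool]:
    """A day is valid iff wear >= min_wear_minutes (inclusive at the bound)."""
    return {day: wear >= rule.min_wear_minutes for day, wear in wear_map.items()}


def is_weekend(day: datetime.date) -> bool:
    """Saturday/Sunday. Weekday = Monday-Friday."""
    return day.weekday() >= 5


def filter_children(
    valid_day_maps: dict[str, dict[datetime.date, bool]],
    rule: ValidDayRule,
) -> tuple[list[str], pd.DataFrame]:
    """Retain children whose valid-day counts meet the per-period minima.

    Parameters
    ----------
    valid_day_maps
        Per child: the mapping from ``valid_days``.

    Returns
    -------
    (retained_ids, exclusion_log)
        The log has one row per child: child_id, n_valid_weekdays,
        n_valid_weekend_days, excluded, reason.
    """
    rows = []
    retained = []
    for child_id, vmap in valid_day_maps.items():
        n_wd = sum(1 for d, ok in vmap.items() if ok and not is_weekend(d))
        n_we = sum(1 for d, ok in vmap.items() if ok and is_weekend(d))
        reasons = []
        if n_wd < rule.min_valid_weekdays:
            reasons.append(
                f"only {n_wd} valid weekday(s), need {rule.min_valid_weekdays}"
            )
        if n_we < rule.min_valid_weekend_days:
            reasons.append(
                f"only {n_we} valid weekend day(s), need {rule.min_valid_weekend_days}"
            )
        excluded = bool(reasons)
        if not excluded:
            retained.append(child_id)
        rows.append(
            {
                "child_id": child_id,
                "n_valid_weekdays": n_wd,
                "n_valid_weekend_days": n_we,
                "excluded": excluded,
                "reason": "; ".join(reasons),
            }
        )
    return retained, pd.DataFrame(
        rows,
        columns=["child_id", "n_valid_weekdays", "n_valid_weekend_days",
                 "excluded", "reason"],
    )
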