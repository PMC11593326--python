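import datetime

import numpy as np
import pandas as pd
import pytest

from accelcut import (
    classify_series,
    day_summaries,
    day_summary,
    detect_nonwear,
    get_cutpoint_set,
    period_summary,
    cohort_tables,
    valid_days,
    wear_minutes_per_day,
    ValidDayRule,
)
from accelcut.aggregate import TOTAL, WEEKDAY, WEEKEND, DaySummary

from conftest import build_series, minutes_series

PATE = get_cutpoint_set("pate")


def summarise_first_day(series, cps=PATE):
    iv = detect_nonwear(series, 20)
    labels = classify_series(series, cps, iv)
    return day_summary(series, labels, series.start.date(), cps)


def test_all_sedentary_worn_day():
    s = minutes_series([(720, 100), (720, 0)])  # 720 worn + 720-min zero run
    d = summarise_first_day(s)
    assert (d.sb_min, d.light_min, d.mvpa_min) == (720.0, 0.0, 0.0)
    assert d.wear_min == 720.0
    assert d.mean_cpm_vertical == pytest.approx(100.0)


def test_minutes_conserve_wear_and_match_recount():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 2500, size=1440)
    s = build_series(counts, epoch_len_s=60)
    iv = detect_nonwear(s, 20)
    labels = classify_series(s, PATE, iv)
    d = day_summary(s, labels, s.start.date(), PATE)
    assert d.sb_min + d.light_min + d.mvpa_min == d.wear_min
    # brute-force recount
    worn = labels != ""
    assert d.mvpa_min == (labels == "mvpa").sum()
    assert d.mean_cpm_vertical == pytest.approx(counts[worn].sum() / worn.sum())


def test_day_type_follows_calendar():
    sat = minutes_series([(1440, 100)], start="2025-01-11")  # a Saturday
    assert summarise_first_day(sat).day_type == WEEKEND
    mon = minutes_series([(1440, 100)], start="2025-01-06")
    assert summarise_first_day(mon).day_type == WEEKDAY


def test_day_summary_refuses_invalid_day_when_rule_given():
    s = minutes_series([(300, 100), (1140, 0)])  # 300 min wear < 600
    iv = detect_nonwear(s, 20)
    labels = classify_series(s, PATE, iv)
    with pytest.raises(ValueError, match="below the valid-day minimum"):
        day_summary(s, labels, s.start.date(), PATE, min_wear_minutes=600)


def _mk_day(child, date, mvpa, day_type):
    return DaySummary(child, date, day_type, wear_min=600.0 + mvpa,
                      sb_min=500.0, light_min=100.0, mvpa_min=mvpa,
                      mean_cpm_vertical=500.0, mean_cpm_vm=1100.0)


def test_active_boundary_on_period_mean():
    mon = datetime.date(2025, 1, 6)
    days = [_mk_day("c", mon, 60.0, WEEKDAY)]
    assert period_summary(days, WEEKDAY, PATE).active  # exactly 60 counts
    days = [_mk_day("c", mon, 59.9, WEEKDAY)]
    assert not period_summary(days, WEEKDAY, PATE).active


def test_single_day_period_equals_that_day():
    mon = datetime.date(2025, 1, 6)
    ps = period_summary([_mk_day("c", mon, 72.5, WEEKDAY)], WEEKDAY, PATE)
    assert ps.mvpa_min == 72.5 and ps.n_days == 1


def test_total_mean_lies_between_period_means():
    mon = datetime.date(2025, 1, 6)
    days = [
        _mk_day("c", mon, 80.0, WEEKDAY),
        _mk_day("c", mon + datetime.timedelta(days=1), 70.0, WEEKDAY),
        _mk_day("c", mon + datetime.timedelta(days=5), 40.0, WEEKEND),
    ]
    wd = period_summary(days, WEEKDAY, PATE).mvpa_min
    we = period_summary(days, WEEKEND, PATE).mvpa_min
    tot = period_summary(days, TOTAL, PATE).mvpa_min
    assert min(wd, we) <= tot <= max(wd, we)
    # total averages days, not the two period means
    assert tot == pytest.approx((80 + 70 + 40) / 3)


def test_empty_period_returns_none():
    mon = datetime.date(2025, 1, 6)
    assert period_summary([_mk_day("c", mon, 70.0, WEEKDAY)], WEEKEND, PATE) is None


def _period_summaries_for(mvpas_by_child, period=WEEKDAY):
    mon = datetime.date(2025, 1, 6)
    out = []
    for child, mvpa in mvpas_by_child.items():
        out.append(period_summary([_mk_day(child, mon, mvpa, WEEKDAY)],
                                  period, PATE))
    return out


def test_cohort_tables_identical_children_collapse_ci():
    meta = pd.DataFrame({"child_id": ["a", "b", "c"], "sex": ["M", "M", "F"]})
    ps = _period_summaries_for({"a": 70.0, "b": 70.0, "c": 70.0})
    intensity, active = cohort_tables(ps, meta)
    male = intensity[(intensity["sex"] == "M")].iloc[0]
    assert male["mvpa_se"] == 0.0
    assert male["mvpa_ci_lo"] == male["mvpa_mean"] == male["mvpa_ci_hi"] == 70.0


def test_cohort_tables_percent_active_arithmetic():
    meta = pd.DataFrame({"child_id": list("abcde"),
                         "sex": ["M", "M", "M", "F", "F"]})
    ps = _period_summaries_for(
        {"a": 80.0, "b": 50.0, "c": 65.0, "d": 40.0, "e": 61.0})
    _, active = cohort_tables(ps, meta)
    row = active.iloc[0]
    assert row["n_active"] == 3
    assert row["pct_active"] == round(100 * 3 / 5, 2)
    assert row["n_active_male"] == 2 and row["n_active_female"] == 1
    assert row["pct_active_male"] == round(100 * 2 / 3, 2)


def test_zero_active_cohort_reports_zero_percent():
    """A cut-point set no child can reach classifies 0% active (and the
    sex chi-square is undefined because one margin is empty)."""
    meta = pd.DataFrame({"child_id": ["a", "b"], "sex": ["M", "F"]})
    ps = _period_summaries_for({"a": 10.0, "b": 20.0})
    with pytest.warns(UserWarning, match="margin"):
        _, active = cohort_tables(ps, meta)
    assert active.iloc[0]["n_active"] == 0
    assert active.iloc[0]["pct_active"] == 0.0
    assert np.isnan(active.iloc[0]["p_sex_difference"])


def test_cross_set_ordering_survives_aggregation(tiny_sim_config):
    from accelcut import simulate_child

    s = simulate_child(tiny_sim_config, 0)
    iv = detect_nonwear(s, 20)
    vd = valid_days(wear_minutes_per_day(s, iv), ValidDayRule())
    means = {}
    for name in ("pate", "butte", "johansson"):
        cps = get_cutpoint_set(name)
        ds = day_summaries(s, cps, iv, vd)
        ps = period_summary(ds, TOTAL, cps)
        means[name] = ps
    assert means["pate"].mvpa_min >= means["butte"].mvpa_min >= means["johansson"].mvpa_min
    assert means["butte"].sb_min <= means["johansson"].sb_min <= means["pate"].sb_min
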