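import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from accelcut import (
    ValidDayRule,
    detect_nonwear,
    filter_children,
    valid_days,
    wear_minutes_per_day,
)
from accelcut.wear import NON_WORN, WORN, worn_mask

from conftest import build_series, minutes_series


def brute_force_nonwear(counts, epoch_len_s, dates, min_minutes):
    """Independent oracle: per-epoch scan for qualifying zero runs per day."""
    n = len(counts)
    out = np.zeros(n, dtype=bool)
    min_epochs = int(np.ceil(min_minutes * 60 / epoch_len_s))
    i = 0
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0 and dates[j] == dates[i]:
                j += 1
            if j - i >= min_epochs:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def test_full_day_of_zeros_is_one_nonworn_interval():
    s = minutes_series([(1440, 0)])
    iv = detect_nonwear(s, 20)
    assert len(iv) == 1
    assert iv[0].status == NON_WORN and iv[0].n_epochs == 1440
    assert wear_minutes_per_day(s, iv) == {datetime.date(2025, 1, 6): 0.0}


def test_nineteen_minute_zero_run_is_kept_as_wear():
    s = minutes_series([(30, 100), (19, 0), (30, 100)])
    iv = detect_nonwear(s, 20)
    assert all(i.status == WORN for i in iv)


def test_twenty_minute_zero_run_is_nonwear_inclusive_bound():
    s = minutes_series([(30, 100), (20, 0), (30, 100)])
    iv = detect_nonwear(s, 20)
    statuses = [i.status for i in iv]
    assert statuses == [WORN, NON_WORN, WORN]
    assert iv[1].n_epochs == 20


def test_zero_run_crossing_midnight_is_split_and_each_part_tested():
    # 15 zero-min before midnight + 15 after: neither half reaches 20 min
    s = minutes_series([(1425, 100), (30, 0), (1410, 100)])
    iv = detect_nonwear(s, 20)
    assert all(i.status == WORN for i in iv)
    # but 25 + 25 min: both halves qualify separately
    s2 = minutes_series([(1415, 100), (50, 0), (1415, 100)])
    iv2 = detect_nonwear(s2, 20)
    nonworn = [i for i in iv2 if i.status == NON_WORN]
    assert len(nonworn) == 2
    assert {i.day for i in nonworn} == {datetime.date(2025, 1, 6),
                                        datetime.date(2025, 1, 7)}


def test_wear_minutes_examples():
    s = minutes_series([(1440, 100)])
    assert wear_minutes_per_day(s, detect_nonwear(s, 20)) == {
        datetime.date(2025, 1, 6): 1440.0
    }
    s = minutes_series([(600, 100), (120, 0), (720, 100)])
    assert wear_minutes_per_day(s, detect_nonwear(s, 20)) == {
        datetime.date(2025, 1, 6): 1320.0
    }


def test_intervals_partition_each_day():
    s = minutes_series([(100, 50), (25, 0), (1315, 80), (700, 0), (740, 90)])
    iv = detect_nonwear(s, 20)
    for day in {i.day for i in iv}:
        day_iv = sorted([i for i in iv if i.day == day],
                        key=lambda i: i.start_epoch)
        for prev, nxt in zip(day_iv, day_iv[1:]):
            assert prev.end_epoch == nxt.start_epoch
            assert prev.status != nxt.status  # statuses alternate
        total = sum(i.n_epochs for i in day_iv)
        assert total == 1440  # fully recorded 60-s day


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(
        st.one_of(st.just(0), st.integers(0, 500)), min_size=60, max_size=2880
    ),
    st.integers(5, 60),
)
def test_detect_nonwear_matches_brute_force_scan(counts, min_minutes):
    s = build_series(np.asarray(counts), epoch_len_s=60)
    iv = detect_nonwear(s, min_minutes)
    mask = ~worn_mask(s, iv)
    expected = brute_force_nonwear(counts, 60, s.dates, min_minutes)
    assert np.array_equal(mask, expected)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.one_of(st.just(0), st.integers(0, 300)),
                min_size=120, max_size=1440))
def test_lowering_threshold_never_decreases_nonwear(counts):
    s = build_series(np.asarray(counts), epoch_len_s=60)
    nw30 = (~worn_mask(s, detect_nonwear(s, 30))).sum()
    nw20 = (~worn_mask(s, detect_nonwear(s, 20))).sum()
    nw10 = (~worn_mask(s, detect_nonwear(s, 10))).sum()
    assert nw10 >= nw20 >= nw30


def test_valid_days_inclusive_at_ten_hours():
    rule = ValidDayRule()
    d1, d2 = datetime.date(2025, 1, 6), datetime.date(2025, 1, 7)
    out = valid_days({d1: 600.0, d2: 599.0}, rule)
    assert out == {d1: True, d2: False}
    assert valid_days({}, rule) == {}


def test_filter_children_per_period_minima():
    rule = ValidDayRule()  # needs >=1 valid weekday and >=1 valid weekend day
    mon = datetime.date(2025, 1, 6)
    week = {mon + datetime.timedelta(days=i): True for i in range(7)}
    no_weekend = {mon + datetime.timedelta(days=i): i < 5 for i in range(7)}
    nothing = {mon + datetime.timedelta(days=i): False for i in range(7)}
    retained, log = filter_children(
        {"ok": week, "weekdays_only": no_weekend, "none": nothing}, rule
    )
    assert retained == ["ok"]
    log = log.set_index("child_id")
    assert not log.loc["ok", "excluded"]
    assert log.loc["weekdays_only", "excluded"]
    assert "weekend" in log.loc["weekdays_only", "reason"]
    assert log.loc["weekdays_only", "n_valid_weekdays"] == 5
    assert log.loc["none", "excluded"]


def test_rule_rejects_non_positive_thresholds():
    with pytest.raises(ValueError):
        ValidDayRule(min_wear_minutes=0)
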