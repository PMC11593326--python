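import dataclasses

import numpy as np
import pytest

from accelcut import (
    SimConfig,
    ValidDayRule,
    day_summaries,
    detect_nonwear,
    get_cutpoint_set,
    simulate_child,
    simulate_cohort,
    valid_days,
    wear_minutes_per_day,
)
from accelcut.simulate import (
    MOD,
    SLEEP_NONWEAR,
    StateParams,
    default_states,
    _profile,
)
from accelcut.wear import worn_mask


ONE_DAY = SimConfig(n_children=2, n_days=1, seed=7)


def test_rejects_epoch_not_dividing_minute():
    with pytest.raises(ValueError, match="divide 60"):
        SimConfig(epoch_len_s=7)


def test_child_index_bounds():
    with pytest.raises(ValueError, match="child_index"):
        simulate_child(ONE_DAY, 2)


def test_series_shape_and_stride():
    s = simulate_child(ONE_DAY, 0)
    assert s.n_epochs == 86400 // 5
    assert s.epoch_len_s == 5
    seven = SimConfig(n_children=1, n_days=7, seed=1)
    assert simulate_child(seven, 0).n_epochs == 7 * 86400 // 5


def test_determinism_same_config_same_series():
    a = simulate_child(ONE_DAY, 0)
    b = simulate_child(ONE_DAY, 0)
    assert a == b
    # children are individually reproducible irrespective of cohort order
    cohort = simulate_cohort(ONE_DAY)
    assert cohort.series[1] == simulate_child(ONE_DAY, 1)


def test_different_seeds_differ():
    a = simulate_child(ONE_DAY, 0)
    b = simulate_child(dataclasses.replace(ONE_DAY, seed=8), 0)
    assert a != b


def test_counts_nonnegative_and_vm_dominates_vertical():
    s = simulate_child(SimConfig(n_children=1, n_days=2, seed=3), 0)
    assert s.axis1.min() >= 0 and s.axis2.min() >= 0 and s.axis3.min() >= 0
    assert np.all(s.vm >= s.axis1)


def test_sleep_only_state_model_emits_all_zeros():
    states = {SLEEP_NONWEAR: default_states()[SLEEP_NONWEAR]}
    cfg = SimConfig(n_children=1, n_days=1, states=states, seed=5)
    s = simulate_child(cfg, 0)
    assert s.axis1.sum() == 0 and s.axis2.sum() == 0 and s.axis3.sum() == 0


def test_sex_assignment_extremes_and_binomial_counts():
    all_male = simulate_cohort(SimConfig(n_children=1, n_days=1,
                                         prop_male=1.0, seed=2))
    assert list(all_male.metadata["sex"]) == ["M"]
    all_female = simulate_cohort(SimConfig(n_children=1, n_days=1,
                                           prop_male=0.0, seed=2))
    assert list(all_female.metadata["sex"]) == ["F"]
    # study design: 134 children, 74 boys expected; binomial sd ~ 5.8
    males = []
    for seed in range(3):
        cfg = SimConfig(n_children=134, n_days=1, seed=seed)
        meta = simulate_cohort(cfg).metadata
        males.append((meta["sex"] == "M").sum())
        assert meta["age_years"].between(3, 5).all()
    assert abs(np.mean(males) - 74) < 3 * 5.8 / np.sqrt(3)


def test_weekend_effect_raises_weekend_sedentary_minutes():
    cps = get_cutpoint_set("butte")
    rule = ValidDayRule()
    diffs = []
    for seed in range(4):
        cfg = SimConfig(n_children=3, n_days=7, weekend_effect=1.5, seed=seed)
        for s in simulate_cohort(cfg).series:
            iv = detect_nonwear(s, rule.min_zero_run_minutes)
            vd = valid_days(wear_minutes_per_day(s, iv), rule)
            ds = day_summaries(s, cps, iv, vd)
            wd = [d.sb_min for d in ds if d.day_type == "weekday"]
            we = [d.sb_min for d in ds if d.day_type == "weekend"]
            if wd and we:
                diffs.append(np.mean(we) - np.mean(wd))
    assert np.mean(diffs) > 0


def _with_mvpa_rate(mult: float) -> dict:
    states = default_states()
    p = states[MOD]
    states[MOD] = dataclasses.replace(
        p, hour_weight=tuple(w * mult for w in p.hour_weight))
    return states


def test_mvpa_rate_multiplier_increases_mvpa_minutes():
    """Monte-Carlo over 10 seeds: raising the MVPA bout entry rate raises
    expected MVPA minutes under every cut-point set."""
    rule = ValidDayRule(min_valid_weekend_days=1, min_valid_weekdays=1)
    totals = {0.5: {}, 2.0: {}}
    for mult in totals:
        for name in ("pate", "butte", "johansson"):
            cps = get_cutpoint_set(name)
            vals = []
            for seed in range(10):
                cfg = SimConfig(n_children=1, n_days=2, start_weekday=4,
                                states=_with_mvpa_rate(mult), seed=seed)
                s = simulate_child(cfg, 0)
                iv = detect_nonwear(s, rule.min_zero_run_minutes)
                ds = day_summaries(s, cps, iv)
                vals.append(np.mean([d.mvpa_min for d in ds]))
            totals[mult][name] = np.mean(vals)
    for name in ("pate", "butte", "johansson"):
        assert totals[2.0][name] > totals[0.5][name]


def test_cohort_mean_vertical_cpm_near_calibration_anchor():
    """Worn-time vertical-axis cpm of a default cohort lands within +-15%
    of the 535-cpm anchor typical of preschool hip accelerometry."""
    cpms = []
    for seed in range(3):
        cfg = SimConfig(n_children=12, seed=seed)
        for s in simulate_cohort(cfg).series:
            mask = worn_mask(s, detect_nonwear(s, 20))
            minutes = mask.sum() * s.epoch_len_s / 60
            cpms.append(s.axis1[mask].sum() / minutes)
    mean_cpm = np.mean(cpms)
    assert 535 * 0.85 <= mean_cpm <= 535 * 1.15


def test_state_params_validation():
    with pytest.raises(ValueError, match="24"):
        StateParams("x", 5.0, (1.0,) * 23, 100.0)
    with pytest.raises(ValueError, match="dwell"):
        StateParams("x", 0.0, _profile(1, 1), 100.0)
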