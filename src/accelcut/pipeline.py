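"""End-to-end orchestration: cohort in, full table bundle out.

A run either simulates a cohort or reads epoch CSVs from disk, then applies
the wear-time rules, classifies epochs under every selected cut-point set,
aggregates to day and period summaries, tabulates intensity minutes and
guideline compliance by sex and period, and cross-tabulates active/inactive
agreement between every pair of cut-point sets (overall and within sex).
Everything is driven by one ``RunConfig`` (YAML-loadable); the bundle is
deterministic for a fixed config and seed and ships with a machine-readable
manifest.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from .aggregate import (PERIODS, cohort_tables, day_summaries, period_summary)
from .agreement import agreement_result, crosstab
from .cutpoints import get_cutpoint_set
from .epoch_io import read_epoch_csv
from .simulate import Cohort, SimConfig, simulate_cohort, write_cohort
from .wear import ValidDayRule, detect_nonwear, filter_children, valid_days, \
    wear_minutes_per_day

__all__ = ["RunConfig", "run", "load_config"]

logger = logging.getLogger(__name__)

#: (name, axis) pairs processed by default: all registered sets.
DEFAULT_SETS = (
    ("pate", "vertical"),
    ("butte", "vertical"),
    ("johansson", "vertical"),
    ("butte", "vector_magnitude"),
    ("johansson", "vector_magnitude"),
)


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    mode : "simulate" (generate a synthetic cohort from ``sim``) or "read"
        (load ``input_dir``: a cohort_metadata.csv plus one epoch CSV per
        child in the canonical dialect).
    """

    mode: str = "simulate"
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None
    rule: ValidDayRule = field(default_factory=ValidDayRule)
    guideline_minutes: float = 60.0
    cutpoint_sets: tuple = DEFAULT_SETS
    out_dir: str = "accelcut_out"
    seed: int | None = None  # overrides sim.seed when given
    write_epoch_files: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "read"):
            raise ValueError("mode must be 'simulate' or 'read'")
        if self.mode == "read" and not self.input_dir:
            raise ValueError("read mode requires input_dir")
        for name, axis in self.cutpoint_sets:
            get_cutpoint_set(name, axis)  # validate selection early


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (missing keys take defaults)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "sim" in kwargs:
        kwargs["sim"] = SimConfig(**kwargs["sim"])
    if "rule" in kwargs:
        kwargs["rule"] = ValidDayRule(**kwargs["rule"])
    if "cutpoint_sets" in kwargs:
        kwargs["cutpoint_sets"] = tuple(
            (e["name"], e.get("axis", "vertical")) if isinstance(e, dict)
            else tuple(e)
            for e in kwargs["cutpoint_sets"]
        )
    return RunConfig(**kwargs)


def _load_cohort(input_dir: str) -> Cohort:
    meta_path = os.path.join(input_dir, "cohort_metadata.csv")
    metadata = pd.read_csv(meta_path)
    series = []
    for _, row in metadata.iterrows():
        path = os.path.join(input_dir, f"{row['child_id']}.csv")
        series.append(read_epoch_csv(path, child_id=str(row["child_id"])))
    if not series:
        # fall back to any epoch CSVs present
        for path in sorted(glob.glob(os.path.join(input_dir, "*.csv"))):
            if os.path.basename(path) != "cohort_metadata.csv":
                series.append(read_epoch_csv(path))
    return Cohort(metadata=metadata, series=series)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; write the bundle; return tables in memory.

    Output files: exclusion_log.csv, day_summaries.csv, period_summaries.csv,
    intensity_minutes_by_sex_period.csv, active_classification.csv,
    agreement_matrix.csv, manifest.yaml.
    """
    if config.mode == "simulate":
        sim = config.sim
        if config.seed is not None:
            from dataclasses import replace
            sim = replace(sim, seed=config.seed)
        cohort = simulate_cohort(sim)
    else:
        cohort = _load_cohort(config.input_dir)

    rule = config.rule
    sets = [get_cutpoint_set(n, a) for n, a in config.cutpoint_sets]

    # wear-time screening
    wear_maps, valid_maps, intervals_by_child = {}, {}, {}
    for s in cohort.series:
        iv = detect_nonwear(s, rule.min_zero_run_minutes)
        intervals_by_child[s.child_id] = iv
        wm = wear_minutes_per_day(s, iv)
        wear_maps[s.child_id] = wm
        valid_maps[s.child_id] = valid_days(wm, rule)
    retained, exclusion_log = filter_children(valid_maps, rule)
    if not retained:
        raise RuntimeError(
            "no children retained after wear-time screening; exclusion log:\n"
            + exclusion_log.to_string(index=False)
        )
    for _, row in exclusion_log[exclusion_log["excluded"]].iterrows():
        logger.info("excluded %s: %s", row["child_id"], row["reason"])

    # classification + aggregation, per cut-point set
    day_rows, period_summaries = [], []
    flags: dict[tuple[str, str], dict[str, bool]] = {}  # (set key, period) -> flags
    for cps in sets:
        for s in cohort.series:
            if s.child_id not in retained:
                continue
            ds = day_summaries(s, cps, intervals_by_child[s.child_id],
                               valid_maps[s.child_id])
            day_rows.extend({**vars(d), "cutpoints": cps.key} for d in ds)
            for period in PERIODS:
                ps = period_summary(ds, period, cps, config.guideline_minutes)
                if ps is not None:
                    period_summaries.append(ps)
                    flags.setdefault((cps.key, period), {})[ps.child_id] = ps.active

    intensity, active = cohort_tables(period_summaries, cohort.metadata)

    # pairwise agreement between cut-point sets, overall and within sex
    sex_of = dict(zip(cohort.metadata["child_id"].astype(str),
                      cohort.metadata["sex"]))
    agree_rows = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            k1, k2 = sets[i].key, sets[j].key
            for period in PERIODS:
                f1 = flags.get((k1, period), {})
                f2 = flags.get((k2, period), {})
                common = sorted(set(f1) & set(f2))
                for sex in ("all", "M", "F"):
                    ids = [c for c in common
                           if sex == "all" or sex_of.get(c) == sex]
                    if not ids:
                        continue
                    table = crosstab({c: f1[c] for c in ids},
                                     {c: f2[c] for c in ids})
                    res = agreement_result(table)
                    agree_rows.append(
                        {"first": k1, "second": k2, "period": period,
                         "sex": sex, "n": table.n, "a": table.a, "b": table.b,
                         "c": table.c, "d": table.d,
                         "percent_agreement": res.percent_agreement,
                         "kappa": res.kappa_reported, "band": res.band}
                    )
    agreement_matrix = pd.DataFrame(agree_rows)

    # write the bundle
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    day_df = pd.DataFrame(day_rows)
    period_df = pd.DataFrame([vars(p) for p in period_summaries])
    tables = {
        "exclusion_log.csv": exclusion_log,
        "day_summaries.csv": day_df,
        "period_summaries.csv": period_df,
        "intensity_minutes_by_sex_period.csv": intensity,
        "active_classification.csv": active,
        "agreement_matrix.csv": agreement_matrix,
    }
    for fname, df in tables.items():
        with open(os.path.join(out, fname), "w", encoding="utf-8",
                  newline="\n") as fh:
            df.to_csv(fh, index=False, lineterminator="\n", float_format="%.6g")
    if config.mode == "simulate" and config.write_epoch_files:
        write_cohort(cohort, os.path.join(out, "cohort"))

    from . import __version__ as pkg_version

    manifest = {
        "accelcut_version": pkg_version,
        "mode": config.mode,
        "seed": (config.seed if config.seed is not None
                 else (config.sim.seed if config.mode == "simulate" else None)),
        "n_children": len(cohort.series),
        "n_retained": len(retained),
        "guideline_minutes": config.guideline_minutes,
        "cutpoint_sets": [list(t) for t in config.cutpoint_sets],
        "valid_day_rule": asdict(rule),
    }
    with open(os.path.join(out, "manifest.yaml"), "w", encoding="utf-8",
              newline="\n") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return {
        "cohort": cohort,
        "retained": retained,
        "exclusion_log": exclusion_log,
        "day_summaries": day_df,
        "period_summaries": period_df,
        "intensity": intensity,
        "active": active,
        "agreement": agreement_matrix,
        "manifest": manifest,
    }
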