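"""Auxiliary statistics: chi-square sex comparison, paired-t sample size,
descriptive mean/CI, and Bonferroni-corrected pairwise letters.

The chi-square for comparing active proportions between sexes is the Pearson
statistic WITHOUT Yates continuity correction (df = 1): the uncorrected form
is the one that matches the p-values compliance studies conventionally print
for 2x2 sex-by-active tables.

The a-priori sample size for a two-sided paired (repeated-measures) t-test
is found by iterating n upward and evaluating exact power from the
noncentral t distribution: with df = n-1, noncentrality dz*sqrt(n) and
rejection beyond +-t(1-alpha/2, n-1), the smallest n whose power reaches the
target is returned together with its critical t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PowerSpec",
    "PairwiseLetterResult",
    "chi2_2x2",
    "paired_t_sample_size",
    "mean_ci",
    "pairwise_letters",
]


@dataclass(frozen=True)
class PowerSpec:
    """A-priori design for a two-sided paired t-test.

    effect_size_dz : standardized mean paired difference (Cohen's d_z > 0).
    alpha : two-sided type-I error level.
    power : target power in (0, 1).
    """

    effect_size_dz: float = 0.5
    alpha: float = 0.05
    power: float = 0.95
    tails: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.effect_size_dz <= 0:
            raise ValueError("effect size d_z must be positive")
        if self.tails != 2:
            raise ValueError("only the two-sided test is supported")


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, df=1) on a 2x2 table.

    ``table`` is (a, b, c, d) row-major or a 2x2 array. Returns
    (statistic, two-sided p). If any row or column margin is zero the test
    is undefined: returns (nan, nan) with a warning.
    """
    arr = np.asarray(table, dtype=float).reshape(2, 2)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn(
            "chi-square undefined: a row or column margin is zero", stacklevel=2
        )
        return float("nan"), float("nan")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def power_paired_t(n: int, dz: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided paired t-test at sample size n."""
    if n < 2:
        return 0.0
    df = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    nc = dz * np.sqrt(n)
    return float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def paired_t_sample_size(spec: PowerSpec, n_max: int = 100_000) -> tuple[int, float]:
    """Smallest n whose exact paired-t power reaches the target.

    Returns (n_required, critical_t) where critical_t = t(1-alpha/2, n-1)
    at the returned n. Raises if the target is not reached by ``n_max``.
    """
    for n in range(2, n_max + 1):
        if power_paired_t(n, spec.effect_size_dz, spec.alpha) >= spec.power:
            return n, float(sps.t.ppf(1 - spec.alpha / 2, n - 1))
    raise ValueError(
        f"power {spec.power} not reachable with n <= {n_max} at "
        f"d_z={spec.effect_size_dz}, alpha={spec.alpha}"
    )


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float, float]:
    """Mean, standard error, and t-based CI bounds: mean +- t(1-(1-level)/2, n-1)*SE."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    m = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(n))
    tq = float(sps.t.ppf(1 - (1 - level) / 2, n - 1))
    return m, se, m - tq * se, m + tq * se


@dataclass(frozen=True)
class PairwiseLetterResult:
    """Compact letter display over paired conditions.

    ``summary``: per condition — n, mean, SE, CI bounds, letters (conditions
    connected through non-significant Bonferroni-adjusted paired t-tests share
    a letter; letters assigned in descending-mean order).
    ``pairwise``: per pair — t statistic, raw p, Bonferroni-adjusted p,
    significant flag.
    """

    summary: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float


def pairwise_letters(
    data: pd.DataFrame, alpha: float = 0.05, ci_level: float = 0.95
) -> PairwiseLetterResult:
    """Bonferroni-corrected pairwise paired t-tests with similarity letters.

    ``data``: one row per child, one column per condition (e.g. the three
    cut-point sets' MVPA means), paired across columns. Each of the k(k-1)/2
    paired t-tests has its p multiplied by the number of pairs (capped at 1);
    conditions are grouped by the transitive closure of the non-significance
    relation and groups lettered A, B, C... in descending-mean order, so two
    conditions share a letter iff they are connected through non-significant
    differences.
    """
    if data.shape[0] < 2:
        raise ValueError("need at least 2 paired observations")
    cols = list(data.columns)
    k = len(cols)
    n_pairs = k * (k - 1) // 2

    pair_rows = []
    nonsig = {c: {c} for c in cols}
    for i in range(k):
        for j in range(i + 1, k):
            t, p = sps.ttest_rel(data[cols[i]], data[cols[j]])
            p_adj = min(1.0, float(p) * n_pairs)
            sig = p_adj < alpha
            if not sig:
                nonsig[cols[i]].add(cols[j])
                nonsig[cols[j]].add(cols[i])
            pair_rows.append(
                {"first": cols[i], "second": cols[j], "t": float(t),
                 "p_raw": float(p), "p_bonferroni": p_adj, "significant": sig}
            )

    # transitive closure: connected components of the non-significance graph
    order = sorted(cols, key=lambda c: -float(data[c].mean()))
    component: dict[str, int] = {}
    next_id = 0
    for c in order:
        if c in component:
            continue
        stack, comp = [c], next_id
        next_id += 1
        while stack:
            u = stack.pop()
            if u in component:
                continue
            component[u] = comp
            stack.extend(v for v in nonsig[u] if v not in component)
    letters = {
        c: chr(ord("A") + component[c]) for c in cols
    }

    sum_rows = []
    for c in order:
        m, se, lo, hi = mean_ci(data[c].values, level=ci_level)
        sum_rows.append(
            {"condition": c, "n": int(data.shape[0]), "mean": m, "se": se,
             "ci_lo": lo, "ci_hi": hi, "letters": letters[c]}
        )
    return PairwiseLetterResult(
        summary=pd.DataFrame(sum_rows),
        pairwise=pd.DataFrame(pair_rows),
        alpha=alpha,
    )
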