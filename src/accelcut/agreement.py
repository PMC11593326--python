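"""Agreement between binary active/inactive classifications.

Two cut-point sets applied to the same cohort yield two active/inactive
labelings; their agreement is summarised by the 2x2 cross-classification,
the raw percent agreement 100*(a+d)/n, Cohen's chance-corrected kappa
(p_o - p_e)/(1 - p_e), and a qualitative band.

Published compliance tables usually print only the marginals (how many
children each cut-point set classified active) and the raw agreement;
``reconstruct_2x2`` recovers the full 2x2 table exactly from those, because
with both marginals and the agreement count fixed the table has a unique
solution: a = (first_active + second_active + A - n) / 2.

Kappa values are *reported* truncated (not rounded) to three decimals —
the convention of the compliance literature this package interoperates
with — while internal computation keeps full precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ContingencyTable2x2",
    "AgreementResult",
    "crosstab",
    "cohen_kappa",
    "percent_agreement",
    "band_kappa",
    "reconstruct_2x2",
    "agreement_result",
    "truncate",
]

#: kappa band boundaries: label applies on [lower, upper) except as noted.
KAPPA_BANDS = (
    (0.80, "excellent"),    # [0.80, 1.00]
    (0.60, "substantial"),  # [0.60, 0.80)
    (0.40, "moderate"),     # [0.40, 0.60)
    (0.20, "reasonable"),   # [0.20, 0.40)
    (0.0, "weak"),          # (0, 0.20); kappa <= 0 -> no agreement
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cross-classification of two binary labelings of the same children.

    a: both active; b: first active only; c: second active only;
    d: both inactive.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if isinstance(v, bool) or v != int(v) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        if self.n < 1:
            raise ValueError("empty table (n = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def first_active(self) -> int:
        return self.a + self.b

    @property
    def second_active(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class AgreementResult:
    table: ContingencyTable2x2
    percent_agreement: float  # rounded to 2 decimals for reporting
    kappa: float              # full precision
    kappa_reported: float     # truncated to 3 decimals
    band: str


def crosstab(flags_first: dict, flags_second: dict) -> ContingencyTable2x2:
    """Cross-classify two {child_id: bool} labelings of the same child set."""
    if set(flags_first) != set(flags_second):
        only1 = sorted(set(flags_first) - set(flags_second))
        only2 = sorted(set(flags_second) - set(flags_first))
        raise ValueError(
            f"child sets differ: {len(only1)} only in first (e.g. {only1[:3]}), "
            f"{len(only2)} only in second (e.g. {only2[:3]})"
        )
    a = b = c = d = 0
    for child, f1 in flags_first.items():
        f2 = flags_second[child]
        if f1 and f2:
            a += 1
        elif f1:
            b += 1
        elif f2:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def cohen_kappa(table: ContingencyTable2x2) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    p_o = (a+d)/n; p_e = ((a+b)(a+c) + (c+d)(b+d)) / n^2. When p_e = 1
    (all mass in one cell) kappa is 1 for perfect agreement on that cell
    and 0 by convention otherwise. Kappa is 0 whenever either classifier
    is constant across children.
    """
    n = table.n
    p_o = (table.a + table.d) / n
    p_e = (
        (table.a + table.b) * (table.a + table.c)
        + (table.c + table.d) * (table.b + table.d)
    ) / n**2
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        warnings.warn(
            "expected agreement is 1 with imperfect observed agreement; "
            "kappa set to 0 by convention",
            stacklevel=2,
        )
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def percent_agreement(table: ContingencyTable2x2) -> float:
    """Raw agreement 100*(a+d)/n, rounded to 2 decimals for reporting."""
    return round(100.0 * (table.a + table.d) / table.n, 2)


def band_kappa(kappa: float) -> str:
    """Qualitative band for a kappa value.

    <=0 no agreement; (0, 0.20) weak; [0.20, 0.40) reasonable;
    [0.40, 0.60) moderate; [0.60, 0.80) substantial; [0.80, 1.00] excellent.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa <= 0:
        return "no agreement"
    for lower, label in KAPPA_BANDS:
        if kappa >= lower:
            return label
    return "weak"  # pragma: no cover — (0, 0.20) handled by the 0.0 entry


def truncate(x: float, decimals: int = 3) -> float:
    """Truncate toward zero to the given number of decimals (no rounding)."""
    q = 10**decimals
    return math.trunc(x * q) / q


def reconstruct_2x2(
    n: int,
    first_active_total: int,
    second_active_total: int,
    percent_agreement: float,
) -> ContingencyTable2x2:
    """Rebuild the full 2x2 table from printed marginals and raw agreement.

    The agreement count is A = round(percent_agreement * n / 100) — (a+d)
    must be an integer. Since n = first + second + A - 2a, the both-active
    cell is a = (first + second + A - n) / 2 and the rest follow from the
    marginals. The solution is additionally verified (and its uniqueness
    confirmed) by brute-force search over all feasible values of a.
    """
    if not (0 <= first_active_total <= n and 0 <= second_active_total <= n):
        raise ValueError("marginal totals must lie in [0, n]")
    A = round(percent_agreement * n / 100.0)
    if not 0 <= A <= n:
        raise ValueError(
            f"agreement count {A} (from {percent_agreement}% of {n}) outside [0, n]"
        )
    num = first_active_total + second_active_total + A - n
    if num % 2 != 0:
        raise ValueError(
            f"infeasible inputs: first+second+A-n = {num} is odd, so the "
            "both-active cell is not an integer; check the printed values"
        )
    a = num // 2
    b = first_active_total - a
    c = second_active_total - a
    d = A - a
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"infeasible inputs: reconstructed cells (a={a}, b={b}, c={c}, "
            f"d={d}) contain a negative count"
        )
    # independent brute-force verification: a is the only feasible choice
    feasible = [
        aa
        for aa in range(0, min(first_active_total, second_active_total) + 1)
        if first_active_total - aa >= 0
        and second_active_total - aa >= 0
        and A - aa >= 0
        and (aa + (first_active_total - aa) + (second_active_total - aa)
             + (A - aa)) == n
    ]
    if feasible != [a]:
        raise ValueError(
            f"reconstruction not unique or inconsistent: feasible a = {feasible}"
        )
    return ContingencyTable2x2(a, b, c, d)


def agreement_result(table: ContingencyTable2x2) -> AgreementResult:
    """Bundle percent agreement, kappa (full + truncated) and band."""
    k = cohen_kappa(table)
    return AgreementResult(
        table=table,
        percent_agreement=percent_agreement(table),
        kappa=k,
        kappa_reported=truncate(k, 3),
        band=band_kappa(k),
    )
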