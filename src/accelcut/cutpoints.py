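"""Published preschool cut-point sets and epoch intensity classification.

Each cut-point set gives two thresholds in counts per minute (cpm) on a
specific axis: an upper bound for sedentary behaviour and a lower bound for
moderate-to-vigorous activity (MVPA); light activity is the band between.
Boundary convention, mirroring the source calibrations: sedentary strictly
below the sedentary bound, MVPA at or above the MVPA bound. Moderate and
vigorous are not separated (no boundary between them is published in the
sets housed here).

Registry (cpm):

========== ================ ========== ===========
set        axis             sedentary< MVPA >=
========== ================ ========== ===========
pate       vertical         800        1680
butte      vertical         239        2120
johansson  vertical         580        3480
butte      vector_magnitude 820        1908
johansson  vector_magnitude 2136       6144
========== ================ ========== ===========

Pate never published a vector-magnitude set. Thresholds are rescaled to the
analysis epoch as exact rationals (threshold x epoch/60) so that no rounding
drift is introduced at short epochs such as 5 s.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .epoch_io import CountSeries
from .wear import WearInterval, worn_mask

__all__ = [
    "CutPointSet",
    "VERTICAL",
    "VECTOR_MAGNITUDE",
    "SEDENTARY",
    "LIGHT",
    "MVPA",
    "UNWORN",
    "get_cutpoint_set",
    "available_cutpoint_sets",
    "register_cutpoint_set",
    "epoch_thresholds",
    "classify_epoch",
    "classify_series",
]

VERTICAL = "vertical"
VECTOR_MAGNITUDE = "vector_magnitude"

SEDENTARY = "sedentary"
LIGHT = "light"
MVPA = "mvpa"
UNWORN = ""  # non-worn epochs carry no intensity label


@dataclass(frozen=True)
class CutPointSet:
    """A named pair of intensity thresholds bound to one axis.

    ``sb_upper_cpm``: counts/min below which an epoch is sedentary (strict).
    ``mvpa_lower_cpm``: counts/min at or above which an epoch is MVPA.
    """

    name: str
    axis: str
    sb_upper_cpm: int
    mvpa_lower_cpm: int

    def __post_init__(self) -> None:
        if self.axis not in (VERTICAL, VECTOR_MAGNITUDE):
            raise ValueError(f"unknown axis {self.axis!r}")
        if not self.sb_upper_cpm < self.mvpa_lower_cpm:
            raise ValueError("sedentary upper bound must lie below the MVPA lower bound")

    @property
    def key(self) -> str:
        return f"{self.name}_{'vm' if self.axis == VECTOR_MAGNITUDE else 'y'}"


_BUILTIN: dict[tuple[str, str], CutPointSet] = {
    (s.name, s.axis): s
    for s in (
        CutPointSet("pate", VERTICAL, 800, 1680),
        CutPointSet("butte", VERTICAL, 239, 2120),
        CutPointSet("johansson", VERTICAL, 580, 3480),
        CutPointSet("butte", VECTOR_MAGNITUDE, 820, 1908),
        CutPointSet("johansson", VECTOR_MAGNITUDE, 2136, 6144),
    )
}

_REGISTRY: dict[tuple[str, str], CutPointSet] = dict(_BUILTIN)


def get_cutpoint_set(name: str, axis: str = VERTICAL) -> CutPointSet:
    """Look up a registered cut-point set by name and axis."""
    try:
        return _REGISTRY[(name, axis)]
    except KeyError:
        if (name, VERTICAL) in _REGISTRY or (name, VECTOR_MAGNITUDE) in _REGISTRY:
            raise KeyError(
                f"cut-point set {name!r} is not defined on axis {axis!r} in its "
                "source study (no such calibration was published)"
            ) from None
        known = sorted({n for n, _ in _REGISTRY})
        raise KeyError(f"unknown cut-point set {name!r}; known: {known}") from None


def available_cutpoint_sets() -> list[CutPointSet]:
    return list(_REGISTRY.values())


def register_cutpoint_set(cps: CutPointSet) -> None:
    """Add a user-defined set. Built-in sets are locked against override."""
    key = (cps.name, cps.axis)
    if key in _BUILTIN:
        raise ValueError(
            f"built-in cut-point set {cps.name}/{cps.axis} cannot be overridden"
        )
    _REGISTRY[key] = cps


def epoch_thresholds(cps: CutPointSet, epoch_len_s: int) -> tuple[Fraction, Fraction]:
    """Rescale cpm thresholds to the per-epoch scale as exact rationals."""
    if 60 % epoch_len_s != 0:
        raise ValueError(f"epoch_len_s={epoch_len_s} must divide 60")
    scale = Fraction(epoch_len_s, 60)
    return cps.sb_upper_cpm * scale, cps.mvpa_lower_cpm * scale


def classify_epoch(count, cps: CutPointSet, epoch_len_s: int = 60) -> str:
    """Label one worn epoch's count: sedentary / light / mvpa.

    Sedentary iff count < sedentary bound; MVPA iff count >= MVPA bound;
    light otherwise. Comparison is exact (rational thresholds).
    """
    if count < 0:
        raise ValueError(f"negative count {count}")
    sb_upper, mvpa_lower = epoch_thresholds(cps, epoch_len_s)
    if count < sb_upper:
        return SEDENTARY
    if count >= mvpa_lower:
        return MVPA
    return LIGHT


def classify_series(
    series: CountSeries,
    cps: CutPointSet,
    wear_intervals: list[WearInterval] | None = None,
) -> np.ndarray:
    """Label every epoch of a series; non-worn epochs get the empty label.

    Uses the set's axis: integer vertical counts or the real-valued vector
    magnitude. Comparisons are exact: per-epoch counts are scaled up by
    60/epoch_len (an integer) and compared against the cpm thresholds, which
    is algebraically identical to comparing against the rational per-epoch
    thresholds without introducing floating-point threshold rounding.
    """
    values = series.axis1 if cps.axis == VERTICAL else series.vm
    factor = 60 // series.epoch_len_s
    scaled = values * factor
    labels = np.full(series.n_epochs, LIGHT, dtype="<U9")
    labels[scaled < cps.sb_upper_cpm] = SEDENTARY
    labels[scaled >= cps.mvpa_lower_cpm] = MVPA
    if wear_intervals is not None:
        labels[~worn_mask(series, wear_intervals)] = UNWORN
    return labels
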