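"""Epoch-level activity-count series: the canonical on-disk dialect and container.

The on-disk format is a plain CSV with header ``timestamp,axis1,axis2,axis3``:
ISO-8601 epoch-start timestamps at a constant stride, integer device counts on
the vertical (axis1) and the two horizontal axes. Vector magnitude is never
stored; it is always recomputed as the Euclidean norm of the three axes so
there is a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountSeries", "read_epoch_csv", "write_epoch_csv", "reintegrate"]


@dataclass
class CountSeries:
    """One child's timestamped epoch counts on three axes.

    Epoch ``k`` covers the half-open interval
    ``[start + k*epoch_len_s, start + (k+1)*epoch_len_s)``; the half-open
    convention makes day assignment at midnight unambiguous.

    Parameters
    ----------
    child_id
        Identifier carried through all downstream summaries.
    start
        Timestamp of the first epoch's start (naive local clock time).
    epoch_len_s
        Epoch length in seconds; must divide 60 so counts-per-minute
        thresholds rescale exactly.
    axis1, axis2, axis3
        Non-negative integer device counts per epoch. ``axis1`` is the
        vertical axis, the one the published cut-point sets calibrate.
    """

    child_id: str
    start: pd.Timestamp
    epoch_len_s: int
    axis1: np.ndarray
    axis2: np.ndarray
    axis3: np.ndarray
    _vm: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        if 60 % self.epoch_len_s != 0:
            raise ValueError(
                f"epoch_len_s={self.epoch_len_s} must divide 60 so that "
                "counts-per-minute thresholds rescale exactly"
            )
        axes = []
        for name in ("axis1", "axis2", "axis3"):
            arr = np.asarray(getattr(self, name))
            if arr.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if arr.size and arr.min() < 0:
                raise ValueError(f"{name} contains negative counts")
            axes.append(arr.astype(np.int64))
        if len({a.shape for a in axes}) != 1:
            raise ValueError("axis arrays must have equal length")
        self.axis1, self.axis2, self.axis3 = axes

    @property
    def n_epochs(self) -> int:
        return int(self.axis1.size)

    @property
    def vm(self) -> np.ndarray:
        """Vector magnitude per epoch: Euclidean norm of the three axes.

        Always ``>= axis1`` since the other two components are non-negative.
        """
        if self._vm is None or self._vm.size != self.axis1.size:
            self._vm = np.sqrt(
                self.axis1.astype(float) ** 2
                + self.axis2.astype(float) ** 2
                + self.axis3.astype(float) ** 2
            )
        return self._vm

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_epochs,
                             freq=f"{self.epoch_len_s}s")

    @property
    def dates(self) -> np.ndarray:
        """Calendar date of each epoch (by epoch start, half-open)."""
        return self.timestamps.normalize().values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "axis1": self.axis1,
                "axis2": self.axis2,
                "axis3": self.axis3,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountSeries):
            return NotImplemented
        return (
            self.child_id == other.child_id
            and self.start == other.start
            and self.epoch_len_s == other.epoch_len_s
            and np.array_equal(self.axis1, other.axis1)
            and np.array_equal(self.axis2, other.axis2)
            and np.array_equal(self.axis3, other.axis3)
        )


def read_epoch_csv(path, child_id: str | None = None) -> CountSeries:
    """Read an epoch CSV (``timestamp,axis1,axis2,axis3``) into a CountSeries.

    The stride between consecutive timestamps must be constant; violations are
    rejected with the 1-based data-row number of the first offending row, as
    are negative counts and unparseable timestamps.
    """
    df = pd.read_csv(path)
    expected = ["timestamp", "axis1", "axis2", "axis3"]
    if list(df.columns) != expected:
        raise ValueError(f"expected header {expected}, found {list(df.columns)}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError):
        # locate the first bad row for the error message
        for i, raw in enumerate(df["timestamp"]):
            try:
                pd.Timestamp(raw)
            except (ValueError, TypeError):
                raise ValueError(f"unparseable timestamp at data row {i + 1}: {raw!r}")
        raise
    for name in ("axis1", "axis2", "axis3"):
        col = pd.to_numeric(df[name])
        bad = np.flatnonzero(col.values < 0)
        if bad.size:
            raise ValueError(f"negative count in {name} at data row {bad[0] + 1}")
    if len(df) == 0:
        raise ValueError("empty epoch file: cannot infer start or stride")
    if len(df) == 1:
        raise ValueError("single-epoch file: cannot infer stride")
    strides = np.diff(ts.values).astype("timedelta64[s]").astype(int)
    if strides[0] <= 0:
        raise ValueError("non-positive stride at data row 2")
    bad = np.flatnonzero(strides != strides[0])
    if bad.size:
        # bad[0] is the gap index; offending row is the later of the pair
        raise ValueError(
            f"non-constant stride at data row {bad[0] + 2}: expected "
            f"{strides[0]} s, found {strides[bad[0]]} s"
        )
    name = child_id if child_id is not None else _stem(path)
    return CountSeries(
        child_id=name,
        start=ts.iloc[0],
        epoch_len_s=int(strides[0]),
        axis1=df["axis1"].values,
        axis2=df["axis2"].values,
        axis3=df["axis3"].values,
    )


def write_epoch_csv(series: CountSeries, path) -> None:
    """Write the canonical epoch CSV: UTF-8, LF endings, ISO timestamps."""
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")


def reintegrate(series: CountSeries, target_epoch_s: int) -> CountSeries:
    """Re-integrate to a coarser epoch by summing axis counts within windows.

    Vector magnitude is recomputed from the summed axes (it is not additive).
    ``target_epoch_s`` must be a multiple of the current epoch length and
    divide a day; the series length must be a whole number of target windows.
    Per-axis totals are conserved exactly.
    """
    if target_epoch_s % series.epoch_len_s != 0:
        raise ValueError(
            f"target epoch {target_epoch_s} s is not a multiple of the "
            f"current epoch {series.epoch_len_s} s"
        )
    if 86400 % target_epoch_s != 0:
        raise ValueError(f"target epoch {target_epoch_s} s does not divide a day")
    factor = target_epoch_s // series.epoch_len_s
    if factor == 1:
        return CountSeries(series.child_id, series.start, series.epoch_len_s,
                           series.axis1.copy(), series.axis2.copy(),
                           series.axis3.copy())
    if series.n_epochs % factor != 0:
        raise ValueError(
            f"series length {series.n_epochs} is not a whole number of "
            f"{target_epoch_s}-s windows"
        )
    def fold(a: np.ndarray) -> np.ndarray:
        return a.reshape(-1, factor).sum(axis=1)
    return CountSeries(
        child_id=series.child_id,
        start=series.start,
        epoch_len_s=target_epoch_s,
        axis1=fold(series.axis1),
        axis2=fold(series.axis2),
        axis3=fold(series.axis3),
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
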