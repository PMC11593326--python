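import numpy as np
import pandas as pd
import pytest

from accelcut import CountSeries, SimConfig


def build_series(counts, epoch_len_s=60, start="2025-01-06 00:00:00",
                 child_id="c1", axis2=None, axis3=None):
    """CountSeries from a vertical-count sequence; horizontal axes default 0."""
    counts = np.asarray(counts)
    zeros = np.zeros_like(counts)
    return CountSeries(
        child_id=child_id,
        start=pd.Timestamp(start),
        epoch_len_s=epoch_len_s,
        axis1=counts,
        axis2=zeros if axis2 is None else np.asarray(axis2),
        axis3=zeros if axis3 is None else np.asarray(axis3),
    )


def minutes_series(segments, start="2025-01-06 00:00:00", child_id="c1"):
    """60-s epoch series from (minutes, count-per-epoch) segments."""
    counts = np.concatenate(
        [np.full(int(m), c, dtype=np.int64) for m, c in segments]
    )
    return build_series(counts, epoch_len_s=60, start=start, child_id=child_id)


@pytest.fixture
def tiny_sim_config():
    """Three children, Friday-Sunday (one weekday + weekend), 5-s epochs."""
    return SimConfig(n_children=3, n_days=3, start_weekday=4, seed=11)
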