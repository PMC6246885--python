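import numpy as np
import pandas as pd
import pytest

from catransient import DffMatrix, TraceMatrix


def make_traces(F, frame_interval_s=4.0, stim_time_s=60.0, cell_ids=None):
    F = np.asarray(F, dtype=float)
    ids = cell_ids or [f"c{i:04d}" for i in range(F.shape[0])]
    times = np.arange(F.shape[1]) * frame_interval_s
    return TraceMatrix(cell_ids=ids, times_s=times, F=F, stim_time_s=stim_time_s)


def make_dff(values, frame_interval_s=4.0, stim_time_s=60.0, mode="response"):
    values = np.asarray(values, dtype=float)
    ids = [f"c{i:04d}" for i in range(values.shape[0])]
    times = np.arange(values.shape[1]) * frame_interval_s
    return DffMatrix(cell_ids=ids, times_s=times, dff=values,
                     baseline_F0=np.ones(values.shape[0]),
                     stim_time_s=stim_time_s, mode=mode)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cell_table():
    return pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(8)],
        "prep_id": ["prep1"] * 4 + ["prep2"] * 4,
        "segment": ["A3", "A3", "A1", "T3", "A3", "A5", "A1", "T3"],
        "hemisegment": ["L", "L", "R", "L", "L", "R", "R", "L"],
        "condition": "eaa-withdrawal",
        "genotype": "control",
    })
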