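import numpy as np
import pandas as pd
import pytest

from emgsi.io import ArtifactTable, EmgRecording, EventTable
from emgsi.montage import ALL_TASKS, CANONICAL_CHANNELS


def make_recording(samples, fs=100.0, **kwargs):
    """Wrap an (n, 10) array — or an (n,) array broadcast to all channels —
    into a recording."""
    samples = np.asarray(samples, float)
    if samples.ndim == 1:
        samples = np.tile(samples[:, None], (1, len(CANONICAL_CHANNELS)))
    return EmgRecording(samples=samples, fs=fs, **kwargs)


def make_events(windows, joint="ankle", leg="less"):
    """Event table for a single task with the given 3 (start, end) windows."""
    rows = [
        {"joint": joint, "leg": leg, "repetition": i + 1, "start_s": s, "end_s": e}
        for i, (s, e) in enumerate(windows)
    ]
    return EventTable(pd.DataFrame(rows))


def full_event_table(rep_s=1.0, gap_s=0.5, start_s=0.0):
    """All 8 tasks with 3 back-to-back repetitions each."""
    rows = []
    t = start_s
    for task in ALL_TASKS:
        for rep in (1, 2, 3):
            rows.append(
                {"joint": task.joint, "leg": task.leg, "repetition": rep,
                 "start_s": t, "end_s": t + rep_s}
            )
            t += rep_s + gap_s
    return EventTable(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def empty_artifacts():
    return ArtifactTable.empty()
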