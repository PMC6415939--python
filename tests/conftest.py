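from datetime import datetime, time

import numpy as np
import pytest

from flysleep.core import ActivityTrace, LightRegime


@pytest.fixture
def regime_8l16d() -> LightRegime:
    """8 h light : 16 h dark, lights-on 09:00 (the short-photoperiod regime)."""
    return LightRegime(mode="LD", lights_on_clock=time(9, 0), light_hours=8.0)


@pytest.fixture
def regime_12l12d() -> LightRegime:
    return LightRegime(mode="LD", lights_on_clock=time(9, 0), light_hours=12.0)


def make_dam_trace(counts, start=datetime(2018, 1, 1, 9, 0), fly_id="f1") -> ActivityTrace:
    return ActivityTrace(
        fly_id=fly_id, modality="DAM", start_time=start, bin_seconds=60,
        values=np.asarray(counts, dtype=float),
    )


def make_dart_trace(mm, bin_seconds=5, start=datetime(2018, 1, 1, 9, 0), fly_id="f1") -> ActivityTrace:
    return ActivityTrace(
        fly_id=fly_id, modality="DART", start_time=start, bin_seconds=bin_seconds,
        values=np.asarray(mm, dtype=float),
    )
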