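import numpy as np
import pandas as pd
import pytest

from emogo.core import ChannelLayout, EventMarker, RawRecording
from emogo.synth import (ArtifactParams, BehaviorParams, BlinkParams,
                         GeneratorParams, NoiseParams)
from emogo.task import TaskSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def layout():
    return ChannelLayout()


@pytest.fixture
def small_task():
    """One-block task without practice, for fast session fixtures."""
    return TaskSpec(n_blocks=1, trials_per_block=72, go_per_block=48,
                    nogo_per_block=24, practice_trials=0)


@pytest.fixture
def clean_generator(small_task):
    """Artifact-free, deterministic-behavior generator conditions."""
    return GeneratorParams(
        n_subjects=1, seed=99, task=small_task,
        behavior=BehaviorParams(go_hit_p=1.0, nogo_commission_p=0.0,
                                anticipatory_p=0.0),
        blink=BlinkParams(rate_per_min=0.0),
        artifact=ArtifactParams(rate_per_min=0.0),
        noise=NoiseParams(pink_sd_uv=3.0, alpha_amp_uv=1.0),
        onset_interval_ms=1400.0,
    )


def make_raw(data, rate=500.0, events=(), layout=None, annotations=()):
    return RawRecording(data=np.asarray(data, dtype=float), rate=rate,
                        layout=layout or ChannelLayout(), events=list(events),
                        annotations=list(annotations))


@pytest.fixture
def trial_log_simple():
    """Hand-built 6-trial completed log (no practice)."""
    return pd.DataFrame(dict(
        trial_id=range(6), block=1, is_practice=False,
        condition=["Go", "Go", "Go", "NoGo", "NoGo", "NoGo"],
        emotion=["happy", "angry", "neutral", "happy", "angry", "neutral"],
        identity=["m1", "m2", "m1", "f1", "f2", "f1"],
        go_duration_ms=550.0, response_window_ms=[550.0] * 3 + [750.0] * 3,
        responded=[True, True, False, False, True, False],
        rt_ms=[400.0, 450.0, np.nan, np.nan, 300.0, np.nan],
        correct=[True, True, False, True, False, True],
    ))
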