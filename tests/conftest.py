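"""Shared fixtures: small synthetic videos sized for fast tests.

The small video keeps the default transition structure (four logistic
steps, 50% total loss, 1.5 s jitter, 1% camera noise) but compresses the
time axis and the frame so the full detection chain runs in seconds.
"""

import numpy as np
import pytest

from phasekin.detect import detect_pixel_transitions
from phasekin.synthetic import (
    SyntheticTraceParams,
    SyntheticVideoParams,
    TransitionSpec,
    generate_video,
)

# the default four-step structure with the time axis compressed; steps are
# kept >= 30 s apart so the prescribed smoothing chain resolves them, as at
# full scale
SMALL_TRANSITIONS = (
    TransitionSpec("T1", 60.0, 1.0, 0.20),
    TransitionSpec("T2a", 100.0, 4.0, 0.10),
    TransitionSpec("T2b", 130.0, 6.0, 0.10),
    TransitionSpec("T3", 170.0, 8.0, 0.10),
)


@pytest.fixture(scope="session")
def small_trace_params() -> SyntheticTraceParams:
    return SyntheticTraceParams(transitions=SMALL_TRANSITIONS)


@pytest.fixture(scope="session")
def small_video_params(small_trace_params) -> SyntheticVideoParams:
    return SyntheticVideoParams(
        trace_params=small_trace_params,
        height=36,
        width=36,
        n_frames=560,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_video(small_video_params):
    video, truth = generate_video(small_video_params)
    return video, truth


@pytest.fixture(scope="session")
def small_detections(small_video):
    video, _ = small_video
    return detect_pixel_transitions(video)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
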