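import warnings

import numpy as np
import pytest

import photomotor as pm


@pytest.fixture(scope="session")
def session_bundle():
    """One default synthetic session (600 s, 10 stimuli, half responders)."""
    return pm.synthesize_session(pm.SessionConfig(), seed=1)


@pytest.fixture(scope="session")
def session_result(session_bundle):
    """Full pipeline output for the shared session."""
    b = session_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pm.analyze_session(b.photometry, b.tracking, b.events, b.annotations)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_speed_trace(speeds, fps=20.0):
    """SpeedTrace from a plain array (NaN = missing frame)."""
    speeds = np.asarray(speeds, dtype=float)
    return pm.SpeedTrace(
        time=np.arange(speeds.size) / fps, speed=speeds, fps=fps, scale=0.1
    )


def brute_force_bouts(speeds, fps=20.0, threshold=3.0, min_duration=0.5):
    """Independent oracle: enumerate supra-threshold runs frame by frame."""
    speeds = np.asarray(speeds, dtype=float)
    frame = 1.0 / fps
    bouts = []
    run = []
    for i, v in enumerate(list(speeds) + [np.nan]):
        if np.isfinite(v) and v > threshold:
            run.append(i)
        else:
            if run and len(run) >= min_duration * fps - 1e-9:
                bouts.append((run[0] * frame, run[-1] * frame + frame))
            run = []
    return bouts
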