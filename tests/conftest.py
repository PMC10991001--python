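import numpy as np
import pytest

import gazeval as gv


@pytest.fixture(scope="session")
def poster():
    return gv.default_poster()


@pytest.fixture(scope="session")
def calib():
    return gv.default_calibration()


@pytest.fixture(scope="session")
def clean_recording(poster):
    """Noiseless still-head validation recording: nine 1-s dwells at
    50 Hz from (0, 0, -600), no offset, no loss."""
    cfg = gv.SimulationConfig(poster=poster, seed=0)
    return gv.simulate_recording(cfg)


@pytest.fixture(scope="session")
def clean_summary_pose(clean_recording, poster):
    rec, _ = clean_recording
    return gv.process_episode(rec, rec.episodes[0], poster, mode="pose_estimated")


def make_series(xy, dt_ms=20.0, eye=(0.0, 0.0, -600.0), valid=None, mode="fixed_distance"):
    """Hand-built poster-gaze series for classifier/quality unit tests."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    xy = xy.copy()
    xy[~valid] = np.nan
    eye_arr = np.tile(np.asarray(eye, dtype=float), (n, 1))
    eye_arr[~valid] = np.nan
    return gv.PosterGazeSeries(
        timestamps=np.arange(n) * dt_ms,
        poster_xy=xy,
        eye_pos=eye_arr,
        gaze_px=np.full((n, 2), np.nan),
        valid=valid,
        reason=np.where(valid, "ok", "gaze-missing").astype(str),
        mode=mode,
        assumed_eye=np.asarray(eye, dtype=float),
    )
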