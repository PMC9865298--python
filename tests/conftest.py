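import numpy as np
import pytest

from posturekit import (
    FilterSpec,
    PostureLabel,
    Schedule,
    SubjectModel,
    default_dataset,
    default_recordings,
    default_schedule,
    generate,
    lowpass_filter,
)
from posturekit.synthetic import PostureModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def noiseless_models(**overrides):
    """Posture models with zero tilt spread, noise and breathing."""
    params = {
        PostureLabel.STANDING: 0.0,
        PostureLabel.SITTING: 20.0,
        PostureLabel.BENDING: 60.0,
        PostureLabel.LYING: 90.0,
    }
    params.update(overrides)
    return {
        p: PostureModel(
            posture=p, tilt_mean_deg=tilt, tilt_std_deg=0.0,
            dynamic_noise_g=0.0, breathing_amp_g=0.0,
        )
        for p, tilt in params.items()
    }


@pytest.fixture(scope="session")
def mini_dataset():
    """A small (2-subject, single-cycle) labelled feature matrix for unit
    tests that need realistic feature structure without the full cohort."""
    schedule = default_schedule(seconds_per_posture=6.0, cycles=1)
    recordings = default_recordings(n_subjects=2, seed=7, schedule=schedule)
    return default_dataset(recordings=recordings, layout="full")


def steady_window_tilts(rec, profile, settle_s=1.5):
    """Per-window mean-vector tilt angles of a recording, keyed by label,
    keeping only windows fully inside one segment and past its transient.

    Returns a dict label -> list of tilt degrees.
    """
    from collections import defaultdict

    from posturekit import WindowSpec, compute_tilt, lowpass_filter, make_windows

    stream = lowpass_filter(rec.stream)
    seg = rec.segment_ids
    seg_start = np.zeros(len(seg), dtype=int)
    boundaries = np.flatnonzero(np.diff(seg)) + 1
    for b in boundaries:
        seg_start[b:] = b
    settle = int(settle_s * stream.fs)
    out = defaultdict(list)
    for start, stop in make_windows(stream, WindowSpec()):
        if seg[start] != seg[stop - 1] or start - seg_start[start] < settle:
            continue
        v = stream.a[start:stop].mean(axis=0)
        out[rec.stream.labels[start]].append(compute_tilt(v, profile).alpha_deg)
    return out


@pytest.fixture(scope="session")
def standing_stream():
    """A filtered static standing recording that passes calibration."""
    rec = generate(
        Schedule(segments=[(PostureLabel.STANDING, 4.0)], transition_s=0.0),
        SubjectModel(subject_id=0),
        seed=3,
        posture_models=noiseless_models(),
    )
    stream = rec.stream
    # small sensor noise, well within the static-condition threshold
    jitter = np.random.default_rng(3).normal(0, 0.005, stream.a.shape)
    return lowpass_filter(stream.with_values(stream.a + jitter), FilterSpec())
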