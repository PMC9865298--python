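"""Synthetic chest-accelerometer recordings with known posture structure.

The generator emulates what a chest-worn ±2 g accelerometer sees across the
four target postures: a unit-norm gravity vector whose direction tilts about
the device x-axis by a posture-dependent angle θ (standing ≈ 0°, sitting
≈ 20°, bending ≈ 60°, lying ≈ 90°), plus a small breathing sinusoid along
the chest-normal axis and white sensor noise, saturated at ±2 g.

Each simulated subject wears the device with a small random mounting
rotation and holds each posture at a characteristic angle drawn once per
(subject, posture) from the posture's tilt distribution — people sit the
way they sit. Posture changes are smoothed by cosine interpolation of θ
over a transition interval; transition samples carry the target posture's
label.

The default cohort — seven subjects, three cycles of all four postures at
30 s per posture, 50 Hz — is the study condition every downstream default
and evaluation in this package assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .evaluation import downsample
from .features import FeatureMatrix, WindowSpec, build_feature_matrix
from .models import PostureLabel
from .preprocessing import FilterSpec, lowpass_filter
from .signal_io import ACCEL_RANGE_G, AccelStream

#: Per-posture tilt means and spreads (degrees): sitting sits closer to
#: standing than to bending — the confusable pairs a single chest sensor
#: struggles with are standing/sitting and bending/lying.
DEFAULT_TILTS = {
    PostureLabel.STANDING: (0.0, 4.0),
    PostureLabel.SITTING: (20.0, 5.0),
    PostureLabel.BENDING: (60.0, 8.0),
    PostureLabel.LYING: (90.0, 6.0),
}

DEFAULT_DYNAMIC_NOISE_G = 0.02
DEFAULT_BREATHING_AMP_G = 0.005
DEFAULT_BREATHING_HZ = 0.25


@dataclass
class PostureModel:
    """Statistical model of one posture as seen by the chest sensor."""

    posture: PostureLabel
    tilt_mean_deg: float
    tilt_std_deg: float
    dynamic_noise_g: float = DEFAULT_DYNAMIC_NOISE_G
    breathing_amp_g: float = DEFAULT_BREATHING_AMP_G
    breathing_hz: float = DEFAULT_BREATHING_HZ

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_mean_deg <= 180.0:
            raise ValidationError("tilt_mean_deg must lie in [0, 180]")
        if min(self.tilt_std_deg, self.dynamic_noise_g, self.breathing_amp_g) < 0:
            raise ValidationError("spread/noise parameters must be non-negative")


def default_posture_models() -> dict[PostureLabel, PostureModel]:
    return {
        p: PostureModel(posture=p, tilt_mean_deg=m, tilt_std_deg=s)
        for p, (m, s) in DEFAULT_TILTS.items()
    }


@dataclass
class SubjectModel:
    """Per-subject device placement: a small mounting rotation and a noise scale."""

    subject_id: int
    offset_x_deg: float = 0.0
    offset_y_deg: float = 0.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if max(abs(self.offset_x_deg), abs(self.offset_y_deg)) >= 15.0:
            raise ValidationError("mounting offsets must stay below 15 degrees")

    def rotation(self) -> np.ndarray:
        """Mounting rotation matrix R = Rx(offset_x) @ Ry(offset_y)."""
        cx, sx = np.cos(np.radians(self.offset_x_deg)), np.sin(np.radians(self.offset_x_deg))
        cy, sy = np.cos(np.radians(self.offset_y_deg)), np.sin(np.radians(self.offset_y_deg))
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        return rx @ ry


def make_subjects(
    n_subjects: int = 7, seed: int = 0, offset_std_deg: float = 3.0
) -> list[SubjectModel]:
    """Cohort with mounting offsets drawn from N(0, offset_std_deg)."""
    rng = np.random.default_rng([int(seed), 2_000_001])
    subjects = []
    for i in range(n_subjects):
        ox, oy = np.clip(rng.normal(0.0, offset_std_deg, 2), -14.9, 14.9)
        subjects.append(SubjectModel(subject_id=i, offset_x_deg=float(ox),
                                     offset_y_deg=float(oy)))
    return subjects


@dataclass
class Schedule:
    """Ordered (posture, duration) segments with smoothed transitions."""

    segments: list[tuple[PostureLabel, float]]
    transition_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigurationError("schedule must contain at least one segment")
        for posture, dur in self.segments:
            if dur <= 0:
                raise ConfigurationError(f"segment duration must be positive, got {dur}")
            if self.transition_s >= dur:
                raise ConfigurationError(
                    "transition_s must be shorter than every segment duration"
                )
        if self.transition_s < 0:
            raise ConfigurationError("transition_s must be non-negative")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))


def default_schedule(
    seconds_per_posture: float = 30.0, cycles: int = 3, transition_s: float = 1.0
) -> Schedule:
    """All four postures in tilt order, repeated ``cycles`` times."""
    order = [PostureLabel.STANDING, PostureLabel.SITTING,
             PostureLabel.BENDING, PostureLabel.LYING]
    return Schedule(
        segments=[(p, seconds_per_posture) for _ in range(cycles) for p in order],
        transition_s=transition_s,
    )


@dataclass
class SyntheticRecording:
    """A generated stream plus the ground truth behind it."""

    stream: AccelStream  # labels embedded
    segment_ids: np.ndarray  # per-sample segment index
    subject: SubjectModel
    realized_tilts_deg: dict[PostureLabel, float] = field(default_factory=dict)


def generate(
    schedule: Schedule,
    subject: SubjectModel | None = None,
    fs: float = 50.0,
    seed: int = 0,
    posture_models: dict[PostureLabel, PostureModel] | None = None,
) -> SyntheticRecording:
    """Simulate one recording; bit-identical for identical arguments.

    The tilt trajectory θ(t) holds each segment's characteristic angle and
    cosine-interpolates over the first ``transition_s`` of every segment
    after the first. The sample at time t reads

        a(t) = R_subject · (0, sin θ(t), cos θ(t)) + (0, 0, b(t)) + ε(t)

    with b a breathing sinusoid and ε white noise, clipped to ±2 g.
    """
    subject = subject or SubjectModel(subject_id=0)
    posture_models = posture_models or default_posture_models()
    rng = np.random.default_rng([int(seed), int(subject.subject_id), 1_000_003])

    # characteristic angle per posture for this subject (one draw each)
    tilts: dict[PostureLabel, float] = {}
    for posture in PostureLabel:
        if posture in posture_models:
            pm = posture_models[posture]
            tilts[posture] = float(rng.normal(pm.tilt_mean_deg, pm.tilt_std_deg))

    n_total = int(round(schedule.total_duration_s * fs))
    t = np.arange(n_total) / fs
    theta = np.empty(n_total)
    labels = np.empty(n_total, dtype=object)
    segment_ids = np.empty(n_total, dtype=int)
    noise_std = np.empty(n_total)
    breath_amp = np.empty(n_total)
    breath_hz = np.empty(n_total)

    edges = np.concatenate([[0.0], np.cumsum([d for _, d in schedule.segments])])
    prev_theta = None
    for k, (posture, _dur) in enumerate(schedule.segments):
        i0 = int(round(edges[k] * fs))
        i1 = int(round(edges[k + 1] * fs)) if k + 1 < len(edges) else n_total
        i1 = min(i1, n_total)
        pm = posture_models[posture]
        th = tilts[posture]
        seg_theta = np.full(i1 - i0, th)
        if prev_theta is not None and schedule.transition_s > 0:
            n_tr = min(int(round(schedule.transition_s * fs)), i1 - i0)
            s = (np.arange(n_tr) + 1) / n_tr
            seg_theta[:n_tr] = prev_theta + (th - prev_theta) * (1 - np.cos(np.pi * s)) / 2
        theta[i0:i1] = seg_theta
        labels[i0:i1] = posture.value
        segment_ids[i0:i1] = k
        noise_std[i0:i1] = pm.dynamic_noise_g * subject.noise_scale
        breath_amp[i0:i1] = pm.breathing_amp_g
        breath_hz[i0:i1] = pm.breathing_hz
        prev_theta = th

    rad = np.radians(theta)
    gravity = np.column_stack([np.zeros(n_total), np.sin(rad), np.cos(rad)])
    a = gravity @ subject.rotation().T

    phase = rng.uniform(0, 2 * np.pi)
    a[:, 2] += breath_amp * np.sin(2 * np.pi * breath_hz * t + phase)
    if np.any(noise_std > 0):
        a += rng.standard_normal((n_total, 3)) * noise_std[:, None]
    a = np.clip(a, -ACCEL_RANGE_G, ACCEL_RANGE_G)

    stream = AccelStream(t=t, a=a, fs=fs, units="g", labels=labels)
    return SyntheticRecording(
        stream=stream, segment_ids=segment_ids, subject=subject,
        realized_tilts_deg=tilts,
    )


def standing_calibration_stream(
    subject: SubjectModel | None = None,
    fs: float = 50.0,
    seed: int = 0,
    duration_s: float = 3.0,
    posture_models: dict[PostureLabel, PostureModel] | None = None,
) -> AccelStream:
    """A short static standing recording at the subject's characteristic
    standing angle, for the calibration stage."""
    schedule = Schedule(
        segments=[(PostureLabel.STANDING, duration_s)], transition_s=0.0
    )
    return generate(schedule, subject, fs=fs, seed=seed,
                    posture_models=posture_models).stream


def default_recordings(
    n_subjects: int = 7,
    seed: int = 0,
    fs: float = 50.0,
    schedule: Schedule | None = None,
    posture_models: dict[PostureLabel, PostureModel] | None = None,
) -> list[SyntheticRecording]:
    """One default-schedule recording per cohort subject."""
    schedule = schedule or default_schedule()
    subjects = make_subjects(n_subjects=n_subjects, seed=seed)
    return [
        generate(schedule, subj, fs=fs, seed=seed, posture_models=posture_models)
        for subj in subjects
    ]


def default_dataset(
    n_subjects: int = 7,
    seed: int = 0,
    fs: float = 50.0,
    target_fs: float | None = None,
    layout: str = "selected",
    window_spec: WindowSpec | None = None,
    filter_spec: FilterSpec | None = None,
    recordings: list[SyntheticRecording] | None = None,
) -> FeatureMatrix:
    """Labelled feature matrix of the default cohort, pipeline-processed.

    Each recording is low-pass filtered (10 Hz), optionally decimated to
    ``target_fs``, windowed, and featurized; rows carry the majority posture
    label, the subject id, and a contiguous-segment group id for
    leakage-safe cross-validation.
    """
    recordings = recordings if recordings is not None else default_recordings(
        n_subjects=n_subjects, seed=seed, fs=fs
    )
    window_spec = window_spec or WindowSpec()
    filter_spec = filter_spec or FilterSpec()
    parts = []
    for rec in recordings:
        stream = lowpass_filter(rec.stream, filter_spec)
        seg = rec.segment_ids
        if target_fs is not None and target_fs != stream.fs:
            factor = round(stream.fs / target_fs)
            stream = downsample(stream, target_fs)
            seg = seg[::factor]
        groups = np.array(
            [f"s{rec.subject.subject_id}-seg{k}" for k in seg], dtype=object
        )
        parts.append(
            build_feature_matrix(
                stream,
                window_spec=window_spec,
                layout=layout,
                group_ids=groups,
                subject_id=rec.subject.subject_id,
            )
        )
    return FeatureMatrix.concat(parts)
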