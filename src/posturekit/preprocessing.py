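"""Noise filtering, chest-tilt computation, and standing-pose calibration.

Electrical/environmental noise is removed with an order-8 Butterworth
low-pass at 10 Hz (posture dynamics live well below that). Batch mode
applies the filter forward-backward (zero phase, magnitude order
effectively doubled); streaming mode applies it causally once, matching
real-time operation.

Calibration assumes the wearer stands still for a couple of seconds after
the device is strapped on: the two axes orthogonal to gravity must read
close to zero, the gravity axis close to ±1 g, and the per-axis scatter
must be small (static condition). The passing mean vector, normalized,
becomes the per-subject reference direction against which the chest tilt
angle α is measured — so small mounting offsets cancel out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

from .errors import (
    CalibrationError,
    ConfigurationError,
    InsufficientDataError,
    SignalLossError,
    ValidationError,
)
from .signal_io import AccelStream

AXIS_NAMES = ("x", "y", "z")

#: Minimum acceleration magnitude (g) for a defined orientation.
MIN_TILT_MAGNITUDE_G = 0.1


@dataclass
class FilterSpec:
    """Low-pass filter configuration.

    ``zero_phase_batch`` filters forward-backward (no group delay, for
    offline processing); ``causal_stream`` is a single causal pass as a
    real-time system would run.
    """

    order: int = 8
    cutoff_hz: float = 10.0
    mode: str = "zero_phase_batch"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ConfigurationError(f"filter order must be >= 1, got {self.order}")
        if self.cutoff_hz <= 0:
            raise ConfigurationError("cutoff_hz must be positive")
        if self.mode not in ("zero_phase_batch", "causal_stream"):
            raise ConfigurationError(f"unknown filter mode {self.mode!r}")


def lowpass_filter(stream: AccelStream, spec: FilterSpec | None = None) -> AccelStream:
    """Butterworth low-pass each axis; same length and timestamps, DC gain 1."""
    spec = spec or FilterSpec()
    nyq = stream.fs / 2.0
    if spec.cutoff_hz >= nyq:
        raise ConfigurationError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {nyq} Hz"
        )
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=stream.fs, output="sos")
    if spec.mode == "zero_phase_batch":
        filtered = sps.sosfiltfilt(sos, stream.a, axis=0)
    else:
        filtered = sps.sosfilt(sos, stream.a, axis=0)
    return stream.with_values(filtered)


def butterworth_gain(f_hz: float, spec: FilterSpec, two_pass: bool = False) -> float:
    """Analog-prototype Butterworth magnitude |H(f)| = (1+(f/fc)^2n)^-1/2.

    Convenience for documentation and sanity checks; ``two_pass`` squares the
    magnitude as forward-backward filtering does.
    """
    mag = 1.0 / np.sqrt(1.0 + (f_hz / spec.cutoff_hz) ** (2 * spec.order))
    return float(mag**2 if two_pass else mag)


@dataclass
class TiltReading:
    """Chest tilt α in degrees, in [0, 180], relative to the stored reference."""

    alpha_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_deg <= 180.0:
            raise ValidationError(f"tilt must lie in [0, 180] deg, got {self.alpha_deg}")


@dataclass
class CalibrationProfile:
    """Stored initial-positioning state from a passing standing calibration."""

    reference_vector: np.ndarray
    gravity_axis: int = 2
    tolerance_g: float = 0.15
    static_std_max_g: float = 0.05
    stored_means: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.reference_vector = np.asarray(self.reference_vector, float)
        self.stored_means = np.asarray(self.stored_means, float)
        if abs(np.linalg.norm(self.reference_vector) - 1.0) > 1e-9:
            raise ValidationError("reference_vector must be unit norm")
        if self.tolerance_g <= 0:
            raise ValidationError("tolerance_g must be positive")

    def to_yaml(self, path) -> None:
        doc = {
            "reference_vector": [float(v) for v in self.reference_vector],
            "gravity_axis": int(self.gravity_axis),
            "tolerance_g": float(self.tolerance_g),
            "static_std_max_g": float(self.static_std_max_g),
            "stored_means": [float(v) for v in self.stored_means],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CalibrationProfile":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            reference_vector=np.asarray(doc["reference_vector"], float),
            gravity_axis=int(doc["gravity_axis"]),
            tolerance_g=float(doc["tolerance_g"]),
            static_std_max_g=float(doc["static_std_max_g"]),
            stored_means=np.asarray(doc["stored_means"], float),
        )


def compute_tilt(v: np.ndarray, profile: CalibrationProfile) -> TiltReading:
    """Angle between an acceleration direction and the standing reference.

    ``v`` is a (window-mean) acceleration 3-vector in g. A magnitude below
    0.1 g has no meaningful orientation (free fall / disconnection) and
    raises :class:`SignalLossError`.
    """
    v = np.asarray(v, float)
    mag = float(np.linalg.norm(v))
    if mag < MIN_TILT_MAGNITUDE_G:
        raise SignalLossError(
            f"acceleration magnitude {mag:.3f} g < {MIN_TILT_MAGNITUDE_G} g: "
            "orientation undefined (free fall or sensor disconnection)"
        )
    cosine = float(np.dot(v, profile.reference_vector) / mag)
    alpha = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
    return TiltReading(alpha_deg=float(alpha))


def calibrate(
    stream: AccelStream,
    gravity_axis: int = 2,
    tolerance_g: float = 0.15,
    static_std_max_g: float = 0.05,
) -> CalibrationProfile:
    """Verify a static standing recording and store the reference direction.

    Checks, on the per-axis means and standard deviations of a filtered
    standing-pose stream of at least 2 s:

    a. both non-gravity axes read |mean| <= ``tolerance_g`` (orthogonal to g);
    b. the gravity axis reads ||mean| - 1| <= ``tolerance_g``;
    c. every axis std <= ``static_std_max_g`` (the wearer was static).

    On success the mean vector is stored and its normalization becomes the
    tilt reference. Any violated condition raises :class:`CalibrationError`
    naming the condition and axis.
    """
    if stream.units != "g":
        raise ValidationError("calibration requires a stream in g units")
    if len(stream) < 2 * stream.fs:
        raise InsufficientDataError(
            f"calibration needs >= 2 s of data ({int(2 * stream.fs)} samples at "
            f"{stream.fs:g} Hz), got {len(stream)}"
        )
    means = stream.a.mean(axis=0)
    stds = stream.a.std(axis=0)
    for ax in range(3):
        if ax == gravity_axis:
            if abs(abs(means[ax]) - 1.0) > tolerance_g:
                raise CalibrationError(
                    f"gravity axis {AXIS_NAMES[ax]} mean {means[ax]:+.3f} g is not "
                    f"within {tolerance_g} g of ±1 g"
                )
        elif abs(means[ax]) > tolerance_g:
            raise CalibrationError(
                f"non-gravity axis {AXIS_NAMES[ax]} mean {means[ax]:+.3f} g exceeds "
                f"tolerance {tolerance_g} g (not orthogonal to gravity)"
            )
    for ax in range(3):
        if stds[ax] > static_std_max_g:
            raise CalibrationError(
                f"static condition violated: axis {AXIS_NAMES[ax]} std "
                f"{stds[ax]:.3f} g exceeds {static_std_max_g} g"
            )
    reference = means / np.linalg.norm(means)
    return CalibrationProfile(
        reference_vector=reference,
        gravity_axis=gravity_axis,
        tolerance_g=tolerance_g,
        static_std_max_g=static_std_max_g,
        stored_means=means.copy(),
    )
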