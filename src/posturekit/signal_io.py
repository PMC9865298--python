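"""Tri-axial acceleration streams and their CSV dialect.

The pipeline's raw substrate is a timestamped stream of chest accelerations.
A chest-worn IMU (±2 g full scale, 50 Hz) streams either raw ADC/mV readings
or values already converted to gravitational units; :func:`raw_to_g` applies
the standard per-axis affine sensor model and saturates at the ±2 g range.

CSV dialect: header ``timestamp_s,ax,ay,az`` with an optional trailing
``label`` column (values ``standing``/``sitting``/``bending``/``lying``)
for training files. UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Accelerometer full-scale range in g (saturating sensor).
ACCEL_RANGE_G = 2.0

#: Default sensitivity of the chest IMU's accelerometer, raw units (mV) per g.
DEFAULT_SENSITIVITY = 660.0

REQUIRED_COLUMNS = ("timestamp_s", "ax", "ay", "az")


class AccelSample(NamedTuple):
    """One timestamped tri-axial acceleration reading."""

    t: float
    ax: float
    ay: float
    az: float


@dataclass
class SensorCalibrationParams:
    """Per-axis affine sensor model: value_g = (raw - offset) / sensitivity."""

    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sensitivity: np.ndarray = field(
        default_factory=lambda: np.full(3, DEFAULT_SENSITIVITY)
    )

    def __post_init__(self) -> None:
        self.offset = np.broadcast_to(np.asarray(self.offset, float), (3,)).copy()
        self.sensitivity = np.broadcast_to(
            np.asarray(self.sensitivity, float), (3,)
        ).copy()
        if np.any(self.sensitivity <= 0):
            raise ValidationError("sensitivity must be strictly positive on all axes")


@dataclass
class AccelStream:
    """An ordered tri-axial acceleration recording.

    Parameters
    ----------
    t
        Sample times in seconds, strictly increasing, nominal spacing 1/fs.
    a
        Accelerations, shape (N, 3), columns x/y/z. In ``units == "g"`` each
        axis lies within the ±2 g sensor range.
    fs
        Sampling frequency in Hz.
    units
        Either ``"raw"`` (uncalibrated sensor units) or ``"g"``.
    labels
        Optional per-sample posture labels (array of str), e.g. from a
        training recording or the synthetic generator.
    """

    t: np.ndarray
    a: np.ndarray
    fs: float
    units: str = "g"
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.units not in ("raw", "g"):
            raise ValidationError(f"units must be 'raw' or 'g', got {self.units!r}")
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValidationError(f"acceleration array must be (N, 3), got {self.a.shape}")
        if self.t.shape[0] != self.a.shape[0]:
            raise ValidationError("timestamp and acceleration lengths differ")
        if self.t.size and self.t[0] < 0:
            raise ValidationError("timestamps must be non-negative")
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            row = int(bad[0]) + 1
            raise ValidationError(
                f"timestamps not strictly increasing: row {row} "
                f"(t={self.t[row]:g} after t={self.t[row - 1]:g})"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != self.t.shape[0]:
                raise ValidationError("label array length differs from stream length")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    def __getitem__(self, i: int) -> AccelSample:
        return AccelSample(float(self.t[i]), *map(float, self.a[i]))

    def __iter__(self) -> Iterator[AccelSample]:
        for i in range(len(self)):
            yield self[i]

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    def with_values(self, a: np.ndarray, **changes) -> "AccelStream":
        """Copy of the stream with replaced acceleration values."""
        return replace(self, a=np.asarray(a, float), **changes)


def read_stream(path, fs: float, units: str = "g") -> AccelStream:
    """Read an acceleration stream from CSV.

    The file must carry the header ``timestamp_s,ax,ay,az``; an optional
    ``label`` column is attached as per-sample labels. Row order is
    preserved and validated (strictly increasing timestamps).
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    try:
        t = df["timestamp_s"].to_numpy(dtype=float)
        a = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric acceleration data: {exc}") from exc
    labels = df["label"].to_numpy(dtype=object) if "label" in df.columns else None
    return AccelStream(t=t, a=a, fs=fs, units=units, labels=labels)


def write_stream(stream: AccelStream, path) -> None:
    """Write a stream in the CSV dialect readable by :func:`read_stream`."""
    df = pd.DataFrame(
        {
            "timestamp_s": stream.t,
            "ax": stream.a[:, 0],
            "ay": stream.a[:, 1],
            "az": stream.a[:, 2],
        }
    )
    if stream.labels is not None:
        df["label"] = stream.labels
    df.to_csv(path, index=False, float_format="%.12g")


def raw_to_g(
    stream: AccelStream, params: SensorCalibrationParams | None = None
) -> AccelStream:
    """Convert raw sensor units to g via the per-axis affine model.

    value_g = (raw - offset) / sensitivity, then saturated to the ±2 g
    sensor range (clipped, not rejected; the clip count is logged).
    """
    if stream.units != "raw":
        raise ValidationError("raw_to_g expects a stream with units='raw'")
    params = params or SensorCalibrationParams()
    g = (stream.a - params.offset) / params.sensitivity
    n_clipped = int(np.count_nonzero(np.abs(g) > ACCEL_RANGE_G))
    if n_clipped:
        logger.info("raw_to_g: clipped %d out-of-range axis values to ±%g g",
                    n_clipped, ACCEL_RANGE_G)
    g = np.clip(g, -ACCEL_RANGE_G, ACCEL_RANGE_G)
    return stream.with_values(g, units="g")
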