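"""Sliding-window segmentation and per-axis time-domain features.

A classification is produced for every 350 ms window advanced in 50 ms
steps. Thirteen time-domain feature families are computed per axis
(39 columns in the full layout):

======  =====================================================================
MAV     mean absolute value, Σ|a_i|/N
STD     population standard deviation, √VAR
VAR     population variance, Σ(a_i−μ)²/N
MAX     window maximum
MIN     window minimum
RMS     root mean square, √(Σa_i²/N)
SSI     simple squared integral, Σa_i²
WENT    Shannon entropy of the normalized energy distribution
        p_i = a_i²/Σa_j², −Σ p_i ln p_i (0·ln 0 := 0)
SKEW    standardized third moment m₃/σ³ (0 when σ ≈ 0)
KURT    standardized fourth moment m₄/σ⁴ (0 when σ ≈ 0)
DAC     dynamic acceleration change, max − min of the filtered signal
SAC     static acceleration change, max − min of the very-low-passed
        (gravity-tracking) component
LEE     log energy entropy, Σ log₂(a_i² + ε), ε = 1e−12
======  =====================================================================

The entropy definitions operate on squared (energy) values because raw
chest accelerations are signed; a plain a·ln(a) form would be undefined.

L1-penalized multinomial logistic regression on standardized columns
serves as the supervised Lasso feature selector; coefficients are
aggregated per family (max |coef| over classes and axes) and families with
non-zero aggregate weight survive. The pipeline's default selected layout
is the six-family set {MAV, VAR, SKEW, KURT, DAC, SAC}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, DegenerateLabelsError, InsufficientDataError, ValidationError
from .preprocessing import AXIS_NAMES, CalibrationProfile, FilterSpec, lowpass_filter
from .signal_io import AccelStream

FEATURE_FAMILIES = (
    "MAV", "STD", "VAR", "MAX", "MIN", "RMS", "SSI",
    "WENT", "SKEW", "KURT", "DAC", "SAC", "LEE",
)

#: Default six-family selection used by the pipeline's "selected" layout.
SELECTED_FAMILIES = ("MAV", "VAR", "SKEW", "KURT", "DAC", "SAC")

_SIGMA_EPS = 1e-12
_LEE_EPS = 1e-12

#: Default cutoff (Hz) of the gravity-tracking low-pass behind SAC.
DEFAULT_STATIC_CUTOFF_HZ = 0.5
#: Order of the gravity-tracking low-pass (gentle, drift-following).
STATIC_FILTER_ORDER = 2


def feature_columns(families=FEATURE_FAMILIES) -> list[str]:
    """Documented column order: families in table order, axes x, y, z within."""
    return [f"{fam}_{ax}" for fam in families for ax in AXIS_NAMES]


@dataclass
class WindowSpec:
    """Sliding-window geometry in milliseconds.

    Sample counts are derived with a ceiling rule so every window covers at
    least the nominal duration (350 ms at 50 Hz → 18 samples, step 3).
    """

    window_ms: float = 350.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ConfigurationError("window_ms and step_ms must be positive")

    def window_samples(self, fs: float) -> int:
        n = ceil(self.window_ms * fs / 1000.0)
        if n < 2:
            raise ConfigurationError(
                f"window of {self.window_ms} ms at {fs:g} Hz spans {n} sample(s); "
                "need at least 2"
            )
        return n

    def step_samples(self, fs: float) -> int:
        s = ceil(self.step_ms * fs / 1000.0)
        return min(max(s, 1), self.window_samples(fs))


def make_windows(stream: AccelStream, spec: WindowSpec | None = None) -> list[tuple[int, int]]:
    """Window index ranges [k·step, k·step + window) fully inside the stream.

    Returns an empty list (with a warning) when the stream is shorter than
    one window; count = floor((N − window)/step) + 1 otherwise.
    """
    spec = spec or WindowSpec()
    w = spec.window_samples(stream.fs)
    s = spec.step_samples(stream.fs)
    n = len(stream)
    if n < w:
        warnings.warn(
            f"stream of {n} samples is shorter than one {w}-sample window; "
            "no windows produced",
            stacklevel=2,
        )
        return []
    count = (n - w) // s + 1
    return [(k * s, k * s + w) for k in range(count)]


def _family_block(a: np.ndarray, static: np.ndarray) -> np.ndarray:
    """All 13 features for one axis, vectorized over windows.

    ``a``: (n_windows, w) filtered (dynamic-bearing) signal;
    ``static``: (n_windows, w) gravity-tracking component. Returns (n, 13)
    in :data:`FEATURE_FAMILIES` order.
    """
    n, w = a.shape
    mu = a.mean(axis=1)
    dev = a - mu[:, None]
    var = np.mean(dev**2, axis=1)
    std = np.sqrt(var)
    mx = a.max(axis=1)
    mn = a.min(axis=1)
    a2 = a**2
    ssi = a2.sum(axis=1)
    rms = np.sqrt(ssi / w)
    mav = np.abs(a).mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        p = a2 / ssi[:, None]
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        went = -plogp.sum(axis=1)
    went = np.where(ssi > 0, went, 0.0)

    ok = std > _SIGMA_EPS
    safe_std = np.where(ok, std, 1.0)
    m3 = np.mean(dev**3, axis=1)
    m4 = np.mean(dev**4, axis=1)
    skew = np.where(ok, m3 / safe_std**3, 0.0)
    kurt = np.where(ok, m4 / safe_std**4, 0.0)

    dac = mx - mn
    sac = static.max(axis=1) - static.min(axis=1)
    lee = np.log2(a2 + _LEE_EPS).sum(axis=1)

    return np.column_stack(
        [mav, std, var, mx, mn, rms, ssi, went, skew, kurt, dac, sac, lee]
    )


@dataclass
class FeatureVector:
    """Features of one window, keyed by (family, axis)."""

    values: dict[tuple[str, str], float]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def as_array(self, families=FEATURE_FAMILIES) -> np.ndarray:
        return np.array(
            [self.values[(fam, ax)] for fam in families for ax in AXIS_NAMES]
        )


def extract_features(window: np.ndarray, static_component: np.ndarray) -> FeatureVector:
    """Feature vector of a single (w, 3) window.

    ``static_component`` is the matching slice of the gravity-tracking
    low-passed stream (same shape), consumed only by the SAC family.
    """
    window = np.atleast_2d(np.asarray(window, float))
    static_component = np.atleast_2d(np.asarray(static_component, float))
    if window.shape[0] < 2:
        raise InsufficientDataError(
            f"window of {window.shape[0]} sample(s) is too short; need >= 2"
        )
    if window.shape != static_component.shape:
        raise ValidationError("window and static_component shapes differ")
    values: dict[tuple[str, str], float] = {}
    for ax_i, ax in enumerate(AXIS_NAMES):
        block = _family_block(window[None, :, ax_i], static_component[None, :, ax_i])
        for fam_i, fam in enumerate(FEATURE_FAMILIES):
            values[(fam, ax)] = float(block[0, fam_i])
    return FeatureVector(values=values)


def compute_static_component(
    stream: AccelStream, static_cutoff_hz: float = DEFAULT_STATIC_CUTOFF_HZ
) -> AccelStream:
    """Gravity-tracking component: gentle low-pass well below posture dynamics."""
    return lowpass_filter(
        stream,
        FilterSpec(order=STATIC_FILTER_ORDER, cutoff_hz=static_cutoff_hz,
                   mode="zero_phase_batch"),
    )


def _majority(codes: np.ndarray, windows: list[tuple[int, int]], names: np.ndarray) -> np.ndarray:
    """Per-window majority vote over per-sample codes; ties → the candidate
    appearing earliest within the window."""
    n_codes = len(names)
    starts = np.array([w[0] for w in windows])
    width = windows[0][1] - windows[0][0]
    view = sliding_window_view(codes, width)[starts]  # (n_windows, width)
    counts = np.stack([(view == c).sum(axis=1) for c in range(n_codes)], axis=1)
    best = counts.max(axis=1)
    winners = counts == best[:, None]
    out_codes = counts.argmax(axis=1)
    tie_rows = np.flatnonzero(winners.sum(axis=1) > 1)
    for r in tie_rows:
        cands = set(np.flatnonzero(winners[r]))
        for c in view[r]:
            if c in cands:
                out_codes[r] = c
                break
    return names[out_codes]


@dataclass
class FeatureMatrix:
    """Windows × features table with optional labels and CV group ids.

    ``data`` columns: ``t_start``, the feature columns in documented order,
    then optional ``label``, ``subject`` and ``group``.
    """

    data: pd.DataFrame
    families: tuple[str, ...] = FEATURE_FAMILIES

    @property
    def feature_names(self) -> list[str]:
        return feature_columns(self.families)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray | None:
        return self.data["label"].to_numpy() if "label" in self.data.columns else None

    @property
    def groups(self) -> np.ndarray | None:
        return self.data["group"].to_numpy() if "group" in self.data.columns else None

    @property
    def t_start(self) -> np.ndarray:
        return self.data["t_start"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def select(self, families=SELECTED_FAMILIES) -> "FeatureMatrix":
        """Restrict to a family subset, preserving documented column order."""
        fams = tuple(f for f in self.families if f in set(families))
        missing = set(families) - set(fams)
        if missing:
            raise ValidationError(f"families not present in matrix: {sorted(missing)}")
        keep = ["t_start"] + feature_columns(fams)
        keep += [c for c in ("label", "subject", "group") if c in self.data.columns]
        return FeatureMatrix(data=self.data[keep].copy(), families=fams)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        fams = tuple(
            dict.fromkeys(
                c.rsplit("_", 1)[0]
                for c in df.columns
                if c.rsplit("_", 1)[0] in FEATURE_FAMILIES
            )
        )
        return cls(data=df, families=fams)

    @classmethod
    def concat(cls, matrices: list["FeatureMatrix"]) -> "FeatureMatrix":
        fams = matrices[0].families
        if any(m.families != fams for m in matrices):
            raise ValidationError("cannot concatenate matrices with different layouts")
        return cls(
            data=pd.concat([m.data for m in matrices], ignore_index=True),
            families=fams,
        )


def build_feature_matrix(
    stream: AccelStream,
    profile: CalibrationProfile | None = None,
    window_spec: WindowSpec | None = None,
    layout: str = "full",
    static_cutoff_hz: float = DEFAULT_STATIC_CUTOFF_HZ,
    group_ids: np.ndarray | None = None,
    subject_id: str | int | None = None,
) -> FeatureMatrix:
    """One feature row per sliding window of a calibrated, filtered stream.

    A window's label (when per-sample labels are present) is the majority
    label of its samples, ties broken toward the label occurring earliest in
    the window; ``group_ids`` (per-sample, e.g. recording-segment indices)
    are condensed the same way into a per-window ``group`` column.
    """
    if stream.units != "g":
        raise ValidationError("feature extraction requires a stream in g units")
    if layout not in ("full", "selected"):
        raise ConfigurationError(f"layout must be 'full' or 'selected', got {layout!r}")
    window_spec = window_spec or WindowSpec()
    windows = make_windows(stream, window_spec)
    families = FEATURE_FAMILIES if layout == "full" else SELECTED_FAMILIES
    cols = feature_columns(FEATURE_FAMILIES)
    if not windows:
        df = pd.DataFrame(columns=["t_start", *cols])
        return FeatureMatrix(data=df, families=FEATURE_FAMILIES).select(families)

    static = compute_static_component(stream, static_cutoff_hz)
    width = windows[0][1] - windows[0][0]
    starts = np.array([w[0] for w in windows])

    blocks = []
    for ax in range(3):
        dyn_view = sliding_window_view(stream.a[:, ax], width)[starts]
        sta_view = sliding_window_view(static.a[:, ax], width)[starts]
        blocks.append(_family_block(dyn_view, sta_view))
    # interleave to documented order: family-major, axis-minor
    stacked = np.stack(blocks, axis=2)  # (n, 13, 3)
    values = stacked.reshape(len(windows), -1)

    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "t_start", stream.t[starts])
    if stream.labels is not None:
        codes, names = pd.factorize(pd.Series(stream.labels))
        df["label"] = _majority(codes, windows, np.asarray(names, dtype=object))
    if subject_id is not None:
        df["subject"] = subject_id
    if group_ids is not None:
        codes, names = pd.factorize(pd.Series(group_ids))
        df["group"] = _majority(codes, windows, np.asarray(names))
    matrix = FeatureMatrix(data=df, families=FEATURE_FAMILIES)
    return matrix.select(families) if layout == "selected" else matrix


@dataclass
class SelectionResult:
    """Outcome of the supervised Lasso family selection."""

    selected_families: tuple[str, ...]
    weights: dict[str, float] = field(default_factory=dict)
    penalty: float = 0.0


def lasso_select(
    matrix: FeatureMatrix,
    labels: np.ndarray | None = None,
    penalty: float = 0.1,
    seed: int = 0,
    max_rows: int | None = 5000,
) -> SelectionResult:
    """Prune feature families with an L1-penalized multinomial linear model.

    Columns are standardized internally; ``penalty`` is the L1 strength
    (the model is fit with C = 1/penalty). A family's aggregate weight is
    the maximum |coefficient| over classes and axes; families above 1e-8
    survive. Deterministic given ``seed``; large matrices are subsampled to
    ``max_rows`` rows (seeded) for tractability.
    """
    if penalty <= 0:
        raise ConfigurationError("penalty must be positive")
    y = labels if labels is not None else matrix.labels
    if y is None:
        raise ValidationError("lasso_select requires labels")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("feature selection needs at least two classes")
    X = matrix.X
    if max_rows is not None and len(X) > max_rows:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(X), size=max_rows, replace=False)
        X, y = X[idx], y[idx]
    Xs = StandardScaler().fit_transform(X)
    clf = LogisticRegression(
        penalty="l1", C=1.0 / penalty, solver="saga", max_iter=5000,
        tol=1e-4, random_state=seed,
    )
    clf.fit(Xs, y)
    coefs = np.abs(clf.coef_)  # (n_classes, n_features)
    names = matrix.feature_names
    weights: dict[str, float] = {fam: 0.0 for fam in matrix.families}
    for j, name in enumerate(names):
        fam = name.rsplit("_", 1)[0]
        weights[fam] = max(weights[fam], float(coefs[:, j].max()))
    selected = tuple(f for f in matrix.families if weights[f] > 1e-8)
    if not selected:
        # keep the single strongest family rather than returning nothing
        strongest = max(weights, key=weights.get)
        selected = (strongest,)
    return SelectionResult(selected_families=selected, weights=weights, penalty=penalty)
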