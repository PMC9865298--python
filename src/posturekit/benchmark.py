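"""Per-window inference latency and process resource probing.

A window classification is "real time" when its mean latency stays below
the sensor sampling period (20 ms at 50 Hz): the pipeline then keeps up
with the incoming stream. Absolute times are hardware-bound; only
machine-relative statements (orderings, the real-time boolean) are
meaningful across runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .features import WindowSpec, compute_static_component, make_windows
from .models import TrainedModel
from .preprocessing import CalibrationProfile
from .signal_io import AccelStream

try:  # optional; a /proc fallback covers its absence
    import psutil
except ImportError:  # pragma: no cover
    psutil = None


@dataclass
class BenchmarkReport:
    """Latency statistics of the full per-window path for one model."""

    model_kind: str
    mean_latency_s: float
    median_latency_s: float
    p95_latency_s: float
    repetitions: int
    n_windows: int
    sampling_period_s: float
    real_time_ok: bool
    cpu_percent: float | None = None
    ram_percent: float | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "BenchmarkReport":
        return cls(**json.loads(Path(path).read_text()))


def time_inference(
    model: TrainedModel,
    stream: AccelStream,
    profile: CalibrationProfile | None = None,
    window_spec: WindowSpec | None = None,
    repetitions: int = 10,
) -> BenchmarkReport:
    """Measure the per-window feature-extraction + prediction path.

    The stream is filtered/static-decomposed once (as a deployed system
    would, causally, ahead of windowing); each repetition then walks every
    window, timing feature computation and single-row prediction, and the
    latency statistics are averaged over repetitions.
    """
    if model is None or getattr(model, "estimator", None) is None:
        raise ValidationError("time_inference requires a trained model")
    window_spec = window_spec or WindowSpec()
    windows = make_windows(stream, window_spec)
    if not windows:
        raise ValidationError("stream too short to benchmark: no windows")
    static = compute_static_component(stream)

    # resolve schema column -> (family, axis index) once, outside the timer
    from .features import FEATURE_FAMILIES, _family_block
    from .preprocessing import AXIS_NAMES

    fam_index = {f: i for i, f in enumerate(FEATURE_FAMILIES)}
    ax_index = {a: i for i, a in enumerate(AXIS_NAMES)}
    plan = []
    for col in model.schema:
        fam, ax = col.rsplit("_", 1)
        plan.append((fam_index[fam], ax_index[ax]))

    latencies = []
    for _ in range(repetitions):
        for start, stop in windows:
            t0 = time.perf_counter()
            blocks = [
                _family_block(
                    stream.a[start:stop, ax][None, :], static.a[start:stop, ax][None, :]
                )
                for ax in range(3)
            ]
            row = np.array([[blocks[ax][0, fi] for fi, ax in plan]])
            model.estimator.predict(row)
            latencies.append(time.perf_counter() - t0)
    lat = np.asarray(latencies)
    period = 1.0 / stream.fs
    mean = float(lat.mean())
    return BenchmarkReport(
        model_kind=model.config.kind,
        mean_latency_s=mean,
        median_latency_s=float(np.median(lat)),
        p95_latency_s=float(np.percentile(lat, 95)),
        repetitions=repetitions,
        n_windows=len(windows),
        sampling_period_s=period,
        real_time_ok=bool(mean < period),
    )


@dataclass
class ResourceSample:
    """Process CPU and system RAM utilization, or unavailable markers."""

    cpu_percent: float | None
    ram_percent: float | None

    @property
    def available(self) -> bool:
        return self.cpu_percent is not None and self.ram_percent is not None


def _proc_fallback(duration_s: float) -> ResourceSample:
    """CPU% of this process from /proc deltas; RAM% from /proc/meminfo."""
    try:
        def cpu_ticks() -> float:
            parts = Path("/proc/self/stat").read_text().rsplit(")", 1)[1].split()
            return float(parts[11]) + float(parts[12])  # utime + stime

        t0, c0 = time.monotonic(), cpu_ticks()
        time.sleep(max(duration_s, 0.01))
        elapsed = time.monotonic() - t0
        ticks = cpu_ticks() - c0
        hz = 100.0  # USER_HZ on linux
        cpu = 100.0 * (ticks / hz) / elapsed

        meminfo = {}
        for line in Path("/proc/meminfo").read_text().splitlines():
            key, _, rest = line.partition(":")
            meminfo[key] = float(rest.split()[0])
        ram = 100.0 * (1.0 - meminfo["MemAvailable"] / meminfo["MemTotal"])
        return ResourceSample(
            cpu_percent=float(np.clip(cpu, 0, 100)),
            ram_percent=float(np.clip(ram, 0, 100)),
        )
    except (OSError, KeyError, IndexError, ValueError):
        return ResourceSample(cpu_percent=None, ram_percent=None)


def sample_resources(duration_s: float = 1.0) -> ResourceSample:
    """Sample process CPU load and memory utilization over ``duration_s``.

    Uses psutil when importable, a /proc probe otherwise; on platforms with
    neither, returns unavailable markers instead of failing.
    """
    if psutil is not None:
        try:
            proc = psutil.Process()
            cpu = proc.cpu_percent(interval=max(duration_s, 0.01))
            ram = psutil.virtual_memory().percent
            return ResourceSample(
                cpu_percent=float(np.clip(cpu, 0, 100)),
                ram_percent=float(np.clip(ram, 0, 100)),
            )
        except Exception:  # pragma: no cover - platform-specific
            pass
    return _proc_fallback(duration_s)
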