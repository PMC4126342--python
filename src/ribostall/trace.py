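"""Constant-force extension trace container and plain-text I/O.

A trace is a uniformly sampled extension-vs-time record taken at one constant
force, with a marker separating the pre-elongation baseline (used for noise
calibration) from the translation recording.

File dialect: UTF-8 TSV with a '#'-prefixed ``key=value`` header.  Required
keys: ``sample_rate_hz``, ``force_pN``, ``baseline_end_s``.  Optional:
``temperature_k`` plus arbitrary metadata keys, preserved on round trip.
Two data columns, ``time_s`` and ``extension_nm``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trace", "read_trace", "write_trace", "TraceFormatError"]

_REQUIRED_KEYS = ("sample_rate_hz", "force_pN", "baseline_end_s")


class TraceFormatError(ValueError):
    """Raised when a trace file is missing header keys or malformed."""


@dataclass
class Trace:
    """Uniformly sampled extension-vs-time record at one constant force."""

    times: np.ndarray
    extension: np.ndarray
    force: float
    baseline_end: float
    temperature: float = 296.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.extension.shape:
            raise ValueError("times and extension must be 1-D and equal length")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least two samples")
        if self.force <= 0:
            raise ValueError("force must be positive")
        dts = np.diff(self.times)
        dt = dts[0]
        if dt <= 0 or not np.allclose(dts, dt, rtol=1e-6, atol=1e-9 * dt):
            raise ValueError("trace sampling must be uniform")
        if not (0.0 <= self.baseline_end <= self.times[-1]):
            raise ValueError("baseline_end must lie within the recorded times")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def n_samples(self) -> int:
        return len(self.times)


def write_trace(trace: Trace, path) -> None:
    """Write a trace in the TSV dialect; lossless float round trip."""
    path = Path(path)
    lines = [
        f"# sample_rate_hz={trace.sample_rate:.17g}",
        f"# force_pN={trace.force:.17g}",
        f"# baseline_end_s={trace.baseline_end:.17g}",
        f"# temperature_k={trace.temperature:.17g}",
    ]
    for key, value in trace.meta.items():
        if key in _REQUIRED_KEYS or key == "temperature_k":
            continue
        lines.append(f"# {key}={value}")
    lines.append("time_s\textension_nm")
    buf = io.StringIO()
    buf.write("\n".join(lines) + "\n")
    np.savetxt(buf, np.column_stack([trace.times, trace.extension]),
               fmt="%.17g", delimiter="\t")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_trace(path) -> Trace:
    """Read a trace from the TSV dialect written by :func:`write_trace`."""
    path = Path(path)
    header: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
    for key in _REQUIRED_KEYS:
        if key not in header:
            raise TraceFormatError(f"trace file {path} missing header key {key!r}")
    frame = pd.read_csv(path, sep="\t", comment="#",
                        float_precision="round_trip")
    if list(frame.columns) != ["time_s", "extension_nm"]:
        raise TraceFormatError(
            f"trace file {path} must have columns time_s, extension_nm")
    def _coerce(value: str):
        for cast in (int, float):
            try:
                return cast(value)
            except ValueError:
                continue
        return value

    meta = {k: _coerce(v) for k, v in header.items()
            if k not in _REQUIRED_KEYS and k != "temperature_k"}
    try:
        return Trace(
            times=frame["time_s"].to_numpy(),
            extension=frame["extension_nm"].to_numpy(),
            force=float(header["force_pN"]),
            baseline_end=float(header["baseline_end_s"]),
            temperature=float(header.get("temperature_k", 296.0)),
            meta=meta,
        )
    except ValueError as exc:
        raise TraceFormatError(f"trace file {path}: {exc}") from exc
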