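"""Trace processing: smoothing, instantaneous velocity, noise calibration,
pause/burst segmentation and per-trace summaries.

The chain mirrors standard constant-force optical-tweezers practice:

1. Savitzky-Golay smoothing of the raw 1 kHz extension over a ~4000-sample
   span (order 2 by default).
2. Instantaneous velocity from the SG first-derivative coefficients over the
   same span (equivalent to differentiating the local polynomial fit),
   converted to codons/s through the WLC model at the trace force.  Sign
   convention: extension decrease (translation) is positive velocity.
3. sigma_pause = standard deviation of the velocity over the pre-elongation
   baseline; samples with |v| < 2.5*sigma_pause are pauses, the rest bursts.
4. Contiguous runs become segments; segments shorter than a minimum duration
   are merged into their longer neighbour; boundary segments are flagged
   censored and excluded from dwell-time statistics.

Velocities within half a smoothing span of either trace end are dropped
(recorded as trimmed), not extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, savgol_coeffs

from .polymer import PolymerModel
from .trace import Trace

__all__ = [
    "VelocitySeries",
    "NoiseEstimate",
    "Segment",
    "TraceResult",
    "smooth",
    "instantaneous_velocity",
    "estimate_sigma_pause",
    "segment",
    "summarize_trace",
    "analyze_trace",
]


def _odd_span(span: int) -> int:
    """SG windows must be odd; an even requested span is widened by one."""
    span = int(span)
    return span + 1 if span % 2 == 0 else span


def _sg_apply(x: np.ndarray, span: int, polyorder: int, deriv: int,
              delta: float) -> np.ndarray:
    """Apply an SG kernel by FFT convolution; edges (half span) set to NaN."""
    span = _odd_span(span)
    if span > len(x):
        raise ValueError(
            f"SG span {span} exceeds series length {len(x)}; shorten the span")
    if polyorder >= span:
        raise ValueError("polyorder must be smaller than the span")
    coeffs = savgol_coeffs(span, polyorder, deriv=deriv, delta=delta)
    out = fftconvolve(x, coeffs, mode="same")
    half = span // 2
    out[:half] = np.nan
    if half > 0:
        out[-half:] = np.nan
    return out


def smooth(trace: Trace, span: int = 4000, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothed extension; NaN within half a span of the ends.

    Reproduces polynomials of degree <= ``polyorder`` exactly in the interior.
    """
    return _sg_apply(trace.extension, span, polyorder, deriv=0, delta=trace.dt)


@dataclass
class VelocitySeries:
    """Instantaneous velocity in codons/s, positive along translation."""

    times: np.ndarray
    velocity: np.ndarray
    half_span: int        # samples trimmed from each end of the source trace
    span: int
    force: float

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def instantaneous_velocity(trace: Trace, model: PolymerModel,
                           span: int = 4000,
                           polyorder: int = 2) -> VelocitySeries:
    """Velocity from SG first-derivative coefficients over ``span`` samples.

    velocity = -(d extension/dt) / (WLC extension per codon at the trace
    force), in codons/s.  Edge samples within half a span are trimmed.
    """
    span = _odd_span(span)
    if span < 2:
        raise ValueError("derivative span must cover at least 2 samples")
    dxdt = _sg_apply(trace.extension, span, polyorder, deriv=1, delta=trace.dt)
    codon_ext = model.extension_per_codon(trace.force)
    vel = -dxdt / codon_ext
    half = span // 2
    sl = slice(half, len(vel) - half)
    return VelocitySeries(times=trace.times[sl], velocity=vel[sl],
                          half_span=half, span=span, force=trace.force)


@dataclass
class NoiseEstimate:
    """Velocity noise scale from the pre-elongation baseline."""

    sigma_pause: float    # codons/s
    n_samples: int


def estimate_sigma_pause(vel: VelocitySeries, trace: Trace) -> NoiseEstimate:
    """Standard deviation of baseline velocity samples.

    Only samples whose full smoothing window lies inside the baseline
    (t <= baseline_end minus half a span) are used, so no window overlaps
    elongation data.
    """
    guard = vel.half_span * vel.dt
    mask = vel.times <= trace.baseline_end - guard
    n = int(mask.sum())
    if n < 2:
        raise ValueError(
            "baseline too short to estimate sigma_pause (needs at least the "
            "smoothing span); supply a noise estimate externally")
    sigma = float(np.std(vel.velocity[mask], ddof=1))
    if sigma <= 1e-9:  # numerically zero: noiseless baseline
        raise ValueError(
            "baseline velocity has zero variance; the pause threshold is "
            "degenerate -- supply a noise estimate externally")
    return NoiseEstimate(sigma_pause=sigma, n_samples=n)


@dataclass
class Segment:
    """A maximal pause or burst interval of a trace."""

    label: str            # "pause" or "burst"
    start: float          # s
    end: float            # s
    distance: float       # codons (smoothed extension drop / codon extension)
    mean_velocity: float  # codons/s
    censored: bool        # touches the analyzed-region boundary

    @property
    def duration(self) -> float:
        return self.end - self.start


def _merge_short_runs(runs: list[list], dt: float,
                      min_samples: int) -> list[list]:
    """Merge runs shorter than ``min_samples`` into their longer neighbour.

    ``runs`` is a list of [label, i0, i1) triples over contiguous samples.
    Shortest offender first; ties go to the leftmost.  After relabelling,
    adjacent equal-label runs coalesce, so labels alternate on return.
    """
    runs = [list(r) for r in runs]

    def _coalesce(rs):
        out = [rs[0]]
        for r in rs[1:]:
            if r[0] == out[-1][0]:
                out[-1][2] = r[2]
            else:
                out.append(r)
        return out

    runs = _coalesce(runs)
    while len(runs) > 1:
        lengths = [r[2] - r[1] for r in runs]
        short = [i for i, ln in enumerate(lengths) if ln < min_samples]
        if not short:
            break
        i = min(short, key=lambda j: lengths[j])
        if i == 0:
            neighbour = 1
        elif i == len(runs) - 1:
            neighbour = i - 1
        else:
            # merge into the longer neighbour; tie goes to the right
            neighbour = i + 1 if lengths[i + 1] >= lengths[i - 1] else i - 1
        runs[i][0] = runs[neighbour][0]
        runs = _coalesce(runs)
    return runs


def segment(vel: VelocitySeries, noise: NoiseEstimate, smoothed: np.ndarray,
            trace: Trace, model: PolymerModel, multiplier: float = 2.5,
            min_segment: float = 0.5) -> list[Segment]:
    """Threshold the post-baseline velocity into pause/burst segments.

    Samples with |v| < multiplier*sigma_pause are pauses.  Segments partition
    (baseline_end, end of analyzed region]; each segment's distance is the
    smoothed-extension drop across it in codons, so distances telescope to
    the end-to-end distance exactly.
    """
    if noise.sigma_pause <= 0:
        raise ValueError("sigma_pause must be positive")
    region = vel.times > trace.baseline_end
    if not region.any():
        raise ValueError("no post-baseline samples to segment")
    idx = np.nonzero(region)[0]
    i_lo, i_hi = int(idx[0]), int(idx[-1]) + 1   # vel-index space, i_hi exclusive
    v = vel.velocity[i_lo:i_hi]
    pause_mask = np.abs(v) < multiplier * noise.sigma_pause

    # contiguous runs of equal label
    change = np.nonzero(np.diff(pause_mask))[0] + 1
    bounds = np.concatenate(([0], change, [len(v)]))
    runs = [["pause" if pause_mask[b0] else "burst", int(b0), int(b1)]
            for b0, b1 in zip(bounds[:-1], bounds[1:])]

    dt = vel.dt
    min_samples = max(1, int(round(min_segment / dt)))
    runs = _merge_short_runs(runs, dt, min_samples)

    codon_ext = model.extension_per_codon(trace.force)
    offset = vel.half_span + i_lo          # vel index -> trace sample index
    n_region = i_hi - i_lo

    # segment boundaries are shared samples: run k spans [b_k, b_{k+1}]
    # (closed), the final boundary being the last analyzed sample, so each
    # segment's distance and duration cover exactly the same samples and
    # distances telescope to the end-to-end drop.
    def _x(vel_region_index: int) -> float:
        return float(smoothed[offset + vel_region_index])

    t0 = vel.times[i_lo]
    segments: list[Segment] = []
    for k, (label, b0, b1) in enumerate(runs):
        b1_eff = min(b1, n_region - 1)
        start = t0 + b0 * dt
        end = t0 + b1_eff * dt
        dist = (_x(b0) - _x(b1_eff)) / codon_ext
        duration = end - start
        if duration <= 0:       # degenerate single-sample tail
            continue
        segments.append(Segment(
            label=label, start=start, end=end, distance=dist,
            mean_velocity=dist / duration,
            censored=(k == 0 or k == len(runs) - 1),
        ))
    return segments


@dataclass
class TraceResult:
    """Per-trace summary of the segmented recording."""

    force: float
    pause_free_velocity: float | None   # codons/s; None if no bursts
    total_distance: float               # codons, over burst segments
    burst_durations: list[float] = field(default_factory=list)  # non-censored
    pause_durations: list[float] = field(default_factory=list)  # non-censored
    n_segments: int = 0

    @property
    def velocity_defined(self) -> bool:
        return self.pause_free_velocity is not None

    def to_dict(self) -> dict:
        return {
            "force_pN": self.force,
            "pause_free_velocity_codons_s": self.pause_free_velocity,
            "total_distance_codons": self.total_distance,
            "burst_durations_s": list(self.burst_durations),
            "pause_durations_s": list(self.pause_durations),
            "n_segments": self.n_segments,
        }


def summarize_trace(trace: Trace, segments: list[Segment]) -> TraceResult:
    """Pause-free velocity and dwell-time lists from a segmented trace.

    pause_free_velocity = (sum of burst distances) / (sum of burst
    durations); dwell-time lists exclude censored (boundary) segments.
    """
    bursts = [s for s in segments if s.label == "burst"]
    total_dist = float(sum(s.distance for s in bursts))
    total_time = float(sum(s.duration for s in bursts))
    velocity = total_dist / total_time if total_time > 0 else None
    return TraceResult(
        force=trace.force,
        pause_free_velocity=velocity,
        total_distance=total_dist,
        burst_durations=[s.duration for s in bursts if not s.censored],
        pause_durations=[s.duration for s in segments
                         if s.label == "pause" and not s.censored],
        n_segments=len(segments),
    )


def analyze_trace(trace: Trace, model: PolymerModel, span: int = 4000,
                  polyorder: int = 2, multiplier: float = 2.5,
                  min_segment: float = 0.5,
                  sigma_override: float | None = None,
                  ) -> tuple[TraceResult, list[Segment]]:
    """Full per-trace chain: smooth, velocity, sigma, segment, summarize.

    ``sigma_override`` (codons/s) replaces the baseline noise estimate; use
    it for traces without a usable baseline or in noise-free validation.
    """
    smoothed = smooth(trace, span=span, polyorder=polyorder)
    vel = instantaneous_velocity(trace, model, span=span, polyorder=polyorder)
    if sigma_override is not None:
        if sigma_override <= 0:
            raise ValueError("sigma_override must be positive")
        noise = NoiseEstimate(sigma_pause=float(sigma_override), n_samples=0)
    else:
        noise = estimate_sigma_pause(vel, trace)
    segments = segment(vel, noise, smoothed, trace, model,
                       multiplier=multiplier, min_segment=min_segment)
    return summarize_trace(trace, segments), segments
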