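"""Stochastic generator of constant-force translation traces.

The ribosome is modelled as a two-state motor.  While TRANSLATING it takes
instantaneous one-codon (3-nt) steps as a Poisson process whose rate follows
the Arrhenius force-velocity law

    v(F) = v0 * exp(-F * x_tilde / kBT),

and it enters an off-pathway PAUSED state at rate ``k_pause_in``.  While
paused it takes no steps and returns to translation at rate ``k_pause_out``;
both pause rates are force independent.  Each step shortens the tether by the
WLC extension of one codon at the applied force.  The event sequence is drawn
exactly (Gillespie-style, no time discretisation); the recorded trace is the
sample-and-hold staircase at the instrument sampling rate plus stationary
Ornstein-Uhlenbeck noise emulating low-pass bead/trap fluctuations.

A :class:`GroundTruth` record of every step time and pause interval
accompanies each trace so downstream analysis can be validated against the
generating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .polymer import PolymerModel
from .trace import Trace

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "true_velocity",
    "simulate_trace",
    "simulate_experiment",
]


@dataclass(frozen=True)
class SimulationParams:
    """Kinetic, polymer and noise parameters of the trace generator.

    Defaults mirror the fitted kinetics of the study conditions this package
    emulates: v0 = 2.9 codons/s, x_tilde = 1.4 nm, pause entry 0.16 1/s,
    pause exit 0.14 1/s, a 62-codon message, 1 kHz sampling, 2 nm OU noise
    with a 50 Hz corner.
    """

    v0: float = 2.9                  # codons/s at zero force
    x_tilde: float = 1.4             # nm, characteristic distance
    k_pause_in: float = 0.16         # 1/s, pause entry while translating
    k_pause_out: float = 0.14        # 1/s, pause exit
    mrna_codons: int = 62            # codons available on the template
    sample_rate: float = 1000.0      # Hz
    baseline_duration: float = 30.0  # s of pre-elongation recording
    max_duration: float = 360.0      # s, total trace cap
    noise_sd: float = 2.0            # nm, stationary OU standard deviation
    noise_corner_freq: float = 50.0  # Hz, OU corner frequency
    polymer: PolymerModel = field(default_factory=PolymerModel)

    def __post_init__(self) -> None:
        if self.v0 < 0 or self.x_tilde <= 0:
            raise ValueError("v0 must be >= 0 and x_tilde > 0")
        if self.k_pause_in < 0 or self.k_pause_out <= 0:
            raise ValueError("pause entry must be >= 0, pause exit > 0")
        if self.mrna_codons < 1:
            raise ValueError("mrna_codons must be >= 1")
        if self.sample_rate <= 0 or self.noise_corner_freq <= 0:
            raise ValueError("frequencies must be positive")
        if self.baseline_duration < 0:
            raise ValueError("baseline_duration must be >= 0")
        if self.max_duration < self.baseline_duration:
            raise ValueError("max_duration must be >= baseline_duration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Event record of one simulated trace, for validation only."""

    step_times: np.ndarray                  # strictly increasing, s
    pause_intervals: list[tuple[float, float]]  # disjoint (start, end), s
    true_params: SimulationParams
    force: float
    seed: int

    def to_dict(self) -> dict:
        """JSON-serialisable summary (used for truth sidecar files)."""
        return {
            "force_pN": self.force,
            "seed": int(self.seed),
            "step_times_s": [float(t) for t in self.step_times],
            "pause_intervals_s": [[float(a), float(b)]
                                  for a, b in self.pause_intervals],
            "v0_codons_s": self.true_params.v0,
            "x_tilde_nm": self.true_params.x_tilde,
            "k_pause_in_s": self.true_params.k_pause_in,
            "k_pause_out_s": self.true_params.k_pause_out,
        }


def true_velocity(params: SimulationParams, force: float) -> float:
    """Pause-free stepping rate v(F) = v0*exp(-F*x_tilde/kBT), codons/s."""
    if force < 0:
        raise ValueError("force must be non-negative")
    return params.v0 * np.exp(-force * params.x_tilde / params.polymer.kbt)


def _ou_noise(rng: np.random.Generator, n: int, sd: float,
              corner_freq: float, dt: float) -> np.ndarray:
    """Stationary OU noise: autocorrelation sd^2*exp(-t/tau), tau = 1/(2*pi*fc)."""
    if sd == 0.0:
        return np.zeros(n)
    rho = np.exp(-2.0 * np.pi * corner_freq * dt)
    white = rng.standard_normal(n) * sd * np.sqrt(1.0 - rho ** 2)
    out = lfilter([1.0], [1.0, -rho], white)
    # stationary initial condition: decaying contribution of x_{-1} ~ N(0, sd^2)
    out += rho ** (np.arange(n) + 1) * rng.standard_normal() * sd
    return out


def simulate_trace(params: SimulationParams, force: float,
                   seed: int) -> tuple[Trace, GroundTruth]:
    """Simulate one constant-force trace and its ground-truth event record.

    The trace starts with ``baseline_duration`` of pause- and step-free
    recording (noise only), then runs the two-state stepping process until
    ``max_duration`` or until the template's ``mrna_codons`` steps have
    occurred.  Reproducible: a given seed yields a bit-identical result.
    """
    if seed is None:
        raise ValueError("a seed is required; trace generation must be reproducible")
    if force <= 0:
        raise ValueError("force must be positive")
    rng = np.random.default_rng(seed)
    v = true_velocity(params, force)
    end = params.max_duration

    t = params.baseline_duration
    steps: list[float] = []
    pauses: list[tuple[float, float]] = []
    translating = True
    pause_start = 0.0
    while t < end and len(steps) < params.mrna_codons:
        if translating:
            dt_step = rng.exponential(1.0 / v) if v > 0 else np.inf
            dt_pause = (rng.exponential(1.0 / params.k_pause_in)
                        if params.k_pause_in > 0 else np.inf)
            dt_next = min(dt_step, dt_pause)
            if not np.isfinite(dt_next):
                t = end
                break
            t += dt_next
            if t >= end:
                t = end
                break
            if dt_step <= dt_pause:
                steps.append(t)
            else:
                translating = False
                pause_start = t
        else:
            dt_next = rng.exponential(1.0 / params.k_pause_out)
            t += dt_next
            if t >= end:
                pauses.append((pause_start, end))
                t = end
                break
            pauses.append((pause_start, t))
            translating = True

    end_time = t if len(steps) == params.mrna_codons else end
    dt = 1.0 / params.sample_rate
    n = int(np.floor(end_time / dt)) + 1
    times = np.arange(n) * dt

    step_times = np.asarray(steps)
    counts = np.searchsorted(step_times, times, side="right")
    codon_ext = params.polymer.extension_per_codon(force)
    clean = (params.mrna_codons - counts) * codon_ext
    extension = clean + _ou_noise(rng, n, params.noise_sd,
                                  params.noise_corner_freq, dt)

    trace = Trace(
        times=times,
        extension=extension,
        force=float(force),
        baseline_end=params.baseline_duration,
        temperature=params.polymer.temperature,
        meta={"seed": int(seed), "n_steps_true": len(steps)},
    )
    truth = GroundTruth(step_times=step_times, pause_intervals=pauses,
                        true_params=params, force=float(force), seed=int(seed))
    return trace, truth


def simulate_experiment(params: SimulationParams, forces, n_per_force,
                        master_seed: int) -> list[tuple[Trace, GroundTruth]]:
    """Simulate a multi-force experiment with deterministic child seeds.

    ``n_per_force`` may be a single count applied to every force or a
    sequence of counts (one per force).  Child seeds are derived from
    ``master_seed`` via :class:`numpy.random.SeedSequence`, so the whole
    collection is reproducible from one integer.
    """
    forces = list(forces)
    if not forces:
        raise ValueError("forces must be non-empty")
    if np.isscalar(n_per_force):
        counts = [int(n_per_force)] * len(forces)
    else:
        counts = [int(c) for c in n_per_force]
        if len(counts) != len(forces):
            raise ValueError("n_per_force sequence must match forces in length")
    if any(c < 1 for c in counts):
        raise ValueError("n_per_force must be >= 1")

    total = sum(counts)
    child_seeds = np.random.SeedSequence(master_seed).generate_state(total)
    child_seeds = (child_seeds >> np.uint32(1)).astype(np.int64)  # < 2**31
    if len(set(child_seeds.tolist())) != total:
        raise ValueError("duplicate derived seeds; choose another master_seed")

    out: list[tuple[Trace, GroundTruth]] = []
    k = 0
    for force, count in zip(forces, counts):
        for replicate in range(count):
            trace, truth = simulate_trace(params, force, int(child_seeds[k]))
            trace.meta.update({"replicate": replicate,
                               "master_seed": int(master_seed)})
            out.append((trace, truth))
            k += 1
    return out


def without_pauses(params: SimulationParams) -> SimulationParams:
    """Copy of ``params`` with pausing switched off (validation helper)."""
    return replace(params, k_pause_in=0.0)
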