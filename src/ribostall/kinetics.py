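"""Force-velocity and dwell-time kinetics.

Aggregates per-trace summaries into distance-weighted force-velocity points,
fits the Arrhenius law v(F) = v0*exp(-F*x_tilde/kBT) by weighted nonlinear
least squares, extrapolates the stall force, fits single-exponential pause
and burst dwell-time distributions by maximum likelihood, tests the force
independence of the pause rates, and classifies the mechanochemical
mechanism (Brownian ratchet vs power stroke) from the characteristic
distance x_tilde.

Mechanism logic: for a power stroke the Arrhenius distance is the distance
to the transition state (x_dagger < step size); for a Brownian ratchet it is
the full step between the pre- and post-translocated states.  With a
crystallographic codon step of 1.48 nm, an x_tilde 95% CI that contains the
full step while excluding the 1-nt and 2-nt substeps (1.48/3, 2*1.48/3 nm)
is consistent with a single-step Brownian ratchet; the CI can never exclude
a power stroke outright, since x_dagger is only bounded above by the step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import CODON_STEP_NM
from .polymer import thermal_energy
from .signal import TraceResult

__all__ = [
    "ForceVelocityPoint",
    "ArrheniusFit",
    "ExponentialFit",
    "PauseKinetics",
    "MechanismCall",
    "aggregate_by_force",
    "fit_arrhenius",
    "stall_force",
    "fit_exponential_dwells",
    "pause_kinetics",
    "per_force_dwell_rates",
    "force_independence_test",
    "classify_mechanism",
]


@dataclass
class ForceVelocityPoint:
    """Distance-weighted mean pause-free velocity at one force."""

    force: float
    mean_velocity: float          # codons/s
    sem: float | None             # codons/s; None when only one trace
    n_traces: int
    total_distance: float         # codons


def aggregate_by_force(results: list[TraceResult]) -> list[ForceVelocityPoint]:
    """Group trace results by force; weight each trace by distance translocated.

    mean = sum(v_i*d_i)/sum(d_i).  The sem is the distance-weighted standard
    error: weighted variance (with an n/(n-1) correction) over an effective
    sample size n_eff = (sum d)^2 / sum d^2.  Force groups whose traces all
    have undefined velocity are dropped with a warning.
    """
    points: list[ForceVelocityPoint] = []
    for force in sorted({r.force for r in results}):
        group = [r for r in results if r.force == force and r.velocity_defined
                 and r.total_distance > 0]
        if not group:
            warnings.warn(f"force {force} pN: no trace with a defined "
                          "velocity; group dropped", stacklevel=2)
            continue
        v = np.array([r.pause_free_velocity for r in group])
        d = np.array([r.total_distance for r in group])
        mean = float(np.sum(v * d) / np.sum(d))
        n = len(group)
        if n >= 2:
            var_w = float(np.sum(d * (v - mean) ** 2) / np.sum(d)) * n / (n - 1)
            n_eff = float(np.sum(d) ** 2 / np.sum(d ** 2))
            sem = float(np.sqrt(var_w / n_eff))
        else:
            sem = None
        points.append(ForceVelocityPoint(
            force=float(force), mean_velocity=mean, sem=sem,
            n_traces=n, total_distance=float(np.sum(d))))
    return points


@dataclass
class ArrheniusFit:
    """Weighted NLLS fit of v(F) = v0*exp(-F*x_tilde/kBT)."""

    v0: float                     # codons/s
    x_tilde: float                # nm
    ci_v0: tuple[float, float]    # 95%
    ci_x_tilde: tuple[float, float]
    covariance: np.ndarray        # 2x2, order (v0, x_tilde)
    temperature: float            # K
    n_points: int

    def to_dict(self) -> dict:
        return {
            "v0_codons_s": self.v0,
            "v0_ci95": list(self.ci_v0),
            "x_tilde_nm": self.x_tilde,
            "x_tilde_ci95": list(self.ci_x_tilde),
            "covariance": self.covariance.tolist(),
            "temperature_k": self.temperature,
            "n_points": self.n_points,
        }


def fit_arrhenius(points: list[ForceVelocityPoint],
                  temperature: float = 296.0) -> ArrheniusFit:
    """Fit the exponential force-velocity law with weights 1/sem^2.

    Points without a defined sem receive the weight of the least precise
    defined point (largest sem); if no point has one, weights are uniform.
    The starting values come from linear regression of ln v on F, so the fit
    is deterministic.  95% CIs use the t quantile with n-2 degrees of
    freedom on the parameter covariance.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 force-velocity points to fit")
    forces = np.array([p.force for p in points])
    vels = np.array([p.mean_velocity for p in points])
    sems = np.array([p.sem if p.sem is not None and p.sem > 0 else np.nan
                     for p in points])
    if np.all(np.isnan(sems)):
        sems = np.ones_like(sems)
    else:
        sems = np.where(np.isnan(sems), np.nanmax(sems), sems)

    kbt = thermal_energy(temperature)
    if np.any(vels <= 0):
        raise ValueError("velocities must be positive for the Arrhenius fit")
    slope, intercept = np.polyfit(forces, np.log(vels), 1)
    p0 = (float(np.exp(intercept)), float(max(-slope * kbt, 1e-6)))

    def model(f, v0, x_tilde):
        return v0 * np.exp(-f * x_tilde / kbt)

    try:
        popt, pcov = optimize.curve_fit(
            model, forces, vels, p0=p0, sigma=sems, absolute_sigma=True,
            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Arrhenius fit did not converge from p0={p0}: {exc}") from exc

    n = len(points)
    tq = stats.t.ppf(0.975, n - 2)
    err = tq * np.sqrt(np.diag(pcov))
    return ArrheniusFit(
        v0=float(popt[0]), x_tilde=float(popt[1]),
        ci_v0=(float(popt[0] - err[0]), float(popt[0] + err[0])),
        ci_x_tilde=(float(popt[1] - err[1]), float(popt[1] + err[1])),
        covariance=pcov, temperature=temperature, n_points=n)


def stall_force(fit: ArrheniusFit, v_stall: float = 0.1,
                ) -> tuple[float, float]:
    """Force (pN) at which velocity falls to ``v_stall`` nt/s, with 1-sigma error.

    F_stall = (kBT/x_tilde) * ln(3*v0 / v_stall); v0 is converted from
    codons/s to nt/s.  The uncertainty comes from first-order propagation of
    the fit covariance.
    """
    kbt = thermal_energy(fit.temperature)
    v0_nt = 3.0 * fit.v0
    if v0_nt < v_stall:
        raise ValueError(
            f"zero-force velocity {v0_nt} nt/s is at or below the stall "
            f"criterion {v_stall} nt/s")
    f_stall = kbt / fit.x_tilde * np.log(v0_nt / v_stall)
    grad = np.array([kbt / (fit.x_tilde * fit.v0), -f_stall / fit.x_tilde])
    var = float(grad @ fit.covariance @ grad)
    return float(f_stall), float(np.sqrt(max(var, 0.0)))


@dataclass
class ExponentialFit:
    """MLE single-exponential fit of a dwell-time sample."""

    rate: float                   # 1/s, = 1/mean
    ci: tuple[float, float]       # exact 95% CI (gamma relation)
    n: int
    ks_statistic: float           # one-sample KS vs fitted exponential
    ks_pvalue: float


def fit_exponential_dwells(durations) -> ExponentialFit:
    """Exponential rate by maximum likelihood (1/mean) with an exact 95% CI.

    For n iid exponential dwells the total 2*rate*sum(t) is chi-squared with
    2n degrees of freedom, giving the exact interval
    [chi2(0.025, 2n), chi2(0.975, 2n)] / (2*sum(t)).  A one-sample
    Kolmogorov-Smirnov statistic against the fitted exponential is returned
    as a goodness-of-fit diagnostic.
    """
    durations = np.asarray(list(durations), dtype=float)
    if len(durations) < 2:
        raise ValueError("need at least 2 dwell times")
    if np.any(durations <= 0):
        raise ValueError("dwell times must be positive")
    total = float(durations.sum())
    n = len(durations)
    rate = n / total
    lo = float(stats.chi2.ppf(0.025, 2 * n) / (2 * total))
    hi = float(stats.chi2.ppf(0.975, 2 * n) / (2 * total))
    ks = stats.kstest(durations, "expon", args=(0.0, 1.0 / rate))
    return ExponentialFit(rate=float(rate), ci=(lo, hi), n=n,
                          ks_statistic=float(ks.statistic),
                          ks_pvalue=float(ks.pvalue))


@dataclass
class PauseKinetics:
    """Pooled pause entry/exit rates across all forces."""

    k_p: float                    # 1/s, pause entry (from burst durations)
    k_p_ci: tuple[float, float]
    k_minus_p: float              # 1/s, pause exit (from pause durations)
    k_minus_p_ci: tuple[float, float]
    n_bursts: int
    n_pauses: int
    low_pause_count: bool = False  # fewer than 5 pooled pauses

    def to_dict(self) -> dict:
        return {
            "k_p_s": self.k_p, "k_p_ci95": list(self.k_p_ci),
            "k_minus_p_s": self.k_minus_p,
            "k_minus_p_ci95": list(self.k_minus_p_ci),
            "n_bursts": self.n_bursts, "n_pauses": self.n_pauses,
            "low_pause_count": self.low_pause_count,
        }


def pause_kinetics(results: list[TraceResult]) -> PauseKinetics:
    """Pool non-censored dwell times across traces and forces; fit both rates.

    Pause entry rate k_p comes from burst durations, pause exit rate
    k_minus_p from pause durations, both as single-exponential MLEs.
    """
    bursts = [d for r in results for d in r.burst_durations]
    pauses = [d for r in results for d in r.pause_durations]
    if len(pauses) < 2:
        raise ValueError("no (or too few) pauses pooled across traces")
    if len(bursts) < 2:
        raise ValueError("too few complete bursts pooled across traces")
    if len(pauses) < 5:
        warnings.warn("fewer than 5 pooled pauses; rates are unreliable",
                      stacklevel=2)
    burst_fit = fit_exponential_dwells(bursts)
    pause_fit = fit_exponential_dwells(pauses)
    return PauseKinetics(
        k_p=burst_fit.rate, k_p_ci=burst_fit.ci,
        k_minus_p=pause_fit.rate, k_minus_p_ci=pause_fit.ci,
        n_bursts=burst_fit.n, n_pauses=pause_fit.n,
        low_pause_count=len(pauses) < 5)


def per_force_dwell_rates(results: list[TraceResult], kind: str,
                          ) -> list[tuple[float, float, tuple[float, float]]]:
    """Per-force dwell rates: list of (force, rate, 95% CI).

    ``kind`` is "burst" (pause entry) or "pause" (pause exit).  Force groups
    with fewer than 2 non-censored dwells are skipped.
    """
    if kind not in ("burst", "pause"):
        raise ValueError("kind must be 'burst' or 'pause'")
    out = []
    for force in sorted({r.force for r in results}):
        dwells = [d for r in results if r.force == force
                  for d in (r.burst_durations if kind == "burst"
                            else r.pause_durations)]
        if len(dwells) < 2:
            continue
        fit = fit_exponential_dwells(dwells)
        out.append((float(force), fit.rate, fit.ci))
    return out


def force_independence_test(per_force_rates) -> dict:
    """Weighted least-squares line of rate vs force; is the slope zero?

    Each rate's weight is 1/sd^2 with sd = (CI_hi - CI_lo)/(2*1.96).
    Verdict "independent" iff the slope's 95% CI contains zero.
    """
    import statsmodels.api as sm

    rates = list(per_force_rates)
    if len(rates) < 3:
        raise ValueError("need at least 3 force groups")
    forces = np.array([r[0] for r in rates])
    values = np.array([r[1] for r in rates])
    sds = np.array([(r[2][1] - r[2][0]) / (2 * stats.norm.ppf(0.975))
                    for r in rates])
    sds = np.where(sds > 0, sds, np.max(sds[sds > 0]) if np.any(sds > 0) else 1.0)
    model = sm.WLS(values, sm.add_constant(forces), weights=1.0 / sds ** 2)
    res = model.fit()
    slope = float(res.params[1])
    lo, hi = (float(x) for x in res.conf_int(alpha=0.05)[1])
    tol = 1e-10 * max(1.0, abs(float(np.mean(values))))  # exact-fit degeneracy
    return {
        "slope_per_pN": slope,
        "slope_ci95": [lo, hi],
        "verdict": "independent" if lo - tol <= 0.0 <= hi + tol
        else "dependent",
        "n_groups": len(rates),
    }


@dataclass
class MechanismCall:
    """Brownian-ratchet vs power-stroke classification from x_tilde."""

    x_step_ref: float = CODON_STEP_NM
    candidate_substeps: list[float] = field(default_factory=lambda: [
        CODON_STEP_NM / 3.0, 2.0 * CODON_STEP_NM / 3.0, CODON_STEP_NM])
    excluded: list[float] = field(default_factory=list)
    call: str = "indeterminate"
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "x_step_nm": self.x_step_ref,
            "candidate_substeps_nm": list(self.candidate_substeps),
            "excluded_nm": list(self.excluded),
            "call": self.call,
            "note": self.note,
        }


def classify_mechanism(fit: ArrheniusFit) -> MechanismCall:
    """Strict-CI mechanism call from the fitted characteristic distance.

    A candidate displacement is "excluded" when it lies outside the x_tilde
    95% CI.  Call = ``brownian_ratchet_consistent`` iff the full codon step
    is inside the CI and both substeps are excluded; ``substep`` iff the
    full step is excluded but a substep is not; otherwise ``indeterminate``.
    A power stroke is never excluded by this test alone (its transition-state
    distance is only bounded above by the step), which the note records.
    """
    lo, hi = fit.ci_x_tilde
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("x_tilde CI must be finite")
    call = MechanismCall()
    inside = [lo <= c <= hi for c in call.candidate_substeps]
    call.excluded = [c for c, ok in zip(call.candidate_substeps, inside)
                     if not ok]
    step_in = inside[-1]
    substeps_in = inside[:-1]
    if step_in and not any(substeps_in):
        call.call = "brownian_ratchet_consistent"
    elif not step_in and any(substeps_in):
        call.call = "substep"
    else:
        call.call = "indeterminate"
    call.note = (
        f"x_tilde = {fit.x_tilde:.2f} nm, 95% CI ({lo:.2f}, {hi:.2f}); "
        "a power-stroke mechanism with a transition state near the full step "
        "cannot be excluded by the characteristic distance alone.")
    return call
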