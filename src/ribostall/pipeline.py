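"""End-to-end orchestration: simulate -> analyze -> fit -> report.

The pipeline is configured by a single :class:`PipelineConfig` (YAML
serialisable) with a simulation block and an analysis block.  Everything is
deterministic given the master seed.  ``run_experiment`` performs the whole
study in memory; the file-based stages used by the CLI live in
:mod:`ribostall.cli`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .energetics import (AMIDE_HYDROLYSIS_KCAL, ESTER_HYDROLYSIS_KCAL,
                         mean_with_sem, transpeptidation_energy,
                         work_and_efficiency)
from .kinetics import (aggregate_by_force, classify_mechanism, fit_arrhenius,
                       force_independence_test, pause_kinetics,
                       per_force_dwell_rates, stall_force)
from .polymer import PolymerModel
from .signal import TraceResult, analyze_trace
from .simulate import SimulationParams, simulate_experiment

__all__ = [
    "AnalysisConfig",
    "PipelineConfig",
    "default_config",
    "analyze_traces",
    "build_report",
    "run_experiment",
    "recovery_study",
]

#: Default force ladder (pN) and replicates per force; 54 traces in total.
DEFAULT_FORCES = (2.0, 4.0, 6.0, 8.0, 10.0)
DEFAULT_N_PER_FORCE = (10, 11, 11, 11, 11)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the trace-processing and fitting chain."""

    span: int = 4000              # SG span in samples (odd-adjusted)
    polyorder: int = 2
    multiplier: float = 2.5       # pause threshold in units of sigma_pause
    min_segment: float = 0.5      # s, shorter segments are merged away
    v_stall_nt_per_s: float = 0.1  # stall criterion


@dataclass(frozen=True)
class PipelineConfig:
    """Full study configuration: generator + analysis + bookkeeping."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    forces: tuple = DEFAULT_FORCES
    n_per_force: tuple = DEFAULT_N_PER_FORCE
    master_seed: int = 20140811
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["forces"] = list(self.forces)
        d["n_per_force"] = list(self.n_per_force) \
            if not np.isscalar(self.n_per_force) else self.n_per_force
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = dict(d.get("simulation", {}))
        poly = PolymerModel(**sim.pop("polymer", {}))
        return cls(
            simulation=SimulationParams(polymer=poly, **sim),
            forces=tuple(d.get("forces", DEFAULT_FORCES)),
            n_per_force=(tuple(d["n_per_force"])
                         if isinstance(d.get("n_per_force"), (list, tuple))
                         else d.get("n_per_force", DEFAULT_N_PER_FORCE)),
            master_seed=int(d.get("master_seed", 20140811)),
            analysis=AnalysisConfig(**d.get("analysis", {})),
            output_dir=d.get("output_dir", "out"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(master_seed: int = 20140811) -> PipelineConfig:
    """The study-condition configuration (54 traces over 2-10 pN)."""
    return PipelineConfig(master_seed=master_seed)


def analyze_traces(traces, model: PolymerModel,
                   cfg: AnalysisConfig) -> tuple[list[TraceResult], int]:
    """Run the per-trace chain over a collection; skip failures with a warning.

    Returns the results and the number of traces skipped.
    """
    results: list[TraceResult] = []
    skipped = 0
    for trace in traces:
        try:
            result, _ = analyze_trace(
                trace, model, span=cfg.span, polyorder=cfg.polyorder,
                multiplier=cfg.multiplier, min_segment=cfg.min_segment)
            results.append(result)
        except ValueError as exc:
            skipped += 1
            warnings.warn(f"trace at {trace.force} pN skipped: {exc}",
                          stacklevel=2)
    return results, skipped


def build_report(results: list[TraceResult], cfg: AnalysisConfig,
                 temperature: float = 296.0) -> dict:
    """Aggregate per-trace results into the full study report.

    Contains the force-velocity table, the Arrhenius fit, the stall force,
    pooled pause kinetics with per-force force-independence tests, the
    mechanism call, and the transpeptidation energy budget.  Blocks that
    cannot be computed (e.g. a fit with fewer than 3 force groups) are
    reported as {"error": ...} rather than aborting the rest.
    """
    report: dict = {}
    points = aggregate_by_force(results)
    report["force_velocity"] = [
        {"force_pN": p.force, "mean_velocity_codons_s": p.mean_velocity,
         "sem_codons_s": p.sem, "n_traces": p.n_traces,
         "total_distance_codons": p.total_distance}
        for p in points]

    fit = None
    try:
        fit = fit_arrhenius(points, temperature=temperature)
        report["arrhenius"] = fit.to_dict()
        f_stall, f_err = stall_force(fit, v_stall=cfg.v_stall_nt_per_s)
        report["stall_force"] = {"f_stall_pN": f_stall, "sd_pN": f_err,
                                 "v_stall_nt_per_s": cfg.v_stall_nt_per_s}
        report["mechanism"] = classify_mechanism(fit).to_dict()
    except (ValueError, RuntimeError) as exc:
        report["arrhenius"] = {"error": str(exc)}

    try:
        kin = pause_kinetics(results)
        report["pause_kinetics"] = kin.to_dict()
        independence = {}
        for kind, name in (("burst", "k_p"), ("pause", "k_minus_p")):
            rates = per_force_dwell_rates(results, kind)
            try:
                independence[name] = force_independence_test(rates)
            except ValueError as exc:
                independence[name] = {"error": str(exc)}
        report["force_independence"] = independence
    except ValueError as exc:
        report["pause_kinetics"] = {"error": str(exc)}

    ester = mean_with_sem(ESTER_HYDROLYSIS_KCAL.values())
    amide = mean_with_sem(AMIDE_HYDROLYSIS_KCAL.values())
    chem = transpeptidation_energy(ester, amide, temperature=temperature)
    report["transpeptidation"] = {
        "delta_g_kcal_mol": chem.delta_g_kcal, "err_kcal_mol": chem.err_kcal,
        "delta_g_kBT": chem.delta_g_kbt, "err_kBT": chem.err_kbt,
    }
    if fit is not None and "stall_force" in report:
        budget = work_and_efficiency(
            report["stall_force"]["f_stall_pN"], chem.delta_g_kbt,
            temperature=temperature)
        report["energy_budget"] = budget.to_dict()
    return report


def run_experiment(config: PipelineConfig) -> dict:
    """Simulate, analyze and report one full synthetic study in memory."""
    pairs = simulate_experiment(config.simulation, config.forces,
                                config.n_per_force, config.master_seed)
    model = config.simulation.polymer
    results, skipped = analyze_traces((t for t, _ in pairs), model,
                                      config.analysis)
    report = build_report(results, config.analysis,
                          temperature=model.temperature)
    report["provenance"] = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
        "n_traces": len(pairs),
        "n_traces_skipped": skipped,
    }
    return report


def recovery_study(master_seeds, base_config: PipelineConfig | None = None,
                   ) -> dict:
    """Repeat the full synthetic study over several master seeds.

    Returns per-seed recovered parameters (v0, x_tilde, k_p, k_minus_p) and
    their medians -- the parameter-recovery check of the whole pipeline.
    """
    base = base_config or default_config()
    per_seed = {"v0": [], "x_tilde": [], "k_p": [], "k_minus_p": [],
                "f_stall": [], "seeds": []}
    for seed in master_seeds:
        cfg = PipelineConfig(
            simulation=base.simulation, forces=base.forces,
            n_per_force=base.n_per_force, master_seed=int(seed),
            analysis=base.analysis, output_dir=base.output_dir)
        report = run_experiment(cfg)
        if "error" in report.get("arrhenius", {}):
            warnings.warn(f"seed {seed}: Arrhenius fit failed; skipped",
                          stacklevel=2)
            continue
        per_seed["seeds"].append(int(seed))
        per_seed["v0"].append(report["arrhenius"]["v0_codons_s"])
        per_seed["x_tilde"].append(report["arrhenius"]["x_tilde_nm"])
        per_seed["f_stall"].append(report["stall_force"]["f_stall_pN"])
        kin = report.get("pause_kinetics", {})
        per_seed["k_p"].append(kin.get("k_p_s", np.nan))
        per_seed["k_minus_p"].append(kin.get("k_minus_p_s", np.nan))
    medians = {key: float(np.nanmedian(vals))
               for key, vals in per_seed.items() if key != "seeds" and vals}
    return {"per_seed": per_seed, "medians": medians,
            "n_traces_per_seed": int(np.sum(base.n_per_force))}
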