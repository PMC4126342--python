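"""Energy bookkeeping: unit conversions, the transpeptidation free-energy
budget, mechanical work near stall, and thermodynamic efficiency.

Energies move between three unit systems -- pN·nm (per molecule), kBT at a
stated temperature, and kcal/mol -- through fixed physical constants, so the
conversion graph is exactly consistent (any cycle returns the start value).

The chemical energy available per elongation cycle is the free-energy
difference between ester and amide bond hydrolysis (transpeptidation trades
an ester bond for an amide bond); each side is an average over published
hydrolysis free energies, with the spread propagated in quadrature.  The
maximal mechanical work per cycle is stall force x step size; the ratio of
the two is the motor's thermodynamic efficiency.

Values are stored at full precision; ``round_to_display`` handles the
1-decimal display convention, and :func:`transpeptidation_energy` also
reports a stepwise-rounded kBT figure (kcal/mol rounded to one decimal
before conversion), matching how such chains are conventionally quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import CODON_STEP_NM, PN_NM_PER_KCAL_PER_MOL
from .polymer import thermal_energy

__all__ = [
    "EnergyQuantity",
    "MeanSem",
    "TranspeptidationEnergy",
    "EnergyBudget",
    "ESTER_HYDROLYSIS_KCAL",
    "AMIDE_HYDROLYSIS_KCAL",
    "convert_energy",
    "mean_with_sem",
    "transpeptidation_energy",
    "work_and_efficiency",
]

_UNITS = ("pN_nm", "kBT", "kcal_per_mol")

#: Published hydrolysis free energies (kcal/mol) used for the ester side.
ESTER_HYDROLYSIS_KCAL = {
    "glycine ethyl ester": -8.40,
    "valyl RNA": -8.40,
    "ethyl acetate": -4.72,
}

#: Published hydrolysis free energies (kcal/mol) used for the amide side.
AMIDE_HYDROLYSIS_KCAL = {
    "asparagine": -3.60,
    "glutamine": -3.40,
}


@dataclass(frozen=True)
class EnergyQuantity:
    """An energy with its unit and the temperature defining kBT."""

    value: float
    unit: str
    temperature: float = 296.0

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; one of {_UNITS}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _to_pn_nm(q: EnergyQuantity) -> float:
    if q.unit == "pN_nm":
        return q.value
    if q.unit == "kBT":
        return q.value * thermal_energy(q.temperature)
    return q.value * PN_NM_PER_KCAL_PER_MOL


def convert_energy(q: EnergyQuantity, to_unit: str) -> EnergyQuantity:
    """Convert an energy between pN_nm, kBT and kcal_per_mol."""
    if to_unit not in _UNITS:
        raise ValueError(f"unknown unit {to_unit!r}; one of {_UNITS}")
    pn_nm = _to_pn_nm(q)
    if to_unit == "pN_nm":
        value = pn_nm
    elif to_unit == "kBT":
        value = pn_nm / thermal_energy(q.temperature)
    else:
        value = pn_nm / PN_NM_PER_KCAL_PER_MOL
    return EnergyQuantity(value=value, unit=to_unit, temperature=q.temperature)


@dataclass(frozen=True)
class MeanSem:
    """Mean with standard error; sem is 0 (flagged) for a single value."""

    mean: float
    sem: float
    n: int

    @property
    def sem_defined(self) -> bool:
        return self.n >= 2


def mean_with_sem(values) -> MeanSem:
    """Arithmetic mean and sample-sd/sqrt(n) standard error."""
    values = np.asarray(list(values), dtype=float)
    if len(values) == 0:
        raise ValueError("need at least one value")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return MeanSem(mean=mean, sem=sem, n=len(values))


@dataclass(frozen=True)
class TranspeptidationEnergy:
    """Free energy released per ester->amide bond exchange."""

    delta_g_kcal: float           # kcal/mol, full precision
    err_kcal: float               # quadrature error
    delta_g_kbt: float            # per molecule, full precision
    err_kbt: float
    reported_kbt: float           # from the 1-decimal-rounded kcal value
    reported_err_kbt: float
    temperature: float = 296.0


def transpeptidation_energy(ester: MeanSem, amide: MeanSem,
                            temperature: float = 296.0,
                            ) -> TranspeptidationEnergy:
    """Transpeptidation free energy: ester mean minus amide mean.

    The ester bond is higher in (hydrolysis) energy, so the exchange
    releases ester - amide (a negative number); errors add in quadrature.
    The kBT equivalents are given both at full precision and via the
    conventionally quoted stepwise-rounded chain (kcal rounded to one
    decimal before converting).
    """
    delta = ester.mean - amide.mean
    err = float(np.hypot(ester.sem, amide.sem))
    factor = PN_NM_PER_KCAL_PER_MOL / thermal_energy(temperature)
    return TranspeptidationEnergy(
        delta_g_kcal=delta, err_kcal=err,
        delta_g_kbt=delta * factor, err_kbt=err * factor,
        reported_kbt=round(delta, 1) * factor,
        reported_err_kbt=round(err, 1) * factor,
        temperature=temperature)


@dataclass
class EnergyBudget:
    """Work near stall in three unit systems, chemistry, and efficiency."""

    work_pn_nm: float
    work_kbt: float
    work_kcal_mol: float
    chem_kbt: float               # magnitude of the chemical energy, kBT
    efficiency: float             # work_kbt / |chem_kbt|
    temperature: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "work_pN_nm": self.work_pn_nm,
            "work_kBT": self.work_kbt,
            "work_kcal_mol": self.work_kcal_mol,
            "chem_kBT": self.chem_kbt,
            "efficiency": self.efficiency,
            "temperature_k": self.temperature,
            "note": self.note,
        }


def work_and_efficiency(f_stall: float, chem_kbt: float,
                        step: float = CODON_STEP_NM,
                        temperature: float = 296.0,
                        work_override_pn_nm: float | None = None,
                        ) -> EnergyBudget:
    """Maximal mechanical work (stall force x step) and its efficiency.

    ``chem_kbt`` is the chemical energy per cycle in kBT (sign ignored).
    ``work_override_pn_nm`` substitutes an externally quoted work figure;
    if it differs from f_stall*step by more than 5% the budget carries a
    consistency note rather than silently preferring either number.
    """
    if f_stall < 0 or step <= 0:
        raise ValueError("stall force must be >= 0 and step > 0")
    if chem_kbt == 0:
        raise ValueError("chemical energy must be nonzero")
    work = f_stall * step
    note = ""
    if work_override_pn_nm is not None:
        if work > 0 and abs(work_override_pn_nm - work) / work > 0.05:
            note = (f"supplied work {work_override_pn_nm:.1f} pN·nm differs "
                    f">5% from stall_force*step = {work:.1f} pN·nm")
        work = float(work_override_pn_nm)
    kbt = thermal_energy(temperature)
    work_kbt = work / kbt
    efficiency = work_kbt / abs(chem_kbt)
    if efficiency > 1:
        note = (note + "; " if note else "") + \
            "efficiency exceeds 1: inputs are inconsistent"
    return EnergyBudget(
        work_pn_nm=work, work_kbt=work_kbt,
        work_kcal_mol=work / PN_NM_PER_KCAL_PER_MOL,
        chem_kbt=abs(chem_kbt), efficiency=float(efficiency),
        temperature=temperature, note=note)


def round_to_display(value: float, decimals: int = 1) -> float:
    """Display-rounding helper kept separate from stored full precision."""
    return round(value, decimals)
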