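"""Van 't Hoff analysis of temperature-dependent binding constants.

ln Kb = -dH/(R T) + dS/R is fitted by ordinary least squares over (T, Kb)
pairs, assuming the binding enthalpy is temperature-independent across the
fitted range. Energies are kcal/mol throughout (R = 1.987204e-3 kcal/mol/K);
entropies are reported in cal/mol/K. The per-temperature Gibbs energy uses
dG = dH - T*dS with the single fitted dS. The signs of dH and dS classify
the dominant binding force (Ross-Subramanian rules): both negative -> van der
Waals / hydrogen bonding; both positive -> hydrophobic; dS > 0 with dH
negative or near zero -> electrostatic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .spectra_io import GAS_CONSTANT_KCAL, ValidationError

__all__ = [
    "ThermoRecord",
    "ThermoResult",
    "BindingForce",
    "vant_hoff_fit",
    "gibbs",
    "binding_force_classification",
]


@dataclass(frozen=True)
class ThermoRecord:
    temperature_K: float
    TdS_kcal_mol: float
    dG_kcal_mol: float


@dataclass(frozen=True)
class ThermoResult:
    """Fitted dH (kcal/mol), dS (cal/mol/K) and per-temperature T*dS, dG."""

    dH_kcal_mol: float
    dS_cal_mol_K: float
    per_temperature: tuple[ThermoRecord, ...]
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_temperature", tuple(self.per_temperature))
        if self.n_points < 2:
            raise ValidationError("Van 't Hoff fit needs >= 2 points")
        for rec in self.per_temperature:
            if abs(rec.dG_kcal_mol
                   - (self.dH_kcal_mol - rec.TdS_kcal_mol)) > 1e-12:
                raise ValidationError("dG must equal dH - T*dS")


class BindingForce(str, enum.Enum):
    vdw_hbond = "vdw_hbond"
    hydrophobic = "hydrophobic"
    electrostatic = "electrostatic"
    indeterminate = "indeterminate"


def vant_hoff_fit(
    kb_by_temperature: Sequence[tuple[float, float]],
) -> ThermoResult:
    """OLS of ln Kb versus 1/T.

    dH = -slope * R and dS = intercept * R (reported in cal/mol/K); each
    input temperature gets a T*dS and dG = dH - T*dS record.

    Parameters
    ----------
    kb_by_temperature
        (temperature_K, Kb_M1) pairs at >= 2 distinct temperatures, Kb > 0.
    """
    pairs = [(float(t), float(k)) for t, k in kb_by_temperature]
    if len(pairs) < 2:
        raise ValidationError("need >= 2 (temperature, Kb) pairs")
    temps = np.array([t for t, _ in pairs])
    kbs = np.array([k for _, k in pairs])
    if np.any(temps <= 0):
        raise ValidationError("temperatures must be > 0 K")
    if np.unique(temps).size != temps.size:
        raise ValidationError("duplicate temperatures")
    if np.any(kbs <= 0):
        raise ValidationError("all Kb must be > 0")
    # sort by temperature so output is invariant to input ordering
    order = np.argsort(temps)
    temps, kbs = temps[order], kbs[order]

    x = 1.0 / temps
    y = np.log(kbs)
    res = stats.linregress(x, y)
    r2 = 1.0 if np.ptp(y) == 0 else float(res.rvalue) ** 2
    dH = -float(res.slope) * GAS_CONSTANT_KCAL
    dS_kcal = float(res.intercept) * GAS_CONSTANT_KCAL
    records = tuple(
        ThermoRecord(
            temperature_K=float(t),
            TdS_kcal_mol=float(t) * dS_kcal,
            dG_kcal_mol=gibbs(dH, float(t) * dS_kcal),
        )
        for t in temps
    )
    return ThermoResult(
        dH_kcal_mol=dH,
        dS_cal_mol_K=dS_kcal * 1000.0,
        per_temperature=records,
        r_squared=r2,
        n_points=len(pairs),
    )


def gibbs(dH_kcal_mol: float, TdS_kcal_mol: float) -> float:
    """Gibbs free energy dG = dH - T*dS, all in kcal/mol."""
    return dH_kcal_mol - TdS_kcal_mol


def binding_force_classification(
    dH_kcal_mol: float,
    dS_cal_mol_K: float,
    near_zero_kcal: float = 0.5,
) -> BindingForce:
    """Classify the dominant non-covalent force from the signs of dH and dS.

    ``near_zero_kcal`` is the half-width of the |dH| band treated as
    "dH ~ 0" for the electrostatic rule.
    """
    if near_zero_kcal < 0:
        raise ValidationError("near_zero_kcal must be >= 0")
    near_zero = abs(dH_kcal_mol) <= near_zero_kcal
    # electrostatic applies when dS > 0 and dH is negative or near zero
    if dS_cal_mol_K > 0 and (dH_kcal_mol < 0 or near_zero):
        return BindingForce.electrostatic
    if dH_kcal_mol < 0 and dS_cal_mol_K < 0:
        return BindingForce.vdw_hbond
    if dH_kcal_mol > 0 and dS_cal_mol_K > 0:
        return BindingForce.hydrophobic
    return BindingForce.indeterminate
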