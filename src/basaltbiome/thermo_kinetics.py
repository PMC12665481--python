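"""Thermodynamic and kinetic predictors of silicate reactivity.

Implements the chain linking water chemistry to host-rock reactivity:

* Gibbs free energy of dissolution from the saturation index,
  dG = R * T * SI * ln(10)   (J/mol);
* the transition-state-theory affinity factor f(dG) = 1 - exp(dG / (R T)),
  ranging from 1 far from equilibrium to 0 at equilibrium, with f = 1
  assumed when dG is undetermined (far-from-equilibrium fallback);
* dissolution rates  r = k * a_H+^n_H * exp(-Ea / (R T)) * f(dG)
  for forsterite olivine and hydrated basaltic glass;
* the redox potential of the sulfate-sulfide couple
  (SO4-- + 10 H+ + 8 e- = H2S + 4 H2O, referenced to SHE):
  EH = (R T ln10 / (8 F)) * (log K - log10 Q),  Q = a_H2S / (a_SO4 a_H+^10);
* a per-well reactivity table with column summaries.

Two input modes exist: mode A consumes published per-well dG and in-situ pH
values directly (bit-exact arithmetic, no speciation model involved); mode B
derives them from full speciation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "R_GAS", "FARADAY", "KELVIN", "PhaseKinetics", "ReactivityResult",
    "gibbs_from_si", "affinity_factor", "dissolution_rate",
    "redox_potential", "reactivity_table", "summarize_reactivity",
]

R_GAS = 8.314        # J mol-1 K-1
FARADAY = 96485.0    # C mol-1
KELVIN = 273.15
LN10 = math.log(10.0)
_N_ELECTRONS = 8     # sulfate -> sulfide


@dataclass(frozen=True)
class PhaseKinetics:
    """TST rate-law parameters for one mineral phase.

    The Arrhenius dependence may be given either as an activation energy
    ``Ea`` (J/mol) or as the equivalent Arrhenius temperature
    ``A_T = Ea / (R ln10)`` (K); whichever the source publishes is stored
    exactly and the other derived from it.
    """

    phase: str
    k: float                      # mol m-2 s-1
    n_H: float                    # reaction order in H+
    Ea: float                     # J mol-1
    pH_valid: tuple = (0.0, 14.0)
    T_valid_C: tuple = (0.0, 150.0)

    def __post_init__(self):
        if self.k <= 0 or self.Ea <= 0:
            raise ValueError(f"{self.phase}: k and Ea must be positive")
        if self.pH_valid[0] >= self.pH_valid[1] or self.T_valid_C[0] >= self.T_valid_C[1]:
            raise ValueError(f"{self.phase}: empty validity window")

    @property
    def arrhenius_T(self) -> float:
        """A_T = Ea / (R ln10), in K."""
        return self.Ea / (R_GAS * LN10)

    def in_window(self, pH: float, T_C: float) -> bool:
        return (self.pH_valid[0] <= pH <= self.pH_valid[1]
                and self.T_valid_C[0] <= T_C <= self.T_valid_C[1])

    @classmethod
    def from_dict(cls, phase: str, d: dict) -> "PhaseKinetics":
        if "arrhenius_T_K" in d:
            ea = float(d["arrhenius_T_K"]) * R_GAS * LN10
        else:
            ea = float(d["Ea_J_mol"])
        k = 10.0 ** float(d["log10_k"]) if "log10_k" in d else float(d["k"])
        return cls(phase=phase, k=k, n_H=float(d["n_H"]), Ea=ea,
                   pH_valid=tuple(d.get("pH_valid", (0.0, 14.0))),
                   T_valid_C=tuple(d.get("T_valid_C", (0.0, 150.0))))

    @staticmethod
    def table_from_yaml(path) -> dict:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return {name: PhaseKinetics.from_dict(name, d) for name, d in raw.items()}


def gibbs_from_si(SI: Optional[float], T: float) -> Optional[float]:
    """dG = R * T * SI * ln10 in J/mol; null SI propagates to null dG."""
    if SI is None:
        return None
    if T <= 0:
        raise ValueError("absolute temperature must be positive")
    return R_GAS * T * SI * LN10


def si_from_gibbs(dG: Optional[float], T: float) -> Optional[float]:
    if dG is None:
        return None
    return dG / (R_GAS * T * LN10)


def affinity_factor(dG: Optional[float], T: float) -> float:
    """TST affinity factor f = 1 - exp(dG/RT).

    Undetermined dG means the far-from-equilibrium fallback f = 1.
    Supersaturation (dG > 0) clamps to 0: precipitation is out of scope.
    """
    if T <= 0:
        raise ValueError("absolute temperature must be positive")
    if dG is None:
        return 1.0
    if dG > 0:
        return 0.0
    return 1.0 - math.exp(dG / (R_GAS * T))


def is_supersaturated(dG: Optional[float]) -> bool:
    return dG is not None and dG > 0


def dissolution_rate(params: PhaseKinetics, pH_T: Optional[float], T: float,
                     dG: Optional[float] = None) -> Optional[float]:
    """r = k * a_H+^n_H * exp(-Ea/RT) * f(dG), with a_H+ = 10^-pH_T.

    Returns None when pH_T is undetermined.
    """
    if pH_T is None or (isinstance(pH_T, float) and math.isnan(pH_T)):
        return None
    a_h = 10.0 ** (-pH_T)
    return (params.k * a_h ** params.n_H
            * math.exp(-params.Ea / (R_GAS * T))
            * affinity_factor(dG, T))


def redox_potential(a_SO4: float, a_H2S: float, a_H: float, T: float,
                    logK: float) -> float:
    """EH (V vs SHE) of the sulfate-sulfide couple from species activities.

    EH = (R T ln10 / (n F)) * (log K - log10 Q) with n = 8 and
    Q = a_H2S / (a_SO4 * a_H+^10).
    """
    for name, a in (("a_SO4", a_SO4), ("a_H2S", a_H2S), ("a_H", a_H)):
        if a is None or a <= 0:
            raise ValueError(f"{name} must be a positive activity")
    log_q = math.log10(a_H2S) - math.log10(a_SO4) - 10.0 * math.log10(a_H)
    return R_GAS * T * LN10 / (_N_ELECTRONS * FARADAY) * (logK - log_q)


@dataclass
class ReactivityResult:
    """One well's derived reactivity quantities (the per-well output row)."""

    well_id: str
    T_K: float
    pH_T: Optional[float]
    dG: dict                 # phase -> J/mol or None
    f: dict                  # phase -> affinity factor in [0, 1]
    rate: dict               # phase -> mol m-2 s-1 or None
    EH: Optional[float]      # V
    flags: list


def _well_result(well_id: str, T_K: float, pH_T: Optional[float],
                 dG_by_phase: dict, EH: Optional[float],
                 kinetics: dict) -> ReactivityResult:
    flags = []
    dGs, fs, rates = {}, {}, {}
    for phase, params in kinetics.items():
        dG = dG_by_phase.get(phase)
        if dG is not None and math.isnan(dG):
            dG = None
        dGs[phase] = dG
        if dG is None:
            flags.append(f"{phase}:far_from_equilibrium_assumed")
        if is_supersaturated(dG):
            flags.append(f"{phase}:supersaturated")
        fs[phase] = affinity_factor(dG, T_K)
        rates[phase] = dissolution_rate(params, pH_T, T_K, dG)
        if pH_T is not None and not params.in_window(pH_T, T_K - KELVIN):
            flags.append(f"{phase}:outside_validity_window")
    return ReactivityResult(well_id, T_K, pH_T, dGs, fs, rates, EH, flags)


def reactivity_table(T_wellhead_C: "pd.Series", mode_a_inputs: pd.DataFrame,
                     kinetics: dict) -> list[ReactivityResult]:
    """Mode-A reactivity table from published per-well inputs.

    ``mode_a_inputs`` is indexed by well id with columns ``dG_Fo_kJ_mol``,
    ``dG_BG_kJ_mol``, ``pH_T`` and optionally ``EH_V`` (NaN = undetermined);
    ``T_wellhead_C`` supplies wellhead temperatures in degC.
    """
    results = []
    for wid, row in mode_a_inputs.iterrows():
        T_K = float(T_wellhead_C[wid]) + KELVIN
        dg = {}
        for phase, col in (("forsterite", "dG_Fo_kJ_mol"),
                           ("basaltic_glass", "dG_BG_kJ_mol")):
            v = row.get(col)
            dg[phase] = None if v is None or (isinstance(v, float) and math.isnan(v)) \
                else float(v) * 1000.0
        eh = row.get("EH_V")
        eh = None if eh is None or (isinstance(eh, float) and math.isnan(eh)) else float(eh)
        ph = row.get("pH_T")
        ph = None if ph is None or (isinstance(ph, float) and math.isnan(ph)) else float(ph)
        results.append(_well_result(wid, T_K, ph, dg, eh, kinetics))
    return results


def results_to_frame(results: Sequence[ReactivityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "well_id": r.well_id,
            "T_C": r.T_K - KELVIN,
            "pH_T": np.nan if r.pH_T is None else r.pH_T,
            "dG_Fo_kJ_mol": np.nan if r.dG["forsterite"] is None
            else r.dG["forsterite"] / 1000.0,
            "dG_BG_kJ_mol": np.nan if r.dG["basaltic_glass"] is None
            else r.dG["basaltic_glass"] / 1000.0,
            "f_Fo": r.f["forsterite"], "f_BG": r.f["basaltic_glass"],
            "r_Fo": np.nan if r.rate["forsterite"] is None else r.rate["forsterite"],
            "r_BG": np.nan if r.rate["basaltic_glass"] is None else r.rate["basaltic_glass"],
            "EH_V": np.nan if r.EH is None else r.EH,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows).set_index("well_id")


def summarize_reactivity(results: Sequence[ReactivityResult]) -> pd.DataFrame:
    """Mean/min/max/sd (over determined wells) of each reactivity column."""
    df = results_to_frame(results)
    cols = ["dG_Fo_kJ_mol", "dG_BG_kJ_mol", "pH_T", "EH_V", "r_Fo", "r_BG"]
    out = {}
    for c in cols:
        x = df[c].dropna().to_numpy(float)
        out[c] = {
            "mean": np.mean(x) if x.size else np.nan,
            "min": np.min(x) if x.size else np.nan,
            "max": np.max(x) if x.size else np.nan,
            "sd": np.std(x, ddof=1) if x.size > 1 else np.nan,
            "n": int(x.size),
        }
    return pd.DataFrame(out).T
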