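"""Reduced aqueous speciation for basalt-hosted groundwaters.

Given a well's total dissolved concentrations this module computes, at any
temperature in 20-115 degC: species activities (Davies activity model),
ionic strength, the pH that satisfies electroneutrality (bracketed
bisection), an electrical-balance adjustment that reconciles the calculated
20 degC pH with the field measurement by varying one concentration within
+/-20%, and saturation indices for forsterite and hydrated basaltic glass.

The species set is deliberately reduced: free major ions, the carbonate,
sulfide and silicic-acid systems, and water self-ionisation.  Aluminium is
carried as free Al3+ (no hydroxo-complexation), a stated simplification
that matters only for the basaltic-glass saturation index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .chem_io import WellRecord

__all__ = [
    "ThermoConstantTable", "SpeciatedWater", "BalanceAdjustment",
    "speciate", "in_situ_speciation", "adjust_electrical_balance",
    "saturation_index",
    "ConvergenceError",
]

# molar masses (g/mol) for ppm -> mol/kg conversion of tracked totals
_TOTAL_MM = {
    "Na": 22.98977, "K": 39.0983, "Ca": 40.078, "Mg": 24.305, "Al": 26.9815,
    "Cl": 35.453, "F": 18.9984, "SO4": 96.06, "CO2": 44.009, "H2S": 34.08,
    "SiO2aq": 60.084,
}

_REQUIRED_REACTIONS = (
    "water", "carbonate_1", "carbonate_2", "sulfide_1", "silicic_1",
    "forsterite", "basaltic_glass", "sulfate_sulfide",
)

_MAX_BISECT = 200
_RESIDUAL_TOL = 1e-12   # eq/kg


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, residual: float):
        super().__init__(f"{msg} (last residual {residual:.3e} eq/kg)")
        self.residual = residual


@dataclass
class ThermoConstantTable:
    """log10 K grids on a temperature grid (degC) with linear interpolation."""

    temperature_grid_C: np.ndarray
    log_k: dict                 # reaction -> np.ndarray over the grid
    davies_A: np.ndarray

    @classmethod
    def from_yaml(cls, path) -> "ThermoConstantTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        grid = np.asarray(raw["temperature_grid_C"], float)
        if not np.all(np.diff(grid) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        logk = {k: np.asarray(v, float) for k, v in raw["log_k"].items()}
        missing = [r for r in _REQUIRED_REACTIONS if r not in logk]
        if missing:
            raise ValueError(f"thermo constant table missing reactions: {missing}")
        for k, v in logk.items():
            if v.shape != grid.shape:
                raise ValueError(f"log_k[{k}] length does not match grid")
        return cls(grid, logk, np.asarray(raw["davies_A"], float))

    def logK(self, reaction: str, T_C: float) -> float:
        return float(np.interp(T_C, self.temperature_grid_C, self.log_k[reaction]))

    def A(self, T_C: float) -> float:
        return float(np.interp(T_C, self.temperature_grid_C, self.davies_A))


@dataclass
class SpeciatedWater:
    """Activities and derived quantities at one temperature."""

    T: float                     # K
    ionic_strength: float        # mol/kg
    activities: dict             # species -> activity (only species with data)
    pH_T: float
    charge_residual: float       # eq/kg at the solved pH

    def activity(self, species: str) -> Optional[float]:
        return self.activities.get(species)


@dataclass
class BalanceAdjustment:
    """Result of the +/-20% electrical-balance adjustment at 20 degC."""

    multipliers: dict            # species -> multiplier in [0.8, 1.2]
    delta_pH: float              # |pH_calc,20 - pH_measured| after adjustment
    balanced: bool               # delta_pH <= 0.2


def _totals_mol_per_kg(record: WellRecord) -> dict:
    """Tracked element-family totals in mol/kg; absent measurements omitted."""
    out = {}
    for name, mm in _TOTAL_MM.items():
        v = getattr(record, name)
        if v is not None:
            out[name] = v / 1000.0 / mm
    return out


def _davies_log_gamma(z: int, I: float, A: float) -> float:
    # the Davies model is only valid to I ~ 0.5 mol/kg; cap the ionic
    # strength entering the expression so extreme-pH bracket evaluations
    # during root-finding stay finite and monotone
    if z == 0 or I <= 0:
        return 0.0
    I = min(I, 1.0)
    sqI = np.sqrt(I)
    return -A * z * z * (sqI / (1.0 + sqI) - 0.3 * I)


# species -> (total family, charge); free ions speciate trivially
_FREE_IONS = {
    "Na+": ("Na", 1), "K+": ("K", 1), "Ca2+": ("Ca", 2), "Mg2+": ("Mg", 2),
    "Al3+": ("Al", 3), "Cl-": ("Cl", -1), "F-": ("F", -1), "SO42-": ("SO4", -2),
}


def _speciate_at_pH(pH: float, totals: dict, constants: ThermoConstantTable,
                    T_C: float):
    """Concentrations (mol/kg) of every species at fixed pH.

    Ionic strength and activity coefficients are solved by fixed-point
    iteration.  Returns (molalities, gammas-by-charge, ionic strength).
    """
    a_H = 10.0 ** (-pH)
    K1 = 10.0 ** constants.logK("carbonate_1", T_C)
    K2 = 10.0 ** constants.logK("carbonate_2", T_C)
    Ks = 10.0 ** constants.logK("sulfide_1", T_C)
    Ksi = 10.0 ** constants.logK("silicic_1", T_C)
    Kw = 10.0 ** constants.logK("water", T_C)
    A = constants.A(T_C)

    I = 0.0
    m: dict = {}
    for _ in range(100):
        g = {z: 10.0 ** _davies_log_gamma(z, I, A) for z in (1, 2, 3)}
        m = {"H+": a_H / g[1], "OH-": Kw / a_H / g[1]}
        for sp, (fam, z) in _FREE_IONS.items():
            if fam in totals:
                m[sp] = totals[fam]
        # carbonate: ct = m0 + m1 + m2 with m1 = K1 m0/(aH g1), m2 = K2 g1 m1/(aH g2)
        if "CO2" in totals:
            r1 = K1 / (a_H * g[1])
            r2 = K2 * g[1] / (a_H * g[2])
            m0 = totals["CO2"] / (1.0 + r1 + r1 * r2)
            m["H2CO3*"] = m0
            m["HCO3-"] = m0 * r1
            m["CO32-"] = m0 * r1 * r2
        if "H2S" in totals:
            r = Ks / (a_H * g[1])
            m["H2S(aq)"] = totals["H2S"] / (1.0 + r)
            m["HS-"] = m["H2S(aq)"] * r
        if "SiO2aq" in totals:
            r = Ksi / (a_H * g[1])
            m["SiO2(aq)"] = totals["SiO2aq"] / (1.0 + r)
            m["H3SiO4-"] = m["SiO2(aq)"] * r
        I_new = 0.5 * sum(mi * _CHARGE[sp] ** 2 for sp, mi in m.items())
        if abs(I_new - I) < 1e-14:
            I = I_new
            break
        I = I_new
    g = {z: 10.0 ** _davies_log_gamma(z, I, A) for z in (0, 1, 2, 3)}
    return m, g, I


_CHARGE = {
    "H+": 1, "OH-": -1, "Na+": 1, "K+": 1, "Ca2+": 2, "Mg2+": 2, "Al3+": 3,
    "Cl-": -1, "F-": -1, "SO42-": -2, "H2CO3*": 0, "HCO3-": -1, "CO32-": -2,
    "H2S(aq)": 0, "HS-": -1, "SiO2(aq)": 0, "H3SiO4-": -1,
}


def _charge_residual(m: dict) -> float:
    return sum(mi * _CHARGE[sp] for sp, mi in m.items())


def speciate(record: WellRecord, T_C: float,
             constants: ThermoConstantTable,
             multipliers: Optional[dict] = None,
             charge_imbalance: float = 0.0) -> SpeciatedWater:
    """Speciate a well's water at temperature ``T_C``.

    The pH is the one satisfying electroneutrality of the (optionally
    adjusted) totals, found by bisection on [0, 14]; the residual of the
    returned solution is below 1e-12 eq/kg.  A non-zero
    ``charge_imbalance`` (eq/kg) is treated as an inert counter-ion: the
    solver targets that residual instead of zero, which lets an
    analytically imbalanced water be carried from one temperature to
    another without the imbalance leaking into the pH.
    """
    if record.pH_20 is None:
        raise ValueError(f"well {record.well_id}: pH_20 is required")
    totals = _totals_mol_per_kg(record)
    for sp, mult in (multipliers or {}).items():
        if sp in totals:
            totals[sp] = totals[sp] * mult

    def residual(pH: float) -> float:
        m, _, _ = _speciate_at_pH(pH, totals, constants, T_C)
        return _charge_residual(m) - charge_imbalance

    lo, hi = 0.0, 14.0
    r_lo, r_hi = residual(lo), residual(hi)
    if not (r_lo > 0 > r_hi):   # pragma: no cover - totals are bounded in practice
        raise ConvergenceError(
            f"well {record.well_id}: charge balance has no root in pH [0, 14]",
            min(abs(r_lo), abs(r_hi)))
    pH = 7.0
    r_mid = residual(pH)
    for _ in range(_MAX_BISECT):
        r_mid = residual(pH)
        if abs(r_mid) < _RESIDUAL_TOL:
            break
        if r_mid > 0:
            lo = pH
        else:
            hi = pH
        pH = 0.5 * (lo + hi)
    else:
        raise ConvergenceError(
            f"well {record.well_id}: charge balance did not converge "
            f"after {_MAX_BISECT} bisections", r_mid)

    m, g, I = _speciate_at_pH(pH, totals, constants, T_C)
    acts = {sp: mi * g[abs(_CHARGE[sp])] for sp, mi in m.items()}
    # pH_T is defined exactly as -log10 a_H+
    acts["H+"] = 10.0 ** (-pH)
    return SpeciatedWater(
        T=T_C + 273.15, ionic_strength=I, activities=acts, pH_T=pH,
        charge_residual=_charge_residual(m),
    )


#: species the balance optimizer may vary, with the sign of dpH/dmultiplier
_ADJUSTABLE = {"Na": +1, "Cl": -1, "SO4": -1, "CO2": -1}


def adjust_electrical_balance(record: WellRecord,
                              constants: ThermoConstantTable,
                              target_dpH: float = 0.2) -> BalanceAdjustment:
    """Reconcile calculated 20 degC pH with the measured one.

    One concentration among Na+, Cl-, SO42- or total CO2 is varied within
    +/-20% of its measured value; among candidates achieving
    |pH_calc,20 - pH_meas| <= ``target_dpH`` the smallest |log multiplier|
    wins.  If no candidate succeeds the best effort is returned flagged.
    """
    from scipy.optimize import brentq

    totals = _totals_mol_per_kg(record)
    target = record.pH_20

    def dpH(species: str, mult: float) -> float:
        w = speciate(record, 20.0, constants, multipliers={species: mult})
        return w.pH_T - target

    base = dpH("Na", 1.0)   # multiplier 1 on any species = unadjusted
    best = BalanceAdjustment({}, abs(base), abs(base) <= target_dpH)
    if best.balanced and best.delta_pH == 0.0:
        return best

    candidates = [(0.0, {}, abs(base))]   # (|log mult|, multipliers, dpH)
    for sp in _ADJUSTABLE:
        if totals.get(sp, 0.0) <= 0.0:
            continue
        g_lo, g_hi = dpH(sp, 0.8), dpH(sp, 1.2)
        if g_lo == 0.0 or g_hi == 0.0 or g_lo * g_hi < 0:
            mult = brentq(lambda x: dpH(sp, x), 0.8, 1.2, xtol=1e-10)
            achieved = abs(dpH(sp, mult))
        else:
            mult = 0.8 if abs(g_lo) < abs(g_hi) else 1.2
            achieved = min(abs(g_lo), abs(g_hi))
        candidates.append((abs(np.log(mult)), {sp: mult}, achieved))

    ok = [c for c in candidates if c[2] <= target_dpH]
    if ok:
        _, mults, achieved = min(ok, key=lambda c: c[0])
        return BalanceAdjustment(mults, achieved, True)
    _, mults, achieved = min(candidates, key=lambda c: c[2])
    return BalanceAdjustment(mults, achieved, False)


def in_situ_speciation(record: WellRecord, constants: ThermoConstantTable,
                       multipliers: Optional[dict] = None) -> SpeciatedWater:
    """Speciate at the wellhead temperature, anchored to the measured pH.

    The residual charge imbalance of the (adjusted) totals is evaluated at
    the measured ~20 degC pH and carried to the wellhead temperature as an
    inert counter-ion, so the in-situ pH reflects the temperature shift of
    the equilibrium constants rather than analytical closure error.  With a
    well-balanced analysis the imbalance is ~0 and this coincides with
    :func:`speciate`.
    """
    totals = _totals_mol_per_kg(record)
    for sp, mult in (multipliers or {}).items():
        if sp in totals:
            totals[sp] = totals[sp] * mult
    m20, _, _ = _speciate_at_pH(record.pH_20, totals, constants, 20.0)
    imbalance = _charge_residual(m20)
    return speciate(record, record.T_wellhead, constants,
                    multipliers=multipliers, charge_imbalance=imbalance)


# IAP stoichiometries: species -> exponent (H+ exponent negative: reactant)
_PHASE_IAP = {
    "forsterite": {"SiO2(aq)": 1.0, "Mg2+": 2.0, "H+": -4.0},
    "basaltic_glass": {"SiO2(aq)": 1.0, "Al3+": 0.35, "H+": -1.05},
}


def saturation_index(water: SpeciatedWater, phase: str,
                     constants: ThermoConstantTable) -> Optional[float]:
    """SI = log10(IAP) - log10 K(T); None when a required activity is absent."""
    if phase not in _PHASE_IAP:
        raise ValueError(f"unknown phase {phase!r}")
    log_iap = 0.0
    for sp, nu in _PHASE_IAP[phase].items():
        a = water.activity(sp)
        if a is None or a <= 0:
            return None
        log_iap += nu * np.log10(a)
    return float(log_iap - constants.logK(phase, water.T - 273.15))
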