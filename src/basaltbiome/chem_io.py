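"""Water-chemistry table I/O, validation, summaries and Piper coordinates.

The reference input is a per-well table of field measurements (wellhead
temperature, pH measured at ~20 degC, conductivity) and laboratory
concentrations in ppm.  Missing measurements are marked "n.d." in the source
tables and are preserved as nulls throughout: any derived quantity that
needs a missing input is itself null, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: markers interpreted as "not determined" when reading chemistry CSVs
MISSING_MARKERS = {"n.d.", "nd", "n.d", "", "-", "—", "na", "NA", "NaN"}

#: concentration columns, all ppm (treated as mg/L: dilute waters, density ~1)
CONCENTRATION_COLUMNS = [
    "O2aq", "DOC", "TN", "H2S", "SiO2aq", "B", "Na", "K", "Ca", "Mg",
    "Al", "Fe", "Cl", "F", "CO2", "SO4",
]

#: default CSV header -> field-name schema
DEFAULT_SCHEMA = {
    "well_id": "well_id",
    "T_C": "T_wellhead",
    "pH_20C": "pH_20",
    "cond_mS_cm": "conductivity",
    "O2aq_ppm": "O2aq",
    "DOC_ppm": "DOC",
    "TN_ppm": "TN",
    "H2S_ppm": "H2S",
    "SiO2_ppm": "SiO2aq",
    "B_ppm": "B",
    "Na_ppm": "Na",
    "K_ppm": "K",
    "Ca_ppm": "Ca",
    "Mg_ppm": "Mg",
    "Al_ppm": "Al",
    "Fe_ppm": "Fe",
    "Cl_ppm": "Cl",
    "F_ppm": "F",
    "CO2_ppm": "CO2",
    "SO4_ppm": "SO4",
    "bedrock_age_Myr": "bedrock_age",
    "campaign": "campaign",
}

# molar masses (g/mol) and charges for the Piper milliequivalent conversion
MOLAR_MASS = {
    "Na": 22.98977, "K": 39.0983, "Ca": 40.078, "Mg": 24.305,
    "Cl": 35.453, "SO4": 96.06, "HCO3": 61.016, "CO2": 44.009,
}
ION_CHARGE = {"Na": 1, "K": 1, "Ca": 2, "Mg": 2, "Cl": 1, "SO4": 2, "HCO3": 1}

# first carbonate dissociation constant at 20 degC (activity scale) used to
# convert total dissolved CO2 to bicarbonate equivalents for the Piper anions
_PK1_20C = 6.38


@dataclass
class WellRecord:
    """One well's measured chemistry; concentrations in ppm, None = n.d."""

    well_id: str
    T_wellhead: float          # degC
    pH_20: float               # measured at ~20 degC
    conductivity: Optional[float] = None   # mS/cm
    O2aq: Optional[float] = None
    DOC: Optional[float] = None
    TN: Optional[float] = None
    H2S: Optional[float] = None
    SiO2aq: Optional[float] = None
    B: Optional[float] = None
    Na: Optional[float] = None
    K: Optional[float] = None
    Ca: Optional[float] = None
    Mg: Optional[float] = None
    Al: Optional[float] = None
    Fe: Optional[float] = None
    Cl: Optional[float] = None
    F: Optional[float] = None
    CO2: Optional[float] = None
    SO4: Optional[float] = None
    bedrock_age: Optional[float] = None    # Myr
    campaign: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.T_wellhead <= 150.0):
            raise ValueError(
                f"well {self.well_id}: T_wellhead {self.T_wellhead} outside [0, 150] degC"
            )
        if not (0.0 <= self.pH_20 <= 14.0):
            raise ValueError(f"well {self.well_id}: pH_20 {self.pH_20} outside [0, 14]")
        for col in CONCENTRATION_COLUMNS + ["conductivity"]:
            v = getattr(self, col)
            if v is not None and v < 0:
                raise ValueError(
                    f"well {self.well_id}: negative concentration {v!r} in column {col}"
                )


def _parse_cell(raw, well_id: str, column: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in MISSING_MARKERS:
        return None
    # below-quantification entries ("< 0.1") carry no usable value: treat as null
    if s.startswith("<"):
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"well {well_id}: cannot parse {column}={raw!r}") from exc


def read_chemistry(path, schema: Optional[dict] = None) -> list[WellRecord]:
    """Read a chemistry CSV into a list of :class:`WellRecord`.

    Unknown columns are a hard error; "n.d." or empty cells become nulls.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in schema]
    if unknown:
        raise ValueError(f"unknown column(s) in {path}: {unknown}")
    if "well_id" not in raw.columns:
        raise ValueError("chemistry table must contain a well_id column")
    if len(raw) == 0:
        raise ValueError("no data rows")

    records: list[WellRecord] = []
    for _, row in raw.iterrows():
        wid = str(row["well_id"]).strip()
        kwargs: dict = {"well_id": wid}
        for csv_col, fieldname in schema.items():
            if csv_col == "well_id" or csv_col not in raw.columns:
                continue
            if fieldname == "campaign":
                kwargs[fieldname] = str(row[csv_col]).strip()
            else:
                kwargs[fieldname] = _parse_cell(row[csv_col], wid, csv_col)
        if not kwargs.get("campaign"):
            kwargs["campaign"] = wid.split("-")[0] if "-" in wid else ""
        if kwargs.get("T_wellhead") is None or kwargs.get("pH_20") is None:
            raise ValueError(f"well {wid}: T and pH_20 are required")
        records.append(WellRecord(**kwargs))

    ids = [r.well_id for r in records]
    dupes = {w for w in ids if ids.count(w) > 1}
    if dupes:
        raise ValueError(f"duplicate well_id(s): {sorted(dupes)}")
    return records


def write_chemistry(records: Sequence[WellRecord], path) -> None:
    """Inverse of :func:`read_chemistry` (round-trips values and n.d. markers)."""
    inv = {v: k for k, v in DEFAULT_SCHEMA.items()}
    cols = list(DEFAULT_SCHEMA)
    rows = []
    for r in records:
        row = {}
        for f in fields(r):
            col = inv.get(f.name)
            if col is None:
                continue
            v = getattr(r, f.name)
            row[col] = "n.d." if v is None else v
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df[[c for c in cols if c in df.columns]]
    df.to_csv(path, index=False)


def records_to_frame(records: Sequence[WellRecord]) -> pd.DataFrame:
    """Tabular view, one row per well, NaN for missing values."""
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        rows.append(d)
    df = pd.DataFrame(rows)
    return df.set_index("well_id")


NUMERIC_COLUMNS = ["T_wellhead", "pH_20", "conductivity"] + CONCENTRATION_COLUMNS


def summarize_chemistry(records: Sequence[WellRecord]) -> pd.DataFrame:
    """Per-column mean/min/max/median/Q1/Q3/IQR over non-missing values.

    Quartiles use linear interpolation (numpy's default, type-7).  Columns
    with no present values yield an all-null row.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")
    df = records_to_frame(records)
    out = {}
    for col in NUMERIC_COLUMNS:
        x = df[col].dropna().to_numpy(float)
        if x.size == 0:
            out[col] = {k: np.nan for k in
                        ("mean", "min", "max", "median", "q1", "q3", "iqr", "n")}
            continue
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        out[col] = {
            "mean": float(np.mean(x)), "min": float(np.min(x)),
            "max": float(np.max(x)), "median": float(med),
            "q1": float(q1), "q3": float(q3), "iqr": float(q3 - q1),
            "n": int(x.size),
        }
    return pd.DataFrame(out).T


def _hco3_equiv_meq(co2_ppm: float, ph_20: float) -> float:
    """Bicarbonate equivalents (meq/L) of total dissolved CO2 at pH_20.

    Total dissolved CO2 is partitioned between H2CO3* and HCO3- by the first
    carbonate dissociation only (a stated simplification; carbonate ion is
    folded into the bicarbonate equivalent).
    """
    dic = co2_ppm / MOLAR_MASS["CO2"]   # mg/L over g/mol -> mmol/L
    k1 = 10.0 ** (-_PK1_20C)
    a_h = 10.0 ** (-ph_20)
    frac = k1 / (k1 + a_h)
    return dic * frac  # charge 1


def piper_coordinates(record: WellRecord) -> Optional[dict]:
    """Ternary milliequivalent fractions for the Piper diagram.

    Returns ``{"cation": (Ca, Mg, Na+K), "anion": (Cl, SO4, HCO3)}`` with each
    triple summing to 1, or None when a required ion is missing.
    """
    needed = ["Na", "K", "Ca", "Mg", "Cl", "SO4", "CO2"]
    vals = {ion: getattr(record, ion) for ion in needed}
    if any(v is None for v in vals.values()):
        return None
    meq = {
        ion: vals[ion] / MOLAR_MASS[ion] * ION_CHARGE[ion]
        for ion in ("Na", "K", "Ca", "Mg", "Cl", "SO4")
    }
    meq["HCO3"] = _hco3_equiv_meq(vals["CO2"], record.pH_20)
    cat_tot = meq["Ca"] + meq["Mg"] + meq["Na"] + meq["K"]
    an_tot = meq["Cl"] + meq["SO4"] + meq["HCO3"]
    if cat_tot <= 0 or an_tot <= 0:
        return None
    return {
        "cation": (meq["Ca"] / cat_tot, meq["Mg"] / cat_tot,
                   (meq["Na"] + meq["K"]) / cat_tot),
        "anion": (meq["Cl"] / an_tot, meq["SO4"] / an_tot, meq["HCO3"] / an_tot),
    }


def piper_table(records: Sequence[WellRecord]) -> pd.DataFrame:
    """Piper fractions for every well (NaN rows where ions are missing)."""
    rows = []
    for r in records:
        c = piper_coordinates(r)
        if c is None:
            rows.append({"well_id": r.well_id, **{k: np.nan for k in
                         ("cat_Ca", "cat_Mg", "cat_NaK", "an_Cl", "an_SO4", "an_HCO3")}})
        else:
            rows.append({
                "well_id": r.well_id,
                "cat_Ca": c["cation"][0], "cat_Mg": c["cation"][1],
                "cat_NaK": c["cation"][2],
                "an_Cl": c["anion"][0], "an_SO4": c["anion"][1],
                "an_HCO3": c["anion"][2],
            })
    return pd.DataFrame(rows).set_index("well_id")
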