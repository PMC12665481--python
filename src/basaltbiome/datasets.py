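"""Bundled reference tables for the 22 Icelandic basalt-hosted wells.

``load_well_chemistry`` returns the per-well field and laboratory chemistry
(the study's main input table).  ``load_reactivity_reference`` returns the
published per-well thermodynamic quantities (Gibbs free energies of
forsterite and basaltic-glass dissolution, in-situ pH, redox potential and
dissolution rates) used as mode-A inputs and as regression references.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .chem_io import WellRecord, read_chemistry


def _data_path(name: str):
    return resources.files("basaltbiome.data").joinpath(name)


def load_well_chemistry() -> list[WellRecord]:
    """The 22-well chemistry table as :class:`~basaltbiome.chem_io.WellRecord`."""
    with resources.as_file(_data_path("iceland_chemistry.csv")) as p:
        return read_chemistry(p)


def load_chemistry_frame() -> pd.DataFrame:
    from .chem_io import records_to_frame
    return records_to_frame(load_well_chemistry())


def load_reactivity_reference() -> pd.DataFrame:
    """Published per-well reactivity table (n.d. -> NaN), indexed by well."""
    with resources.as_file(_data_path("iceland_reactivity.csv")) as p:
        df = pd.read_csv(p, na_values=["n.d."])
    return df.set_index("well_id")


def default_thermo_constants():
    from .speciation import ThermoConstantTable
    with resources.as_file(_data_path("thermo_constants.yaml")) as p:
        return ThermoConstantTable.from_yaml(p)


def default_phase_kinetics() -> dict:
    from .thermo_kinetics import PhaseKinetics
    with resources.as_file(_data_path("phase_kinetics.yaml")) as p:
        return PhaseKinetics.table_from_yaml(p)
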