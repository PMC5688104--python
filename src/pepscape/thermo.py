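"""Binding thermodynamics: dissociation constants and free energies.

Converts between Kd (nM) and the binding free energy dG = R T ln(Kd in
molar), R = 1.987e-3 kcal/(mol K). The default temperature is 293 K, the
unique temperature at which the conversion reproduces the bundled
calorimetric reference table self-consistently.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

R_KCAL = 1.987e-3          # kcal / (mol K)
DEFAULT_TEMPERATURE = 293.0


@dataclass(frozen=True)
class BindingMeasurement:
    """One peptide's measured dissociation constant and free energy."""

    peptide: str
    kd_nM: float
    kd_err_nM: float
    dg_kcal: float
    dg_err_kcal: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError("Kd must be positive")
        if self.dg_kcal >= 0:
            raise ValueError("a binder must have negative dG")


def kd_to_dg(kd_nM: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant in nM."""
    if kd_nM <= 0:
        raise ValueError("Kd must be positive")
    return R_KCAL * temperature * float(np.log(kd_nM * 1e-9))

def dg_to_kd(dg_kcal: float,
             temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Dissociation constant (nM) from a binding free energy (kcal/mol)."""
    return float(np.exp(dg_kcal / (R_KCAL * temperature))) * 1e9


def load_binding_table() -> pd.DataFrame:
    """The bundled ITC reference table of MDM2-binding peptides.

    Columns: name, sequence, kd_nM, kd_err_nM, dg_kcal, dg_err_kcal. The
    p53-P27N dG is carried exactly as printed in its source, which is
    slightly off the round-trip value (documented in the methods note).
    """
    with resources.files("pepscape.data").joinpath(
            "binding_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def binding_measurements(temperature: float = DEFAULT_TEMPERATURE
                         ) -> list[BindingMeasurement]:
    table = load_binding_table()
    return [
        BindingMeasurement(peptide=getattr(row, "name"), kd_nM=row.kd_nM,
                           kd_err_nM=row.kd_err_nM, dg_kcal=row.dg_kcal,
                           dg_err_kcal=row.dg_err_kcal,
                           temperature=temperature)
        for row in table.itertuples(index=False)
    ]
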