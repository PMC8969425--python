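"""Mass/molar unit conversions.

Concentrations are handled externally in ng/mL and internally in nmol/mL;
doses externally in mg and internally in nmol.  Both conversions divide by
the analyte's molecular weight (g/mol):

* ng/mL / (g/mol) = nmol/mL  (1e-9 g / 1e-3 L over g/mol gives 1e-6 mol/L)
* mg -> nmol multiplies by 1e6 / MW.
"""

from __future__ import annotations

import numpy as np

from .models import Analyte

__all__ = [
    "conc_to_molar",
    "conc_to_mass",
    "dose_to_molar",
    "dose_to_mass",
    "mass_to_molar",
]


def _check_nonneg(value, what: str):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{what} must be non-negative")
    return arr


def conc_to_molar(value_ng_ml, analyte: Analyte):
    """Concentration ng/mL -> nmol/mL."""
    arr = _check_nonneg(value_ng_ml, "concentration")
    out = arr / analyte.molecular_weight
    return float(out) if np.isscalar(value_ng_ml) else out


def conc_to_mass(value_nmol_ml, analyte: Analyte):
    """Concentration nmol/mL -> ng/mL."""
    arr = _check_nonneg(value_nmol_ml, "concentration")
    out = arr * analyte.molecular_weight
    return float(out) if np.isscalar(value_nmol_ml) else out


def dose_to_molar(value_mg, analyte: Analyte):
    """Dose mg -> nmol."""
    arr = _check_nonneg(value_mg, "dose")
    out = arr * 1e6 / analyte.molecular_weight
    return float(out) if np.isscalar(value_mg) else out


def dose_to_mass(value_nmol, analyte: Analyte):
    """Dose nmol -> mg."""
    arr = _check_nonneg(value_nmol, "dose")
    out = arr * analyte.molecular_weight / 1e6
    return float(out) if np.isscalar(value_nmol) else out


def mass_to_molar(value, analyte: Analyte, kind: str = "concentration"):
    """Convert a mass quantity to molar units.

    ``kind="concentration"`` treats ``value`` as ng/mL and returns nmol/mL;
    ``kind="dose"`` treats it as mg and returns nmol.
    """
    if kind == "concentration":
        return conc_to_molar(value, analyte)
    if kind == "dose":
        return dose_to_molar(value, analyte)
    raise ValueError(f"unknown kind {kind!r}")
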