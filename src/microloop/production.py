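"""Bacterial carbon production from ³H-leucine incorporation.

Incorporation rates (pmol Leu l⁻¹ h⁻¹, blank-corrected against
formaldehyde-killed controls) convert to carbon production with the
standard leucine chain:

    BP (μgC l⁻¹ h⁻¹) = Leu (mol l⁻¹ h⁻¹) × 131.2 g mol⁻¹ × (1/0.073)
                        × 0.86 × ID × 10⁶ μg g⁻¹

where 131.2 is the molar mass of leucine, 0.073 the mass fraction of
leucine in cell protein, 0.86 the cellular carbon:protein ratio and the
isotope dilution ID is taken as 1. The chain collapses to
1.5456 × 10⁻³ μgC per pmol Leu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import (C_TO_PROTEIN, ISOTOPE_DILUTION, LEU_MOLAR_MASS,
                        PCT_LEU, LeucineAssay)
from .errors import InputError, ParameterError

#: μg of carbon produced per pmol of leucine incorporated:
#: 1e-12 mol × 131.2 g/mol ÷ 0.073 × 0.86 × 1e6 μg/g
UGC_PER_PMOL_LEU = (
    1e-12 * LEU_MOLAR_MASS / PCT_LEU * C_TO_PROTEIN * ISOTOPE_DILUTION * 1e6
)


@dataclass(frozen=True)
class LeucineConstants:
    """Conversion constants, overridable for sensitivity analysis."""

    molar_mass: float = LEU_MOLAR_MASS  # g mol^-1
    pct_leu: float = PCT_LEU
    c_to_protein: float = C_TO_PROTEIN
    isotope_dilution: float = ISOTOPE_DILUTION

    def __post_init__(self):
        for name in ("molar_mass", "pct_leu", "c_to_protein",
                     "isotope_dilution"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    @property
    def ugc_per_pmol(self) -> float:
        return (1e-12 * self.molar_mass / self.pct_leu
                * self.c_to_protein * self.isotope_dilution * 1e6)


def blank_correct(assay: LeucineAssay) -> float:
    """Net leucine incorporation: mean(live) − mean(killed controls).

    Negative nets (controls above live) are floored at 0 with a warning.
    Units: pmol l⁻¹ h⁻¹.
    """
    live = np.asarray(assay.live, dtype=float)
    controls = np.asarray(assay.controls, dtype=float)
    if live.size == 0 or controls.size == 0:
        raise InputError("need live measurements and killed controls")
    net = float(live.mean() - controls.mean())
    if net < 0:
        warnings.warn(
            f"killed controls exceed live incorporation in assay "
            f"{assay.experiment}/{assay.treatment}; flooring at 0",
            stacklevel=2,
        )
        net = 0.0
    return net


def leucine_to_carbon(net_leu: float,
                      constants: LeucineConstants | None = None) -> float:
    """Convert a net leucine rate (pmol l⁻¹ h⁻¹) to BP (μgC l⁻¹ h⁻¹)."""
    if net_leu < 0:
        raise InputError("net leucine incorporation must be >= 0")
    c = constants or LeucineConstants()
    return net_leu * c.ugc_per_pmol


def carbon_to_leucine(bp: float,
                      constants: LeucineConstants | None = None) -> float:
    """Inverse conversion: BP (μgC l⁻¹ h⁻¹) back to pmol Leu l⁻¹ h⁻¹."""
    if bp < 0:
        raise InputError("bacterial production must be >= 0")
    c = constants or LeucineConstants()
    return bp / c.ugc_per_pmol


def bacterial_production(assay: LeucineAssay,
                         constants: LeucineConstants | None = None) -> float:
    """Blank-correct an assay and convert to μgC l⁻¹ h⁻¹."""
    return leucine_to_carbon(blank_correct(assay), constants)
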