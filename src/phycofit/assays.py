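"""Closed-form assay conversions accompanying the kinetics.

Two pure unit conversions: spectrophotometric chlorophyll-a estimation
from absorbance at 665 nm, and gravimetric lipid content as percent of
dry biomass.  No dilution factors or path-length corrections are
applied.
"""

from __future__ import annotations

__all__ = ["chlorophyll_a", "lipid_content"]

#: mg/L of chlorophyll a per absorbance unit at 665 nm (90% methanol extract)
CHLOROPHYLL_A_COEFF = 13.43


def chlorophyll_a(od665: float) -> float:
    """Chlorophyll-a concentration (mg/L) from absorbance at 665 nm.

    Linear conversion ``13.43 * OD665`` for a 90% methanol extract.
    """
    if od665 < 0:
        raise ValueError("absorbance must be nonnegative")
    return CHLOROPHYLL_A_COEFF * od665


def lipid_content(lipid_mass: float, dry_biomass_mass: float) -> float:
    """Lipid content as percent of dry biomass (% w/w).

    ``100 * lipid_mass / dry_biomass_mass`` with both masses in the same
    unit (g); the lipid mass cannot exceed the biomass it came from.
    """
    if dry_biomass_mass <= 0:
        raise ValueError("dry biomass mass must be positive")
    if lipid_mass < 0:
        raise ValueError("lipid mass must be nonnegative")
    if lipid_mass > dry_biomass_mass:
        raise ValueError("lipid mass cannot exceed dry biomass mass")
    return 100.0 * lipid_mass / dry_biomass_mass
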