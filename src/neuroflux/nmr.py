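"""Peak-area arithmetic for ¹H-[¹³C] edited and plasma ¹H spectra.

This layer starts where spectral processing ends: with integrated peak
areas.  Two quantities are derived.  Fractional ¹³C enrichment is the
ratio of the ¹³C-only area (edited difference spectrum, or the summed
¹³C satellite area of a plasma resonance) to the total ¹²C+¹³C area.
Concentration follows from an internal reference of known amount
([2-¹³C]glycine for tissue extracts, formate for plasma) after
normalising each area by its proton multiplicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "PeakMeasurement",
    "EnrichmentAboveUnity",
    "enrichment_from_edited",
    "concentration_from_reference",
]

#: Fraction of glucose present as the α anomer in solution; the 5.2 ppm
#: H1 resonance reports only this fraction of total glucose.
ALPHA_ANOMER_FRACTION = 0.36


class EnrichmentAboveUnity(UserWarning):
    """Edited area exceeded the total area (noise or mis-integration)."""


@dataclass(frozen=True)
class PeakMeasurement:
    """One quantified resonance plus its concentration reference."""

    analyte: str
    area_nonedited: float
    n_protons: int
    ref_analyte: str
    ref_area: float
    ref_n_protons: int
    ref_amount: float  # μmol (extracts) or mmol/L (plasma)
    area_edited: float | None = None
    tissue_mass_g: float | None = None

    def __post_init__(self) -> None:
        if self.area_nonedited < 0 or self.ref_area < 0:
            raise ValueError("peak areas must be non-negative")
        if self.n_protons < 1 or self.ref_n_protons < 1:
            raise ValueError("proton counts must be >= 1")


def enrichment_from_edited(area_edited: float, area_nonedited: float) -> float:
    """Fractional ¹³C enrichment = labelled area / total area.

    Values above 1 are reported as-is with an
    :class:`EnrichmentAboveUnity` warning rather than silently clamped.
    """
    if area_nonedited <= 0:
        raise ValueError("total (non-edited) area must be positive")
    if area_edited < 0:
        raise ValueError("edited area must be non-negative")
    ratio = area_edited / area_nonedited
    if ratio > 1.0:
        warnings.warn(
            f"enrichment {ratio:.3f} exceeds 1; check peak integration",
            EnrichmentAboveUnity, stacklevel=2)
    return ratio


def concentration_from_reference(
    peak: PeakMeasurement,
    *,
    anomeric_fraction: float | None = None,
) -> float:
    """Concentration from a peak area and an internal reference.

    amount = ref_amount · (area / n_protons) / (ref_area / ref_n_protons),
    divided by ``tissue_mass_g`` when set (μmol/g for extracts; in
    plasma the reference is a concentration and the result is mmol/L).
    ``anomeric_fraction`` corrects an anomer-specific resonance (e.g.
    glucose α-H1 at 5.2 ppm) up to the total analyte; pass
    :data:`ALPHA_ANOMER_FRACTION` for glucose H1.
    """
    if peak.ref_area <= 0:
        raise ValueError("reference area must be positive")
    amount = (peak.ref_amount
              * (peak.area_nonedited / peak.n_protons)
              / (peak.ref_area / peak.ref_n_protons))
    if anomeric_fraction is not None:
        if not 0 < anomeric_fraction <= 1:
            raise ValueError("anomeric_fraction must be in (0, 1]")
        amount /= anomeric_fraction
    if peak.tissue_mass_g is not None:
        if peak.tissue_mass_g <= 0:
            raise ValueError("tissue_mass_g must be positive")
        amount /= peak.tissue_mass_g
    return amount
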