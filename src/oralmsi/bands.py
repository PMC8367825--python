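"""Spectral band identities and the anatomical-site vocabulary.

The imaging head illuminates tissue with four narrowband LEDs — violet
(405 nm) for autofluorescence excitation and green/yellow/red (545, 575,
610 nm) for diffuse reflectance.  545 nm sits near a hemoglobin isosbestic
point with strong absorption by both HbO2 and Hb; 610 nm is a weakly
absorbing reference where deoxyhemoglobin dominates what little absorption
remains; 575 nm overlaps the second HbO2 absorption band and is used for
the inflammation ratio R610/R575.
"""

from __future__ import annotations

import enum


class SpectralBand(str, enum.Enum):
    """One of the four fixed acquisition bands."""

    F405 = "F405"
    R545 = "R545"
    R575 = "R575"
    R610 = "R610"

    @property
    def center_wavelength(self) -> int:
        """Center wavelength of the illumination LED, in nm."""
        return _WAVELENGTH_NM[self]

    @property
    def modality(self) -> str:
        """``"fluorescence"`` for F405, ``"reflectance"`` otherwise."""
        return "fluorescence" if self is SpectralBand.F405 else "reflectance"

    @property
    def is_reflectance(self) -> bool:
        return self is not SpectralBand.F405


_WAVELENGTH_NM = {
    SpectralBand.F405: 405,
    SpectralBand.R545: 545,
    SpectralBand.R575: 575,
    SpectralBand.R610: 610,
}

#: The three diffuse-reflectance bands, in wavelength order.
REFLECTANCE_BANDS = (SpectralBand.R545, SpectralBand.R575, SpectralBand.R610)

#: All four bands, in wavelength order.
ALL_BANDS = (SpectralBand.F405,) + REFLECTANCE_BANDS


# Oral anatomical sites, grouped by surface keratinization.  Keratinized and
# non-keratinized mucosa differ in scattering and blood content, so the
# classifier keeps separate threshold models per group.
KERATINIZED_SITES = frozenset(
    {
        "gingiva",
        "vermillion_border",
        "dorsal_tongue",
        "hard_palate",
        "alveolus",
    }
)

NON_KERATINIZED_SITES = frozenset(
    {
        "buccal_mucosa_left",
        "buccal_mucosa_right",
        "lateral_tongue",
        "ventral_tongue",
        "floor_of_mouth",
        "inner_lip",
        "sulcus",
    }
)

ANATOMICAL_SITES = KERATINIZED_SITES | NON_KERATINIZED_SITES


def site_group(anatomical_site: str) -> str:
    """Map an anatomical site to ``"keratinized"`` or ``"non_keratinized"``.

    The mapping is total over :data:`ANATOMICAL_SITES`; unknown terms raise
    ``ValueError``.
    """
    if anatomical_site in KERATINIZED_SITES:
        return "keratinized"
    if anatomical_site in NON_KERATINIZED_SITES:
        return "non_keratinized"
    raise ValueError(f"unknown anatomical site: {anatomical_site!r}")


def base_site(anatomical_site: str) -> str:
    """Strip a laterality suffix: ``buccal_mucosa_left`` -> ``buccal_mucosa``."""
    for suffix in ("_left", "_right"):
        if anatomical_site.endswith(suffix):
            return anatomical_site[: -len(suffix)]
    return anatomical_site
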