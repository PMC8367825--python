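"""Pixel-wise band ratios, pseudo-color rendering and chromophore inversion.

The screening statistic is the diffuse-reflectance ratio R610/R545: 545 nm
sits on a strong hemoglobin absorption band, 610 nm is nearly
absorption-free, so the ratio grows with blood content and falls with
oxygenation — both hallmarks of malignant transformation.  R610/R575 plays
the same role for tissue inflammation.  Given the two-chromophore
Beer-Lambert model, any two reflectance bands also invert to absolute
oxy-/deoxyhemoglobin concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np

from .bands import SpectralBand
from .imageset import MultispectralCaptureSet
from .phantom import OpticalProperties

#: Default smallest usable denominator: one 8-bit count.
MIN_DENOMINATOR = 1.0 / 255.0

#: tHb below this (mM) leaves StO2 undefined (0/0 guard).
THB_EPSILON = 1e-6


@dataclass
class RatioMap:
    """A pixel-wise band ratio with a validity mask.

    ``values`` is zero at invalid pixels (saturated in either band, or
    denominator below the floor); invalid pixels are excluded from every
    downstream statistic.
    """

    numerator_band: SpectralBand
    denominator_band: SpectralBand
    values: np.ndarray
    valid_mask: np.ndarray

    @property
    def kind(self) -> str:
        return f"{self.numerator_band.value}/{self.denominator_band.value}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ChromophoreMaps:
    """Per-pixel chromophore solution of the two-band Beer-Lambert system.

    Concentrations are in mM relative to the configured baseline
    reflectances and path length.  ``sto2`` is NaN where tHb is too small
    for the fraction to be defined; ``clip_mask`` flags pixels where a
    (noise-induced) negative solution was clipped to zero; ``valid_mask``
    is False at saturated or non-positive-reflectance pixels.
    """

    c_hbo2: np.ndarray
    c_hb: np.ndarray
    thb: np.ndarray
    sto2: np.ndarray
    clip_mask: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class PseudoColorParams:
    """Monotone colormap rendering window for scalar maps."""

    colormap_name: str = "viridis"
    display_min: float = 0.0
    display_max: float = 4.0

    def __post_init__(self) -> None:
        if not self.display_min < self.display_max:
            raise ValueError("display_min must be < display_max")


def compute_ratio_map(
    capture: MultispectralCaptureSet,
    numerator_band: SpectralBand,
    denominator_band: SpectralBand,
    min_denominator: float = MIN_DENOMINATOR,
) -> RatioMap:
    """Pixel-by-pixel division of two reflectance frames.

    Pixels are invalid where the capture's saturation mask is set or the
    denominator falls below ``min_denominator``; their ratio is carried
    as 0.
    """
    for band in (numerator_band, denominator_band):
        if not band.is_reflectance:
            raise ValueError(
                f"{band.value} is a fluorescence band; ratios use reflectance bands only"
            )
    if not min_denominator > 0:
        raise ValueError("min_denominator must be positive")
    num = capture.images[numerator_band]
    den = capture.images[denominator_band]
    valid = (den >= min_denominator) & ~capture.saturation_mask
    values = np.zeros_like(num)
    np.divide(num, den, out=values, where=valid)
    return RatioMap(
        numerator_band=numerator_band,
        denominator_band=denominator_band,
        values=values,
        valid_mask=valid,
    )


def invert_chromophores(
    capture: MultispectralCaptureSet, props: OpticalProperties | None = None
) -> ChromophoreMaps:
    """Solve the 545/610-nm Beer-Lambert system for (C_HbO2, C_Hb) per pixel.

    Per non-saturated pixel with positive reflectance in both bands the
    2x2 linear system ``d * E @ c = -ln(R / k)`` is solved in closed form;
    negative components are clipped to zero and flagged.
    """
    props = props or OpticalProperties()
    b545, b610 = SpectralBand.R545, SpectralBand.R610
    e = np.array(
        [
            [props.eps(b545, "HbO2"), props.eps(b545, "Hb")],
            [props.eps(b610, "HbO2"), props.eps(b610, "Hb")],
        ]
    )
    det = np.linalg.det(e)
    if abs(det) < 1e-12:
        raise ValueError("extinction submatrix for (R545, R610) is singular")
    e_inv = np.linalg.inv(e) / props.path_length_cm

    r545 = capture.images[b545]
    r610 = capture.images[b610]
    valid = ~capture.saturation_mask & (r545 > 0) & (r610 > 0)

    a545 = np.zeros_like(r545)
    a610 = np.zeros_like(r610)
    np.log(
        np.divide(r545, props.baseline[b545], where=valid, out=np.ones_like(r545)),
        out=a545,
        where=valid,
    )
    np.log(
        np.divide(r610, props.baseline[b610], where=valid, out=np.ones_like(r610)),
        out=a610,
        where=valid,
    )
    a545 *= -1.0
    a610 *= -1.0

    c_hbo2 = e_inv[0, 0] * a545 + e_inv[0, 1] * a610
    c_hb = e_inv[1, 0] * a545 + e_inv[1, 1] * a610

    clip_mask = valid & ((c_hbo2 < 0) | (c_hb < 0))
    c_hbo2 = np.where(valid, np.maximum(c_hbo2, 0.0), 0.0)
    c_hb = np.where(valid, np.maximum(c_hb, 0.0), 0.0)
    thb = c_hbo2 + c_hb
    sto2 = np.full_like(thb, np.nan)
    defined = valid & (thb > THB_EPSILON)
    np.divide(c_hbo2, thb, out=sto2, where=defined)
    return ChromophoreMaps(
        c_hbo2=c_hbo2,
        c_hb=c_hb,
        thb=thb,
        sto2=sto2,
        clip_mask=clip_mask,
        valid_mask=valid,
    )


#: Reserved render color for invalid pixels (neutral mid-gray).
INVALID_RGB = (128, 128, 128)


def pseudo_color(
    values: RatioMap | np.ndarray, params: PseudoColorParams | None = None
) -> np.ndarray:
    """Render a scalar map as an 8-bit RGB image through a monotone colormap.

    Values are clamped to ``[display_min, display_max]``; invalid pixels of
    a :class:`RatioMap` render in a reserved neutral gray.
    """
    params = params or PseudoColorParams()
    if isinstance(values, RatioMap):
        grid = values.values
        valid = values.valid_mask
    else:
        grid = np.asarray(values, dtype=float)
        valid = np.ones_like(grid, dtype=bool)
    span = params.display_max - params.display_min
    normed = np.clip((grid - params.display_min) / span, 0.0, 1.0)
    cmap = matplotlib.colormaps[params.colormap_name]
    rgb = (cmap(normed)[..., :3] * 255).astype(np.uint8)
    rgb[~valid] = INVALID_RGB
    return rgb
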