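"""Tissue-phantom forward simulator.

No clinical image data accompanies the method, so this module generates
synthetic oral-mucosa capture sets with known per-pixel ground truth, and
labelled score cohorts whose class distributions are calibrated to the
reported clinical summary statistics (healthy median 1.41 / IQR 0.55, OPML
3.04 / 0.98, SCC 3.59 / 1.07 for the R610/R545 ratio).

The optical model is a two-chromophore modified Beer-Lambert law on diffuse
reflectance:

    R(band) = k(band) * exp(-d * (eps(band, HbO2) * C_HbO2 + eps(band, Hb) * C_Hb))

with k the bloodless-tissue baseline reflectance, d an effective mean photon
path length (cm) and eps molar extinction coefficients (cm^-1 mM^-1).  The
sign is the physically consistent one: absorption reduces reflectance.
Lesions raise total hemoglobin and lower oxygen saturation, which raises
the R610/R545 ratio; inflammation patches raise deoxyhemoglobin, which
shows up in R610/R575; specular spots saturate all reflectance bands.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .bands import REFLECTANCE_BANDS, SpectralBand
from .imageset import MultispectralCaptureSet, ScoreRecord

# Extinction coefficients in cm^-1 mM^-1, rounded from standard compiled
# hemoglobin tables.  At 610 nm deoxyhemoglobin absorbs ~7.5x more strongly
# than oxyhemoglobin, which is what makes R610 a near-absorption-free
# reference for the HbO2-sensitive R545 band.
DEFAULT_EXTINCTION = {
    (SpectralBand.R545, "HbO2"): 52.0,
    (SpectralBand.R545, "Hb"): 48.0,
    (SpectralBand.R575, "HbO2"): 59.0,
    (SpectralBand.R575, "Hb"): 37.0,
    (SpectralBand.R610, "HbO2"): 1.10,
    (SpectralBand.R610, "Hb"): 8.25,
}

#: Baseline (bloodless-tissue) reflectance per band; red reflects more.
DEFAULT_BASELINE = {
    SpectralBand.R545: 0.80,
    SpectralBand.R575: 0.82,
    SpectralBand.R610: 0.90,
}

#: Effective mean photon path length in mucosa, cm.
DEFAULT_PATH_LENGTH_CM = 0.25

#: Simulator convention for oxygen saturation by tissue grade (tumors are
#: hypoxic); configurable, not a clinical claim.
DEFAULT_STO2_BY_GRADE = {"normal": 0.98, "OPML": 0.85, "SCC": 0.70}


@dataclass(frozen=True)
class OpticalProperties:
    """Two-chromophore optical model parameters.

    ``extinction`` maps ``(band, chromophore)`` to cm^-1 mM^-1 for
    chromophores ``"HbO2"`` and ``"Hb"`` at the three reflectance bands;
    ``baseline`` is the bloodless reflectance k(band) in (0, 1];
    ``path_length_cm`` is the effective mean photon path d.
    """

    extinction: dict = field(default_factory=lambda: dict(DEFAULT_EXTINCTION))
    baseline: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    path_length_cm: float = DEFAULT_PATH_LENGTH_CM

    def __post_init__(self) -> None:
        for band in REFLECTANCE_BANDS:
            for chrom in ("HbO2", "Hb"):
                if self.extinction[(band, chrom)] < 0:
                    raise ValueError("extinction coefficients must be >= 0")
            if not 0 < self.baseline[band] <= 1:
                raise ValueError("baseline reflectance must lie in (0, 1]")
        if not self.extinction[(SpectralBand.R545, "HbO2")] > self.extinction[
            (SpectralBand.R610, "HbO2")
        ]:
            raise ValueError("HbO2 extinction must be stronger at 545 nm than 610 nm")
        ratio = self.extinction[(SpectralBand.R610, "Hb")] / self.extinction[
            (SpectralBand.R610, "HbO2")
        ]
        if not 7.0 <= ratio <= 8.0:
            raise ValueError(
                f"Hb/HbO2 extinction ratio at 610 nm must lie in [7, 8], got {ratio:.3g}"
            )
        if not self.path_length_cm > 0:
            raise ValueError("path length must be positive")

    def eps(self, band: SpectralBand, chromophore: str) -> float:
        return self.extinction[(band, chromophore)]

    def effective_extinction(self, band: SpectralBand, sto2: float) -> float:
        """Saturation-weighted extinction g(band) = eps_HbO2*StO2 + eps_Hb*(1-StO2)."""
        return self.eps(band, "HbO2") * sto2 + self.eps(band, "Hb") * (1.0 - sto2)

    def reflectance(
        self, band: SpectralBand, c_hbo2: np.ndarray | float, c_hb: np.ndarray | float
    ) -> np.ndarray | float:
        """Noise-free diffuse reflectance of the two-chromophore model."""
        absorbance = self.path_length_cm * (
            self.eps(band, "HbO2") * c_hbo2 + self.eps(band, "Hb") * c_hb
        )
        return self.baseline[band] * np.exp(-absorbance)


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]  # (x, y)
    axes: tuple[float, float]  # semi-axes (ax, ay), pixels


@dataclass(frozen=True)
class Lesion(Ellipse):
    grade: str = "OPML"  # "OPML" | "SCC"
    target_ratio: float = 3.0  # desired hotspot R610/R545
    sto2: float | None = None  # default: DEFAULT_STO2_BY_GRADE[grade]

    def __post_init__(self) -> None:
        if self.grade not in ("OPML", "SCC"):
            raise ValueError("lesion grade must be 'OPML' or 'SCC'")
        if not self.target_ratio > 0:
            raise ValueError("target_ratio must be positive")


@dataclass(frozen=True)
class InflammationPatch(Ellipse):
    hb_multiplier: float = 3.0


@dataclass(frozen=True)
class SpecularSpot:
    center: tuple[float, float]
    radius: float


@dataclass
class PhantomScene:
    """Scene description for the forward simulator."""

    width: int = 128
    height: int = 128
    background: tuple[float, float] = (0.012, 0.003)  # (C_HbO2, C_Hb), mM
    lesions: list[Lesion] = field(default_factory=list)
    inflammation_patches: list[InflammationPatch] = field(default_factory=list)
    specular_spots: list[SpecularSpot] = field(default_factory=list)
    fluorescence_base: float = 0.6
    fluorescence_lesion_loss: float = 0.5  # fractional autofluorescence loss
    fluorescence_ppix_gain: float = 0.15  # added PpIX emission inside lesions
    noise_sigma: float = 0.0  # additive Gaussian std on normalized intensity
    seed: int = 0
    site_id: str = "phantom"
    anatomical_site: str = "buccal_mucosa_left"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for e in list(self.lesions) + list(self.inflammation_patches):
            cx, cy = e.center
            ax, ay = e.axes
            if not (0 <= cx - ax and cx + ax < self.width and 0 <= cy - ay and cy + ay < self.height):
                raise ValueError("ellipse extends outside image bounds")
            if ax <= 0 or ay <= 0:
                raise ValueError("ellipse semi-axes must be positive")


@dataclass
class GroundTruth:
    """Per-pixel truth emitted alongside a simulated capture set."""

    c_hbo2: np.ndarray  # mM
    c_hb: np.ndarray  # mM
    grade_map: np.ndarray  # str labels {"normal","OPML","SCC"}
    expected_ratio_map: np.ndarray  # noise-free R610/R545


# ---------------------------------------------------------------------------
# Analytic inversion at fixed oxygen saturation


def target_ratio_to_concentrations(
    target_ratio: float, sto2: float, props: OpticalProperties | None = None
) -> tuple[float, float]:
    """Concentrations producing a requested noise-free R610/R545 ratio.

    At fixed saturation the ratio is ``(k610/k545) * exp(d*(g545-g610)*tHb)``
    with g the saturation-weighted extinction, so tHb follows by taking logs.
    Returns ``(C_HbO2, C_Hb) = (StO2*tHb, (1-StO2)*tHb)`` in mM.
    """
    props = props or OpticalProperties()
    if not 0.0 <= sto2 <= 1.0:
        raise ValueError("StO2 must lie in [0, 1]")
    k545 = props.baseline[SpectralBand.R545]
    k610 = props.baseline[SpectralBand.R610]
    baseline_ratio = k610 / k545
    if target_ratio <= baseline_ratio:
        raise ValueError(
            f"target ratio {target_ratio:.4g} not achievable: baseline ratio is "
            f"{baseline_ratio:.4g} and absorption only increases the ratio"
        )
    g545 = props.effective_extinction(SpectralBand.R545, sto2)
    g610 = props.effective_extinction(SpectralBand.R610, sto2)
    if g545 <= g610:
        raise ValueError("effective extinction at 545 nm must exceed that at 610 nm")
    thb = math.log(target_ratio / baseline_ratio) / (props.path_length_cm * (g545 - g610))
    return sto2 * thb, (1.0 - sto2) * thb


# ---------------------------------------------------------------------------
# Forward rendering


def _ellipse_weight(shape: tuple[int, int], ellipse: Ellipse, taper_px: float = 2.0) -> np.ndarray:
    """Membership weight of an ellipse: 1 in the core, cosine taper over the
    outermost ``taper_px`` pixels, 0 outside."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = ellipse.center
    ax, ay = ellipse.axes
    rho = np.sqrt(((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2)
    # Approximate pixel distance to the boundary along the minor axis.
    dist_to_edge = (1.0 - rho) * min(ax, ay)
    w_map = np.clip(dist_to_edge / taper_px, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * w_map))


def forward_reflectance(
    scene: PhantomScene, props: OpticalProperties | None = None
) -> tuple[MultispectralCaptureSet, GroundTruth]:
    """Render a four-band capture set from a phantom scene.

    Lesion concentrations come from :func:`target_ratio_to_concentrations`
    so each lesion's flat core reaches exactly its target hotspot ratio;
    inflammation patches scale the deoxyhemoglobin map; specular spots are
    set to full scale and flagged in the saturation mask; Gaussian noise is
    added last and intensities clipped to [0, 1].
    """
    props = props or OpticalProperties()
    shape = (scene.height, scene.width)
    c_hbo2 = np.full(shape, scene.background[0], dtype=float)
    c_hb = np.full(shape, scene.background[1], dtype=float)
    grade_map = np.full(shape, "normal", dtype=object)

    for lesion in scene.lesions:
        sto2 = DEFAULT_STO2_BY_GRADE[lesion.grade] if lesion.sto2 is None else lesion.sto2
        les_hbo2, les_hb = target_ratio_to_concentrations(lesion.target_ratio, sto2, props)
        w = _ellipse_weight(shape, lesion)
        c_hbo2 = c_hbo2 + w * (les_hbo2 - c_hbo2)
        c_hb = c_hb + w * (les_hb - c_hb)
        grade_map[w > 0.5] = lesion.grade

    for patch in scene.inflammation_patches:
        w = _ellipse_weight(shape, patch)
        c_hb = c_hb * (1.0 + w * (patch.hb_multiplier - 1.0))

    images = {
        band: np.asarray(props.reflectance(band, c_hbo2, c_hb)) for band in REFLECTANCE_BANDS
    }
    expected_ratio = images[SpectralBand.R610] / images[SpectralBand.R545]

    lesion_weight = np.zeros(shape)
    for lesion in scene.lesions:
        lesion_weight = np.maximum(lesion_weight, _ellipse_weight(shape, lesion))
    images[SpectralBand.F405] = (
        scene.fluorescence_base * (1.0 - scene.fluorescence_lesion_loss * lesion_weight)
        + scene.fluorescence_ppix_gain * lesion_weight
    )

    saturation = np.zeros(shape, dtype=bool)
    if scene.specular_spots:
        yy, xx = np.mgrid[0 : scene.height, 0 : scene.width]
        for spot in scene.specular_spots:
            cx, cy = spot.center
            saturation |= (xx - cx) ** 2 + (yy - cy) ** 2 <= spot.radius**2

    rng = np.random.default_rng(scene.seed)
    for band in list(images):
        img = images[band]
        if scene.noise_sigma > 0:
            img = img + rng.normal(0.0, scene.noise_sigma, size=shape)
        img = np.clip(img, 0.0, 1.0)
        if band.is_reflectance:
            img = np.where(saturation, 1.0, img)
        images[band] = img
    saturation |= np.stack(
        [images[b] >= 1.0 for b in REFLECTANCE_BANDS], axis=0
    ).any(axis=0)

    capture = MultispectralCaptureSet(
        images=images,
        exposures={b: 1.0 for b in images},
        site_id=scene.site_id,
        anatomical_site=scene.anatomical_site,
        saturation_mask=saturation,
        bit_depth=16,
        extra={"simulated": True, "seed": scene.seed},
    )
    truth = GroundTruth(
        c_hbo2=c_hbo2, c_hb=c_hb, grade_map=grade_map, expected_ratio_map=expected_ratio
    )
    return capture, truth


# ---------------------------------------------------------------------------
# Score cohorts calibrated to the clinical class summaries


@dataclass(frozen=True)
class ClassDistribution:
    """Log-normal score distribution pinned to a (median, IQR) pair.

    For X ~ LogNormal(mu, sigma): median = exp(mu) and
    IQR = median * 2*sinh(sigma*z75), so both parameters follow in closed
    form from the targets (z75 = 0.6745 is the 75% normal quantile).
    """

    median: float
    iqr: float

    def __post_init__(self) -> None:
        if not self.median > 0:
            raise ValueError("median must be positive")
        if self.iqr < 0:
            raise ValueError("IQR must be >= 0")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        z75 = norm.ppf(0.75)
        return math.asinh(self.iqr / (2.0 * self.median)) / z75

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(self.mu, self.sigma, size=n)


#: Class distributions calibrated to the reported clinical medians/IQRs.
DEFAULT_CLASS_DISTRIBUTIONS = {
    "normal": ClassDistribution(median=1.41, iqr=0.55),
    "OPML": ClassDistribution(median=3.04, iqr=0.98),
    "SCC": ClassDistribution(median=3.59, iqr=1.07),
}

_COHORT_SITES = (
    "buccal_mucosa_left",
    "buccal_mucosa_right",
    "lateral_tongue",
    "dorsal_tongue",
    "gingiva",
    "floor_of_mouth",
)


@dataclass
class CohortSpec:
    """Specification of a labelled synthetic score cohort."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"normal": 40, "OPML": 40, "SCC": 49}
    )
    distributions: dict[str, ClassDistribution] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DISTRIBUTIONS)
    )
    normal_source: str = "patient"
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.n_per_class.items():
            if n < 0:
                raise ValueError(f"negative count for class {label!r}")
            if n > 0 and label not in self.distributions:
                raise ValueError(f"no distribution configured for class {label!r}")


def generate_cohort(spec: CohortSpec) -> list[ScoreRecord]:
    """Draw a labelled score cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records: list[ScoreRecord] = []
    for label in ("normal", "OPML", "SCC"):
        n = spec.n_per_class.get(label, 0)
        if n == 0:
            continue
        scores = spec.distributions[label].sample(n, rng)
        sites = rng.choice(_COHORT_SITES, size=n)
        source = spec.normal_source if label == "normal" else "patient"
        for i, (s, site) in enumerate(zip(scores, sites)):
            records.append(
                ScoreRecord(
                    site_id=f"{label}-{i:04d}",
                    anatomical_site=str(site),
                    score=float(s),
                    label=label,
                    source=source,
                )
            )
    return records


# ---------------------------------------------------------------------------
# JSON loading (CLI support)


def scene_from_json(path: str | Path) -> PhantomScene:
    """Build a :class:`PhantomScene` from a JSON description."""
    data = json.loads(Path(path).read_text())
    lesions = [
        Lesion(
            center=tuple(item["center"]),
            axes=tuple(item["axes"]),
            grade=item.get("grade", "OPML"),
            target_ratio=float(item.get("target_ratio", 3.0)),
            sto2=item.get("sto2"),
        )
        for item in data.get("lesions", [])
    ]
    patches = [
        InflammationPatch(
            center=tuple(item["center"]),
            axes=tuple(item["axes"]),
            hb_multiplier=float(item.get("hb_multiplier", 3.0)),
        )
        for item in data.get("inflammation_patches", [])
    ]
    spots = [
        SpecularSpot(center=tuple(item["center"]), radius=float(item["radius"]))
        for item in data.get("specular_spots", [])
    ]
    kwargs = {
        k: data[k]
        for k in (
            "width",
            "height",
            "fluorescence_base",
            "fluorescence_lesion_loss",
            "fluorescence_ppix_gain",
            "noise_sigma",
            "seed",
            "site_id",
            "anatomical_site",
        )
        if k in data
    }
    if "background" in data:
        kwargs["background"] = tuple(data["background"])
    return PhantomScene(
        lesions=lesions, inflammation_patches=patches, specular_spots=spots, **kwargs
    )


def cohort_spec_from_json(path: str | Path) -> CohortSpec:
    data = json.loads(Path(path).read_text())
    kwargs = {}
    if "n_per_class" in data:
        kwargs["n_per_class"] = {k: int(v) for k, v in data["n_per_class"].items()}
    if "distributions" in data:
        kwargs["distributions"] = {
            k: ClassDistribution(median=float(v["median"]), iqr=float(v["iqr"]))
            for k, v in data["distributions"].items()
        }
    for k in ("seed", "normal_source"):
        if k in data:
            kwargs[k] = data[k]
    return CohortSpec(**kwargs)
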