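"""Capture-set data model, polygon ROIs and score tables.

A capture set is one screening acquisition: four co-registered monochrome
frames (F405, R545, R575, R610) plus acquisition metadata.  On disk it is a
directory holding one grayscale TIFF/PNG per band and a JSON sidecar with
exposures and site metadata.  Pixel intensities are kept as floats in
[0, 1]; the camera bit depth is metadata, not part of the math.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .bands import ALL_BANDS, ANATOMICAL_SITES, SpectralBand, site_group

VALID_LABELS = ("normal", "OPML", "SCC")
VALID_SOURCES = ("patient", "healthy_volunteer")

_SIDECAR_NAME = "capture.json"
_SIDECAR_KEYS = ("bands", "exposures", "site_id", "anatomical_site", "bit_depth")


@dataclass
class MultispectralCaptureSet:
    """Four co-registered band images plus acquisition metadata.

    Parameters
    ----------
    images
        Mapping band -> 2-D float array with values in [0, 1].
    exposures
        Mapping band -> positive exposure multiplier used at capture.
    site_id
        Free-form identifier of the imaged site (patient/visit/site key).
    anatomical_site
        Controlled-vocabulary term; see :data:`oralmsi.bands.ANATOMICAL_SITES`.
    saturation_mask
        Boolean array, ``True`` where any band hit full scale (specular
        highlights, overexposure).  Saturated pixels are excluded from all
        downstream statistics.
    bit_depth
        Bit depth of the raw frames (metadata only).
    extra
        Unknown sidecar keys, preserved on round-trip.
    """

    images: dict[SpectralBand, np.ndarray]
    exposures: dict[SpectralBand, float]
    site_id: str
    anatomical_site: str
    saturation_mask: np.ndarray
    bit_depth: int = 16
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [b for b in ALL_BANDS if b not in self.images]
        if missing:
            raise ValueError(f"missing band image(s): {[b.value for b in missing]}")
        shapes = {b: np.asarray(im).shape for b, im in self.images.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"band images have mismatched dimensions: {shapes}")
        for b, im in self.images.items():
            arr = np.asarray(im, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"{b.value}: expected a 2-D grayscale image")
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{b.value}: intensities must lie in [0, 1]")
            self.images[b] = arr
        if self.anatomical_site not in ANATOMICAL_SITES:
            raise ValueError(f"unknown anatomical site: {self.anatomical_site!r}")
        self.saturation_mask = np.asarray(self.saturation_mask, dtype=bool)
        if self.saturation_mask.shape != first:
            raise ValueError("saturation_mask dimensions differ from the images")
        for b, e in self.exposures.items():
            if not e > 0:
                raise ValueError(f"exposure for {b.value} must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[SpectralBand.R545].shape

    @property
    def site_group(self) -> str:
        return site_group(self.anatomical_site)


@dataclass(frozen=True)
class RegionOfInterest:
    """A closed polygon drawn on the image, in pixel coordinates.

    Coordinates are 0-based with pixel centers at integer positions,
    x rightward and y downward; the polygon is implicitly closed.
    """

    label: str  # "lesion" | "healthy"
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.label not in ("lesion", "healthy"):
            raise ValueError(f"ROI label must be 'lesion' or 'healthy', got {self.label!r}")
        if len(self.vertices) < 3:
            raise ValueError("an ROI polygon needs at least 3 vertices")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )


@dataclass(frozen=True)
class ScoreRecord:
    """One site's scalar R610/R545 lesion statistic with its pathology label."""

    site_id: str
    anatomical_site: str
    score: float
    label: str  # "normal" | "OPML" | "SCC"
    source: str = "patient"  # "patient" | "healthy_volunteer"

    def __post_init__(self) -> None:
        if not self.score > 0:
            raise ValueError(f"score must be positive, got {self.score}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {VALID_LABELS}")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {VALID_SOURCES}")


# ---------------------------------------------------------------------------
# Capture-set directory I/O


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))


def read_capture_set(directory: str | Path) -> MultispectralCaptureSet:
    """Read a capture-set directory (four band images + JSON sidecar).

    Integer pixel values are normalized by the sidecar bit depth's maximum;
    pixels at full scale are flagged in the saturation mask.
    """
    directory = Path(directory)
    sidecar_path = directory / _SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    for key in _SIDECAR_KEYS:
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} lacks required key {key!r}")

    bit_depth = int(meta["bit_depth"])
    full_scale = 2**bit_depth - 1
    images: dict[SpectralBand, np.ndarray] = {}
    saturated: np.ndarray | None = None
    for band_name, file_name in meta["bands"].items():
        band = SpectralBand(band_name)
        path = directory / file_name
        if not path.exists():
            raise FileNotFoundError(f"missing band file for {band.value}: {path}")
        raw = _read_image(path)
        if np.issubdtype(raw.dtype, np.integer):
            sat = raw >= full_scale
            img = raw.astype(float) / full_scale
        else:  # float images are assumed already normalized
            img = raw.astype(float)
            sat = img >= 1.0
        if images and img.shape != next(iter(images.values())).shape:
            raise ValueError(
                f"band images have mismatched dimensions: {band.value} is "
                f"{img.shape}, expected {next(iter(images.values())).shape}"
            )
        images[band] = img
        saturated = sat if saturated is None else (saturated | sat)

    exposures = {SpectralBand(b): float(e) for b, e in meta["exposures"].items()}
    extra = {k: v for k, v in meta.items() if k not in _SIDECAR_KEYS}
    return MultispectralCaptureSet(
        images=images,
        exposures=exposures,
        site_id=str(meta["site_id"]),
        anatomical_site=str(meta["anatomical_site"]),
        saturation_mask=saturated,
        bit_depth=bit_depth,
        extra=extra,
    )


def write_capture_set(capture: MultispectralCaptureSet, directory: str | Path) -> Path:
    """Write a capture set as one 16/8-bit TIFF per band plus the JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    full_scale = 2**capture.bit_depth - 1
    dtype = np.uint16 if capture.bit_depth > 8 else np.uint8
    band_files = {}
    for band, img in capture.images.items():
        file_name = f"{band.value}.tiff"
        raw = np.rint(np.clip(img, 0.0, 1.0) * full_scale).astype(dtype)
        tifffile.imwrite(directory / file_name, raw)
        band_files[band.value] = file_name
    meta = {
        "bands": band_files,
        "exposures": {b.value: e for b, e in capture.exposures.items()},
        "site_id": capture.site_id,
        "anatomical_site": capture.anatomical_site,
        "bit_depth": capture.bit_depth,
        **capture.extra,
    }
    sidecar = directory / _SIDECAR_NAME
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return directory


# ---------------------------------------------------------------------------
# ROI rasterization and I/O


def rasterize_roi(roi: RegionOfInterest, width: int, height: int) -> np.ndarray:
    """Rasterize a polygon ROI onto a ``height x width`` boolean grid.

    A pixel is inside when its center (integer coordinates) falls inside the
    polygon under even-odd fill, decided by a crossing-number test on the
    ray running in +x from the center.
    """
    if width < 1 or height < 1:
        raise ValueError("width and height must be >= 1")
    verts = np.asarray(roi.vertices, dtype=float)
    if (
        verts[:, 0].min() < 0
        or verts[:, 0].max() >= width
        or verts[:, 1].min() < 0
        or verts[:, 1].max() >= height
    ):
        raise ValueError("ROI vertex outside image bounds")

    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    px, py = np.meshgrid(xs, ys)  # (H, W)

    x1 = verts[:, 0]
    y1 = verts[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)

    inside = np.zeros((height, width), dtype=bool)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:  # horizontal edges never cross the +x ray
            continue
        # Half-open in y so shared vertices count once.
        straddles = (ey1 > py) != (ey2 > py)
        x_at = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= straddles & (px < x_at)
    return inside


def read_rois(path: str | Path) -> list[RegionOfInterest]:
    """Read a JSON list of ``{"label": ..., "vertices": [[x, y], ...]}``."""
    data = json.loads(Path(path).read_text())
    return [
        RegionOfInterest(label=item["label"], vertices=tuple(map(tuple, item["vertices"])))
        for item in data
    ]


def write_rois(rois: Iterable[RegionOfInterest], path: str | Path) -> None:
    payload = [
        {"label": roi.label, "vertices": [list(v) for v in roi.vertices]} for roi in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Score tables

_SCORE_COLUMNS = ["site_id", "anatomical_site", "score", "label", "source"]


def write_score_table(records: Sequence[ScoreRecord], path: str | Path) -> None:
    """Write score records as CSV with a fixed header (lossless round-trip)."""
    df = pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "anatomical_site": r.anatomical_site,
                "score": r.score,
                "label": r.label,
                "source": r.source,
            }
            for r in records
        ],
        columns=_SCORE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_score_table(path: str | Path) -> list[ScoreRecord]:
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table {path} lacks column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        if row["label"] not in VALID_LABELS:
            raise ValueError(f"row {i}: unknown label {row['label']!r}")
        records.append(
            ScoreRecord(
                site_id=str(row["site_id"]),
                anatomical_site=str(row["anatomical_site"]),
                score=float(row["score"]),
                label=str(row["label"]),
                source=str(row["source"]),
            )
        )
    return records


def scores_by_label(
    records: Iterable[ScoreRecord],
) -> dict[str, list[float]]:
    """Group scores by pathology label."""
    out: dict[str, list[float]] = {}
    for r in records:
        out.setdefault(r.label, []).append(r.score)
    return out
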