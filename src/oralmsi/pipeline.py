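"""End-to-end screening pipeline for one imaged site.

Mirrors the device workflow: read the four-band capture, build the three
diffuse-reflectance ratio maps, locate the lesion hotspot and score it,
take the healthy-mucosa references, classify against a threshold model and
write a JSON report plus pseudo-color renderings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio

from . import __version__
from .bands import SpectralBand
from .classify import ThresholdModel, classify
from .imageset import RegionOfInterest, read_capture_set, read_rois
from .ratio import MIN_DENOMINATOR, PseudoColorParams, compute_ratio_map, pseudo_color
from .scoring import healthy_reference, score_lesion

#: Ratio maps computed for every site, as (numerator, denominator) pairs.
RATIO_KINDS = (
    (SpectralBand.R610, SpectralBand.R545),
    (SpectralBand.R610, SpectralBand.R575),
    (SpectralBand.R545, SpectralBand.R575),
)


@dataclass
class RunConfig:
    """Knobs for one pipeline run; hashed into every report."""

    min_denominator: float = MIN_DENOMINATOR
    healthy_window: int = 7
    display_min: float = 0.0
    display_max: float = 4.0
    colormap: str = "viridis"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "min_denominator": self.min_denominator,
            "healthy_window": self.healthy_window,
            "display_min": self.display_min,
            "display_max": self.display_max,
            "colormap": self.colormap,
            "seed": self.seed,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})


def run_pipeline(
    capture_dir: str | Path,
    roi_file: str | Path,
    model_file: str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Process one capture set end to end and return the site report.

    The ROI file must contain one ``lesion`` polygon; a ``healthy``
    polygon is used for the reference means when present.  When
    ``out_dir`` is given, the report JSON and pseudo-color PNGs are
    written there; the JSON is byte-stable across identical runs.
    """
    config = config or RunConfig()
    capture_dir = Path(capture_dir)
    roi_file = Path(roi_file)
    model_file = Path(model_file)
    for path, what in ((roi_file, "ROI file"), (model_file, "model file")):
        if not path.exists():
            raise FileNotFoundError(f"{what} not found: {path}")

    capture = read_capture_set(capture_dir)
    rois = read_rois(roi_file)
    lesion_rois = [r for r in rois if r.label == "lesion"]
    healthy_rois = [r for r in rois if r.label == "healthy"]
    if not lesion_rois:
        raise ValueError(f"no lesion ROI in {roi_file}")
    lesion_roi: RegionOfInterest = lesion_rois[0]
    model = ThresholdModel.load(model_file)

    maps = {
        f"{num.value}/{den.value}": compute_ratio_map(
            capture, num, den, min_denominator=config.min_denominator
        )
        for num, den in RATIO_KINDS
    }
    primary = maps["R610/R545"]
    inflammation = maps["R610/R575"]

    score = score_lesion(primary, lesion_roi, site_id=capture.site_id)
    references: dict[str, float | None] = {"R610/R545": None, "R610/R575": None}
    if healthy_rois:
        references["R610/R545"] = healthy_reference(primary, healthy_rois[0])
        references["R610/R575"] = healthy_reference(inflammation, healthy_rois[0])
    tissue_class, color = classify(score.score, model)

    lesion_scores = {
        kind: score_lesion(m, lesion_roi, site_id=capture.site_id).score
        for kind, m in maps.items()
    }

    report = {
        "site_id": capture.site_id,
        "anatomical_site": capture.anatomical_site,
        "site_group": capture.site_group,
        "scores": lesion_scores,
        "hotspot": {"x": score.hotspot[0], "y": score.hotspot[1]},
        "n_window_pixels": score.n_window_pixels,
        "healthy_reference": references,
        "classification": {"class": tissue_class, "color": color},
        "model": {"group": model.group, "version": model.version,
                  "t_opml": model.t_opml, "t_scc": model.t_scc},
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        params = PseudoColorParams(
            colormap_name=config.colormap,
            display_min=config.display_min,
            display_max=config.display_max,
        )
        for kind, m in maps.items():
            name = kind.replace("/", "_over_")
            iio.imwrite(out_dir / f"pcm_{name}.png", pseudo_color(m, params))
    return report
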