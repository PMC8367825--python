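"""ROI hotspot scoring.

The device reduces a lesion to one number: within the clinician-drawn ROI
it finds the pixel with the maximal R610/R545 ratio (the presumptive most
malignant site, and the suggested biopsy spot) and reports the mean of the
5x5 window centered there.  A reference mean is taken over an adjoining
healthy ROI, which should be free of inflammation — i.e. have a low
R610/R575 ratio — and this module can also propose such a region
automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imageset import RegionOfInterest, rasterize_roi
from .ratio import RatioMap

WINDOW = 5  # hotspot averaging window (pixels, square)


@dataclass
class LesionScore:
    """Scalar lesion statistic for one ROI.

    ``score`` is the mean ratio over the valid pixels of the 5x5 window
    centered at ``hotspot`` (the valid in-ROI argmax); ``n_window_pixels``
    counts the pixels that entered that mean.
    """

    site_id: str
    ratio_kind: str
    hotspot: tuple[int, int]  # (x, y)
    score: float
    n_window_pixels: int
    healthy_reference: float | None = None
    inflammation_reference: float | None = None


def _roi_mask(ratio_map: RatioMap, roi: RegionOfInterest) -> np.ndarray:
    h, w = ratio_map.shape
    return rasterize_roi(roi, w, h)


def score_lesion(
    ratio_map: RatioMap, lesion_roi: RegionOfInterest, site_id: str = ""
) -> LesionScore:
    """Hotspot score: 5x5 window mean around the in-ROI ratio maximum.

    The hotspot is the valid in-ROI pixel with the largest ratio (ties go
    to the smallest row-major index).  The window is clipped at image
    borders and restricted to valid pixels; window pixels need not lie in
    the ROI.
    """
    mask = _roi_mask(ratio_map, lesion_roi) & ratio_map.valid_mask
    if not mask.any():
        raise ValueError("lesion ROI contains no valid pixel")
    candidates = np.where(mask, ratio_map.values, -np.inf)
    flat_idx = int(np.argmax(candidates))  # first max in row-major order
    hy, hx = np.unravel_index(flat_idx, ratio_map.shape)

    half = WINDOW // 2
    h, w = ratio_map.shape
    y0, y1 = max(hy - half, 0), min(hy + half + 1, h)
    x0, x1 = max(hx - half, 0), min(hx + half + 1, w)
    win_vals = ratio_map.values[y0:y1, x0:x1]
    win_valid = ratio_map.valid_mask[y0:y1, x0:x1]
    n = int(win_valid.sum())
    score = float(win_vals[win_valid].mean())
    return LesionScore(
        site_id=site_id,
        ratio_kind=ratio_map.kind,
        hotspot=(int(hx), int(hy)),
        score=score,
        n_window_pixels=n,
    )


def healthy_reference(ratio_map: RatioMap, healthy_roi: RegionOfInterest) -> float:
    """Mean ratio over the valid pixels of a healthy-mucosa ROI."""
    mask = _roi_mask(ratio_map, healthy_roi) & ratio_map.valid_mask
    if not mask.any():
        raise ValueError("healthy ROI contains no valid pixel")
    return float(ratio_map.values[mask].mean())


def suggest_healthy_roi(
    inflammation_map: RatioMap,
    lesion_roi: RegionOfInterest,
    window_size: int = 7,
) -> RegionOfInterest:
    """Propose a healthy reference region: the coolest inflammation window.

    Scans every ``window_size`` square fully outside the lesion ROI whose
    pixels are all valid, and returns the one with the minimal mean
    R610/R575 ratio as a rectangular ROI (ties go to the smallest
    row-major corner).
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd integer >= 3")
    h, w = inflammation_map.shape
    if window_size > min(h, w):
        raise ValueError("window_size exceeds image dimensions")
    lesion_mask = _roi_mask(inflammation_map, lesion_roi)

    from numpy.lib.stride_tricks import sliding_window_view

    vals = sliding_window_view(inflammation_map.values, (window_size, window_size))
    valid = sliding_window_view(inflammation_map.valid_mask, (window_size, window_size))
    lesion = sliding_window_view(lesion_mask, (window_size, window_size))
    ok = valid.all(axis=(2, 3)) & ~lesion.any(axis=(2, 3))
    if not ok.any():
        raise ValueError("no all-valid window lies fully outside the lesion ROI")
    means = np.where(ok, vals.mean(axis=(2, 3)), np.inf)
    flat = int(np.argmin(means))  # first min in row-major corner order
    cy, cx = np.unravel_index(flat, means.shape)
    # Rectangle enclosing exactly the window's pixel centers (low edges are
    # clipped at 0 for corner windows; a center on the left/top edge still
    # rasterizes as inside under the even-odd crossing test).
    x_lo = max(cx - 0.4, 0.0)
    y_lo = max(cy - 0.4, 0.0)
    x_hi = cx + window_size - 1 + 0.4
    y_hi = cy + window_size - 1 + 0.4
    return RegionOfInterest(
        label="healthy",
        vertices=((x_lo, y_lo), (x_hi, y_lo), (x_hi, y_hi), (x_lo, y_hi)),
    )
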