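"""Ambient-light exposure calibration.

Before screening, the device balances the four LED channels by adjusting
per-band camera exposures over a tissue phantom until the mean pixel
intensities of the four frames agree to within a tolerance of their joint
mean.  The tolerance band runs from 2.5% to 4%: strict on the first
attempt, relaxing linearly toward 4% as retries accumulate.  A global
exposure rescale drives the operating level toward mid-scale (0.5) so the
frames are neither starved nor saturated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .bands import ALL_BANDS, SpectralBand

TOLERANCE_MIN = 0.025
TOLERANCE_MAX = 0.04
TARGET_LEVEL = 0.5
STEP_CLIP = (0.1, 10.0)

CaptureFn = Callable[[SpectralBand, float], np.ndarray]


@dataclass
class ExposureSettings:
    """Per-band exposure multipliers (all positive)."""

    exposure: dict[SpectralBand, float] = field(
        default_factory=lambda: {b: 1.0 for b in ALL_BANDS}
    )

    def __post_init__(self) -> None:
        for band, e in self.exposure.items():
            if not e > 0:
                raise ValueError(f"exposure for {band.value} must be positive")


@dataclass
class CalibrationResult:
    settings: ExposureSettings
    retries_used: int
    tolerance_applied: float
    frame_means: dict[SpectralBand, float]
    converged: bool


def retry_tolerance(retry: int, max_retries: int) -> float:
    """Tolerance for 0-indexed ``retry``: linear from 2.5% to 4% across retries."""
    if max_retries <= 1:
        return TOLERANCE_MIN
    frac = min(retry, max_retries - 1) / (max_retries - 1)
    return TOLERANCE_MIN + (TOLERANCE_MAX - TOLERANCE_MIN) * frac


def _clip_step(factor: float) -> float:
    return float(np.clip(factor, *STEP_CLIP))


def calibrate(
    capture_fn: CaptureFn,
    initial: ExposureSettings | None = None,
    max_retries: int = 5,
) -> CalibrationResult:
    """Balance per-band exposures until all four frame means agree.

    Each retry captures all four frames at the current exposures, computes
    the grand mean of the frame means, and stops if every frame mean is
    within the retry's tolerance of the grand mean.  Otherwise exposures
    are rescaled multiplicatively — a global factor driving the level to
    0.5, then a per-band factor ``grand_mean / frame_mean`` — with each
    factor clipped to [0.1x, 10x].  Fully saturated frames never count as
    converged.
    """
    if max_retries < 1:
        raise ValueError("max_retries must be >= 1")
    exposures = dict((initial or ExposureSettings()).exposure)

    best_means: dict[SpectralBand, float] = {}
    for retry in range(max_retries):
        means = {}
        pinned = False
        for band in ALL_BANDS:
            frame = np.asarray(capture_fn(band, exposures[band]), dtype=float)
            if frame.size == 0:
                raise ValueError(f"capture for {band.value} returned an empty frame")
            means[band] = float(frame.mean())
            pinned |= bool((frame >= 1.0).all())
        best_means = means
        grand = float(np.mean(list(means.values())))
        tol = retry_tolerance(retry, max_retries)
        balanced = grand > 0 and all(
            abs(m - grand) <= tol * grand for m in means.values()
        )
        if balanced and not pinned:
            # Leave the operating level at mid-scale for the returned settings.
            level_factor = _clip_step(TARGET_LEVEL / grand)
            settings = ExposureSettings({b: e * level_factor for b, e in exposures.items()})
            return CalibrationResult(
                settings=settings,
                retries_used=retry,
                tolerance_applied=tol,
                frame_means=means,
                converged=True,
            )
        # Global level drive first, then per-band balancing.
        level_factor = _clip_step(TARGET_LEVEL / grand) if grand > 0 else STEP_CLIP[1]
        for band in ALL_BANDS:
            band_factor = _clip_step(grand / means[band]) if means[band] > 0 else STEP_CLIP[1]
            exposures[band] *= level_factor * band_factor

    return CalibrationResult(
        settings=ExposureSettings(exposures),
        retries_used=max_retries,
        tolerance_applied=retry_tolerance(max_retries - 1, max_retries),
        frame_means=best_means,
        converged=False,
    )


def linear_camera(
    gains: dict[SpectralBand, float], level: float = 0.05, shape: tuple[int, int] = (8, 8)
) -> CaptureFn:
    """Simulated camera whose frame mean is ``min(gain * exposure * level, 1)``.

    A convenience for tests and the CLI; clips at full scale like a real
    sensor.
    """

    def fn(band: SpectralBand, exposure: float) -> np.ndarray:
        value = min(gains[band] * exposure * level, 1.0)
        return np.full(shape, value)

    return fn
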