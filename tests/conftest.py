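import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oralmsi import ALL_BANDS, MultispectralCaptureSet, SpectralBand

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_capture(
    images: dict[SpectralBand, np.ndarray] | None = None,
    shape: tuple[int, int] = (16, 16),
    fill: float = 0.5,
    saturation=None,
    anatomical_site: str = "buccal_mucosa_left",
) -> MultispectralCaptureSet:
    """Minimal in-memory capture set for unit tests."""
    if images is None:
        images = {b: np.full(shape, fill) for b in ALL_BANDS}
    else:
        shape = next(iter(images.values())).shape
        for b in ALL_BANDS:
            images.setdefault(b, np.full(shape, fill))
    if saturation is None:
        saturation = np.zeros(shape, dtype=bool)
    return MultispectralCaptureSet(
        images=images,
        exposures={b: 1.0 for b in ALL_BANDS},
        site_id="test",
        anatomical_site=anatomical_site,
        saturation_mask=saturation,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20211)
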