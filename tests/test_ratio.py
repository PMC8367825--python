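"""Ratio maps, chromophore inversion and pseudo-color rendering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oralmsi import (
    Lesion,
    OpticalProperties,
    PhantomScene,
    PseudoColorParams,
    SpectralBand,
    compute_ratio_map,
    forward_reflectance,
    invert_chromophores,
    pseudo_color,
)
from oralmsi.ratio import INVALID_RGB
from conftest import make_capture


class TestComputeRatioMap:
    def test_constant_division(self):
        cap = make_capture(
            {SpectralBand.R610: np.full((8, 8), 0.5), SpectralBand.R545: np.full((8, 8), 0.25)}
        )
        rm = compute_ratio_map(cap, SpectralBand.R610, SpectralBand.R545)
        assert rm.valid_mask.all()
        np.testing.assert_allclose(rm.values, 2.0)

    def test_identity_ratio(self):
        cap = make_capture(fill=0.3)
        rm = compute_ratio_map(cap, SpectralBand.R545, SpectralBand.R545)
        np.testing.assert_allclose(rm.values[rm.valid_mask], 1.0)

    def test_fluorescence_band_rejected(self):
        cap = make_capture()
        with pytest.raises(ValueError, match="fluorescence"):
            compute_ratio_map(cap, SpectralBand.F405, SpectralBand.R545)

    def test_dark_denominator_and_saturation_invalidated(self):
        num = np.full((4, 4), 0.5)
        den = np.full((4, 4), 0.5)
        den[0, 0] = 1e-4  # below the 1/255 floor
        sat = np.zeros((4, 4), dtype=bool)
        sat[1, 1] = True
        cap = make_capture({SpectralBand.R610: num, SpectralBand.R545: den}, saturation=sat)
        rm = compute_ratio_map(cap, SpectralBand.R610, SpectralBand.R545)
        assert not rm.valid_mask[0, 0] and rm.values[0, 0] == 0.0
        assert not rm.valid_mask[1, 1] and rm.values[1, 1] == 0.0
        assert rm.valid_mask.sum() == 14

    def test_matches_scalar_loop_oracle(self, rng):
        """Elementwise equality with an independent per-pixel division loop
        on 100 random 16x16 band pairs."""
        for _ in range(100):
            num = rng.uniform(0, 1, (16, 16))
            den = rng.uniform(0, 1, (16, 16))
            cap = make_capture({SpectralBand.R610: num, SpectralBand.R545: den})
            rm = compute_ratio_map(cap, SpectralBand.R610, SpectralBand.R545)
            for i in range(16):
                for j in range(16):
                    if den[i, j] >= 1 / 255:
                        assert rm.valid_mask[i, j]
                        assert rm.values[i, j] == num[i, j] / den[i, j]
                    else:
                        assert not rm.valid_mask[i, j]

    def test_reciprocity(self, rng):
        num = rng.uniform(0.1, 1, (12, 12))
        den = rng.uniform(0.1, 1, (12, 12))
        cap = make_capture({SpectralBand.R610: num, SpectralBand.R545: den})
        ab = compute_ratio_map(cap, SpectralBand.R610, SpectralBand.R545)
        ba = compute_ratio_map(cap, SpectralBand.R545, SpectralBand.R610)
        both = ab.valid_mask & ba.valid_mask
        np.testing.assert_allclose(ab.values[both] * ba.values[both], 1.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        num = rng.uniform(0.1, 0.4, (8, 8))
        den = rng.uniform(0.1, 0.4, (8, 8))
        cap1 = make_capture({SpectralBand.R610: num, SpectralBand.R545: den})
        cap2 = make_capture({SpectralBand.R610: 2 * num, SpectralBand.R545: 2 * den})
        rm1 = compute_ratio_map(cap1, SpectralBand.R610, SpectralBand.R545)
        rm2 = compute_ratio_map(cap2, SpectralBand.R610, SpectralBand.R545)
        np.testing.assert_allclose(rm1.values, rm2.values, rtol=1e-12)


class TestInvertChromophores:
    def test_zero_absorption_gives_zero_concentrations(self):
        props = OpticalProperties()
        cap = make_capture(
            {
                SpectralBand.R545: np.full((8, 8), props.baseline[SpectralBand.R545]),
                SpectralBand.R610: np.full((8, 8), props.baseline[SpectralBand.R610]),
            }
        )
        maps = invert_chromophores(cap, props)
        np.testing.assert_allclose(maps.c_hbo2, 0.0, atol=1e-12)
        np.testing.assert_allclose(maps.c_hb, 0.0, atol=1e-12)
        assert np.isnan(maps.sto2).all()  # tHb = 0 leaves StO2 undefined

    def test_phantom_parameter_recovery(self):
        """Noise-free forward output inverts back to the true concentration
        maps within 1e-6 mM at every non-saturated pixel (128x128)."""
        scene = PhantomScene(
            width=128,
            height=128,
            lesions=[
                Lesion(center=(40, 60), axes=(20, 14), grade="OPML", target_ratio=3.0),
                Lesion(center=(95, 40), axes=(12, 18), grade="SCC", target_ratio=4.5),
            ],
        )
        cap, truth = forward_reflectance(scene)
        maps = invert_chromophores(cap)
        ok = ~cap.saturation_mask
        assert np.abs(maps.c_hbo2 - truth.c_hbo2)[ok].max() < 1e-6
        assert np.abs(maps.c_hb - truth.c_hb)[ok].max() < 1e-6

    def test_pure_oxyhemoglobin_pixel(self):
        props = OpticalProperties()
        c = 0.08
        cap = make_capture(
            {
                SpectralBand.R545: np.full((4, 4), float(props.reflectance(SpectralBand.R545, c, 0.0))),
                SpectralBand.R610: np.full((4, 4), float(props.reflectance(SpectralBand.R610, c, 0.0))),
            }
        )
        maps = invert_chromophores(cap, props)
        np.testing.assert_allclose(maps.sto2, 1.0, atol=1e-6)

    def test_inversion_linearity(self):
        """Doubling both true concentrations doubles recovered tHb."""
        props = OpticalProperties()

        def capture_for(c_hbo2, c_hb):
            return make_capture(
                {
                    SpectralBand.R545: np.full(
                        (4, 4), float(props.reflectance(SpectralBand.R545, c_hbo2, c_hb))
                    ),
                    SpectralBand.R610: np.full(
                        (4, 4), float(props.reflectance(SpectralBand.R610, c_hbo2, c_hb))
                    ),
                }
            )

        thb1 = invert_chromophores(capture_for(0.03, 0.01), props).thb[0, 0]
        thb2 = invert_chromophores(capture_for(0.06, 0.02), props).thb[0, 0]
        assert thb2 == pytest.approx(2 * thb1, rel=1e-9)

    def test_negative_solutions_clipped_and_flagged(self):
        props = OpticalProperties()
        # R545 above baseline is unphysical under the model -> negative C.
        cap = make_capture(
            {
                SpectralBand.R545: np.full((4, 4), 0.95),
                SpectralBand.R610: np.full((4, 4), props.baseline[SpectralBand.R610]),
            }
        )
        maps = invert_chromophores(cap, props)
        assert maps.clip_mask.all()
        assert (maps.c_hbo2 >= 0).all() and (maps.c_hb >= 0).all()

    def test_sto2_bounded_where_defined(self, rng):
        cap = make_capture(
            {
                SpectralBand.R545: rng.uniform(0.05, 0.9, (16, 16)),
                SpectralBand.R610: rng.uniform(0.05, 0.9, (16, 16)),
            }
        )
        maps = invert_chromophores(cap)
        defined = ~np.isnan(maps.sto2)
        assert ((maps.sto2[defined] >= 0) & (maps.sto2[defined] <= 1)).all()


class TestPseudoColor:
    def test_uniform_at_display_min(self):
        img = pseudo_color(np.zeros((4, 4)), PseudoColorParams(display_min=0, display_max=1))
        assert (img == img[0, 0]).all()

    def test_monotone_rendering_order(self):
        params = PseudoColorParams(colormap_name="viridis", display_min=0, display_max=1)
        img = pseudo_color(np.array([[0.2, 0.8]]), params)
        # viridis brightens with value; compare luminance
        lum = img.astype(float) @ np.array([0.299, 0.587, 0.114])
        assert lum[0, 1] > lum[0, 0]

    def test_clamping_above_display_max(self):
        params = PseudoColorParams(display_min=0, display_max=1)
        img = pseudo_color(np.array([[1.0, 7.0]]), params)
        assert (img[0, 0] == img[0, 1]).all()

    def test_invalid_pixels_render_neutral(self):
        from oralmsi import RatioMap

        rm = RatioMap(
            numerator_band=SpectralBand.R610,
            denominator_band=SpectralBand.R545,
            values=np.array([[2.0, 0.0]]),
            valid_mask=np.array([[True, False]]),
        )
        img = pseudo_color(rm)
        assert tuple(img[0, 1]) == INVALID_RGB

    def test_degenerate_display_range_rejected(self):
        with pytest.raises(ValueError):
            PseudoColorParams(display_min=1.0, display_max=1.0)


@given(
    st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4),
    st.floats(1.1, 5.0),
)
def test_ratio_scale_invariance_property(values, factor):
    """Multiplying both bands by one constant leaves the ratio unchanged
    wherever both versions are valid."""
    num = np.array(values).reshape(2, 2)
    den = num[::-1]
    cap1 = make_capture({SpectralBand.R610: num, SpectralBand.R545: den})
    scaled_num = np.clip(num / factor, 0, 1)
    scaled_den = np.clip(den / factor, 0, 1)
    cap2 = make_capture({SpectralBand.R610: scaled_num, SpectralBand.R545: scaled_den})
    rm1 = compute_ratio_map(cap1, SpectralBand.R610, SpectralBand.R545)
    rm2 = compute_ratio_map(cap2, SpectralBand.R610, SpectralBand.R545)
    both = rm1.valid_mask & rm2.valid_mask
    np.testing.assert_allclose(rm1.values[both], rm2.values[both], rtol=1e-9)
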