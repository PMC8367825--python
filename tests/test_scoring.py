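"""ROI hotspot scoring against brute-force oracles."""

import numpy as np
import pytest

from oralmsi import (
    RatioMap,
    RegionOfInterest,
    SpectralBand,
    healthy_reference,
    rasterize_roi,
    score_lesion,
    suggest_healthy_roi,
)


def ratio_map(values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return RatioMap(
        numerator_band=SpectralBand.R610,
        denominator_band=SpectralBand.R545,
        values=values,
        valid_mask=np.asarray(valid, dtype=bool),
    )


def rect_roi(x0, y0, x1, y1, label="lesion"):
    return RegionOfInterest(label, ((x0, y0), (x1, y0), (x1, y1), (x0, y1)))


def oracle_score(rm: RatioMap, roi: RegionOfInterest):
    """Independent scalar reimplementation: enumerate every in-ROI valid
    pixel, pick the max (row-major ties), average the clipped 5x5 window."""
    h, w = rm.shape
    mask = rasterize_roi(roi, w, h)
    best = None
    for y in range(h):
        for x in range(w):
            if mask[y, x] and rm.valid_mask[y, x]:
                if best is None or rm.values[y, x] > rm.values[best[1], best[0]]:
                    best = (x, y)
    assert best is not None
    bx, by = best
    vals = []
    for y in range(max(by - 2, 0), min(by + 3, h)):
        for x in range(max(bx - 2, 0), min(bx + 3, w)):
            if rm.valid_mask[y, x]:
                vals.append(rm.values[y, x])
    return best, sum(vals) / len(vals), len(vals)


class TestScoreLesion:
    def test_uniform_field(self):
        rm = ratio_map(np.full((20, 20), 2.5))
        score = score_lesion(rm, rect_roi(4.5, 4.5, 15.5, 15.5))
        assert score.score == pytest.approx(2.5)
        assert score.n_window_pixels == 25

    def test_single_hotspot_arithmetic(self):
        vals = np.ones((20, 20))
        vals[10, 10] = 5.0
        rm = ratio_map(vals)
        score = score_lesion(rm, rect_roi(5.5, 5.5, 14.5, 14.5))
        assert score.hotspot == (10, 10)
        assert score.score == pytest.approx((24 * 1.0 + 5.0) / 25)  # 1.16
        assert score.n_window_pixels == 25

    def test_window_includes_out_of_roi_pixels(self):
        vals = np.ones((10, 10))
        vals[5, 5] = 3.0
        vals[5, 7] = 9.0  # outside ROI but inside the 5x5 window
        rm = ratio_map(vals)
        roi = rect_roi(3.6, 3.6, 6.4, 6.4)  # centers 4..6 only
        score = score_lesion(rm, roi)
        assert score.hotspot == (5, 5)
        assert score.score == pytest.approx((23 * 1.0 + 3.0 + 9.0) / 25)

    def test_border_window_clipped(self):
        vals = np.ones((10, 10))
        vals[0, 0] = 4.0
        rm = ratio_map(vals)
        score = score_lesion(rm, rect_roi(0.0, 0.0, 2.4, 2.4))
        assert score.hotspot == (0, 0)
        assert score.n_window_pixels == 9  # 3x3 after clipping
        assert score.score == pytest.approx((8 * 1.0 + 4.0) / 9)

    def test_invalid_pixels_excluded(self):
        vals = np.ones((10, 10))
        vals[5, 5] = 2.0
        vals[5, 6] = 50.0  # higher but invalid -> cannot be the hotspot
        valid = np.ones((10, 10), dtype=bool)
        valid[5, 6] = False
        rm = ratio_map(vals, valid)
        score = score_lesion(rm, rect_roi(3.5, 3.5, 7.5, 7.5))
        assert score.hotspot == (5, 5)
        assert score.n_window_pixels == 24

    def test_no_valid_pixel_errors(self):
        rm = ratio_map(np.ones((8, 8)), np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="no valid pixel"):
            score_lesion(rm, rect_roi(2.5, 2.5, 5.5, 5.5))

    def test_row_major_tie_break(self):
        vals = np.ones((10, 10))
        vals[6, 3] = 2.0
        vals[4, 7] = 2.0  # earlier row wins
        rm = ratio_map(vals)
        score = score_lesion(rm, rect_roi(1.5, 1.5, 8.5, 8.5))
        assert score.hotspot == (7, 4)

    def test_matches_exhaustive_oracle(self, rng):
        """Equality with the brute-force enumeration on 50 random maps and
        rectangular ROIs with random invalid pixels."""
        for _ in range(50):
            h, w = int(rng.integers(8, 20)), int(rng.integers(8, 20))
            vals = rng.uniform(0.5, 5.0, (h, w))
            valid = rng.uniform(size=(h, w)) > 0.1
            rm = ratio_map(vals, valid)
            x0 = rng.uniform(0, w - 4)
            y0 = rng.uniform(0, h - 4)
            roi = rect_roi(x0, y0, min(x0 + rng.uniform(2, w), w - 0.51),
                           min(y0 + rng.uniform(2, h), h - 0.51))
            mask = rasterize_roi(roi, w, h) & valid
            if not mask.any():
                continue
            score = score_lesion(rm, roi)
            (bx, by), expected, n = oracle_score(rm, roi)
            assert score.hotspot == (bx, by)
            assert score.score == pytest.approx(expected)
            assert score.n_window_pixels == n

    def test_monotone_in_roi_pixels(self, rng):
        """Raising any in-ROI pixel never lowers the score."""
        vals = rng.uniform(1.0, 2.0, (12, 12))
        rm = ratio_map(vals.copy())
        roi = rect_roi(2.5, 2.5, 9.5, 9.5)
        base = score_lesion(rm, roi).score
        for _ in range(10):
            y, x = rng.integers(3, 10, 2)
            bumped = vals.copy()
            bumped[y, x] += rng.uniform(0.1, 3.0)
            assert score_lesion(ratio_map(bumped), roi).score >= base - 1e-12

    def test_translation_equivariance(self, rng):
        vals = np.ones((20, 20))
        patch = rng.uniform(1, 3, (4, 4))
        vals[5:9, 5:9] = patch
        shifted = np.ones((20, 20))
        shifted[8:12, 9:13] = patch
        s1 = score_lesion(ratio_map(vals), rect_roi(4.5, 4.5, 9.5, 9.5))
        s2 = score_lesion(ratio_map(shifted), rect_roi(8.5, 7.5, 13.5, 12.5))
        assert s2.score == pytest.approx(s1.score)
        assert s2.hotspot == (s1.hotspot[0] + 4, s1.hotspot[1] + 3)


class TestHealthyReference:
    def test_uniform(self):
        rm = ratio_map(np.full((10, 10), 1.3))
        assert healthy_reference(rm, rect_roi(1.5, 1.5, 7.5, 7.5, "healthy")) == pytest.approx(1.3)

    def test_half_and_half(self):
        vals = np.ones((10, 10))
        vals[:, 5:] = 2.0
        rm = ratio_map(vals)
        roi = rect_roi(3.5, 0.0, 6.5, 9.0, "healthy")  # centers x=4..6 -> 1,1,2... wait
        # centers x in {4,5,6}: one column at 1.0, two at 2.0 -> mean 5/3
        assert healthy_reference(rm, roi) == pytest.approx((1.0 + 2.0 + 2.0) / 3)

    def test_matches_oracle_mean(self, rng):
        vals = rng.uniform(0.5, 4.0, (15, 15))
        valid = rng.uniform(size=(15, 15)) > 0.2
        rm = ratio_map(vals, valid)
        roi = rect_roi(2.5, 3.5, 11.5, 12.5, "healthy")
        mask = rasterize_roi(roi, 15, 15) & valid
        expected = vals[mask].mean()
        assert healthy_reference(rm, roi) == pytest.approx(expected)


class TestSuggestHealthyRoi:
    def test_unique_cool_patch_found(self):
        vals = np.full((30, 30), 2.0)
        vals[20:27, 3:10] = 0.5  # cool 7x7 patch
        rm = ratio_map(vals)
        lesion = rect_roi(12.5, 2.5, 27.5, 12.5)
        roi = suggest_healthy_roi(rm, lesion, window_size=7)
        mask = rasterize_roi(roi, 30, 30)
        ys, xs = np.where(mask)
        assert (xs.min(), xs.max()) == (3, 9)
        assert (ys.min(), ys.max()) == (20, 26)

    def test_forced_choice_when_lesion_covers_rest(self):
        vals = np.full((10, 10), 1.0)
        rm = ratio_map(vals)
        lesion = rect_roi(2.6, 0.0, 9.4, 9.4)  # leaves only columns 0-2 free
        roi = suggest_healthy_roi(rm, lesion, window_size=3)
        mask = rasterize_roi(roi, 10, 10)
        ys, xs = np.where(mask)
        assert xs.max() <= 2

    def test_no_candidate_errors(self):
        rm = ratio_map(np.ones((8, 8)))
        lesion = rect_roi(0.0, 0.0, 7.4, 7.4)
        with pytest.raises(ValueError, match="no all-valid window"):
            suggest_healthy_roi(rm, lesion, window_size=5)

    def test_matches_exhaustive_search_oracle(self, rng):
        """The proposed window has the minimal mean among all fully-valid,
        fully-outside candidates, with row-major corner tie-break."""
        for _ in range(30):
            h = w = 24
            vals = rng.uniform(0.5, 3.0, (h, w))
            valid = rng.uniform(size=(h, w)) > 0.05
            rm = ratio_map(vals, valid)
            lesion = rect_roi(8.5, 8.5, 16.5, 16.5)
            lesion_mask = rasterize_roi(lesion, w, h)
            k = 5
            best = None
            for y0 in range(h - k + 1):
                for x0 in range(w - k + 1):
                    win_valid = valid[y0 : y0 + k, x0 : x0 + k]
                    win_lesion = lesion_mask[y0 : y0 + k, x0 : x0 + k]
                    if win_valid.all() and not win_lesion.any():
                        m = vals[y0 : y0 + k, x0 : x0 + k].mean()
                        if best is None or m < best[0] - 1e-15:
                            best = (m, x0, y0)
            roi = suggest_healthy_roi(rm, lesion, window_size=k)
            mask = rasterize_roi(roi, w, h)
            ys, xs = np.where(mask)
            assert (xs.min(), ys.min()) == (best[1], best[2])
            assert mask.sum() == k * k
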