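"""Vegetation indices, segmentation and plot-level aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soymaturity import synthetic as syn
from soymaturity.features import (
    FEATURE_NAMES,
    SpectralImage,
    compute_vegetation_indices,
    extract_plot_features,
    read_mask_tiff,
    remove_small_regions,
    segment_canopy,
    write_mask_tiff,
)

reflectance = st.floats(min_value=0.01, max_value=1.0, allow_nan=False)


def _hand_indices(b, g, r, re, n):
    """Independent hand evaluation of the seven index formulas."""
    ndvi = (n - r) / (n + r)
    return {
        "CCCI": ((n - re) / (n + re)) / ndvi,
        "MTVI2": 1.5 * (1.2 * (n - g) - 2.5 * (r - g))
        / np.sqrt((2 * n + 1) ** 2 - (6 * n - 5 * np.sqrt(r)) - 0.5),
        "BNDVI": (n - b) / (n + b),
        "GLI": (2 * g - r - b) / (2 * g + r + b),
        "CI": (r - b) / r,
        "H": np.arctan2(2 * r - g - b, np.sqrt(3) * (g - b)),
        "V": max(r, g, b),
    }


class TestVegetationIndices:
    @pytest.mark.parametrize(
        "spectrum",
        [
            (0.1, 0.3, 0.2, 0.4, 0.6),
            (0.04, 0.08, 0.05, 0.30, 0.50),  # green canopy
            (0.09, 0.16, 0.20, 0.28, 0.32),  # senesced canopy
        ],
    )
    def test_matches_hand_evaluation(self, spectrum):
        fv = compute_vegetation_indices(*spectrum)
        hand = _hand_indices(*spectrum)
        for name in FEATURE_NAMES:
            assert fv[name] == pytest.approx(hand[name], abs=1e-12)

    def test_worked_spectrum_values(self):
        # blue .1 green .3 red .2 re .4 nir .6: NDVI = 0.5 and the rest follow
        fv = compute_vegetation_indices(0.1, 0.3, 0.2, 0.4, 0.6)
        assert fv.CCCI == pytest.approx(0.4)
        assert fv.BNDVI == pytest.approx(5 / 7)
        assert fv.GLI == pytest.approx(1 / 3)
        assert fv.CI == pytest.approx(0.5)
        assert fv.H == pytest.approx(0.0)
        assert fv.V == pytest.approx(0.3)

    def test_zero_ccci_numerator(self):
        fv = compute_vegetation_indices(0.1, 0.2, 0.25, 0.5, 0.5)
        assert fv.CCCI == pytest.approx(0.0)

    def test_equal_band_symmetry(self):
        fv = compute_vegetation_indices(0.3, 0.3, 0.3, 0.3, 0.3)
        assert fv.BNDVI == 0.0 and fv.GLI == 0.0 and fv.CI == 0.0
        assert fv.H == 0.0 and "H" in fv.flags  # 0/0 fallback
        assert fv.V == pytest.approx(0.3)

    def test_negative_reflectance_rejected(self):
        with pytest.raises(ValueError):
            compute_vegetation_indices(-0.1, 0.3, 0.2, 0.4, 0.6)

    @settings(max_examples=200, derandomize=True)
    @given(b=reflectance, g=reflectance, r=reflectance, re=reflectance, n=reflectance)
    def test_ranges(self, b, g, r, re, n):
        fv = compute_vegetation_indices(b, g, r, re, n)
        if "BNDVI" not in fv.flags:
            assert -1.0 <= fv.BNDVI <= 1.0
        if "GLI" not in fv.flags:
            assert -1.0 <= fv.GLI <= 1.0
        assert 0.0 <= fv.V <= 1.0

    @settings(max_examples=100, derandomize=True)
    @given(b=reflectance, g=reflectance, r=reflectance, re=reflectance,
           n=reflectance, c=st.floats(min_value=0.1, max_value=3.0))
    def test_scale_invariance(self, b, g, r, re, n, c):
        """Ratio-form indices are invariant to a global gain; V scales."""
        base = compute_vegetation_indices(b, g, r, re, n)
        scaled = compute_vegetation_indices(c * b, c * g, c * r, c * re, c * n)
        for name in ("CCCI", "BNDVI", "GLI", "CI", "H"):
            if name not in base.flags and name not in scaled.flags:
                assert scaled[name] == pytest.approx(base[name], rel=1e-9, abs=1e-9)
        assert scaled.V == pytest.approx(min(c * base.V, 1.0), rel=1e-9)


class TestSegmentation:
    def test_constant_image_returns_empty_mask(self):
        img = SpectralImage.from_stack(np.full((5, 8, 8), 0.2))
        with pytest.warns(UserWarning):
            mask = segment_canopy(img)
        assert not mask.any()

    def test_threshold_two_block(self):
        # left block NDVI 0.8, right block NDVI ~0.05
        stack = np.zeros((5, 4, 8))
        stack[2, :, :4], stack[4, :, :4] = 0.05, 0.45   # red, nir -> NDVI .8
        stack[2, :, 4:], stack[4, :, 4:] = 0.30, 0.332  # NDVI ~.05
        stack[0], stack[1], stack[3] = 0.1, 0.1, 0.1
        mask = segment_canopy(SpectralImage.from_stack(stack), method="threshold",
                              cutoff=0.3)
        assert mask[:, :4].all() and not mask[:, 4:].any()

    def test_chan_vese_recovers_rendered_canopy(self):
        img, true = syn.render_plot_image(-5, syn.ImageSpec(pixel_noise_sd=0.0), seed=0)
        seg = remove_small_regions(segment_canopy(img), min_area=25)
        dice = 2 * np.logical_and(seg, true).sum() / (seg.sum() + true.sum())
        assert dice >= 0.95

    def test_empty_image_rejected(self):
        img = SpectralImage.from_stack(np.zeros((5, 0, 4)))
        with pytest.raises(ValueError):
            segment_canopy(img)


class TestRemoveSmallRegions:
    def test_boundary_inclusive(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, :5] = True
        assert remove_small_regions(mask, min_area=5).sum() == 5
        assert remove_small_regions(mask, min_area=6).sum() == 0

    def test_matches_brute_force_labelling(self, rng):
        """Random masks agree with an exhaustive flood-fill area filter."""
        def brute(mask, min_area):
            out = np.zeros_like(mask)
            seen = np.zeros_like(mask)
            h, w = mask.shape
            for si in range(h):
                for sj in range(w):
                    if mask[si, sj] and not seen[si, sj]:
                        comp, stack = [], [(si, sj)]
                        seen[si, sj] = True
                        while stack:
                            i, j = stack.pop()
                            comp.append((i, j))
                            for di in (-1, 0, 1):
                                for dj in (-1, 0, 1):
                                    a, b = i + di, j + dj
                                    if 0 <= a < h and 0 <= b < w and mask[a, b] \
                                            and not seen[a, b]:
                                        seen[a, b] = True
                                        stack.append((a, b))
                        if len(comp) >= min_area:
                            for i, j in comp:
                                out[i, j] = True
            return out

        for _ in range(3):
            mask = rng.random((64, 64)) < 0.35
            got = remove_small_regions(mask, min_area=4)
            assert np.array_equal(got, brute(mask, 4))

    def test_never_adds_foreground(self, rng):
        mask = rng.random((32, 32)) < 0.4
        out = remove_small_regions(mask, min_area=9)
        assert not (out & ~mask).any()


class TestPlotFeatures:
    def test_single_pixel_identity(self):
        stack = np.random.default_rng(3).uniform(0.05, 0.6, (5, 4, 4))
        img = SpectralImage.from_stack(stack)
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        fv = extract_plot_features(img, mask)
        ref = compute_vegetation_indices(*(stack[b, 2, 1] for b in range(5)))
        for name in FEATURE_NAMES:
            assert fv[name] == pytest.approx(ref[name], abs=1e-12)

    def test_uniform_canopy_equals_single_spectrum(self):
        stack = np.empty((5, 6, 6))
        for b, v in enumerate((0.05, 0.1, 0.07, 0.3, 0.5)):
            stack[b] = v
        fv = extract_plot_features(SpectralImage.from_stack(stack),
                                   np.ones((6, 6), dtype=bool))
        ref = compute_vegetation_indices(0.05, 0.1, 0.07, 0.3, 0.5)
        for name in FEATURE_NAMES:
            assert fv[name] == pytest.approx(ref[name], abs=1e-12)

    def test_empty_mask_flagged_missing(self):
        img = SpectralImage.from_stack(np.full((5, 4, 4), 0.2))
        fv = extract_plot_features(img, np.zeros((4, 4), dtype=bool))
        assert fv.flags == frozenset(FEATURE_NAMES)
        assert np.isnan(fv.to_array()).all()


class TestSpectralImageIO:
    def test_tiff_roundtrip(self, tmp_path):
        img, mask = syn.render_plot_image(3, syn.ImageSpec(height=16, width=20,
                                                           pixel_noise_sd=0.01), seed=5)
        img.to_tiff(tmp_path / "plot.tif")
        back = SpectralImage.from_tiff(tmp_path / "plot.tif")
        assert np.allclose(back.data, img.data, atol=1e-6)
        write_mask_tiff(mask, tmp_path / "mask.tif")
        assert np.array_equal(read_mask_tiff(tmp_path / "mask.tif"), mask)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            SpectralImage({"blue": np.zeros((2, 2)), "green": np.zeros((3, 2)),
                           "red": np.zeros((2, 2)), "rededge": np.zeros((2, 2)),
                           "nir": np.zeros((2, 2))})
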