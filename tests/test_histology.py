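"""Fiber segmentation and dye-positivity quantification."""

import numpy as np
import pandas as pd
import pytest

import gaitloop as gl
from gaitloop.histology import (BinaryMask, Channel, ChannelImage,
                                FiberLabelMap, SegmentationParams)


@pytest.fixture(scope="module")
def clean_mosaic():
    spec = gl.MosaicSpec(grid=(8, 8), positive_fraction=0.4, seed=7)
    return gl.generate_fiber_mosaic(spec)


def green_image(pixels):
    return ChannelImage(np.asarray(pixels, float), Channel.LAMININ_GREEN)


def red_image(pixels):
    return ChannelImage(np.asarray(pixels, float), Channel.DYE_RED)


class TestEnhanceContrast:
    def test_constant_image_stays_constant(self):
        out = gl.enhance_contrast(green_image(np.full((64, 64), 0.3)),
                                  SegmentationParams())
        assert np.unique(out.pixels).size == 1

    def test_checkerboard_levels_stay_distinct(self):
        base = np.indices((64, 64)).sum(0) % 2 * 0.5 + 0.2
        out = gl.enhance_contrast(green_image(base), SegmentationParams())
        assert np.unique(out.pixels).size >= 2
        assert 0.0 <= out.pixels.min() and out.pixels.max() <= 1.0

    def test_increases_border_contrast_under_vignetting(self, clean_mosaic):
        green, _, truth = clean_mosaic
        h, w = green.pixels.shape
        yy, xx = np.mgrid[0:h, 0:w]
        vignette = 0.4 + 0.6 * np.exp(-(((yy - h / 2) / h) ** 2 +
                                        ((xx - w / 2) / w) ** 2) / 0.08)
        dimmed = green_image(green.pixels * vignette)
        out = gl.enhance_contrast(dimmed, SegmentationParams())
        border = truth.labels == 0
        interior = truth.labels > 0
        contrast_in = dimmed.pixels[border].mean() - dimmed.pixels[interior].mean()
        contrast_out = out.pixels[border].mean() - out.pixels[interior].mean()
        assert contrast_out > contrast_in


class TestBinarize:
    def test_uniform_image_gives_empty_mask(self):
        mask = gl.binarize_fibers(green_image(np.full((64, 64), 0.5)),
                                  SegmentationParams())
        assert not mask.mask.any()
        assert mask.warnings

    def test_complete_borders_enclose_ground_truth_regions(self, clean_mosaic):
        from scipy import ndimage as ndi
        green, _, truth = clean_mosaic
        params = SegmentationParams()
        mask = gl.binarize_fibers(gl.enhance_contrast(green, params), params)
        n_regions = ndi.label(~mask.mask,
                              structure=np.array([[0, 1, 0], [1, 1, 1],
                                                  [0, 1, 0]]))[1]
        # enclosed regions = fibers + the surrounding exterior region
        assert n_regions == truth.n_fibers + 1

    def test_small_border_gaps_closed(self):
        from scipy import ndimage as ndi
        spec = gl.MosaicSpec(grid=(6, 6), gap_probability=1.0, gap_width_px=1,
                             seed=3)
        green, _, truth = gl.generate_fiber_mosaic(spec)
        params = SegmentationParams(gap_close_radius_px=2)
        mask = gl.binarize_fibers(gl.enhance_contrast(green, params), params)
        n_regions = ndi.label(~mask.mask,
                              structure=np.array([[0, 1, 0], [1, 1, 1],
                                                  [0, 1, 0]]))[1]
        assert n_regions == truth.n_fibers + 1

    def test_dye_threshold_extremes(self):
        img = red_image(np.random.default_rng(0).uniform(0.05, 1.0, (64, 64)))
        assert gl.binarize_dye(img, 0.0).mask.all()
        disk_img = np.zeros((64, 64))
        disk_img[20:30, 20:30] = 0.5
        mask = gl.binarize_dye(red_image(disk_img), 0.25)
        assert mask.mask.sum() == 100

    def test_dye_threshold_monotone(self, clean_mosaic):
        """Raising the dye threshold never increases any fiber's dye fraction."""
        green, red, truth = clean_mosaic
        fmap = FiberLabelMap.from_labels(truth.labels)
        lo = gl.score_dye_positivity(fmap, gl.binarize_dye(red, 0.3), 0.5)
        hi = gl.score_dye_positivity(fmap, gl.binarize_dye(red, 0.7), 0.5)
        assert (hi.fibers["dye_fraction"] <= lo.fibers["dye_fraction"] + 1e-12).all()


class TestSegmentFibers:
    def test_empty_mask_gives_empty_map(self):
        fmap = gl.segment_fibers(BinaryMask(np.zeros((64, 64), bool)),
                                 SegmentationParams())
        assert fmap.n_fibers == 0

    def test_clean_mosaic_recovers_fiber_count(self, clean_mosaic):
        green, _, truth = clean_mosaic
        params = SegmentationParams()
        enhanced = gl.enhance_contrast(green, params)
        mask = gl.binarize_fibers(enhanced, params)
        fmap = gl.segment_fibers(mask, params, intensity=enhanced.pixels)
        assert fmap.n_fibers == truth.n_fibers

    def test_touching_fibers_split_by_watershed(self):
        """Two convex regions sharing a thin border stay separate labels."""
        img = np.full((96, 96), 0.1)
        img[20:76, 20:76] = 0.1
        border = np.zeros((96, 96), bool)
        border[20:76, 20] = border[20:76, 75] = True
        border[20, 20:76] = border[75, 20:76] = True
        border[20:76, 47] = True  # shared wall
        fmap = gl.segment_fibers(BinaryMask(border),
                                 SegmentationParams(ac_iters_pre=0,
                                                    ac_iters_post=0))
        assert fmap.n_fibers == 2

    def test_labels_partition_foreground(self, clean_mosaic):
        green, _, truth = clean_mosaic
        params = SegmentationParams()
        enhanced = gl.enhance_contrast(green, params)
        fmap = gl.segment_fibers(gl.binarize_fibers(enhanced, params), params,
                                 intensity=enhanced.pixels)
        areas = fmap.fibers["area_px"].sum()
        assert areas == (fmap.labels > 0).sum()
        assert areas <= fmap.labels.size


class TestLayerPeeling:
    def test_five_by_five_grid_leaves_center_fiber(self):
        spec = gl.MosaicSpec(grid=(5, 5), lattice="square", jitter_px=0, seed=0)
        _, _, truth = gl.generate_fiber_mosaic(spec)
        fmap = gl.peel_outer_layers(FiberLabelMap.from_labels(truth.labels), 2)
        assert fmap.n_fibers == 25
        included = fmap.included_ids
        assert len(included) == 1
        layers = fmap.fibers["layer_index"]
        assert (layers == 0).sum() == 16  # perimeter ring
        assert (layers == 1).sum() == 8   # next ring
        assert layers[included[0]] == 2   # the center fiber

    def test_isolated_fiber_is_layer_zero(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[28:36, 28:36] = 1
        fmap = gl.peel_outer_layers(FiberLabelMap.from_labels(labels), 2)
        assert fmap.fibers.loc[1, "layer_index"] == 0
        assert bool(fmap.fibers.loc[1, "excluded"])

    def test_zero_layers_excludes_nothing(self, clean_mosaic):
        _, _, truth = clean_mosaic
        fmap = gl.peel_outer_layers(FiberLabelMap.from_labels(truth.labels), 0)
        assert not fmap.fibers["excluded"].any()

    def test_peeling_composes(self, clean_mosaic):
        """peel(1) twice equals peel(2)."""
        _, _, truth = clean_mosaic
        base = FiberLabelMap.from_labels(truth.labels)
        once_twice = gl.peel_outer_layers(gl.peel_outer_layers(base, 1), 1)
        direct = gl.peel_outer_layers(base, 2)
        pd.testing.assert_series_equal(once_twice.fibers["excluded"],
                                       direct.fibers["excluded"])


class TestDyeScoring:
    def make_single_fiber(self, area_side=10):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[10:10 + area_side, 10:10 + area_side] = 1
        return FiberLabelMap.from_labels(labels), labels

    def test_fully_dyed_fiber_is_positive(self):
        fmap, labels = self.make_single_fiber()
        out = gl.score_dye_positivity(fmap, labels > 0, 0.5)
        assert bool(out.fibers.loc[1, "positive"])

    def test_exactly_half_dyed_is_not_positive(self):
        """Positivity requires strictly more than 50% coverage."""
        fmap, labels = self.make_single_fiber()
        dye = np.zeros_like(labels, bool)
        dye[10:15, 10:20] = True  # exactly 50 of 100 pixels
        out = gl.score_dye_positivity(fmap, dye, 0.5)
        assert out.fibers.loc[1, "dye_fraction"] == 0.5
        assert not bool(out.fibers.loc[1, "positive"])

    def test_51_percent_is_positive(self):
        fmap, labels = self.make_single_fiber()
        dye = np.zeros_like(labels, bool)
        dye.flat[np.flatnonzero(labels.ravel())[:51]] = True
        out = gl.score_dye_positivity(fmap, dye, 0.5)
        assert out.fibers.loc[1, "dye_fraction"] == pytest.approx(0.51)
        assert bool(out.fibers.loc[1, "positive"])

    def test_shape_mismatch_rejected(self):
        fmap, _ = self.make_single_fiber()
        with pytest.raises(ValueError):
            gl.score_dye_positivity(fmap, np.zeros((32, 32), bool), 0.5)

    def test_positivity_fraction_monotone(self, clean_mosaic):
        """Raising the positivity fraction never raises percent positive."""
        green, red, truth = clean_mosaic
        fmap = FiberLabelMap.from_labels(truth.labels)
        dye = gl.binarize_dye(red, 0.5)
        pcts = []
        for frac in (0.3, 0.5, 0.7):
            scored = gl.score_dye_positivity(fmap, dye, frac)
            pcts.append(gl.percent_positive(scored))
        assert pcts[0] >= pcts[1] >= pcts[2]


class TestPercentPositive:
    def test_arithmetic(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        for k in range(10):
            labels[2 + 6 * (k // 5):6 + 6 * (k // 5),
                   2 + 12 * (k % 5):8 + 12 * (k % 5)] = k + 1
        fmap = FiberLabelMap.from_labels(labels)
        fibers = fmap.fibers.copy()
        fibers.loc[[1, 2, 3], "positive"] = True
        fmap = FiberLabelMap(labels, fibers)
        assert gl.percent_positive(fmap) == pytest.approx(30.0)

    def test_no_included_fibers_is_an_error(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[30:34, 30:34] = 1
        fmap = gl.peel_outer_layers(FiberLabelMap.from_labels(labels), 2)
        with pytest.raises(ValueError):
            gl.percent_positive(fmap)


class TestEndToEnd:
    def test_clean_mosaic_recovery_within_two_points(self, clean_mosaic):
        green, red, truth = clean_mosaic
        _, summary = gl.quantify_section(green, red)
        assert summary["percent_positive"] == pytest.approx(
            truth.percent_positive(2), abs=2.0)

    def test_percent_positive_invariant_to_rotation_and_mirror(self,
                                                               clean_mosaic):
        green, red, _ = clean_mosaic
        _, base = gl.quantify_section(green, red)
        rot = gl.quantify_section(
            ChannelImage(np.rot90(green.pixels), Channel.LAMININ_GREEN),
            ChannelImage(np.rot90(red.pixels), Channel.DYE_RED))[1]
        mir = gl.quantify_section(
            ChannelImage(green.pixels[:, ::-1], Channel.LAMININ_GREEN),
            ChannelImage(red.pixels[:, ::-1], Channel.DYE_RED))[1]
        assert rot["percent_positive"] == pytest.approx(
            base["percent_positive"], abs=1e-9)
        assert mir["percent_positive"] == pytest.approx(
            base["percent_positive"], abs=1e-9)
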