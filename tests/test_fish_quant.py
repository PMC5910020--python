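import numpy as np
import pandas as pd
import pytest

import synaptofilter as sf
from synaptofilter.core_io import AnalysisConfig, ConfigurationError, ValidationError
from synaptofilter.fish_quant import (
    CalibrationResult,
    calibrate_threshold,
    classify_cells,
    coexpression_table,
    combine_z,
    count_per_cell,
    detect_puncta,
    quantify_stack,
    segment_cells,
    threshold_channel,
)
from synaptofilter.synth_fish import FishSceneParams, _add_gaussian_spot


def _disk_image(centers, radius=12.0, shape=(200, 200), intensity=100.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = intensity
    return img


class TestCombineZ:
    def test_identical_slices_project_to_themselves(self):
        params = FishSceneParams(n_cells=0, shape_zyx=(6, 32, 32))
        stack, _ = sf.generate_stack(params)
        groups = combine_z(stack, 3)
        assert len(groups) == 2
        np.testing.assert_array_equal(groups[0]["probe"],
                                      stack.channel("probe")[0])

    def test_max_projection_dominates_every_slice(self):
        rng = np.random.default_rng(0)
        vox = rng.uniform(0, 50, size=(3, 5, 32, 32))
        stack = sf.ImageStack(voxels=vox, pixel_size_xy=0.3,
                              channel_roles={"marker": 0, "probe": 1,
                                             "bead": 2})
        groups = combine_z(stack, 3)
        for z in range(3):
            assert np.all(groups[0]["marker"] >= vox[0, z] - 1e-12)

    def test_single_slice_punctum_survives_with_peak_intensity(self):
        vox = np.zeros((3, 6, 64, 64))
        _add_gaussian_spot(vox[1, 2], 30.0, 30.0, 80.0, 1.2)
        stack = sf.ImageStack(voxels=vox, pixel_size_xy=0.3,
                              channel_roles={"marker": 0, "probe": 1,
                                             "bead": 2})
        groups = combine_z(stack, 3)
        np.testing.assert_allclose(groups[0]["probe"].max(),
                                   vox[1, 2].max())
        assert groups[1]["probe"].max() == 0

    def test_group_size_larger_than_depth_rejected(self):
        params = FishSceneParams(n_cells=0, shape_zyx=(2, 16, 16))
        stack, _ = sf.generate_stack(params)
        with pytest.raises(ValidationError):
            combine_z(stack, 3)


class TestThresholdChannel:
    def test_zero_threshold_is_identity(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        res = threshold_channel(img, "fixed", 0.0)
        np.testing.assert_array_equal(res.image, img)

    def test_threshold_above_max_zeroes_everything(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        res = threshold_channel(img, "fixed", 10.0)
        assert np.all(res.image == 0)

    def test_otsu_splits_bimodal_levels(self):
        img = np.concatenate([np.full(500, 10.0), np.full(500, 90.0)])
        res = threshold_channel(img.reshape(20, 50), "otsu")
        assert 10.0 < res.threshold < 90.0
        assert not res.fallback

    def test_degenerate_otsu_falls_back_flagged(self):
        res = threshold_channel(np.full((8, 8), 7.0), "otsu", value=5.0)
        assert res.fallback
        assert res.threshold == 5.0


class TestSegmentation:
    def test_blank_marker_yields_no_segments(self):
        labels, segments = segment_cells(np.zeros((64, 64)))
        assert segments == []
        assert labels.max() == 0

    def test_well_separated_disks_segmented_exactly(self):
        centers = [(40, 40), (40, 150), (150, 40), (150, 150), (95, 95)]
        img = _disk_image(centers)
        labels, segments = segment_cells(img)
        assert len(segments) == 5
        got = sorted((round(s.centroid[0]), round(s.centroid[1]))
                     for s in segments)
        assert got == sorted(centers)
        for s in segments:
            assert s.area == pytest.approx(np.pi * 12**2, rel=0.10)

    def test_touching_disks_split_by_watershed(self):
        # two disks overlapping ~20%: watershed places a boundary between
        # the intensity maxima
        img = _disk_image([(60, 50), (60, 69)], radius=12.0)
        labels, segments = segment_cells(img)
        assert len(segments) == 2
        cys = sorted(s.centroid[1] for s in segments)
        assert cys[0] < 60 < cys[1]

    def test_translation_equivariance(self):
        img = _disk_image([(50, 50)], radius=12.0)
        shifted = np.roll(img, (30, 20), axis=(0, 1))
        _, seg_a = segment_cells(img)
        _, seg_b = segment_cells(shifted)
        assert seg_b[0].centroid[0] == pytest.approx(
            seg_a[0].centroid[0] + 30, abs=0.5
        )
        assert seg_b[0].centroid[1] == pytest.approx(
            seg_a[0].centroid[1] + 20, abs=0.5
        )


class TestDetectPuncta:
    def test_single_spot_found_at_center(self):
        img = np.zeros((64, 64))
        _add_gaussian_spot(img, 30.2, 31.7, 80.0, 1.2)
        coords = detect_puncta(img)
        assert coords.shape == (1, 2)
        assert np.hypot(coords[0, 0] - 30.2, coords[0, 1] - 31.7) <= 1.0

    def test_fifty_separated_spots_counted_exactly(self):
        img = np.zeros((300, 300))
        rng = np.random.default_rng(1)
        pts = []
        while len(pts) < 50:
            p = rng.uniform(10, 290, 2)
            if all(np.hypot(*(p - q)) >= 6.0 for q in pts):
                pts.append(p)
        for y, x in pts:
            _add_gaussian_spot(img, y, x, 80.0, 1.2)
        assert detect_puncta(img).shape[0] == 50

    def test_empty_image_no_detections(self):
        assert detect_puncta(np.zeros((32, 32))).size == 0


class TestCountingAndClassification:
    def test_punctum_assignment_inside_and_outside_masks(self):
        img = _disk_image([(50, 50)], radius=12.0, shape=(100, 100))
        labels, segments = segment_cells(img)
        coords = {"probe": np.array([[50.0, 50.0], [10.0, 10.0]])}
        counts = count_per_cell(labels, coords, segments)
        assert counts.loc[0, "count_probe"] == 1  # centroid punctum counted
        # the outside punctum is counted nowhere
        assert counts["count_probe"].sum() == 1

    @pytest.mark.parametrize("count,expected", [(11, True), (10, False), (0, False)])
    def test_strict_cutoff_boundary(self, count, expected):
        # published convention: positive means MORE THAN the cutoff (>10)
        df = pd.DataFrame({"count_probe": [count]})
        out = classify_cells(df, {"probe": 10})
        assert bool(out.loc[0, "flag_probe"]) is expected

    def test_missing_cutoff_for_used_channel_raises(self):
        df = pd.DataFrame({"count_probe": [1], "count_bead": [1]})
        with pytest.raises(ConfigurationError):
            classify_cells(df, {"probe": 10})

    def test_raising_cutoff_never_adds_positives(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"count_probe": rng.poisson(8, 200)})
        n_pos = [
            classify_cells(df, {"probe": t})["flag_probe"].sum()
            for t in range(0, 30)
        ]
        assert all(a >= b for a, b in zip(n_pos, n_pos[1:]))


class TestCalibrateThreshold:
    def test_gap_case_ties_break_low(self):
        counts = [0, 1, 3, 12, 15, 20]
        labels = [False, False, False, True, True, True]
        res = calibrate_threshold(counts, labels)
        assert res == CalibrationResult(threshold=3, accuracy=1.0,
                                        separable=True)

    def test_matches_exhaustive_scan_oracle_on_overlap(self):
        rng = np.random.default_rng(5)
        counts = np.concatenate([rng.poisson(1, 80), rng.poisson(25, 120)])
        labels = np.array([False] * 80 + [True] * 120)
        res = calibrate_threshold(counts, labels)
        # brute-force oracle: best accuracy over every integer threshold
        accs = {
            t: np.mean((counts > t) == labels)
            for t in range(counts.min() - 1, counts.max() + 1)
        }
        best = max(accs.values())
        assert res.accuracy == pytest.approx(best)
        assert accs[res.threshold] == pytest.approx(best)
        assert all(accs[t] < best for t in accs if t < res.threshold)

    def test_inverted_labels_flagged_by_low_accuracy(self):
        counts = [0, 1, 2, 15, 16, 17]
        labels = [True, True, True, False, False, False]
        res = calibrate_threshold(counts, labels)
        assert res.accuracy <= 0.5
        assert not res.separable

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_threshold([1, 2, 3], [True, True, True])


class TestCoexpression:
    def _flags(self, n_triple, n_double_only, n_other=0):
        rows = (
            [{"marker": True, "bead": True, "probe": True}] * n_triple
            + [{"marker": True, "bead": True, "probe": False}] * n_double_only
            + [{"marker": False, "bead": False, "probe": False}] * n_other
        )
        return pd.DataFrame(rows)

    def test_published_ppn_counts_give_76_3_percent(self):
        table = coexpression_table(self._flags(306, 401 - 306, 50))
        prop = table.proportion(["marker", "bead", "probe"],
                                ["marker", "bead"])
        assert prop * 100 == pytest.approx(76.3, abs=0.05)
        assert prop > 0.70

    def test_rare_coexpression_case(self):
        table = coexpression_table(self._flags(4, 178 - 4))
        prop = table.proportion(["marker", "bead", "probe"],
                                ["marker", "bead"])
        assert prop * 100 == pytest.approx(2.2, abs=0.05)

    def test_uniform_flags_give_unity(self):
        table = coexpression_table(self._flags(10, 0))
        assert table.proportion(["marker", "probe"], ["marker"]) == 1.0

    def test_zero_denominator_flagged_absent(self):
        table = coexpression_table(self._flags(0, 0, 5))
        assert table.proportion(["marker", "probe"], ["marker"]) is None


class TestEndToEnd:
    def test_noiseless_counts_equal_ground_truth_exactly(self):
        params = FishSceneParams(n_cells=12, shape_zyx=(5, 360, 360), seed=5)
        stack, truth = sf.generate_stack(params)
        cells = quantify_stack(stack)
        assert len(cells) == len(truth)
        for _, t in truth.iterrows():
            d = np.hypot(cells["y"] - t.cy, cells["x"] - t.cx)
            j = d.idxmin()
            assert d[j] < 3.0
            assert cells.loc[j, "count_probe"] == t.count_probe
            assert cells.loc[j, "count_bead"] == t.count_bead

    def test_label_order_permutation_invariance(self):
        # quantification depends only on geometry, not generation order:
        # same scene, different cell iteration seeds for clutterless noise
        params = FishSceneParams(n_cells=6, shape_zyx=(5, 256, 256), seed=8)
        stack, truth = sf.generate_stack(params)
        cells = quantify_stack(stack)
        merged = truth.merge(
            cells.assign(
                key=cells[["y", "x"]].round(0).astype(int).apply(tuple, axis=1)
            ),
            left_on=truth[["cy", "cx"]].round(0).astype(int).apply(tuple, axis=1),
            right_on="key",
            how="inner",
        )
        assert len(merged) == len(truth)
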