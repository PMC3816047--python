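import numpy as np
import pytest

from camvessel import (
    classify_skeleton,
    normalize_to_control,
    remove_wide_vessels,
    skeletonize,
    vessel_area,
)
from conftest import make_mask, spanning_bar
from oracles import area_oracle, classify_oracle, opening_oracle


class TestRemoveWideVessels:
    def test_thin_bar_kept_wide_bar_removed(self):
        # 2 px at 2 um/px = 4 um (thin); 12 px = 24 um (wide); cutoff 15 um
        m = np.zeros((40, 60), dtype=np.uint8)
        m[5:7, :] = 1
        m[20:32, :] = 1
        thin = remove_wide_vessels(make_mask(m, pixel_size_um=2.0), 15.0)
        assert np.array_equal(thin.labels[5:7, :], np.ones((2, 60)))
        assert thin.labels[20:32, :].sum() == 0

    def test_matches_opening_oracle(self, rng):
        m = (rng.random((28, 28)) < 0.4).astype(np.uint8)
        result = remove_wide_vessels(make_mask(m, 2.0), 15.0).labels.astype(bool)
        expected = m.astype(bool) & ~opening_oracle(m, radius=4)
        assert np.array_equal(result, expected)

    def test_empty_mask_passes_through(self):
        thin = remove_wide_vessels(make_mask(np.zeros((8, 8))), 15.0)
        assert thin.labels.sum() == 0

    def test_single_pixel_survives(self):
        m = np.zeros((9, 9), dtype=np.uint8)
        m[4, 4] = 1
        thin = remove_wide_vessels(make_mask(m, 1.0), 15.0)
        assert thin.labels[4, 4] == 1

    def test_output_subset_of_input(self, rng):
        m = (rng.random((30, 30)) < 0.5).astype(np.uint8)
        thin = remove_wide_vessels(make_mask(m, 1.0), 15.0)
        assert np.all(thin.labels <= m)

    def test_subpixel_cutoff_rejected(self):
        with pytest.raises(ValueError):
            remove_wide_vessels(make_mask(np.ones((4, 4)), pixel_size_um=20.0), 15.0)

    @pytest.mark.parametrize("width_um,kept", [(5, True), (10, True), (13, True), (17, False), (25, False), (40, False)])
    def test_bar_width_band(self, width_um, kept):
        # bars span the field of view, 1 um/px
        m = spanning_bar(80, 90, width_um)
        thin = remove_wide_vessels(make_mask(m, 1.0), 15.0)
        if kept:
            assert np.array_equal(thin.labels, m)
        else:
            assert thin.labels.sum() == 0


class TestVesselArea:
    def test_full_mask_area(self):
        area_px, area_um2 = vessel_area(make_mask(np.ones((10, 10)), 2.0))
        assert (area_px, area_um2) == (100, 400.0)

    def test_empty_mask(self):
        assert vessel_area(make_mask(np.zeros((3, 3)))) == (0, 0.0)

    def test_matches_double_loop_count(self, rng):
        m = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        assert vessel_area(make_mask(m))[0] == area_oracle(m)


class TestSkeletonize:
    def test_one_pixel_line_unchanged(self):
        m = np.zeros((7, 9), dtype=np.uint8)
        m[3, 1:8] = 1
        assert np.array_equal(skeletonize(make_mask(m)).labels, m)

    def test_bar_thins_to_single_path(self):
        from scipy import ndimage

        m = np.zeros((15, 30), dtype=np.uint8)
        m[5:10, 4:24] = 1
        skel = skeletonize(make_mask(m)).labels
        assert np.all(skel <= m)  # skeleton is a subset
        # same connectivity, one-pixel thickness via the distance transform
        assert ndimage.label(skel, np.ones((3, 3)))[1] == 1
        dist = ndimage.distance_transform_edt(skel)
        assert dist.max() <= 1.0

    def test_empty_mask(self):
        assert skeletonize(make_mask(np.zeros((5, 5)))).labels.sum() == 0

    def test_component_count_preserved(self, rng):
        from scipy import ndimage

        m = np.zeros((40, 40), dtype=np.uint8)
        m[5:9, 2:38] = 1
        m[20:24, 2:20] = 1
        m[30, 25:35] = 1
        skel = skeletonize(make_mask(m)).labels
        s8 = np.ones((3, 3))
        assert ndimage.label(skel, s8)[1] == ndimage.label(m, s8)[1] == 3


class TestClassifySkeleton:
    def test_diagonal_y_junction(self):
        # two diagonal arms and one vertical arm meeting at the centre:
        # centre has 3 neighbours (junction), arm interiors 2 (mid), tips 1
        m = np.zeros((5, 5), dtype=np.uint8)
        for i, j in [(0, 0), (1, 1), (0, 4), (1, 3), (2, 2), (3, 2), (4, 2)]:
            m[i, j] = 1
        stats = classify_skeleton(make_mask(m))
        assert stats.junction_count == 1
        assert stats.endpoint_count == 3
        assert stats.mid_count == 3
        assert stats.skeleton_px == 7
        assert stats.junction_cluster_count == 1
        assert stats.branch_segment_count == 3

    def test_plus_shape_under_8_connectivity(self):
        # with 8-neighbour counting the four pixels around a plus centre
        # touch each other diagonally, so the whole 5-px core is one
        # junction cluster rather than one junction pixel
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 1:4] = 1
        m[1:4, 2] = 1
        stats = classify_skeleton(make_mask(m))
        assert stats.junction_count == 5
        assert stats.junction_cluster_count == 1
        assert stats.endpoint_count + stats.mid_count + stats.junction_count == 5

    def test_three_pixel_line(self):
        m = np.zeros((3, 5), dtype=np.uint8)
        m[1, 1:4] = 1
        stats = classify_skeleton(make_mask(m))
        assert (stats.endpoint_count, stats.mid_count, stats.junction_count) == (2, 1, 0)
        assert stats.branch_segment_count == 1
        assert stats.mean_branch_length_um == pytest.approx(3.0)

    def test_matches_neighbour_count_oracle(self, rng):
        for _ in range(10):
            m = (rng.random((20, 20)) < 0.25).astype(np.uint8)
            stats = classify_skeleton(make_mask(m))
            n_end, n_mid, n_junc = classify_oracle(m)
            assert (stats.endpoint_count, stats.mid_count, stats.junction_count) == (
                n_end,
                n_mid,
                n_junc,
            )

    def test_partition_identity_on_random_masks(self, rng):
        for _ in range(20):
            m = (rng.random((25, 25)) < 0.3).astype(np.uint8)
            stats = classify_skeleton(make_mask(m))
            assert (
                stats.endpoint_count + stats.mid_count + stats.junction_count
                == stats.skeleton_px
            )


class TestNormalizeToControl:
    def test_half_of_control(self):
        assert normalize_to_control([50.0], [100.0, 100.0]).tolist() == [50.0]

    def test_self_normalization_averages_to_100(self, rng):
        vals = rng.random(10) + 0.5
        assert normalize_to_control(vals, vals).mean() == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        assert normalize_to_control([20.0, 40.0], [40.0]).tolist() == [50.0, 100.0]

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [])
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [0.0, 0.0])
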