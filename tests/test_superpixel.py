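"""Improved SLIC clustering: seeding, distance, assignment, gated update,
connectivity enforcement and boundary extraction."""

import numpy as np
import pytest
from skimage import measure

from texslic import PipelineConfig
from texslic.superpixel import (
    assign_pixels,
    boundary_mask,
    enforce_connectivity,
    init_centers,
    iterate,
    pixel_distance,
    update_centers,
)


def two_region_image(h=40, w=80, left=50, right=200):
    img = np.full((h, w), left, dtype=np.uint8)
    img[:, w // 2 :] = right
    return img


class TestInit:
    def test_grid_span_and_positions(self):
        img = np.zeros((100, 100), dtype=np.uint8)
        centers, state = init_centers(img, None, 4)
        assert state.span == pytest.approx(50.0)
        got = sorted(zip(centers.row, centers.col))
        assert got == [(25.0, 25.0), (25.0, 75.0), (75.0, 25.0), (75.0, 75.0)]

    def test_single_center_at_midpoint(self):
        img = np.zeros((40, 60), dtype=np.uint8)
        centers, _ = init_centers(img, None, 1)
        assert (centers.row[0], centers.col[0]) == (20.0, 30.0)

    def test_alpha_is_population_std(self):
        img = two_region_image()
        _, state = init_centers(img, None, 4)
        assert state.alpha == pytest.approx(img.std())

    def test_constant_image_alpha_zero(self):
        _, state = init_centers(np.full((20, 20), 7, dtype=np.uint8), None, 4)
        assert state.alpha == 0.0

    def test_k_larger_than_pixels_rejected(self):
        with pytest.raises(ValueError):
            init_centers(np.zeros((5, 5), dtype=np.uint8), None, 26)

    def test_unassigned_initial_state(self):
        _, state = init_centers(np.zeros((10, 10), dtype=np.uint8), None, 4)
        assert np.all(state.labels == -1)
        assert np.all(np.isinf(state.dists))


class TestDistance:
    def test_identical_pixel_gives_zero(self):
        d = pixel_distance(100.0, (5.0, 5.0), 30.0, 100, 5, 5, 30, 10.0, 10.0, 10.0)
        assert d == 0.0

    def test_pure_gray_component(self):
        # |100-110|/Nc=10 -> a single unit component
        d = pixel_distance(100.0, (5.0, 5.0), 0.0, 110, 5, 5, None, 10.0, 10.0, 10.0)
        assert d == pytest.approx(1.0)

    def test_homogeneity(self):
        d1 = pixel_distance(100.0, (0.0, 0.0), 0.0, 110, 3, 4, 5, 10.0, 10.0, 10.0)
        d2 = pixel_distance(100.0, (0.0, 0.0), 0.0, 120, 6, 8, 10, 10.0, 10.0, 10.0)
        assert d2 == pytest.approx(2 * d1)

    def test_texture_term_omitted_when_disabled(self):
        with_t = pixel_distance(0.0, (0.0, 0.0), 0.0, 0, 0, 0, 50, 10.0, 1.0, 10.0)
        without = pixel_distance(0.0, (0.0, 0.0), 0.0, 0, 0, 0, None, 10.0, 1.0, 10.0)
        assert with_t > without == 0.0

    def test_literal_mode_squares_gray(self):
        lit = pixel_distance(
            100.0, (0.0, 0.0), 0.0, 110, 0, 0, None, 10.0, 10.0, 10.0, literal=True
        )
        assert lit == pytest.approx(10.0)  # (10^2)/10


class TestAssignUpdate:
    def test_two_regions_claimed_by_matching_centers(self):
        img = two_region_image()  # 40x80, split at col 40, seeds at cols 20/60
        centers, state = init_centers(img, None, 2)
        assign_pixels(centers, img, None, state)
        left_label = state.labels[20, 5]
        right_label = state.labels[20, 75]
        assert left_label != right_label
        assert np.all(state.labels[:, :40] == left_label)
        assert np.all(state.labels[:, 40:] == right_label)

    def test_constant_image_voronoi_tie_prefers_lower_index(self):
        img = np.full((20, 40), 128, dtype=np.uint8)
        centers, state = init_centers(img, None, 2)
        assign_pixels(centers, img, None, state)
        # midline column is equidistant to both seeds: earlier center wins
        mid = np.argmin(np.abs(np.arange(40) - 20))
        assert np.all(state.labels[:, mid] == 0)
        assert np.all(state.labels >= 0)

    def test_gate_excludes_outlier_grays(self):
        # member grays {100,...,100,250}, center gray 100, alpha 30:
        # the 250 outlier is excluded, so the new center gray stays 100
        img = np.full((4, 4), 100, dtype=np.uint8)
        img[0, 3] = 250
        centers, state = init_centers(img, None, 1)
        centers.gray[0] = 100.0
        state.labels[:] = 0
        state.alpha = 30.0
        update_centers(centers, img, None, state, gated=True)
        assert centers.gray[0] == pytest.approx(100.0)

    def test_gate_fallback_on_empty_set(self):
        img = two_region_image(h=8, w=8)
        centers, state = init_centers(img, None, 1)
        centers.gray[0] = 125.0  # farther than alpha=75 from both 50 and 200
        state.labels[:] = 0
        state.alpha = 10.0
        update_centers(centers, img, None, state, gated=True, record_audit=True)
        assert state.audit[-1]["fallbacks"] == [0]
        assert centers.gray[0] == pytest.approx(img.mean())

    def test_plain_update_equals_gated_when_all_within_gate(self):
        img = np.full((10, 10), 90, dtype=np.uint8)
        img[0, 0] = 95
        for gated in (False, True):
            centers, state = init_centers(img, None, 1)
            state.labels[:] = 0
            state.alpha = 50.0
            update_centers(centers, img, None, state, gated=gated)
            assert centers.gray[0] == pytest.approx(img.mean())

    def test_normalizers_track_max_member_distance(self):
        img = two_region_image(h=8, w=8)
        centers, state = init_centers(img, None, 1)
        centers.gray[0] = 50.0
        state.labels[:] = 0
        update_centers(centers, img, None, state, gated=False)
        assert centers.nc[0] == 150.0  # |50-200|


class TestIterate:
    def test_recovers_region_means(self):
        img = two_region_image()
        cfg = PipelineConfig(n_superpixels=2, variant="improved_slic")
        state, centers = iterate(img, None, cfg)
        grays = sorted(centers.gray[centers.active])
        assert abs(grays[0] - 50) <= 1 and abs(grays[-1] - 200) <= 1

    def test_single_iteration_runs_one_assign_one_update(self):
        img = two_region_image()
        cfg = PipelineConfig(n_superpixels=4, n_iterations=1, variant="improved_slic")
        state, _ = iterate(img, None, cfg, record_audit=True)
        assert len(state.audit) == 1
        assert np.all(state.labels >= 0)

    def test_deterministic(self):
        img = two_region_image()
        cfg = PipelineConfig(n_superpixels=9, variant="proposed")
        from texslic.texture import texture_map

        tex = texture_map(img)
        s1, _ = iterate(img, tex, cfg)
        s2, _ = iterate(img, tex, cfg)
        assert np.array_equal(s1.labels, s2.labels)


class TestConnectivity:
    def _assert_connected(self, labels):
        for lab in np.unique(labels):
            n = measure.label(labels == lab, connectivity=1).max()
            assert n == 1, f"label {lab} split into {n} components"

    def test_connected_labels_only_renumbered(self):
        img = np.full((60, 60), 100, dtype=np.uint8)
        centers, state = init_centers(img, None, 4)
        state.labels = np.repeat(
            np.repeat(np.arange(4).reshape(2, 2), 30, axis=0), 30, axis=1
        ).astype(np.int32)
        before = state.labels.copy()
        enforce_connectivity(state)
        # same partition, labels dense
        assert len(np.unique(state.labels)) == 4
        for lab in np.unique(before):
            region = before == lab
            assert len(np.unique(state.labels[region])) == 1
        self._assert_connected(state.labels)

    def test_orphan_pixel_absorbed(self):
        img = np.full((12, 12), 100, dtype=np.uint8)
        centers, state = init_centers(img, None, 2)
        state.labels = np.zeros((12, 12), dtype=np.int32)
        state.labels[:, 6:] = 1
        state.labels[3, 2] = 1  # orphan of label 1 inside label 0
        enforce_connectivity(state)
        self._assert_connected(state.labels)
        assert len(np.unique(state.labels)) == 2

    def test_checkerboard_collapses_to_connected_regions(self):
        img = np.full((16, 16), 100, dtype=np.uint8)
        centers, state = init_centers(img, None, 4)
        state.labels = np.indices((16, 16)).sum(axis=0).astype(np.int32) % 2
        enforce_connectivity(state)
        assert np.all(state.labels >= 0)
        self._assert_connected(state.labels)

    def test_gray_aware_merge_prefers_matching_tissue(self):
        # a small bright fragment wedged between a huge dark region and a
        # smaller bright one must join the bright one
        img = np.full((20, 20), 50, dtype=np.uint8)
        img[:, 16:] = 200
        state_labels = np.zeros((20, 20), dtype=np.int32)
        state_labels[:, 16:] = 1
        state_labels[9:11, 14:16] = 2  # 4-px fragment, gray 50 under it
        img[9:11, 14:16] = 200  # but its gray matches region 1
        centers, state = init_centers(img, None, 2)
        state.labels = state_labels
        enforce_connectivity(state, img)
        assert len(np.unique(state.labels)) == 2
        assert state.labels[9, 14] == state.labels[9, 17]


class TestBoundary:
    def test_single_label_empty_mask(self):
        assert not boundary_mask(np.zeros((5, 5), dtype=int)).any()

    def test_two_by_two_split_all_boundary(self):
        assert boundary_mask(np.array([[0, 0], [1, 1]])).all()

    def test_vertical_split_marks_middle_columns(self):
        lab = np.zeros((4, 4), dtype=int)
        lab[:, 2:] = 1
        b = boundary_mask(lab)
        expected = np.zeros((4, 4), dtype=bool)
        expected[:, 1:3] = True
        assert np.array_equal(b, expected)
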