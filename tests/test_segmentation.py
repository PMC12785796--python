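"""Segmentation tests: projections, Otsu, fusion chain, association."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

from virotrace3d.core import ChannelStack
from virotrace3d.segmentation import (
    SegmentationParams,
    associate,
    fill_holes_z,
    filter_small_instances,
    max_project,
    otsu_threshold,
    refine_nuclei_3d,
    segment_cells,
    segment_nuclei_planar,
    segment_timepoint,
)


def _stack_from_volume(volume: np.ndarray) -> ChannelStack:
    data = np.broadcast_to(volume, (1, 4, *volume.shape)).copy()
    return ChannelStack(data=data)


class TestMaxProject:
    def test_single_plane_is_identity(self, rng):
        vol = rng.integers(0, 255, (1, 16, 16))
        stack = _stack_from_volume(vol)
        np.testing.assert_array_equal(max_project(stack, "nuclei", 0), vol[0])

    def test_pixelwise_maximum_of_two_planes(self):
        vol = np.zeros((2, 4, 4))
        vol[0, 1, 1], vol[1, 1, 1] = 3, 7
        assert max_project(_stack_from_volume(vol), "nuclei", 0)[1, 1] == 7

    def test_dominates_every_input_plane(self, rng):
        vol = rng.uniform(0, 1, (6, 12, 12))
        mip = max_project(_stack_from_volume(vol), "nuclei", 0)
        assert np.all(mip[None] >= vol)

    def test_missing_channel_or_timepoint_raises(self, rng):
        stack = _stack_from_volume(rng.uniform(0, 1, (2, 8, 8)))
        with pytest.raises(KeyError):
            max_project(stack, "phase", 0)
        with pytest.raises(IndexError):
            max_project(stack, "nuclei", 5)


class TestOtsu:
    def test_matches_exhaustive_maximizer_on_random_8bit(self, rng):
        """Exhaustive between-class-variance search over all gray levels."""
        for _ in range(25):
            img = np.concatenate(
                [
                    rng.integers(0, 120, rng.integers(50, 500)),
                    rng.integers(100, 256, rng.integers(50, 500)),
                ]
            ).astype(np.uint8)
            thr = otsu_threshold(img)
            best_t, best_v = None, -1.0
            for t in range(int(img.min()), int(img.max())):
                lo, hi = img[img <= t], img[img > t]
                if lo.size == 0 or hi.size == 0:
                    continue
                w0, w1 = lo.size / img.size, hi.size / img.size
                v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
                if v > best_v:
                    best_t, best_v = t, v
            assert thr == best_t

    def test_agrees_with_skimage_on_bimodal_data(self, rng):
        img = np.concatenate(
            [rng.normal(60, 10, 3000), rng.normal(200, 12, 1500)]
        ).clip(0, 255).astype(np.uint8)
        mine = otsu_threshold(img)
        theirs = skimage_otsu(img)
        # same gray level up to skimage's bin-placement convention
        assert abs(mine - theirs) <= 1

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 7, dtype=np.uint8))


class TestPlanarNuclei:
    def test_two_separated_discs_give_two_labels(self):
        img = np.zeros((96, 96))
        yy, xx = np.mgrid[0:96, 0:96]
        img[(yy - 25) ** 2 + (xx - 25) ** 2 < 14**2] = 200
        img[(yy - 70) ** 2 + (xx - 70) ** 2 < 14**2] = 200
        labels = segment_nuclei_planar(img, SegmentationParams.desk_scale())
        assert labels.max() == 2

    def test_blank_image_yields_empty_labeling(self):
        labels = segment_nuclei_planar(np.zeros((32, 32)))
        assert labels.max() == 0

    def test_overlapping_discs_split_by_watershed(self):
        img = np.zeros((96, 96))
        yy, xx = np.mgrid[0:96, 0:96]
        img[(yy - 48) ** 2 + (xx - 34) ** 2 < 15**2] = 200
        img[(yy - 48) ** 2 + (xx - 60) ** 2 < 15**2] = 200
        labels = segment_nuclei_planar(img, SegmentationParams.desk_scale())
        # distance transform of the fused blob has two regional maxima
        assert labels.max() == 2

    def test_pluggable_backend_is_used(self):
        sentinel = np.ones((8, 8), dtype=np.int32)
        params = SegmentationParams(planar_backend=lambda im: sentinel)
        np.testing.assert_array_equal(
            segment_nuclei_planar(np.zeros((8, 8)), params), sentinel
        )


class TestRefine3D:
    def _block_volume(self, volumes):
        """Rectangular objects of exactly the requested voxel volumes."""
        vol = np.zeros((20, 64, 96), dtype=np.uint16)
        labels2d = np.zeros((64, 96), dtype=np.int32)
        x0 = 2
        for i, (nvox, missing) in enumerate(volumes, start=1):
            # 10 z-planes x 40 y x ceil(nvox/400) footprint
            nx = nvox // 400
            vol[5:15, 10:50, x0 : x0 + nx] = 1000
            if missing:
                vol[5, 10, x0] = 0
            labels2d[10:50, x0 : x0 + nx] = i
            x0 += nx + 6
        return vol, labels2d

    def test_volume_filter_boundary_at_10000_voxels(self):
        vol, labels2d = self._block_volume([(10000, False), (10000, True)])
        params = SegmentationParams(
            gaussian_sigma=0.01, downscale_factor=1, min_nucleus_volume=10_000
        )
        out = refine_nuclei_3d(vol, labels2d, params)
        volumes = {
            int(l): int((out == l).sum()) for l in np.unique(out) if l != 0
        }
        assert volumes == {1: 10_000}  # 9,999-voxel object removed

    def test_otsu_fusion_recovers_planar_instance_labels(self, rng):
        vol, labels2d = self._block_volume([(10000, False), (8000, False)])
        params = SegmentationParams(
            gaussian_sigma=0.01, downscale_factor=1, min_nucleus_volume=100
        )
        out = refine_nuclei_3d(vol, labels2d, params)
        assert set(np.unique(out)) == {0, 1, 2}

    def test_z_gap_bounded_by_foreground_is_filled(self):
        mask = np.zeros((7, 3, 3), dtype=bool)
        mask[1, 1, 1] = mask[5, 1, 1] = True
        filled = fill_holes_z(mask)
        assert filled[1:6, 1, 1].all()
        assert not filled[0, 1, 1] and not filled[6, 1, 1]
        # in-plane holes untouched
        ring = np.zeros((1, 5, 5), dtype=bool)
        ring[0] = True
        ring[0, 2, 2] = False
        np.testing.assert_array_equal(fill_holes_z(ring), ring)

    def test_constant_volume_returns_empty_mask(self):
        vol = np.full((4, 8, 8), 9, dtype=np.uint16)
        out = refine_nuclei_3d(vol, np.ones((8, 8), dtype=np.int32))
        assert out.max() == 0

    def test_misaligned_planar_labels_raise(self):
        with pytest.raises(ValueError):
            refine_nuclei_3d(np.zeros((4, 8, 8)), np.zeros((9, 9), dtype=int))


class TestCellsAndAssociation:
    def test_filter_small_instances_respects_strict_inequality(self):
        labels = np.zeros((1, 10, 10), dtype=np.int32)
        labels[0, :5, :5] = 1  # 25 voxels
        labels[0, 6:9, 6:9] = 2  # 9 voxels
        out = filter_small_instances(labels, 10)
        assert set(np.unique(out)) == {0, 1}
        assert (filter_small_instances(labels, 9) == 2).sum() == 9

    def test_nucleus_contained_in_its_cell(self, e2e_field):
        _, _, _, result = e2e_field
        nuclei, cells = result["nuclei_by_t"][0], result["cells_by_t"][0]
        assert np.all(cells[nuclei > 0] > 0)

    def test_membrane_island_without_nucleus_is_excluded(self, rng):
        membrane = np.zeros((10, 64, 64))
        membrane[2:8, 5:25, 5:25] = 600  # hosts the nucleus
        membrane[2:8, 40:60, 40:60] = 600  # orphan island
        nuclei = np.zeros((10, 64, 64), dtype=np.int32)
        nuclei[4:6, 12:18, 12:18] = 1
        params = SegmentationParams.desk_scale()
        cells = segment_cells(membrane + rng.normal(100, 3, membrane.shape), nuclei, params)
        assert cells[4, 50, 50] == 0
        assert cells[4, 15, 15] == 1

    def test_two_nuclei_two_cells_bijection(self, e2e_field):
        _, _, truth, result = e2e_field
        nuclei, cells = result["nuclei_by_t"][0], result["cells_by_t"][0]
        mapping, flagged = associate(nuclei, cells)
        assert not flagged
        assert len(set(mapping.values())) == len(mapping) == len(truth.cells_by_t)

    def test_associate_prefers_maximal_overlap(self):
        nuclei = np.zeros((1, 4, 10), dtype=np.int32)
        nuclei[0, :, 2:7] = 1  # 60/40 split between cells A and B
        cells = np.zeros((1, 4, 10), dtype=np.int32)
        cells[0, :, :5] = 1
        cells[0, :, 5:] = 2
        mapping, _ = associate(nuclei, cells)
        assert mapping == {1: 1}

    def test_nucleus_without_cell_is_flagged(self):
        nuclei = np.zeros((1, 4, 4), dtype=np.int32)
        nuclei[0, 1, 1] = 1
        mapping, flagged = associate(nuclei, np.zeros_like(nuclei))
        assert mapping == {} and flagged == [1]


class TestEndToEndSegmentation:
    def test_noiseless_jaccard_against_ground_truth(self, e2e_field):
        """Per-nucleus and per-cell instance overlap with ground truth."""
        _, _, truth, result = e2e_field
        nuc, true_nuc = result["nuclei_by_t"][0], truth.nuclei_by_t[0]
        for lbl in np.unique(true_nuc):
            if lbl == 0:
                continue
            best = 0.0
            for cand in np.unique(nuc):
                if cand == 0:
                    continue
                inter = int(((true_nuc == lbl) & (nuc == cand)).sum())
                union = int(((true_nuc == lbl) | (nuc == cand)).sum())
                best = max(best, inter / union)
            assert best >= 0.8
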