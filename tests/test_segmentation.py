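import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix

from loctrans import segmentation as seg
from loctrans.config import SegmentationConfig
from loctrans.stack import ImageStack, LabelVolume
from conftest import brute_force_distance_map


def matched_agreement(gt_labels: np.ndarray, pred: np.ndarray) -> float:
    both = (gt_labels > 0) & (pred > 0)
    cont = coo_matrix(
        (np.ones(both.sum()), (gt_labels[both], pred[both]))
    ).toarray()
    r, c = linear_sum_assignment(-cont)
    return cont[r, c].sum() / (gt_labels > 0).sum()


class TestEnhanceMembrane:
    def test_constant_image_zero_response(self):
        st = ImageStack(np.full((8, 16, 16), 7.0), (0.3, 0.1, 0.1))
        out = seg.enhance_membrane(st)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_step_edge_max_on_edge_plane(self):
        img = np.zeros((8, 16, 16))
        img[:, :, 8:] = 100.0
        out = seg.enhance_membrane(ImageStack(img, (0.3, 0.1, 0.1)))
        profile = out.data[4, 8]  # response along x through the step
        assert profile.argmax() in (7, 8)

    def test_boundary_response_dominates(self, small_embryo):
        _, membrane, labels, _ = small_embryo
        out = seg.enhance_membrane(membrane)
        b = labels.boundary_mask()
        assert out.data[b].mean() > 2 * out.data[~b].mean()

    def test_rejects_2d(self):
        with pytest.raises(ValueError):
            seg.enhance_membrane(ImageStack(np.zeros((8, 8)), (0.1, 0.1)))


class TestDenoise:
    def test_sigma_zero_identity(self):
        rng = np.random.default_rng(0)
        st = ImageStack(rng.random((6, 12, 12)), (0.3, 0.1, 0.1))
        out = seg.denoise_spot_channel(st, 0.0)
        assert np.array_equal(out.data, st.data)

    def test_hot_pixel_suppressed(self):
        img = np.zeros((9, 21, 21))
        img[4, 10, 10] = 1000.0
        st = ImageStack(img, (0.3, 0.1, 0.1))
        out = seg.denoise_spot_channel(st, (0.6, 0.3, 0.3))
        assert out.data.max() < 100.0
        # interior kernel mass is conserved
        assert out.data.sum() == pytest.approx(1000.0, rel=1e-6)

    def test_negative_sigma_rejected(self):
        st = ImageStack(np.zeros((4, 4, 4)), (0.3, 0.1, 0.1))
        with pytest.raises(ValueError):
            seg.denoise_spot_channel(st, -1.0)


class TestEmbryoMask:
    def test_dice_against_true_ellipsoid(self, small_embryo):
        _, membrane, _, mask = small_embryo
        m = seg.embryo_mask(membrane)
        dice = 2 * (m & mask).sum() / (m.sum() + mask.sum())
        assert dice >= 0.95

    def test_no_rois_empty_exclusion(self):
        m = seg.exclusion_mask((4, 8, 8), (0.3, 0.1, 0.1), None)
        assert not m.any()

    def test_roi_box_marks_voxels_and_clips(self):
        with pytest.warns(UserWarning, match="clip"):
            m = seg.exclusion_mask(
                (4, 8, 8),
                (0.3, 0.1, 0.1),
                [{"min_um": (0, 0, 0), "max_um": (10, 0.4, 0.4)}],
            )
        assert m[:, :4, :4].all()
        assert not m[:, 5:, 5:].any()


class TestSegmentCells:
    def test_single_cell_gives_one_label(self):
        from loctrans import synthetic as syn

        geom = syn.EmbryoGeometry(
            volume_shape=(24, 48, 48), n_cells=1, seed=2
        )
        membrane, labels, mask = syn.generate_embryo(geom)
        enh = seg.enhance_membrane(membrane)
        out = seg.segment_cells(enh, labels.labels > 0)
        assert out.n_labels == 1

    def test_sixteen_cells_recovered(self, seg_embryo):
        _, membrane, labels, _ = seg_embryo
        enh = seg.enhance_membrane(membrane)
        mask = seg.embryo_mask(membrane)
        out = seg.segment_cells(enh, mask)
        assert out.n_labels == 16
        assert matched_agreement(labels.labels, out.labels) >= 0.95

    def test_two_blocks_split_on_bright_plane(self):
        img = np.zeros((21, 16, 16))
        img[10] = 500.0  # bright separating plane
        mask = np.ones_like(img, bool)
        st = ImageStack(img, (0.3, 0.1, 0.1))
        out = seg.segment_cells(st, mask, SegmentationConfig(h_minima_depth=5))
        assert out.n_labels == 2
        assert len(np.unique(out.labels[:9])) == 1
        assert len(np.unique(out.labels[12:])) == 1

    def test_empty_mask_rejected(self):
        st = ImageStack(np.zeros((4, 8, 8)), (0.3, 0.1, 0.1))
        with pytest.raises(ValueError, match="mask"):
            seg.segment_cells(st, np.zeros((4, 8, 8), bool))


class TestDistanceToMembrane:
    def test_plane_grid_arithmetic(self):
        labels = np.zeros((1, 5, 5), np.int64)
        labels[0, :, :] = 1
        labels[0, :, 0] = 2  # boundary column at x=0 and x=1 (inner mode)
        vol = LabelVolume(labels, (0.1, 0.1, 0.1))
        dmap = seg.distance_to_membrane(vol)
        # boundary voxels at x in {0, 1}; voxel x=3 is 0.2 um from x=1
        assert dmap.distances[0, 2, 3] == pytest.approx(0.2)
        assert dmap.distances[0, 2, 0] == 0.0

    def test_anisotropic_z_spacing(self):
        labels = np.zeros((4, 4, 4), np.int64)
        labels[:] = 1
        labels[0] = 2  # boundary plane pair at z = 0/1
        vol = LabelVolume(labels, (0.4, 0.1, 0.1))
        dmap = seg.distance_to_membrane(vol)
        assert dmap.distances[2, 2, 2] == pytest.approx(0.4)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_on_random_volumes(self, trial):
        rng = np.random.default_rng(trial)
        shape = tuple(rng.integers(4, 13, size=3))
        vs = tuple(rng.uniform(0.08, 0.45, size=3))
        labels = rng.integers(0, 3, size=shape).astype(np.int64)
        vol = LabelVolume(labels, vs)
        if not vol.boundary_mask().any():
            pytest.skip("degenerate draw without boundary")
        dmap = seg.distance_to_membrane(vol)
        oracle = brute_force_distance_map(vol.boundary_mask(), vs)
        assert np.allclose(dmap.distances, oracle, atol=1e-9)

    def test_no_boundary_rejected(self):
        vol = LabelVolume(np.zeros((3, 3, 3), np.int64), (0.1, 0.1, 0.1))
        with pytest.raises(ValueError, match="boundary"):
            seg.distance_to_membrane(vol)

    def test_voxel_calibration_propagates(self, small_embryo):
        _, _, labels, _ = small_embryo
        dmap = seg.distance_to_membrane(labels)
        assert dmap.voxel_size == labels.voxel_size
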