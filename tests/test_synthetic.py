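import numpy as np
import pytest

from loctrans import synthetic as syn
from loctrans.frap import correct_trace


class TestGenerateEmbryo:
    def test_single_cell_membrane_is_surface_shell(self):
        geom = syn.EmbryoGeometry(
            volume_shape=(24, 48, 48), n_cells=1,
            psf_sigma_um=(1e-9, 1e-9, 1e-9), membrane_intensity=500,
            background_level=0, seed=0,
        )
        membrane, labels, mask = syn.generate_embryo(geom)
        assert labels.n_labels == 1
        shell = labels.boundary_mask()
        assert np.all(membrane.data[shell] > 0)
        assert np.all(membrane.data[~shell] == 0)

    def test_same_seed_voxel_identical(self):
        geom = syn.EmbryoGeometry(n_cells=6, seed=3)
        m1, l1, k1 = syn.generate_embryo(geom)
        m2, l2, k2 = syn.generate_embryo(geom)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(l1.labels, l2.labels)
        assert np.array_equal(k1, k2)

    def test_boundary_voxels_brighter_than_background(self, small_embryo):
        _, membrane, labels, _ = small_embryo
        b = labels.boundary_mask()
        assert membrane.data[b].mean() > 2 * np.median(membrane.data)

    def test_cells_partition_embryo_interior(self, small_embryo):
        _, _, labels, mask = small_embryo
        assert np.array_equal(labels.labels > 0, mask)

    def test_too_small_volume_rejected(self):
        geom = syn.EmbryoGeometry(volume_shape=(4, 8, 8), n_cells=50)
        with pytest.raises(ValueError, match="too small"):
            syn.generate_embryo(geom)


class TestSpotPlacement:
    def test_p_membrane_one_all_in_band(self, small_embryo):
        _, _, labels, _ = small_embryo
        p = syn.SpotPlacementParams(n_spots=50, p_membrane=1.0, seed=1)
        _, gt = syn.place_and_render_spots(labels, p)
        assert (gt.spots.membrane_distance_um <= p.band_width_um).all()

    def test_p_membrane_zero_none_in_band(self, small_embryo):
        _, _, labels, _ = small_embryo
        p = syn.SpotPlacementParams(n_spots=50, p_membrane=0.0, seed=1)
        _, gt = syn.place_and_render_spots(labels, p)
        assert (gt.spots.membrane_distance_um > p.band_width_um).all()

    def test_realized_fraction_converges(self, small_embryo):
        # binomial: at n=2000 the realized fraction lies within ~3 sd
        _, _, labels, _ = small_embryo
        p = syn.SpotPlacementParams(n_spots=2000, p_membrane=0.5, seed=4)
        _, gt = syn.place_and_render_spots(labels, p)
        frac = (gt.spots.membrane_distance_um <= 0.35).mean()
        assert abs(frac - 0.5) < 0.03

    def test_one_ground_truth_row_per_spot(self, small_embryo):
        _, _, labels, _ = small_embryo
        p = syn.SpotPlacementParams(n_spots=37, seed=2)
        _, gt = syn.place_and_render_spots(labels, p)
        assert len(gt.spots) == 37
        assert (gt.spots.membrane_distance_um >= 0).all()

    def test_deterministic(self, small_embryo):
        _, _, labels, _ = small_embryo
        p = syn.SpotPlacementParams(n_spots=20, seed=9)
        img1, gt1 = syn.place_and_render_spots(labels, p)
        img2, gt2 = syn.place_and_render_spots(labels, p)
        assert np.array_equal(img1.data, img2.data)
        assert gt1.spots.equals(gt2.spots)


class TestColocScenes:
    def test_full_overlap_perfect_efficiency_identical_positions(
        self, small_embryo
    ):
        _, _, labels, _ = small_embryo
        p = syn.ColocParams(
            n_mrna=40, true_overlap_fraction=1.0,
            detection_efficiency=(1.0, 1.0), max_pairing_offset_um=0.0,
            seed=5,
        )
        ch1, ch2, gt = syn.generate_coloc_pair(labels, p)
        a = gt.spots[gt.spots.channel == 1][["z_um", "y_um", "x_um"]].to_numpy()
        b = gt.spots[gt.spots.channel == 2][["z_um", "y_um", "x_um"]].to_numpy()
        assert np.allclose(a, b)
        assert len(gt.pairings()) == 40

    def test_zero_overlap_no_pairings(self, small_embryo):
        _, _, labels, _ = small_embryo
        p = syn.ColocParams(n_mrna=30, true_overlap_fraction=0.0, seed=6)
        _, _, gt = syn.generate_coloc_pair(labels, p)
        assert gt.pairings() == []
        assert (gt.spots.channel == 2).sum() == 0

    def test_detection_efficiency_thins_channel(self, small_embryo):
        # binomial oracle at n=1000: fraction of channel-1 spots with a
        # rendered partner ~ 0.62 +/- 0.03
        _, _, labels, _ = small_embryo
        p = syn.ColocParams(
            n_mrna=1000, true_overlap_fraction=1.0,
            detection_efficiency=(1.0, 0.62), seed=7,
        )
        _, _, gt = syn.generate_coloc_pair(labels, p)
        n1 = (gt.spots.channel == 1).sum()
        assert n1 == 1000
        assert abs(len(gt.pairings()) / n1 - 0.62) < 0.03


class TestSimulateFrap:
    def test_immobile_trace_flat_after_correction(self):
        p = syn.FrapSimParams(
            mobile_fraction=0.0, acquisition_bleach_rate=0.995, seed=0
        )
        trace, _ = syn.simulate_frap(p)
        c = correct_trace(trace)
        assert np.allclose(c.corrected[c.post], 0.0, atol=1e-12)

    def test_uncorrupted_trace_equals_truth_times_prebleach(self):
        p = syn.FrapSimParams(
            acquisition_bleach_rate=1.0, background_level=0.0, seed=0
        )
        trace, gt = syn.simulate_frap(p)
        post = trace.time_s >= 0
        pre = p.prebleach_intensity
        expected = pre * (
            (1 - p.bleach_depth) + gt.normalized_prebleach
        )
        assert np.allclose(trace.bleached[post], expected)

    def test_closed_form_recovery_at_half_time(self):
        # 0.6 * (1 - e^{-ln 2}) = 0.30
        p = syn.FrapSimParams(mobile_fraction=0.6, half_time_s=120.0, seed=0)
        _, gt = syn.simulate_frap(p)
        i = int(np.flatnonzero(gt.time_s == 120.0)[0])
        assert gt.recovery_fraction[i] == pytest.approx(0.30, abs=1e-12)

    def test_time_grid(self):
        p = syn.FrapSimParams(seed=0)
        trace, _ = syn.simulate_frap(p)
        assert trace.time_s[trace.n_prebleach] == 0.0
        assert np.allclose(np.diff(trace.time_s), 20.0)
        assert trace.time_s[-1] == 1200.0


class TestLinescanFixture:
    def test_construction_values(self):
        img, layout = syn.generate_linescan_image(300, 100, 50)
        assert layout["expected_ratio"] == pytest.approx(5.0)
        assert img.data.max() == 300
        assert img.data.min() == 50

    def test_no_enrichment(self):
        _, layout = syn.generate_linescan_image(100, 100, 0)
        assert layout["expected_ratio"] == pytest.approx(1.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_linescan_image(100, 200, 50)
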