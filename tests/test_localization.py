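import numpy as np
import pytest
from scipy.spatial import cKDTree

from loctrans import synthetic as syn
from loctrans.image_io import new_spot_table
from loctrans.localization import (
    categorize_spots,
    proximity_fraction,
    relocalization_report,
    spot_membrane_distances,
    zflip_null,
)
from loctrans.segmentation import distance_to_membrane
from loctrans.stack import DistanceMap, ImageStack


def table_with_distances(distances):
    n = len(distances)
    t = new_spot_table(np.tile([1.0, 1.0, 1.0], (n, 1)))
    t["membrane_distance_um"] = distances
    return t


class TestSpotDistances:
    def test_spot_on_boundary_voxel_zero(self, small_embryo):
        _, _, labels, _ = small_embryo
        dmap = distance_to_membrane(labels)
        b = np.argwhere(labels.boundary_mask())[0]
        center = b * np.array(labels.voxel_size)
        t = new_spot_table(center[None, :])
        out = spot_membrane_distances(t, dmap)
        assert out.membrane_distance_um.iloc[0] == 0.0

    def test_interpolated_close_to_brute_force(self, small_embryo):
        _, _, labels, _ = small_embryo
        dmap = distance_to_membrane(labels)
        vs = np.array(labels.voxel_size)
        rng = np.random.default_rng(3)
        inside = np.argwhere(labels.labels > 0)
        pts = (
            inside[rng.choice(len(inside), 100, replace=False)]
            + rng.uniform(-0.5, 0.5, (100, 3))
        ) * vs
        t = new_spot_table(pts)
        out = spot_membrane_distances(t, dmap)
        boundary_pts = np.argwhere(labels.boundary_mask()) * vs
        brute = cKDTree(boundary_pts).query(pts)[0]
        half_diag = np.linalg.norm(vs) / 2
        assert np.all(
            np.abs(out.membrane_distance_um.to_numpy() - brute) <= half_diag
        )

    def test_spot_outside_map_rejected(self):
        dmap = DistanceMap(np.zeros((4, 4, 4)), (0.1, 0.1, 0.1))
        t = new_spot_table(np.array([[10.0, 10.0, 10.0]]))
        with pytest.raises(ValueError, match="outside"):
            spot_membrane_distances(t, dmap)


class TestProximityFraction:
    def test_closed_band_arithmetic(self):
        t = table_with_distances([0.10, 0.30, 0.35, 0.40, 1.20])
        res = proximity_fraction(t, 0.35)
        assert res.n_within == 3
        assert res.fraction_within == pytest.approx(0.60)

    def test_all_beyond_cutoff(self):
        res = proximity_fraction(table_with_distances([0.5, 0.9]), 0.35)
        assert res.fraction_within == 0.0

    def test_monotone_in_cutoff(self):
        t = table_with_distances(np.linspace(0, 2, 40))
        fr = [
            proximity_fraction(t, c).fraction_within
            for c in (0.1, 0.35, 0.7, 1.5)
        ]
        assert fr == sorted(fr)

    def test_zero_spots_rejected(self):
        with pytest.raises(ValueError):
            proximity_fraction(new_spot_table(), 0.35)


class TestZFlip:
    def test_involution_and_intensity_preserved(self):
        rng = np.random.default_rng(0)
        st = ImageStack(rng.random((5, 8, 8)), (0.3, 0.1, 0.1))
        flipped = zflip_null(st)
        assert np.array_equal(zflip_null(flipped).data, st.data)
        assert flipped.data.sum() == st.data.sum()

    def test_single_voxel_moves_to_mirror_plane(self):
        img = np.zeros((5, 4, 4))
        img[0, 2, 2] = 1.0
        flipped = zflip_null(ImageStack(img, (0.3, 0.1, 0.1)))
        assert flipped.data[4, 2, 2] == 1.0
        assert flipped.data[0, 2, 2] == 0.0


class TestCategorize:
    def _maps(self):
        # membrane distance large everywhere except x=0; nuclear distance
        # small near x=4
        mem = np.tile(np.arange(5, dtype=float)[None, None, :], (1, 5, 1)) * 0.5
        nuc = mem[..., ::-1].copy()
        vs = (0.5, 0.5, 0.5)
        return DistanceMap(mem, vs), DistanceMap(nuc, vs)

    def test_rule_application(self):
        dmem, dnuc = self._maps()
        t = new_spot_table(
            np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 0.1], [0.0, 1.0, 1.0]])
        )
        out = categorize_spots(t, dmem, dnuc, cutoff_um=0.35)
        # x=2.0 um -> nuclear dist 0, membrane 2: nuclear_pore
        # x=0.1 -> membrane ~0.1: plasma_membrane; x=1.0 -> far: cytosol
        assert list(out.category) == [
            "nuclear_pore", "plasma_membrane", "cytosol"
        ]

    def test_without_nuclear_map(self):
        dmem, _ = self._maps()
        t = new_spot_table(np.array([[0.0, 1.0, 0.1], [0.0, 1.0, 2.0]]))
        out = categorize_spots(t, dmem, None, cutoff_um=0.35)
        assert list(out.category) == ["plasma_membrane", "cytosol"]

    def test_exclusion_mask_drops_spots(self):
        dmem, dnuc = self._maps()
        t = new_spot_table(np.array([[0.0, 1.0, 0.1], [0.0, 1.0, 2.0]]))
        excl = np.zeros((1, 5, 5), bool)
        excl[0, 2, 0] = True  # voxel of the first spot
        out = categorize_spots(t, dmem, dnuc, 0.35, exclusion=excl)
        assert len(out) == 1

    def test_class_recovery_on_synthetic_placement(self, small_embryo):
        # 80% of spots placed in the membrane band are recovered as
        # membrane-category spots within +/-0.05
        _, _, labels, _ = small_embryo
        params = syn.SpotPlacementParams(n_spots=800, p_membrane=0.8, seed=6)
        _, gt = syn.place_and_render_spots(labels, params)
        dmap = distance_to_membrane(labels)
        t = new_spot_table(gt.spots[["z_um", "y_um", "x_um"]].to_numpy())
        out = categorize_spots(t, dmap, None, cutoff_um=0.35)
        frac = (out.category == "plasma_membrane").mean()
        assert abs(frac - 0.8) < 0.05


class TestRelocalizationReport:
    def _embryo(self, cats):
        t = new_spot_table(np.tile([1.0, 1.0, 1.0], (len(cats), 1)))
        t["category"] = cats
        return t

    def test_percentages_and_mean(self):
        e1 = self._embryo(["nuclear_pore"] * 6 + ["cytosol"] * 4)
        e2 = self._embryo(["nuclear_pore"] * 8 + ["cytosol"] * 2)
        rep = relocalization_report({"a": e1, "b": e2}, min_spots=7)
        assert rep.loc[0, "pct_nuclear_pore"] == pytest.approx(60.0)
        assert rep.loc[1, "pct_nuclear_pore"] == pytest.approx(80.0)
        assert rep.iloc[-1]["pct_nuclear_pore"] == pytest.approx(70.0)

    def test_strict_inclusion_boundary(self):
        e7 = self._embryo(["cytosol"] * 7)
        e8 = self._embryo(["cytosol"] * 8)
        rep = relocalization_report({"seven": e7, "eight": e8}, min_spots=7)
        assert not rep.loc[0, "included"]
        assert rep.loc[1, "included"]
        # summary only over included embryos
        assert rep.iloc[-1]["n_spots"] == 8
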