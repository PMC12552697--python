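"""Scaffold geometry: implicit fields, calibration, and pore metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgbr.image import ImageVolume
from sgbr.geometry import (ScaffoldSpec, UnsupportedFamilyError,
                           CalibrationError, tpms_field, unit_cell_grid,
                           calibrate_iso_level, voxelize, volume_fraction,
                           pore_size, strut_size, bcc_lattice,
                           generate_scaffold)


def grid(n, h):
    return ImageVolume(np.zeros((n, n, n)), (h, h, h))


class TestTpmsField:
    def test_gyroid_vanishes_at_origin(self):
        """Every term of the gyroid field is zero at the cell origin."""
        spec = ScaffoldSpec("gyroid", 3.5, voxel_spacing=0.1)
        g = ImageVolume(np.zeros((2, 2, 2)), (0.01,) * 3,
                        origin=(-0.005, -0.005, -0.005))
        f = tpms_field(spec, g)
        assert abs(f.values[0, 0, 0]) < 1e-12

    def test_schwarz_p_is_three_at_origin(self):
        spec = ScaffoldSpec("schwarz_p", 2.0, voxel_spacing=0.05)
        g = ImageVolume(np.zeros((2, 2, 2)), (0.01,) * 3,
                        origin=(-0.005, -0.005, -0.005))
        f = tpms_field(spec, g)
        assert f.values[0, 0, 0] == pytest.approx(3.0, abs=1e-12)

    @pytest.mark.parametrize("family,L", [("gyroid", 3.5), ("schwarz_p", 2.0)])
    def test_matches_pointwise_formula(self, family, L):
        """Field values equal an independent scalar evaluation, including
        at the quarter-cell point (L/4, L/4, L/4)."""
        spec = ScaffoldSpec(family, L, voxel_spacing=L / 14)
        g = unit_cell_grid(spec)
        f = tpms_field(spec, g)
        k = 2 * np.pi / L
        cx, cy, cz = g.voxel_centers()
        X, Y, Z = np.meshgrid(k * cx, k * cy, k * cz, indexing="ij")
        if family == "gyroid":
            ref = (np.sin(X) * np.cos(Y) + np.sin(Y) * np.cos(Z)
                   + np.sin(Z) * np.cos(X))
        else:
            ref = np.cos(X) + np.cos(Y) + np.cos(Z)
        np.testing.assert_allclose(f.values, ref, atol=1e-12)
        # explicit quarter-cell spot check against a hand evaluation
        q = k * L / 4.0
        hand = (np.sin(q) * np.cos(q) * 3.0 if family == "gyroid"
                else 3.0 * np.cos(q))
        i = np.argmin(np.abs(cx - L / 4))
        assert f.values[i, i, i] == pytest.approx(
            hand, abs=abs(hand) * 0.2 + 0.2)  # nearest voxel centre

    def test_periodicity(self):
        """Shifting the grid by one unit cell reproduces the field."""
        spec = ScaffoldSpec("gyroid", 3.5, voxel_spacing=0.25)
        g = unit_cell_grid(spec)
        f0 = tpms_field(spec, g)
        g_shift = ImageVolume(g.values, g.spacing, origin=(3.5, 3.5, 3.5))
        f1 = tpms_field(spec, g_shift)
        np.testing.assert_allclose(f0.values, f1.values, atol=1e-9)

    def test_non_tpms_family_rejected(self):
        spec = ScaffoldSpec("bcc_beam", 1.875, strut_or_beam_size=0.4,
                            voxel_spacing=0.1)
        with pytest.raises(UnsupportedFamilyError):
            tpms_field(spec, grid(8, 0.2))


class TestSpecValidation:
    def test_resolution_floor(self):
        with pytest.raises(ValueError):
            ScaffoldSpec("gyroid", 3.5, voxel_spacing=1.0)

    def test_beam_thickness_bound(self):
        with pytest.raises(ValueError):
            ScaffoldSpec("bcc_beam", 1.875, strut_or_beam_size=1.0,
                         voxel_spacing=0.1)


class TestCalibration:
    @pytest.mark.parametrize("family,L,h", [("gyroid", 3.5, 0.1),
                                            ("schwarz_p", 2.0, 0.05)])
    def test_equal_split_iso_level_is_zero(self, family, L, h):
        """Both surfaces split space 50/50 at level zero by symmetry."""
        spec = ScaffoldSpec(family, L, 0.5, voxel_spacing=h)
        f = tpms_field(spec, unit_cell_grid(spec))
        t = calibrate_iso_level(f, 0.5)
        assert abs(t) < 0.02
        vf = volume_fraction(voxelize(f, t))
        assert vf == pytest.approx(0.5, abs=2e-3)

    def test_dense_grid_counting_oracle(self):
        """Calibrated 30% level agrees with voxel counting at 2x finer
        sampling (independent count on an independent grid)."""
        spec = ScaffoldSpec("gyroid", 3.5, 0.3, voxel_spacing=0.1)
        f = tpms_field(spec, unit_cell_grid(spec))
        t = calibrate_iso_level(f, 0.3, tol=1e-3)
        fine = tpms_field(spec, unit_cell_grid(spec, spacing=0.05))
        frac_fine = float((fine.values <= t).mean())
        assert frac_fine == pytest.approx(0.3, abs=5e-3)

    @pytest.mark.parametrize("family", ["gyroid", "schwarz_p"])
    def test_round_trip_over_targets(self, family):
        """volume_fraction(voxelize(field, calibrate(v))) == v +- tol."""
        spec = ScaffoldSpec(family, 3.5, voxel_spacing=0.1)
        f = tpms_field(spec, unit_cell_grid(spec))
        for v in (0.2, 0.3, 0.5, 0.7):
            t = calibrate_iso_level(f, v, tol=1e-3)
            assert volume_fraction(voxelize(f, t)) == pytest.approx(v,
                                                                    abs=2e-3)

    def test_monotone_in_target(self):
        spec = ScaffoldSpec("gyroid", 3.5, voxel_spacing=0.15)
        f = tpms_field(spec, unit_cell_grid(spec))
        isos = [calibrate_iso_level(f, v) for v in (0.2, 0.35, 0.5, 0.65, 0.8)]
        assert all(b >= a for a, b in zip(isos, isos[1:]))

    def test_constant_field_fails(self):
        f = ImageVolume(np.ones((8, 8, 8)), (0.1,) * 3)
        with pytest.raises(CalibrationError):
            calibrate_iso_level(f, 0.5)


class TestVoxelizeAndVolumeFraction:
    def test_constant_fields(self):
        g = grid(6, 0.2)
        assert not voxelize(g.with_values(np.ones((6, 6, 6))), 0).values.any()
        assert voxelize(g.with_values(-np.ones((6, 6, 6))), 0).values.all()

    def test_all_solid_and_checkerboard(self):
        g = grid(6, 0.2)
        assert volume_fraction(g.with_values(np.ones((6, 6, 6), bool))) == 1.0
        idx = np.indices((6, 6, 6)).sum(axis=0) % 2 == 0
        assert volume_fraction(g.with_values(idx)) == 0.5

    def test_empty_region_error(self):
        g = grid(4, 0.2)
        with pytest.raises(ValueError):
            volume_fraction(g.with_values(np.ones((4, 4, 4), bool)),
                            region=np.zeros((4, 4, 4), bool))


class TestPoreSize:
    def test_open_cube(self):
        """An all-void 10 mm cube admits a 10 mm inscribed sphere."""
        m = ImageVolume(np.zeros((20, 20, 20), bool), (0.5,) * 3)
        d, perc = pore_size(m, periodic=False)
        assert d == pytest.approx(10.0, abs=0.5)

    def test_cylindrical_channel(self):
        """A straight 2 mm channel admits a 2 mm sphere (one-voxel tol)."""
        n, h = 40, 0.1
        vals = np.ones((n, n, n), bool)
        c = (np.arange(n) + 0.5) * h
        X, Y = np.meshgrid(c, c, indexing="ij")
        vals[(X - 2) ** 2 + (Y - 2) ** 2 <= 1.0, :] = False
        d, perc = pore_size(ImageVolume(vals, (h,) * 3), periodic=False)
        assert perc
        assert d == pytest.approx(2.0, abs=1.2 * h)

    def test_gyroid_matches_sphere_fitting_oracle(self, gyroid_cell_fine):
        """Distance-transform pore size equals brute-force morphological
        opening by growing spheres on the same periodic grid."""
        from scipy import ndimage
        mask, _ = gyroid_cell_fine
        d, perc = pore_size(mask)
        assert perc
        h = mask.spacing[0]
        void = ~np.tile(mask.values.astype(bool), (3, 3, 3))
        n = mask.shape[0]
        centre = (slice(n, 2 * n),) * 3

        def sphere_fits(radius_vox):
            r = int(radius_vox)
            ax = np.arange(-r, r + 1)
            X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
            ball = X * X + Y * Y + Z * Z <= r * r
            return ndimage.binary_erosion(void, structure=ball)[centre].any()

        r_vox = d / 2.0 / h
        assert sphere_fits(np.floor(r_vox))
        assert not sphere_fits(np.ceil(r_vox) + 1)

    def test_all_solid_error(self):
        with pytest.raises(ValueError):
            pore_size(ImageVolume(np.ones((6, 6, 6), bool), (0.1,) * 3))


class TestStrutSize:
    def test_slab_thickness(self):
        sv = np.zeros((30, 30, 30), bool)
        sv[:, :, 10:20] = True
        assert strut_size(ImageVolume(sv, (0.1,) * 3)) == pytest.approx(
            1.0, abs=0.1)

    def test_printed_beam_thickness_round_trip(self):
        """A 0.4 mm solid cylinder measures 0.4 mm within one voxel."""
        n, h = 32, 0.025
        c = (np.arange(n) + 0.5) * h
        X, Y = np.meshgrid(c, c, indexing="ij")
        cyl = (X - 0.4) ** 2 + (Y - 0.4) ** 2 <= 0.2 ** 2
        sv = np.zeros((n, n, 12), bool)
        sv[cyl, :] = True
        assert strut_size(ImageVolume(sv, (h,) * 3)) == pytest.approx(
            0.4, abs=h)

    def test_gyroid_matches_erosion_oracle(self, gyroid_cell_fine):
        """The thinnest strut disappears under erosion by its half-width
        but survives erosion one voxel smaller."""
        from scipy import ndimage
        mask, _ = gyroid_cell_fine
        s = strut_size(mask)
        h = mask.spacing[0]
        solid = np.tile(mask.values.astype(bool), (3, 3, 3))
        r_vox = int(round(s / 2.0 / h))

        def erode(r):
            if r <= 0:
                return solid
            ax = np.arange(-r, r + 1)
            X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
            return ndimage.binary_erosion(
                solid, structure=X * X + Y * Y + Z * Z <= r * r)

        from scipy.ndimage import label
        n_before = label(erode(max(r_vox - 1, 0)))[1]
        n_after = label(erode(r_vox + 1))[1]
        # erosion past the half-width severs or removes the thinnest path
        assert n_after == 0 or n_after > n_before

    def test_all_void_error(self):
        with pytest.raises(ValueError):
            strut_size(ImageVolume(np.zeros((6, 6, 6), bool), (0.1,) * 3))


class TestBccLattice:
    def test_single_cell_matches_capsule_oracle(self):
        """Voxelized beams equal the analytic capsule union of the
        corner-to-centre segments (measured on the unwarped central cell
        of a 3x3x3-cell block)."""
        cell, beam, h = 1.875, 0.5, 0.075
        n = int(round(3 * cell / h))
        region = ImageVolume(np.ones((n, n, n), bool), (h,) * 3)
        spec = ScaffoldSpec("bcc_beam", cell, strut_or_beam_size=beam,
                            voxel_spacing=h)
        lat = bcc_lattice(spec, region).values

        # independent capsule-union oracle over all 27 cells
        segs = []
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    lo = np.array([i, j, k], float) * cell
                    c = lo + cell / 2
                    for ci in (0, 1):
                        for cj in (0, 1):
                            for ck in (0, 1):
                                segs.append((lo + np.array([ci, cj, ck])
                                             * cell, c))
        ax = (np.arange(n) + 0.5) * h
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        inside = np.zeros((n, n, n), bool)
        r2 = (beam / 2) ** 2
        for a, b in segs:
            ab = b - a
            L2 = ab @ ab
            t = np.clip(((X - a[0]) * ab[0] + (Y - a[1]) * ab[1]
                         + (Z - a[2]) * ab[2]) / L2, 0, 1)
            d2 = ((X - a[0] - t * ab[0]) ** 2 + (Y - a[1] - t * ab[1]) ** 2
                  + (Z - a[2] - t * ab[2]) ** 2)
            inside |= d2 <= r2
        m = int(round(cell / h))
        centre = (slice(m, 2 * m),) * 3
        mismatch = (lat[centre] != inside[centre]).mean()
        assert mismatch < 1e-3

    def test_empty_region(self):
        region = ImageVolume(np.zeros((10, 10, 10), bool), (0.2,) * 3)
        spec = ScaffoldSpec("bcc_beam", 1.875, strut_or_beam_size=0.4,
                            voxel_spacing=0.2)
        assert not bcc_lattice(spec, region).values.any()

    def test_rotation_preserves_solid_volume(self):
        """0 vs 45 degree lattices have equal solid volume in a spherical
        envelope (rigid motion preserves beam lengths away from the
        boundary)."""
        h, R = 0.075, 6.0
        n = int(2 * R / h) + 8
        c = (np.arange(n) + 0.5) * h - n * h / 2
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        region = ImageVolume(X * X + Y * Y + Z * Z <= R * R, (h,) * 3)
        vols = {}
        for rot in (0.0, 45.0):
            spec = ScaffoldSpec("bcc_beam", 1.875, strut_or_beam_size=0.6,
                                lattice_rotation=rot, voxel_spacing=h)
            vols[rot] = int(bcc_lattice(spec, region).values.sum())
        assert abs(vols[0.0] - vols[45.0]) / vols[0.0] < 0.02


class TestConvergence:
    def test_pore_and_strut_richardson(self):
        """Halving the spacing changes both metrics by less than the
        coarser spacing of each pair."""
        vals = {}
        for h in (0.2, 0.1, 0.05):
            spec = ScaffoldSpec("gyroid", 3.5, 0.5, voxel_spacing=h)
            mask, _ = generate_scaffold(spec)
            vals[h] = (pore_size(mask)[0], strut_size(mask))
        for coarse, fine in ((0.2, 0.1), (0.1, 0.05)):
            assert abs(vals[coarse][0] - vals[fine][0]) < coarse
            assert abs(vals[coarse][1] - vals[fine][1]) < coarse


@settings(max_examples=20, deadline=None, derandomize=True)
@given(v=st.floats(0.1, 0.9))
def test_calibration_round_trip_property(v):
    """Any attainable target fraction round-trips through calibration."""
    spec = ScaffoldSpec("gyroid", 3.5, voxel_spacing=0.25)
    f = tpms_field(spec, unit_cell_grid(spec))
    t = calibrate_iso_level(f, v, tol=1e-3)
    assert volume_fraction(voxelize(f, t)) == pytest.approx(v, abs=0.05)
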