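import numpy as np
import pytest

import diffusekit as dk
from diffusekit.images import geometry_factors, hkl_to_pixel, rotation_series


@pytest.fixture
def smooth_map(supercell_model):
    grid = dk.ReciprocalGrid.for_model(supercell_model, d_min=2.5)
    vals = 200.0 * np.exp(-grid.s_mod**2 / 0.15) * (1.2 + np.sin(2 * np.pi * grid.s_mod * 4))
    return dk.DiffuseMap(grid, vals, grid.in_sphere.copy(), provenance="synthetic")


class TestModeFilter:
    def test_constant_image_unchanged(self):
        img = dk.DetectorImage(pixels=np.full((40, 40), 100.0))
        out = dk.mode_filter(img, kernel=15, bin_width=1.0)
        assert np.array_equal(out.pixels, img.pixels)
        assert not out.mask.any()

    def test_single_outlier_replaced_by_background(self):
        pix = np.full((40, 40), 100.0)
        pix[20, 20] = 10000.0
        out = dk.mode_filter(dk.DetectorImage(pixels=pix), kernel=15, bin_width=1.0)
        assert out.pixels[20, 20] == 100.0
        assert np.all(out.pixels == 100.0)

    def test_no_new_values_invented(self):
        rng = np.random.default_rng(0)
        pix = rng.integers(90, 110, size=(30, 30)).astype(float)
        out = dk.mode_filter(dk.DetectorImage(pixels=pix), kernel=5, bin_width=1.0)
        # every output value is an occupied bin representative of the input
        in_bins = set(np.floor(pix.ravel()).astype(int))
        out_bins = set(np.floor(out.pixels.ravel()).astype(int))
        assert out_bins <= in_bins

    def test_tie_breaks_to_lowest_bin(self):
        # neighborhood with equal counts of 10 and 20 -> 10 wins
        pix = np.tile(np.array([[10.0, 20.0]]), (3, 3))[:3, :3]
        pix = np.array([[10.0, 20, 10], [20, 10, 20], [10, 20, 20]])
        out = dk.mode_filter(dk.DetectorImage(pixels=pix), kernel=3, bin_width=1.0)
        # center window: five 20s vs four 10s -> 20; corner windows tie -> 10
        assert out.pixels[1, 1] == 20.0
        assert out.pixels[0, 0] == 10.0

    def test_masked_neighborhood_propagates(self):
        pix = np.full((20, 20), 50.0)
        mask = np.zeros((20, 20), dtype=bool)
        mask[:5, :5] = True
        out = dk.mode_filter(dk.DetectorImage(pixels=pix, mask=mask), kernel=3, bin_width=1.0)
        assert out.mask[0, 0]          # fully masked neighborhood
        assert not out.mask[10, 10]
        assert out.pixels[6, 6] == 50.0  # partially masked neighborhood still works

    def test_invalid_kernel_rejected(self):
        img = dk.DetectorImage(pixels=np.zeros((10, 10)))
        with pytest.raises(ValueError):
            dk.mode_filter(img, kernel=4)
        with pytest.raises(ValueError):
            dk.mode_filter(img, kernel=15, bin_width=0)


class TestGeometryCorrection:
    def test_beam_center_factor_unity(self, detector_geometry):
        f = geometry_factors(detector_geometry)
        cy, cx = detector_geometry.beam_center
        # nearest pixel to the (half-integer) beam centre
        assert abs(f[int(round(cy)), int(round(cx))] - 1.0) < 1e-3

    def test_inverse_construction_recovered(self, detector_geometry):
        flat = 123.4
        synth = flat * geometry_factors(detector_geometry)
        img = dk.DetectorImage(pixels=synth, geometry=detector_geometry)
        out = dk.correct_geometry(img)
        assert np.allclose(out.pixels, flat, rtol=1e-9)

    def test_factors_match_scalar_oracle(self, detector_geometry):
        """Per-pixel P and Omega recomputed pixel-by-pixel from first principles."""
        g = detector_geometry
        f = geometry_factors(g)
        rng = np.random.default_rng(1)
        for _ in range(20):
            i, j = rng.integers(0, g.shape[0]), rng.integers(0, g.shape[1])
            x = (j - g.beam_center[1]) * g.pixel_mm
            y = (i - g.beam_center[0]) * g.pixel_mm
            r = np.sqrt(x * x + y * y + g.distance_mm**2)
            cos2t = g.distance_mm / r
            sin2t2 = 1 - cos2t**2
            phi = np.arctan2(y, x)
            P = 0.5 * (1 - sin2t2 * np.cos(phi) ** 2) + 0.5 * (1 - sin2t2 * np.sin(phi) ** 2)
            assert np.isclose(f[i, j], P * cos2t**3, rtol=1e-12)

    def test_unpolarized_limit_formula(self):
        g = dk.DetectorGeometry(
            distance_mm=50, pixel_mm=0.5, wavelength=1.0, shape=(64, 64),
            beam_center=(31.5, 31.5), polarization_fraction=0.5,
        )
        f = geometry_factors(g)
        i, j = 10, 50
        x = (j - 31.5) * 0.5
        y = (i - 31.5) * 0.5
        r = np.sqrt(x**2 + y**2 + 50**2)
        cos2t = 50 / r
        assert np.isclose(f[i, j], (1 + cos2t**2) / 2 * cos2t**3, rtol=1e-12)

    def test_missing_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            dk.correct_geometry(dk.DetectorImage(pixels=np.ones((4, 4))))

    def test_correction_invertible(self, detector_geometry):
        rng = np.random.default_rng(2)
        pix = rng.uniform(10, 100, detector_geometry.shape)
        img = dk.DetectorImage(pixels=pix, geometry=detector_geometry)
        out = dk.correct_geometry(img)
        back = out.pixels * geometry_factors(detector_geometry)
        assert np.allclose(back, pix, rtol=1e-12)


class TestEwaldMapping:
    def test_beam_center_maps_to_origin(self, detector_geometry, supercell_model):
        setting = rotation_series(supercell_model.lattice, [0.0])[0]
        hkl = dk.pixel_to_hkl(
            np.array(detector_geometry.beam_center), detector_geometry, setting
        )
        assert np.allclose(hkl, 0, atol=1e-12)

    def test_forward_backward_consistency(self, detector_geometry, supercell_model):
        setting = rotation_series(supercell_model.lattice, [13.0])[0]
        rng = np.random.default_rng(3)
        # forward-project random hkl near the Ewald sphere, then invert
        ny, nx = detector_geometry.shape
        pix = rng.uniform(10, 110, (50, 2))
        hkl = dk.pixel_to_hkl(pix, detector_geometry, setting)
        ij, offset, visible = hkl_to_pixel(hkl, detector_geometry, setting)
        assert np.allclose(offset, 0, atol=1e-9)  # pixel hkl sit on the sphere
        assert np.allclose(ij[visible], pix[visible], atol=1e-6)

    def test_bragg_relation_satisfied(self, detector_geometry, supercell_model):
        """|s| of a pixel's hkl obeys |s| = 2 sin(theta) / lambda."""
        setting = rotation_series(supercell_model.lattice, [0.0])[0]
        g = detector_geometry
        pix = np.array([[100.0, 30.0]])
        hkl = dk.pixel_to_hkl(pix, g, setting)[0]
        s = supercell_model.lattice.unit_cell().s_modulus(hkl)
        x = (30.0 - g.beam_center[1]) * g.pixel_mm
        y = (100.0 - g.beam_center[0]) * g.pixel_mm
        two_theta = np.arctan2(np.hypot(x, y), g.distance_mm)
        assert np.isclose(s, 2 * np.sin(two_theta / 2) / g.wavelength, rtol=1e-9)

    def test_axis_aligned_bragg_angle_gives_h_near_one(self, supercell_model):
        """A pixel at 2theta = 2 arcsin(lambda/2a) along a* indexes to h ~ 1."""
        unit = supercell_model.lattice.unit_cell()
        geom = dk.DetectorGeometry(
            distance_mm=100.0, pixel_mm=0.2, wavelength=1.54,
            shape=(512, 512), beam_center=(255.5, 255.5),
        )
        setting = dk.OrientationSetting(matrix=unit.reciprocal_matrix, angle_deg=0.0)
        two_theta = 2 * np.arcsin(geom.wavelength / (2 * unit.a))
        r_mm = geom.distance_mm * np.tan(two_theta)
        pix = np.array([geom.beam_center[0], geom.beam_center[1] + r_mm / geom.pixel_mm])
        h, k, l = dk.pixel_to_hkl(pix, geom, setting)
        # the curvature of the Ewald sphere leaves h = cos(theta) ~ 1 and a
        # small negative l; k stays zero by symmetry
        assert abs(h - 1.0) < 0.01
        assert abs(k) < 1e-9
        assert np.isclose(unit.s_modulus(np.array([h, k, l])),
                          2 * np.sin(two_theta / 2) / geom.wavelength, rtol=1e-9)


class TestIntegrate:
    def test_constant_images_give_constant_map(self, smooth_map, detector_geometry):
        grid = smooth_map.grid
        settings = rotation_series(grid.lattice, [0.0, 2.0, 4.0])
        images = [
            dk.DetectorImage(
                pixels=np.full(detector_geometry.shape, 42.0),
                geometry=detector_geometry, orientation=s,
            )
            for s in settings
        ]
        dmap, counts = dk.integrate(images, grid)
        assert np.allclose(dmap.values[dmap.measured], 42.0)
        assert counts.sum() == 3 * np.prod(detector_geometry.shape)

    def test_pixel_count_conservation(self, smooth_map, detector_geometry):
        grid = smooth_map.grid
        settings = rotation_series(grid.lattice, [0.0])
        mask = np.zeros(detector_geometry.shape, dtype=bool)
        mask[:10] = True
        img = dk.DetectorImage(
            pixels=np.ones(detector_geometry.shape),
            mask=mask, geometry=detector_geometry, orientation=settings[0],
        )
        _, counts = dk.integrate([img], grid)
        # all unmasked pixels land in-resolution for this geometry
        assert counts.sum() == (~mask).sum()

    def test_simulate_integrate_round_trip(self, smooth_map, detector_geometry):
        """Render a smooth noiseless map, re-integrate, correlate > 0.95."""
        grid = smooth_map.grid
        settings = rotation_series(grid.lattice, np.arange(0, 20, 2.0))
        images = [dk.simulate_image(smooth_map, detector_geometry, s) for s in settings]
        merged, counts = dk.integrate(images, grid)
        assert dk.pearson(merged, smooth_map) > 0.95


class TestReindex:
    def test_involution(self, random_map):
        a = random_map(seed=4)
        back = dk.reindex_map(dk.reindex_map(a, "2h"), "2h")
        assert np.array_equal(back.values, a.values)

    def test_impulse_moves_correctly(self, unit_grid):
        dmap = dk.DiffuseMap.constant(unit_grid, 0.0)
        off = unit_grid.to_dense_offset(np.array([1, 2, 3]))
        dmap.values[off] = 5.0
        out = dk.reindex_map(dmap, "2h")
        assert out.value_at([1, -2, -3]) == 5.0
        assert out.value_at([1, 2, 3]) == 0.0

    def test_p4m_map_invariant_under_l_twofold(self, random_map):
        sym = dk.symmetrize(random_map(seed=5), "P4/m")
        out = dk.reindex_map(sym, "2l")
        assert np.allclose(out.values, sym.values, atol=1e-12)

    def test_twofolds_commute(self, random_map):
        a = random_map(seed=6)
        hk = dk.reindex_map(dk.reindex_map(a, "2h"), "2k")
        kh = dk.reindex_map(dk.reindex_map(a, "2k"), "2h")
        assert np.array_equal(hk.values, kh.values)
        # composition of two orthogonal 2-folds is the third
        l2 = dk.reindex_map(a, "2l")
        assert np.array_equal(hk.values, l2.values)

    def test_unsupported_operation_rejected(self, random_map):
        with pytest.raises(ValueError, match="unsupported reindex"):
            dk.reindex_map(random_map(seed=7), "3h")


class TestSimulateImage:
    def test_constant_map_gives_constant_image(self, detector_geometry, supercell_model):
        grid = dk.ReciprocalGrid.for_model(supercell_model, d_min=2.5)
        dmap = dk.DiffuseMap.constant(grid, 7.0)
        setting = rotation_series(grid.lattice, [0.0])[0]
        img = dk.simulate_image(dmap, detector_geometry, setting)
        assert np.allclose(img.pixels[~img.mask], 7.0, rtol=1e-12)

    def test_matches_trilinear_oracle(self, detector_geometry, supercell_model):
        grid = dk.ReciprocalGrid.for_model(supercell_model, d_min=2.5)
        rng = np.random.default_rng(8)
        dmap = dk.DiffuseMap(
            grid, rng.random(grid.shape), np.ones(grid.shape, dtype=bool)
        )
        dmap.measured[:] = True  # full box measured for the oracle
        setting = rotation_series(grid.lattice, [3.0])[0]
        img = dk.simulate_image(dmap, detector_geometry, setting)
        # independent scalar oracle on a handful of pixels
        for i, j in [(5, 5), (60, 100), (100, 30), (64, 64)]:
            hkl = dk.pixel_to_hkl(np.array([float(i), float(j)]), detector_geometry, setting)
            c = hkl * np.array(grid.sampling) + np.array(grid.bounds)
            c0 = np.floor(c).astype(int)
            f = c - c0
            val = 0.0
            for da in (0, 1):
                for db in (0, 1):
                    for dc in (0, 1):
                        w = (f[0] if da else 1 - f[0]) * (f[1] if db else 1 - f[1]) * (
                            f[2] if dc else 1 - f[2]
                        )
                        val += w * dmap.values[c0[0] + da, c0[1] + db, c0[2] + dc]
            assert np.isclose(img.pixels[i, j], val, rtol=1e-12)

    def test_unmeasured_corners_renormalized(self, detector_geometry, supercell_model):
        grid = dk.ReciprocalGrid.for_model(supercell_model, d_min=2.5)
        dmap = dk.DiffuseMap.constant(grid, 3.0)  # measured only inside sphere
        setting = rotation_series(grid.lattice, [0.0])[0]
        img = dk.simulate_image(dmap, detector_geometry, setting)
        # wherever any corner is measured the renormalized value is exactly 3
        assert np.allclose(img.pixels[~img.mask], 3.0, rtol=1e-12)


class TestRenderImages:
    def test_zero_map_renders_zero(self, detector_geometry, supercell_model):
        grid = dk.ReciprocalGrid.for_model(supercell_model, d_min=2.5)
        dmap = dk.DiffuseMap.constant(grid, 0.0)
        settings = rotation_series(grid.lattice, [0.0, 1.0])
        imgs = dk.render_images(dmap, detector_geometry, settings, apply_corrections=False)
        for img in imgs:
            assert np.all(img.pixels == 0)

    def test_constant_map_renders_constant(self, detector_geometry, supercell_model):
        grid = dk.ReciprocalGrid.for_model(supercell_model, d_min=2.5)
        dmap = dk.DiffuseMap.constant(grid, 11.0)
        settings = rotation_series(grid.lattice, [0.0])
        imgs = dk.render_images(dmap, detector_geometry, settings, apply_corrections=False)
        assert np.allclose(imgs[0].pixels[~imgs[0].mask], 11.0)

    def test_spikes_added_and_removed_by_mode_filter(self, detector_geometry, supercell_model):
        grid = dk.ReciprocalGrid.for_model(supercell_model, d_min=2.5)
        dmap = dk.DiffuseMap.constant(grid, 100.0)
        bragg = dk.BraggSet(map=dk.DiffuseMap.constant(grid, 1.0))
        settings = rotation_series(grid.lattice, [0.0])
        clean = dk.render_images(dmap, detector_geometry, settings, apply_corrections=False)[0]
        spiked = dk.render_images(
            dmap, detector_geometry, settings, bragg=bragg,
            bragg_intensity=5000.0, rocking_width=0.05, apply_corrections=False,
        )[0]
        spike_pix = spiked.pixels > clean.pixels + 1
        assert spike_pix.sum() > 0
        # spikes exceed 10x the local background...
        assert np.all(spiked.pixels[spike_pix] > 10 * 100.0)
        # ...and the mode filter restores the background level
        filtered = dk.mode_filter(spiked, kernel=15, bin_width=1.0)
        assert np.allclose(filtered.pixels[spike_pix], 100.0)
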