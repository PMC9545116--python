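import numpy as np
import pytest

from qsmme.core import GAMMA, wrap_phase
from qsmme.phantom_sim import (Ellipsoid, PhantomSpec, Region, TissueProps,
                               attach_fields, build_phantom,
                               default_head_phantom, erode_mask,
                               load_label_phantom, simulate_fields,
                               simulate_gre, sphere_phantom)


def _uniform_tissue(chi=0.1, sd=0.0):
    return TissueProps(chi, sd, 1.0, 0.0, 50.0, 0.0)


class TestBuildPhantom:
    def test_zero_sd_gives_piecewise_constant_maps(self):
        spec = sphere_phantom(grid_shape=(32, 32, 32), chi_ppm=0.3)
        lv, gt = build_phantom(spec)
        sphere = lv.labels == 2
        assert np.all(gt.chi_true[sphere] == 0.3)
        assert np.all(gt.chi_true[lv.labels == 1] == 0.0)
        assert np.all(gt.m0_true[lv.brain_mask] == 1.0)

    def test_sphere_voxel_count_matches_volume(self):
        r = 9.0
        spec = PhantomSpec(grid_shape=(40, 40, 40), regions=[
            Region("s", Ellipsoid((20, 20, 20), (r, r, r)),
                   _uniform_tissue())])
        lv, _ = build_phantom(spec)
        # brute-force count of the sphere inequality on the same grid
        g = np.ogrid[:40, :40, :40]
        brute = int((sum((gi - 20) ** 2 for gi in g) <= r * r).sum())
        assert lv.labels.sum() == brute
        assert abs(brute - 4 / 3 * np.pi * r ** 3) / (4 / 3 * np.pi * r ** 3) < 0.05

    def test_default_region_list_covers_head_anatomy(self):
        spec = default_head_phantom((48, 48, 48))
        names = {r.name for r in spec.regions}
        assert {"CN", "GP", "PU", "TH", "vein", "GM", "WM", "CSF"} <= names

    def test_later_regions_overwrite_earlier(self):
        t1, t2 = _uniform_tissue(0.1), _uniform_tissue(0.5)
        spec = PhantomSpec(grid_shape=(24, 24, 24), regions=[
            Region("a", Ellipsoid((12, 12, 12), (8, 8, 8)), t1),
            Region("b", Ellipsoid((12, 12, 12), (4, 4, 4)), t2)])
        lv, gt = build_phantom(spec)
        assert gt.chi_true[12, 12, 12] == 0.5
        assert gt.chi_true[12, 12, 5] == 0.1

    def test_region_outside_grid_raises(self):
        spec = PhantomSpec(grid_shape=(16, 16, 16), regions=[
            Region("far", Ellipsoid((100, 100, 100), (2, 2, 2)),
                   _uniform_tissue())])
        with pytest.raises(ValueError, match="outside the grid"):
            build_phantom(spec)

    def test_property_sampling_is_seeded(self):
        spec = default_head_phantom((24, 24, 24), seed=3)
        _, a = build_phantom(spec)
        _, b = build_phantom(spec)
        np.testing.assert_array_equal(a.chi_true, b.chi_true)


class TestSimulateFields:
    def test_zero_chi_gives_zero_fields(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[4:12, 4:12, 4:12] = True
        tot, bg, loc = simulate_fields(np.zeros((16, 16, 16)), mask)
        assert np.all(tot.values == 0)
        assert np.all(bg.values == 0)
        assert np.all(loc.values == 0)

    def test_decomposition_is_exact(self, small_head):
        _, lv, gt = small_head
        resid = gt.db_total.values - (gt.db_background.values
                                      + gt.db_local_true.values)
        assert np.abs(resid[lv.brain_mask]).max() < 1e-18

    def test_sphere_external_field_matches_closed_form(self):
        spec = sphere_phantom(grid_shape=(128,) * 3, chi_ppm=1.0,
                              radius_frac=0.08, mask_frac=0.40)
        lv, gt = build_phantom(spec)
        gt = attach_fields(gt, spec, lv)
        n = 128
        sphere = lv.labels == 2
        reff = (3 * sphere.sum() / (4 * np.pi)) ** (1 / 3)
        x, y, z = np.meshgrid(*[np.arange(n) - n / 2] * 3, indexing="ij")
        r = np.maximum(np.sqrt(x ** 2 + y ** 2 + z ** 2), 1e-9)
        ext = 3.0 * 1e-6 / 3 * (reff / r) ** 3 * (3 * (z / r) ** 2 - 1)
        shell = (r > 1.6 * reff) & (r < 0.25 * n)
        err = np.linalg.norm(gt.db_total.values[shell] - ext[shell])
        assert err / np.linalg.norm(ext[shell]) < 0.01

    def test_field_is_linear_in_chi(self, rng):
        mask = np.zeros((24, 24, 24), bool)
        mask[6:18, 6:18, 6:18] = True
        a = rng.normal(size=(24, 24, 24))
        b = rng.normal(size=(24, 24, 24))
        fa, _, _ = simulate_fields(a, mask)
        fb, _, _ = simulate_fields(b, mask)
        fab, _, _ = simulate_fields(2 * a + b, mask)
        np.testing.assert_allclose(fab.values, 2 * fa.values + fb.values,
                                   atol=1e-18)

    def test_nonunit_direction_rejected(self):
        with pytest.raises(ValueError):
            simulate_fields(np.zeros((8, 8, 8)), np.ones((8, 8, 8), bool),
                            b0_direction=(0, 0, 0))


class TestSimulateGre:
    def test_noiseless_flat_signal(self):
        spec = PhantomSpec(grid_shape=(8, 8, 8), regions=[
            Region("t", Ellipsoid((4, 4, 4), (10, 10, 10)),
                   TissueProps(0.0, 0.0, 1.0, 0.0, 1e9, 0.0))],
            noise_sd=0.0)
        lv, gt = build_phantom(spec)
        gt.db_total = simulate_fields(gt.chi_true, lv.brain_mask)[0]
        g = simulate_gre(gt, spec, 1)[0]
        np.testing.assert_allclose(g.magnitude, 1.0, rtol=1e-6)
        np.testing.assert_allclose(g.phase, 0.0, atol=1e-12)

    def test_default_echo_times(self):
        spec = default_head_phantom((16, 16, 16))
        np.testing.assert_allclose(
            spec.echo_times_s, [3.0e-3, 8.4e-3, 13.8e-3, 19.2e-3, 24.6e-3])

    def test_phase_noise_sd_matches_reciprocal_snr(self, rng):
        # 10^4 draws of a unit-magnitude voxel: SD(phase) ~ noise_sd
        spec = PhantomSpec(grid_shape=(22, 22, 22), regions=[
            Region("t", Ellipsoid((11, 11, 11), (30, 30, 30)),
                   TissueProps(0.0, 0.0, 1.0, 0.0, 1e9, 0.0))],
            noise_sd=0.07, seed=11)
        lv, gt = build_phantom(spec)
        gt.db_total = simulate_fields(gt.chi_true, lv.brain_mask)[0]
        g = simulate_gre(gt, spec, 1)[0]
        sd = g.phase[..., 0].std()
        assert abs(sd - 0.07) / 0.07 < 0.05

    def test_noise_free_signal_phase_is_exact(self, small_head):
        spec, lv, gt = small_head
        from dataclasses import replace
        g = simulate_gre(gt, replace(spec, noise_sd=0.0), 1)[0]
        for i, te in enumerate(spec.echo_times_s):
            expect = wrap_phase(GAMMA * gt.db_total.values * te
                                + gt.phi0_true)
            m = gt.m0_true > 0
            np.testing.assert_allclose(g.phase[..., i][m], expect[m],
                                       atol=1e-9)

    def test_repeats_share_truth_but_not_noise(self, small_head_gre):
        g1, g2 = small_head_gre
        assert not np.allclose(g1.phase, g2.phase)
        # same seed reproduces bit-identically
        assert g1.magnitude.dtype == g2.magnitude.dtype

    def test_simulation_is_deterministic(self, small_head):
        spec, lv, gt = small_head
        a = simulate_gre(gt, spec, 1)[0]
        b = simulate_gre(gt, spec, 1)[0]
        np.testing.assert_array_equal(a.magnitude, b.magnitude)
        np.testing.assert_array_equal(a.phase, b.phase)


class TestErodeMask:
    def test_radius_zero_is_identity(self):
        m = np.zeros((10, 10, 10), bool)
        m[2:8, 2:8, 2:8] = True
        np.testing.assert_array_equal(erode_mask(m, 0), m)

    def test_cube_erodes_to_single_voxel(self):
        m = np.zeros((15, 15, 15), bool)
        m[2:13, 2:13, 2:13] = True  # 11^3 cube
        out = erode_mask(m, 5)
        assert out.sum() == 1
        assert out[7, 7, 7]

    def test_empty_result_raises_with_radius(self):
        m = np.zeros((8, 8, 8), bool)
        m[3:5, 3:5, 3:5] = True
        with pytest.raises(ValueError, match="radius 3"):
            erode_mask(m, 3)


class TestLabelLoader:
    def test_external_label_volume_roundtrip(self):
        labels = np.zeros((20, 20, 20), np.int32)
        labels[5:15, 5:15, 5:15] = 1
        labels[8:12, 8:12, 8:12] = 2
        tissues = {"WM": _uniform_tissue(-0.03), "GP": _uniform_tissue(0.18)}
        spec, lv, gt = load_label_phantom(labels, {1: "WM", 2: "GP"}, tissues)
        assert gt.chi_true[10, 10, 10] == 0.18
        assert gt.chi_true[6, 6, 6] == -0.03
        assert lv.brain_mask.sum() == (labels > 0).sum()
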