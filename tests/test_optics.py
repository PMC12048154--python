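import numpy as np
import pytest
from scipy.integrate import quad

from grinsim import optics as opt


class TestAsphereSag:
    def test_zero_on_axis(self):
        assert opt.asphere_sag(0.0, opt.AsphereProfile(c=0.01, k=0.3)) == 0.0

    def test_matches_exact_sphere(self):
        R = 200.0
        p = opt.AsphereProfile(c=1.0 / R)
        for r in (10.0, 50.0, 150.0):
            exact = R - np.sqrt(R**2 - r**2)
            assert abs(opt.asphere_sag(r, p) - exact) < 1e-10

    def test_paraboloid_limit(self):
        p = opt.AsphereProfile(c=0.02, k=-1.0)
        for r in (5.0, 80.0, 400.0):
            assert abs(opt.asphere_sag(r, p) - 0.02 * r**2 / 2.0) < 1e-10

    def test_alpha_terms_add_even_powers(self):
        p = opt.AsphereProfile(c=0.0, k=0.0, alpha=(1e-4, -1e-9))
        r = 30.0
        assert opt.asphere_sag(r, p) == pytest.approx(1e-4 * r**2 - 1e-9 * r**4)

    def test_domain_error_names_limit(self):
        p = opt.AsphereProfile(c=0.01, k=0.0)
        with pytest.raises(ValueError, match="100"):
            opt.asphere_sag(150.0, p)


class TestFocalSurface:
    def test_anchored_at_axis(self):
        poly = opt.FocalSurfaceModel("polynomial", poly_coeffs=(3.0, 0.0, 1e-3))
        assert opt.focal_surface_height(0.0, poly) == 0.0
        shells = opt.FocalSurfaceModel("spherical_shells", shell_radii=(273.0, 2000.0))
        assert np.allclose(opt.focal_surface_height(0.0, shells), 0.0)

    def test_shell_sag_arithmetic(self):
        m = opt.FocalSurfaceModel("spherical_shells", shell_radii=(273.0,))
        expect = 273.0 - np.sqrt(273.0**2 - 100.0**2)
        assert opt.focal_surface_height(100.0, m)[0] == pytest.approx(expect, abs=1e-12)

    def test_all_zero_polynomial_is_flat(self):
        m = opt.FocalSurfaceModel("polynomial", poly_coeffs=(0.0,) * 6)
        r = np.linspace(0, 200, 50)
        assert np.allclose(opt.focal_surface_height(r, m), 0.0)

    def test_shell_domain_error(self):
        m = opt.FocalSurfaceModel("spherical_shells", shell_radii=(100.0,))
        with pytest.raises(ValueError):
            opt.focal_surface_height(150.0, m)

    @pytest.mark.parametrize(
        "model",
        [
            opt.FocalSurfaceModel("polynomial", poly_coeffs=(0.0,), center_depth=50.0),
            opt.FocalSurfaceModel(
                "polynomial",
                poly_coeffs=(0.0, 0.0, 1e-3, 0.0, 1e-9, 0.0),
                center_depth=80.0,
            ),
            opt.FocalSurfaceModel(
                "spherical_shells", shell_radii=(273.0,), center_depth=100.0, sign=1.0
            ),
        ],
        ids=["flat", "polynomial", "shell"],
    )
    def test_normal_matches_finite_difference(self, model):
        for r in (0.0, 40.0, 120.0):
            n = opt.surface_normal(r, model)
            assert n[2] > 0
            assert np.linalg.norm(n) == pytest.approx(1.0)
            h = 1e-5
            d = (
                float(np.atleast_1d(opt.surface_depth(r + h, model)).ravel()[0])
                - float(np.atleast_1d(opt.surface_depth(max(r - h, 0), model)).ravel()[0])
            ) / (h + min(h, r))
            expect = np.array([-d, 0.0, 1.0])
            expect /= np.linalg.norm(expect)
            assert np.allclose(n, expect, atol=1e-5)

    def test_flat_surface_normal_is_axial(self):
        m = opt.FocalSurfaceModel("polynomial", poly_coeffs=(0.0,))
        assert np.allclose(opt.surface_normal(73.0, m), [0, 0, 1])


class TestPSFModel:
    def test_constant_model(self):
        m = opt.PSFSizeModel(axial=(0.0, 0.0, 7.0), lateral=(0.0, 0.0, 1.0))
        lat, ax = opt.psf_axes(np.array([0.0, 50.0, 199.0]), m)
        assert np.allclose(ax, 7.0) and np.allclose(lat, 1.0)

    def test_evenness_in_r(self):
        m = opt.PSFSizeModel(axial=(1e-8, 1e-4, 5.0), lateral=(0.0, 1e-5, 0.9))
        for r in (3.0, 77.0):
            assert opt.psf_axes(r, m) == opt.psf_axes(-r, m)

    def test_nonpositive_config_rejected(self):
        m = opt.PSFSizeModel(axial=(0.0, 0.0, -1.0), lateral=(0.0, 0.0, 1.0))
        with pytest.raises(ValueError):
            opt.psf_axes(10.0, m)

    def test_effective_radius_matches_scan(self):
        m = opt.PSFSizeModel(axial=(2.5e-8, 2.5e-4, 5.0), lateral=(0.0, 0.0, 1.0))
        r_bis = opt.effective_fov_radius(m)
        rs = np.arange(0.0, 250.0, 0.01)
        vals = 2.5e-8 * rs**4 + 2.5e-4 * rs**2 + 5.0
        r_scan = rs[np.argmax(vals >= 10.0)]
        assert abs(r_bis - r_scan) <= 0.01

    def test_extrapolation_cap_applies(self):
        m = opt.PSFSizeModel(
            axial=(1e-6, 0.0, 5.0), lateral=(0.0, 0.0, 1.0), axial_cap_um=40.0
        )
        _, ax = opt.psf_axes(200.0, m)
        assert ax == 40.0


class TestMagnification:
    def test_identity_mapping(self):
        m = opt.MagnificationModel()
        assert opt.magnification_factor(123.0, m) == 1.0
        assert opt.real_distance(88.0, m) == pytest.approx(88.0, abs=1e-9)
        assert opt.nominal_distance(88.0, m) == 88.0

    def test_round_trip_inverse(self):
        m = opt.MagnificationModel(dist=(-4e-9, 1e-6, 1.0, 0.0))
        for r in (0.0, 30.0, 120.0, 210.0):
            nom = opt.nominal_distance(r, m)
            assert opt.real_distance(nom, m) == pytest.approx(r, abs=1e-6)

    def test_non_monotone_g_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            opt.MagnificationModel(dist=(0.0, -1e-2, 1.0, 0.0), r_range=300.0)

    def test_distance_calibration_consistent_with_local_magnification(self):
        # g implied by f: real(x_nom) = int_0^x 1/f(u) du; fitting the
        # quartic basis to (real, nominal) samples must reproduce g
        f_coeffs = (0.0, 2e-6, 1.0)
        xs = np.linspace(0.0, 200.0, 41)
        reals = np.array(
            [
                quad(lambda u: 1.0 / (f_coeffs[0] * u**4 + f_coeffs[1] * u**2 + f_coeffs[2]), 0, x)[0]
                for x in xs
            ]
        )
        design = np.column_stack([reals**4, reals**2, reals, np.ones_like(reals)])
        coef, *_ = np.linalg.lstsq(design, xs, rcond=None)
        m = opt.MagnificationModel(mag=f_coeffs, dist=tuple(coef), r_range=250.0)
        # quartic g reproduces the quadrature-derived mapping to < 0.1 µm
        assert np.allclose(opt.nominal_distance(reals, m), xs, atol=0.1)


class TestDefaults:
    def test_fold_report_matches_printed_values(self):
        assert opt.fov_fold_report(46, 100) == {"radius_fold": 2.17, "area_fold": 4.7}
        assert opt.fov_fold_report(34, 52) == {"radius_fold": 1.53, "area_fold": 2.3}

    def test_corrected_fov_larger_than_uncorrected(self):
        for size in ("6.4", "8.8"):
            rc = opt.effective_fov_radius(opt.default_optics(f"corrected-{size}").psf)
            ru = opt.effective_fov_radius(opt.default_optics(f"uncorrected-{size}").psf)
            assert rc > ru

    def test_intensity_normalised_on_axis(self):
        for pt in opt.PROBE_TYPES:
            assert opt.default_optics(pt).intensity(0.0) == 1.0

    def test_yaml_round_trip(self, tmp_path):
        o = opt.default_optics("uncorrected-8.8")
        p = tmp_path / "optics.yaml"
        o.save(p)
        o2 = opt.OpticsModel.load(p)
        assert o2.probe_type == o.probe_type
        assert o2.focal_surface.shell_radii == o.focal_surface.shell_radii
        assert o2.psf.axial == o.psf.axial
        r = np.linspace(0, 150, 10)
        assert np.allclose(o2.intensity(r), o.intensity(r))

    def test_unknown_probe_type(self):
        with pytest.raises(ValueError):
            opt.default_optics("corrected-99")
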