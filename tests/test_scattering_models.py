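"""Form-factor kernels: closed forms, quadrature averages, mixtures."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import argrelextrema

from lipidscatter import scattering_models as sm


class TestSphereAmplitude:
    def test_limit_at_zero_is_one(self):
        assert sm.sphere_amplitude(0.0) == 1.0

    def test_value_at_pi(self):
        # 3(sin x - x cos x)/x^3 at x = pi reduces to 3/pi^2
        assert sm.sphere_amplitude(math.pi) == pytest.approx(
            0.3039635509270133, rel=1e-12)

    def test_series_matches_direct_form_at_crossover(self):
        # the small-x series and the direct form agree where they hand over
        x = np.array([0.009, 0.0099, 0.0101, 0.011])
        direct = 3 * (np.sin(x) - x * np.cos(x)) / x**3
        assert sm.sphere_amplitude(x) == pytest.approx(direct, rel=1e-9)

    def test_first_minimum_of_squared_amplitude(self):
        # F^2 first vanishes where tan x = x: x* = 4.493409457909064
        x = np.linspace(3.5, 5.5, 20001)
        f2 = np.asarray(sm.sphere_amplitude(x)) ** 2
        x_min = x[np.argmin(f2)]
        assert x_min == pytest.approx(4.493409457909064, abs=1e-3)

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            sm.sphere_amplitude(-0.1)


class TestCoreShellSphere:
    def test_zero_contrast_gives_background(self, q_grid):
        p = sm.SphereCoreShellParams(30, 20, 0.4, 0.4, 0.4,
                                     scale=3.0, background=0.7)
        assert sm.core_shell_sphere_intensity(p, q_grid) == pytest.approx(
            np.full_like(q_grid, 0.7))

    def test_zero_shell_reduces_to_homogeneous_sphere(self, q_grid):
        p = sm.SphereCoreShellParams(40, 0.0, 0.4, 0.9, 0.334, 1.5, 0.0)
        got = sm.core_shell_sphere_intensity(p, q_grid)
        v = 4 / 3 * math.pi * 40.0**3
        amp = v * (0.4 - 0.334) * np.asarray(sm.sphere_amplitude(q_grid * 40))
        assert got == pytest.approx(1.5 * amp**2, rel=1e-12)

    def test_forward_limit_identity(self):
        # small radii keep the q = 1e-6 evaluation within 1e-10 of q -> 0
        p = sm.SphereCoreShellParams(5, 5, 0.2, 0.5, 0.334, 2.0, 0.01)
        num = sm.core_shell_sphere_intensity(p, np.array([1e-6]))[0]
        assert num == pytest.approx(sm.forward_intensity(p), rel=1e-10)

    def test_negative_q_rejected(self, css_params):
        with pytest.raises(ValueError):
            sm.core_shell_sphere_intensity(css_params, np.array([-0.1]))


class TestEllipsoid:
    def test_sphere_limit_matches_closed_form(self, q_grid):
        e = sm.EllipsoidCoreShellParams(30, 30, 20, 0.24, 0.38, 0.334,
                                        2.0, 1e-3)
        s = sm.SphereCoreShellParams(30, 20, 0.24, 0.38, 0.334, 2.0, 1e-3)
        ie = sm.core_shell_ellipsoid_intensity(e, q_grid)
        isph = sm.core_shell_sphere_intensity(s, q_grid)
        assert ie == pytest.approx(isph, rel=1e-6)

    def test_micelle_preset_has_minimum_and_broad_peak(self, micelle_params):
        # the globular-micelle signature: minimum near 0.06, peak above 0.1
        q = np.linspace(0.02, 0.2, 1801)
        i = sm.core_shell_ellipsoid_intensity(micelle_params, q)
        minima = q[argrelextrema(i, np.less)[0]]
        maxima = q[argrelextrema(i, np.greater)[0]]
        assert any(0.05 <= m <= 0.07 for m in minima)
        first_min = minima[0]
        assert any(0.10 <= m <= 0.14 for m in maxima if m > first_min)

    def test_scale_linearity(self, micelle_params, q_grid):
        i1 = sm.core_shell_ellipsoid_intensity(micelle_params, q_grid)
        doubled = sm.EllipsoidCoreShellParams(
            micelle_params.core_polar_radius,
            micelle_params.core_equatorial_radius,
            micelle_params.shell_thickness, micelle_params.sld_core,
            micelle_params.sld_shell, micelle_params.sld_solvent,
            2 * micelle_params.scale, micelle_params.background)
        i2 = sm.core_shell_ellipsoid_intensity(doubled, q_grid)
        b = micelle_params.background
        assert (i2 - b) == pytest.approx(2 * (i1 - b), rel=1e-12)

    def test_quadrature_order_doubling_converged(self, micelle_params, q_grid):
        i1 = sm.core_shell_ellipsoid_intensity(micelle_params, q_grid,
                                               order=sm.DEFAULT_QUAD_ORDER)
        i2 = sm.core_shell_ellipsoid_intensity(micelle_params, q_grid,
                                               order=2 * sm.DEFAULT_QUAD_ORDER)
        assert np.max(np.abs(i1 - i2) / i2) < 1e-6

    def test_convergence_failure_raises(self, micelle_params, q_grid):
        with pytest.raises(sm.QuadratureError):
            sm.core_shell_ellipsoid_intensity(micelle_params, q_grid,
                                              order=4,
                                              convergence_rtol=1e-14)

    def test_axial_ratio_is_derived(self, micelle_params):
        r = micelle_params.axial_ratio
        assert r == pytest.approx(23.0 / 28.0)
        assert r < 1  # oblate preset

    def test_forward_limit(self, micelle_params):
        num = sm.core_shell_ellipsoid_intensity(micelle_params,
                                                np.array([1e-7]))[0]
        assert num == pytest.approx(sm.forward_intensity(micelle_params),
                                    rel=1e-8)


class TestVesicle:
    def test_definition_bit_identical_to_solvent_core_sphere(self, q_grid):
        v = sm.VesicleParams(260, 40, 0.36, 0.334, 1.2, 1e-3)
        s = sm.SphereCoreShellParams(260, 40, 0.334, 0.36, 0.334, 1.2, 1e-3)
        got = sm.vesicle_intensity(v, q_grid)
        want = sm.core_shell_sphere_intensity(s, q_grid)
        assert np.array_equal(got, want)

    def test_normalized_forward_form_factor_is_one(self):
        v = sm.VesicleParams(50, 10, 0.36, 0.334, 1.0, 0.0)
        num = sm.vesicle_intensity(v, np.array([1e-7]))[0]
        assert num / sm.forward_intensity(v) == pytest.approx(1.0, rel=1e-8)

    def test_thin_shell_oscillation_spacing(self):
        # shell fringes repeat with period ~ pi / (R_core + t/2)
        v = sm.VesicleParams(1000.0, 10.0, 0.36, 0.334, 1.0, 0.0)
        q = np.linspace(0.01, 0.12, 40001)
        i = sm.vesicle_intensity(v, q)
        maxima = q[argrelextrema(i, np.greater)[0]]
        spacings = np.diff(maxima)
        expected = math.pi / (v.core_radius + v.shell_thickness / 2.0)
        assert np.median(spacings) == pytest.approx(expected, rel=0.05)


class TestCylinder:
    def test_normalized_forward_form_factor_is_one(self):
        c = sm.CylinderParams(80, 40, 0.36, 0.334, 1.0, 0.0)
        num = sm.cylinder_intensity(c, np.array([1e-7]))[0]
        assert num / sm.forward_intensity(c) == pytest.approx(1.0, rel=1e-8)

    def test_against_dense_quadrature_oracle(self):
        # independent oracle: adaptive quadrature of the tilt average,
        # assembled from scratch (not the package's fixed-order path)
        c = sm.CylinderParams(80.0, 40.0, 0.36, 0.334, 1.7, 5e-4)
        from scipy.special import j1

        def oracle(qv):
            v = math.pi * c.radius**2 * c.length
            drho = c.sld_cyl - c.sld_solvent

            def integrand(alpha):
                xr = qv * c.radius * math.sin(alpha)
                xl = qv * c.length / 2.0 * math.cos(alpha)
                radial = 2 * j1(xr) / xr if xr > 1e-10 else 1.0
                axial = math.sin(xl) / xl if abs(xl) > 1e-10 else 1.0
                return (v * drho * radial * axial) ** 2 * math.sin(alpha)

            val, _ = quad(integrand, 0.0, math.pi / 2, limit=400,
                          epsabs=0.0, epsrel=1e-10)
            return c.scale * val + c.background

        q20 = np.geomspace(5e-3, 0.4, 20)
        want = np.array([oracle(qv) for qv in q20])
        got = sm.cylinder_intensity(c, q20)
        assert got == pytest.approx(want, rel=1e-6)

    def test_disc_preset_strictly_positive(self, q_grid):
        c = sm.preset("gm1_dopc_disc")
        assert c.is_disc
        assert np.all(sm.cylinder_intensity(c, q_grid) > 0)

    def test_quadrature_order_doubling_converged(self, q_grid):
        c = sm.CylinderParams(80, 40, 0.36, 0.334, 1.0, 1e-4)
        i1 = sm.cylinder_intensity(c, q_grid, order=sm.DEFAULT_QUAD_ORDER)
        i2 = sm.cylinder_intensity(c, q_grid, order=2 * sm.DEFAULT_QUAD_ORDER)
        assert np.max(np.abs(i1 - i2) / i2) < 1e-6


class TestLamellar:
    def test_peak_centers_for_60A(self):
        p = sm.LamellarPatternParams(60.0, n_orders=2,
                                     order_amplitudes=[1.0, 0.4])
        centers = p.peak_centers()
        assert centers == pytest.approx([0.10471975511965977,
                                         0.20943951023931953], rel=1e-12)
        # the rendered pattern peaks at those centers
        q = np.linspace(0.05, 0.25, 20001)
        i = sm.lamellar_pattern(p, q)
        maxima = q[argrelextrema(i, np.greater)[0]]
        assert maxima == pytest.approx(centers, abs=2e-5)

    def test_zero_amplitudes_leave_baseline_only(self):
        p = sm.LamellarPatternParams(60.0, n_orders=1, order_amplitudes=[0.0],
                                     baseline_amplitude=1e-4,
                                     baseline_exponent=2.0)
        q = np.geomspace(0.01, 0.3, 50)
        assert sm.lamellar_pattern(p, q) == pytest.approx(1e-4 * q**-2.0)

    def test_centers_scale_inversely_with_d(self):
        p1 = sm.LamellarPatternParams(60.0, n_orders=3,
                                      order_amplitudes=[1, 1, 1])
        p2 = sm.LamellarPatternParams(120.0, n_orders=3,
                                      order_amplitudes=[1, 1, 1])
        assert p2.peak_centers() == pytest.approx(p1.peak_centers() / 2.0,
                                                  rel=1e-14)


class TestMixture:
    def test_unit_weight_selects_component(self, q_grid, micelle_params):
        ves = sm.preset("dopc_vesicle")
        m = sm.MixtureModel([micelle_params, ves], [1.0, 0.0])
        assert sm.mixture_intensity(m, q_grid) == pytest.approx(
            sm.core_shell_ellipsoid_intensity(micelle_params, q_grid),
            rel=1e-14)

    def test_exact_weighted_sum(self, q_grid, micelle_params):
        ves = sm.preset("dopc_vesicle")
        m = sm.MixtureModel([micelle_params, ves], [0.7, 2.5])
        want = (0.7 * sm.core_shell_ellipsoid_intensity(micelle_params, q_grid)
                + 2.5 * sm.vesicle_intensity(ves, q_grid))
        assert sm.mixture_intensity(m, q_grid) == pytest.approx(want,
                                                                rel=1e-14)

    def test_vesicle_dominates_mixed_preset_at_low_q(self):
        from lipidscatter import synthetic_data as syn
        m = syn.preset("dopc_gm1_90_10_mixture").model
        q_low = np.geomspace(0.01, 0.03, 20)
        total = sm.mixture_intensity(m, q_low)
        ves_term = m.weights[0] * sm.evaluate(m.components[0], q_low)
        # integrated over the band (pointwise ratios drop only inside the
        # sharp vesicle form-factor minima)
        assert ves_term.sum() / total.sum() > 0.9
        assert np.median(ves_term / total) > 0.9

    def test_negative_weight_rejected(self, micelle_params):
        with pytest.raises(ValueError):
            sm.MixtureModel([micelle_params], [-0.1])


@pytest.mark.parametrize("name", sm.PRESET_NAMES)
def test_intensity_never_below_background(name, q_grid):
    model = sm.preset(name)
    i = sm.evaluate(model, q_grid)
    background = getattr(model, "background", 0.0)
    assert np.all(i >= background - 1e-15)


def test_params_dict_roundtrip(micelle_params):
    for model in [micelle_params, sm.preset("dopc_vesicle"),
                  sm.preset("dopc_lamellar_60A"),
                  sm.MixtureModel([sm.preset("dopc_vesicle"),
                                   micelle_params], [1.0, 0.2])]:
        back = sm.params_from_dict(sm.params_to_dict(model))
        q = np.geomspace(0.01, 0.4, 30)
        assert sm.evaluate(back, q) == pytest.approx(sm.evaluate(model, q),
                                                     rel=1e-14)


def test_unknown_preset_lists_available():
    with pytest.raises(KeyError, match="gm1_micelle"):
        sm.preset("no_such_shape")


@pytest.mark.parametrize("bad", [
    dict(core_radius=-1, shell_thickness=1, sld_core=0, sld_shell=1,
         sld_solvent=0),
    dict(core_radius=1, shell_thickness=-1, sld_core=0, sld_shell=1,
         sld_solvent=0),
    dict(core_radius=1, shell_thickness=1, sld_core=0, sld_shell=1,
         sld_solvent=0, scale=-1),
])
def test_invalid_sphere_params_rejected(bad):
    with pytest.raises(ValueError):
        sm.SphereCoreShellParams(**bad)
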