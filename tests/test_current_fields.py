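"""Analytic current densities, frame conversions and grid sampling."""

import numpy as np
import pytest

import spherebidomain.bidomain_solver as solver
import spherebidomain.current_fields as cf
from spherebidomain._series import HarmonicSeries
from spherebidomain.parameters import (
    SourcePair,
    SphericalPoint,
    default_config,
    default_parameters,
    default_sources,
)


def _fd_gradient(series, r, th, ph, h):
    """Central finite-difference gradient in spherical components."""
    fr = (series.values(r + h, th, ph) - series.values(r - h, th, ph)) / (2 * h)
    dth = h / r
    ft = (series.values(r, th + dth, ph) - series.values(r, th - dth, ph)) / (
        2 * dth * r
    )
    dph = 1e-6
    fp = (series.values(r, th, ph + dph) - series.values(r, th, ph - dph)) / (
        2 * dph * r * np.sin(th)
    )
    return fr, ft, fp


class TestGradient:
    def test_constant_series_has_zero_gradient(self):
        K = np.zeros((3, 3), dtype=complex)
        K[0, 0] = 0.7
        s = HarmonicSeries(K, "power")
        g = cf.gradient_spherical(s, 1e-3, 0.8, 0.3)
        assert g.magnitude == pytest.approx(0.0, abs=1e-18)

    def test_single_dipole_term_is_uniform_z_field(self, rng):
        """b_{1,0} r Y_1^0 = b sqrt(3/4pi) z: gradient is constant along z."""
        b = 2.5
        K = np.zeros((2, 2), dtype=complex)
        K[1, 0] = b
        s = HarmonicSeries(K, "power")
        expected = b * np.sqrt(3.0 / (4 * np.pi))
        for _ in range(5):
            r, th, ph = rng.uniform(0.1e-3, 2e-3), rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)
            g = cf.gradient_spherical(s, r, th, ph)
            vx, vy, vz = cf.to_cartesian(g, th, ph)
            assert vx == pytest.approx(0.0, abs=1e-12 * expected)
            assert vy == pytest.approx(0.0, abs=1e-12 * expected)
            assert vz == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("family", ["bessel", "power", "inv_power"])
    def test_analytic_matches_finite_difference(self, default_model, rng, family):
        cfg, par, src, co = default_model
        series = {
            "bessel": solver.vm_series(co),
            "power": solver.psi_series(co),
            "inv_power": solver.bath_series(co),
        }[family]
        lo, hi = (0.2, 0.9) if family != "inv_power" else (1.1, 1.8)
        r = rng.uniform(lo, hi, 40) * cfg.a
        th = rng.uniform(0.1, np.pi - 0.1, 40)
        ph = rng.uniform(0.0, 2 * np.pi, 40)
        gr, gt, gp = series.gradient(r, th, ph)
        fr, ft, fp = _fd_gradient(series, r, th, ph, 1e-6 * cfg.a)
        scale = np.max(np.sqrt(gr**2 + gt**2 + gp**2))
        for an, fd in ((gr, fr), (gt, ft), (gp, fp)):
            assert np.max(np.abs(an - fd)) <= 1e-6 * scale

    def test_polar_axis_limit_continuous(self, axisym_model):
        """Explicit polar limits agree with evaluation just off the axis.

        The gradient varies by O(theta) off the pole, so the comparison is
        scaled to the overall gradient magnitude at the point.
        """
        s, co = axisym_model
        vm = solver.vm_series(co)
        for theta_pole in (0.0, np.pi):
            g_pole = vm.gradient(1.1e-3, theta_pole, 0.3)
            g_near = vm.gradient(1.1e-3, abs(theta_pole - 1e-7), 0.3)
            mag = np.sqrt(sum(c**2 for c in g_near))
            for c_pole, c_near in zip(g_pole, g_near):
                assert abs(c_pole - c_near) <= 1e-5 * mag

    def test_polar_limit_general_geometry(self, default_model):
        """Same continuity for a configuration with nonzero nu=1 content."""
        cfg, par, src, co = default_model
        for series in (solver.vm_series(co), solver.psi_series(co)):
            g_pole = series.gradient(1.2e-3, 0.0, 0.7)
            g_near = series.gradient(1.2e-3, 1e-7, 0.7)
            mag = np.sqrt(sum(c**2 for c in g_near))
            for c_pole, c_near in zip(g_pole, g_near):
                assert abs(c_pole - c_near) <= 1e-5 * mag


class TestCurrentDensities:
    def test_no_intracellular_radial_current_at_boundary(self, default_model):
        cfg, par, src, co = default_model
        th = np.linspace(0.1, np.pi - 0.1, 16)
        ph = np.linspace(0.0, 2 * np.pi, 16, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        r = np.full(T.size, cfg.a)
        j_i = cf.current_density_i(r, T.ravel(), P.ravel(), co, par)
        j_e = cf.current_density_e(r, T.ravel(), P.ravel(), co, src, par)
        assert np.max(np.abs(j_i.v_r)) <= 1e-10 * np.max(j_e.magnitude)

    def test_coincident_pair_zero_current(self):
        cfg, par = default_config(), default_parameters()
        src = SourcePair(
            SphericalPoint(5e-3, 1.0, 2.0), SphericalPoint(5e-3, 1.0, 2.0), 1e-3
        )
        co = solver.coefficients(cfg, par, src)
        j_i = cf.current_density_i(1e-3, 0.7, 0.2, co, par)
        j_o = cf.current_density_o(1e-3, 0.7, 0.2, co, par)
        assert j_i.magnitude == pytest.approx(0.0, abs=1e-18)
        assert j_o.magnitude == pytest.approx(0.0, abs=1e-18)

    def test_total_current_consistent_across_paths(self, default_model, rng):
        """J_i + J_o equals -(ri^-1 grad phi_i + ro^-1 grad phi_o) recomputed."""
        cfg, par, src, co = default_model
        r, th, ph = 1.1e-3, 0.9, 2.2
        j = cf.current_density_i(r, th, ph, co, par) + cf.current_density_o(
            r, th, ph, co, par
        )
        ri, ro = par.rho_i, par.rho_o
        ki, ko = ri / (ri + ro), ro / (ri + ro)
        vm_g = solver.vm_series(co).gradient(r, th, ph)
        psi_g = solver.psi_series(co).gradient(r, th, ph)
        for k, (gv, gp) in enumerate(zip(vm_g, psi_g)):
            expected = -(ki * gv + gp) / ri - (-ko * gv + gp) / ro
            assert [j.v_r, j.v_theta, j.v_phi][k] == pytest.approx(expected, rel=1e-12)

    def test_lone_monopole_far_field(self):
        """With the sphere's response zeroed, |J_e| = I0/(4 pi d^2) at distance d."""
        cfg, par = default_config(), default_parameters()
        src = default_sources()
        co = solver.coefficients(cfg, par, src)
        zero = solver.CoefficientSet(
            a_mu_nu=np.zeros_like(co.a_mu_nu),
            b_mu_nu=np.zeros_like(co.b_mu_nu),
            c_mu_nu=np.zeros_like(co.c_mu_nu),
            mu_max=co.mu_max,
            tissue_radius=co.tissue_radius,
            lam=co.lam,
        )
        lone = SourcePair(src.p_plus, SphericalPoint(1e3, 0.5, 0.5), src.I_0)
        p = src.p_plus
        d = 1e-3
        j = cf.current_density_e(p.r - d, p.theta, p.phi, zero, lone, par)
        assert j.magnitude == pytest.approx(src.I_0 / (4 * np.pi * d**2), rel=1e-3)

    def test_source_flux_recovers_injected_current(self, default_model):
        from spherebidomain.scenarios import source_flux

        cfg, par, src, co = default_model
        flux = source_flux(cfg, par, src, co)
        assert flux == pytest.approx(src.I_0, rel=1e-3)
        sink_flux = source_flux(cfg, par, src, co, which="-")
        assert sink_flux == pytest.approx(-src.I_0, rel=1e-3)

    def test_transmembrane_current_consistency(self, default_model):
        """|div J_i| = |V_m| / rho_m by finite differences on stencils.

        The membrane current V_m/rho_m drains the intracellular domain, so
        div J_i = -V_m/rho_m with the decaying-Helmholtz sign convention.
        """
        cfg, par, src, co = default_model
        x0, y0, z0 = 0.6e-3, -0.4e-3, 0.5e-3
        h = cfg.a / 400

        def ji_cart(x, y, z):
            r, th, ph = cf.cartesian_to_spherical_coords(x, y, z)
            j = cf.current_density_i(r, th, ph, co, par)
            return cf.to_cartesian(j, th, ph)

        div = (
            (ji_cart(x0 + h, y0, z0)[0] - ji_cart(x0 - h, y0, z0)[0])
            + (ji_cart(x0, y0 + h, z0)[1] - ji_cart(x0, y0 - h, z0)[1])
            + (ji_cart(x0, y0, z0 + h)[2] - ji_cart(x0, y0, z0 - h)[2])
        ) / (2 * h)
        r, th, ph = cf.cartesian_to_spherical_coords(x0, y0, z0)
        vm = solver.transmembrane_potential(r, th, ph, co)
        assert div == pytest.approx(-vm / par.rho_m, rel=1e-3)

    def test_domain_guards(self, default_model):
        cfg, par, src, co = default_model
        with pytest.raises(ValueError):
            cf.current_density_i(3e-3, 0.5, 0.5, co, par)
        with pytest.raises(ValueError):
            cf.current_density_e(1e-3, 0.5, 0.5, co, src, par)


class TestFrameConversion:
    @pytest.mark.parametrize(
        "v, th, ph, expected",
        [
            ((1, 0, 0), 0.0, 0.0, (0, 0, 1)),  # r-hat = z-hat at the pole
            ((1, 0, 0), np.pi / 2, 0.0, (1, 0, 0)),
            ((0, 1, 0), np.pi / 2, 0.0, (0, 0, -1)),  # theta-hat points -z
            ((0, 0, 1), np.pi / 2, 0.0, (0, 1, 0)),
        ],
    )
    def test_known_rotations(self, v, th, ph, expected):
        out = cf.to_cartesian(cf.SphericalVector(*map(float, v)), th, ph)
        np.testing.assert_allclose(out, expected, atol=1e-15)

    def test_round_trip_preserves_vector(self, rng):
        v = cf.SphericalVector(*rng.normal(size=3))
        th, ph = rng.uniform(0.1, np.pi - 0.1), rng.uniform(0, 2 * np.pi)
        back = cf.from_cartesian(*cf.to_cartesian(v, th, ph), th, ph)
        for a, b in zip((v.v_r, v.v_theta, v.v_phi), (back.v_r, back.v_theta, back.v_phi)):
            assert a == pytest.approx(b, abs=1e-14)

    def test_norm_preserved(self, rng):
        v = cf.SphericalVector(*rng.normal(size=3))
        th, ph = rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)
        vx, vy, vz = cf.to_cartesian(v, th, ph)
        assert np.sqrt(vx**2 + vy**2 + vz**2) == pytest.approx(v.magnitude)


class TestSampleGrid:
    def test_dims_and_mask(self, small_current_grid, default_model):
        cfg, _, _, _ = default_model
        g = small_current_grid
        assert g.Jx.shape == (16, 16, 7)
        X, Y, Z = g.meshgrid()
        r = np.sqrt(X**2 + Y**2 + Z**2)
        shell = 0.5 * max(g.spacing)
        inside = (r < cfg.a) & (np.abs(r - cfg.a) > shell)
        outside = (r > cfg.a) & (np.abs(r - cfg.a) > shell)
        assert np.all(g.mask[inside] == cf.MASK_TISSUE)
        assert np.all(g.mask[outside] == cf.MASK_BATH)
        assert np.all(g.mask[np.abs(r - cfg.a) <= shell] == cf.MASK_EXCLUDED)

    def test_masked_nodes_zeroed(self, small_current_grid):
        g = small_current_grid
        excl = g.mask == cf.MASK_EXCLUDED
        assert np.all(g.Jx[excl] == 0.0)
        assert np.all(g.magnitude()[excl] == 0.0)

    def test_values_match_pointwise_evaluation(self, small_current_grid, default_model):
        cfg, par, src, co = default_model
        g = small_current_grid
        X, Y, Z = g.meshgrid()
        for idx in [(2, 3, 1), (8, 8, 3), (14, 2, 5)]:
            x, y, z = X[idx], Y[idx], Z[idx]
            r, th, ph = cf.cartesian_to_spherical_coords(x, y, z)
            if g.mask[idx] == cf.MASK_TISSUE:
                v = cf.current_density_i(r, th, ph, co, par) + cf.current_density_o(
                    r, th, ph, co, par
                )
            elif g.mask[idx] == cf.MASK_BATH:
                v = cf.current_density_e(r, th, ph, co, src, par)
            else:
                continue
            vx, vy, vz = cf.to_cartesian(v, th, ph)
            assert g.Jx[idx] == pytest.approx(vx, rel=1e-12)
            assert g.Jy[idx] == pytest.approx(vy, rel=1e-12)
            assert g.Jz[idx] == pytest.approx(vz, rel=1e-12)

    def test_mirror_symmetry_about_electrode_plane(self, small_current_grid):
        """Both electrodes in z=0: Jx, Jy even in z and Jz odd in z."""
        g = small_current_grid
        ok = (g.mask != cf.MASK_EXCLUDED) & (g.mask[:, :, ::-1] != cf.MASK_EXCLUDED)
        scale = np.max(g.magnitude())
        assert np.max(np.abs((g.Jx - g.Jx[:, :, ::-1])[ok])) <= 1e-12 * scale
        assert np.max(np.abs((g.Jy - g.Jy[:, :, ::-1])[ok])) <= 1e-12 * scale
        assert np.max(np.abs((g.Jz + g.Jz[:, :, ::-1])[ok])) <= 1e-12 * scale

    def test_interior_total_current_divergence_free(self, default_model):
        """div(J_i + J_o) = 0: membrane current only exchanges the domains."""
        cfg, par, src, co = default_model
        x0, y0, z0 = 0.5e-3, 0.3e-3, -0.6e-3
        h = cfg.a / 400

        def j_cart(x, y, z):
            r, th, ph = cf.cartesian_to_spherical_coords(x, y, z)
            j = cf.current_density_i(r, th, ph, co, par) + cf.current_density_o(
                r, th, ph, co, par
            )
            return cf.to_cartesian(j, th, ph)

        div = (
            (j_cart(x0 + h, y0, z0)[0] - j_cart(x0 - h, y0, z0)[0])
            + (j_cart(x0, y0 + h, z0)[1] - j_cart(x0, y0 - h, z0)[1])
            + (j_cart(x0, y0, z0 + h)[2] - j_cart(x0, y0, z0 - h)[2])
        ) / (2 * h)
        scale = np.linalg.norm(j_cart(x0, y0, z0)) / cfg.a
        assert abs(div) < 1e-3 * scale
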