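"""Cuboid-magnet fields against independent oracles, and force algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nasomag.errors import ConfigurationError, ParameterError
from nasomag.magnetics import (MU0, FieldSample, Magnet, ParticleProps,
                               cuboid_H, cuboid_field, grad_B_map, grad_H,
                               magnetophoretic_force, protocol_layout,
                               total_field)

# -- independent oracles -----------------------------------------------------


def surface_charge_H(point, magnet, order=48, nsub=4):
    """Gauss-Legendre surface integration of the magnetic charge model.

    For each magnetization component, integrates sigma = +-M_axis over the
    two faces normal to that body axis, with panel subdivision for accuracy.
    Fully independent of the closed form under test.
    """
    R = magnet.rotation_matrix
    Mb = R.T @ magnet.magnetization
    body = R.T @ (np.asarray(point, float) - np.asarray(magnet.center, float))
    hl = np.asarray(magnet.half_lengths, float)
    nodes, wts = np.polynomial.legendre.leggauss(order)
    H = np.zeros(3)
    for ax in range(3):
        if Mb[ax] == 0.0:
            continue
        o1, o2 = [k for k in range(3) if k != ax]
        a1, a2 = hl[o1], hl[o2]
        for s in (1.0, -1.0):
            for i in range(nsub):
                for j in range(nsub):
                    x0 = -a1 + 2 * a1 * i / nsub
                    x1 = -a1 + 2 * a1 * (i + 1) / nsub
                    y0 = -a2 + 2 * a2 * j / nsub
                    y1 = -a2 + 2 * a2 * (j + 1) / nsub
                    xs = 0.5 * (x1 - x0) * nodes + 0.5 * (x0 + x1)
                    ys = 0.5 * (y1 - y0) * nodes + 0.5 * (y0 + y1)
                    XX, YY = np.meshgrid(xs, ys, indexing="ij")
                    WW = np.outer(wts, wts) * 0.25 * (x1 - x0) * (y1 - y0)
                    src = np.zeros((3,) + XX.shape)
                    src[o1], src[o2], src[ax] = XX, YY, s * hl[ax]
                    r = body[:, None, None] - src
                    d3 = (r**2).sum(0) ** 1.5
                    H += s * Mb[ax] / (4 * np.pi) * np.array(
                        [(r[k] / d3 * WW).sum() for k in range(3)]
                    )
    return R @ H


def dipole_H(point, magnet):
    r = np.asarray(point, float) - np.asarray(magnet.center, float)
    rn = np.linalg.norm(r)
    rh = r / rn
    m = magnet.moment
    return (3.0 * rh * (m @ rh) - m) / (4.0 * np.pi * rn**3)


CUBE = Magnet(center=(0, 0, 0), half_lengths=(0.01, 0.01, 0.01),
              remanence=(0, 0, 1.2))
ROT = ((0.0, 0.0, 1.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0))
SKEW = Magnet(center=(0.01, -0.02, 0.005), half_lengths=(0.004, 0.008, 0.012),
              rotation=ROT, remanence=(0.3, -0.5, 0.9))


class TestCuboidField:
    def test_cube_center_demagnetizing_factor(self):
        M = 1.2 / MU0
        H = cuboid_H((0.0, 0.0, 0.0), CUBE)
        assert np.allclose(H, [0, 0, -M / 3], rtol=1e-6, atol=M * 1e-9)

    def test_mirror_symmetry(self):
        p = np.array([0.004, 0.013, 0.017])
        H = cuboid_H(p, CUBE)
        Hm = cuboid_H(p * np.array([1, -1, 1]), CUBE)
        assert np.allclose(Hm, H * np.array([1, -1, 1]), rtol=1e-10)

    @pytest.mark.parametrize("magnet,point", [
        (CUBE, (0.012, 0.007, 0.015)),
        (CUBE, (0.0, 0.0, 0.025)),
        (SKEW, (0.04, 0.01, -0.02)),
        (SKEW, (-0.01, -0.045, 0.03)),
    ])
    def test_matches_surface_integration(self, magnet, point):
        H = cuboid_H(point, magnet)
        Ho = surface_charge_H(point, magnet)
        assert np.linalg.norm(H - Ho) / np.linalg.norm(Ho) < 1e-6

    def test_dipole_far_field(self):
        L = 2 * max(CUBE.half_lengths)
        for direction in (np.array([0, 0, 1.0]), np.array([1.0, 1, 1]) / 3**0.5):
            p = 10 * L * direction
            H = cuboid_H(p, CUBE)
            Hd = dipole_H(p, CUBE)
            assert np.linalg.norm(H - Hd) / np.linalg.norm(Hd) < 0.01

    def test_edge_singularity_offset_not_crash(self):
        # exactly on a magnet edge: flagged, finite
        H, J, flagged = cuboid_field((0.01, 0.0, 0.01), CUBE)
        assert np.all(np.isfinite(H)) and np.all(np.isfinite(J))
        assert flagged

    def test_interior_field_continuity_of_B(self):
        # B_z = mu0 (H_z + M) just inside a pole face equals mu0 H_z outside
        zin, zout = 0.01 - 1e-6, 0.01 + 1e-6
        M = np.linalg.norm(CUBE.magnetization)
        Bz_in = MU0 * (cuboid_H((0, 0, zin), CUBE)[2] + M)
        Bz_out = MU0 * cuboid_H((0, 0, zout), CUBE)[2]
        assert Bz_in == pytest.approx(Bz_out, rel=1e-3)


class TestJacobian:
    def test_matches_finite_differences(self):
        pt = np.array([0.012, 0.007, 0.015])
        J = grad_H(pt, SKEW)
        eps = 1e-6
        Jfd = np.zeros((3, 3))
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            Jfd[:, j] = (cuboid_H(pt + e, SKEW) - cuboid_H(pt - e, SKEW)) / (2 * eps)
        assert np.max(np.abs(J - Jfd)) / np.max(np.abs(Jfd)) < 1e-4

    def test_exterior_curl_and_div_free(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-0.08, 0.08, size=(300, 3))
        hl = np.asarray(CUBE.half_lengths)
        outside = np.any(np.abs(pts) > hl * 1.2, axis=1)
        pts = pts[outside][:100]
        assert len(pts) == 100
        _, J, _ = cuboid_field(pts, CUBE)
        scale = np.abs(J).max(axis=(1, 2))
        asym = np.abs(J - np.swapaxes(J, 1, 2)).max(axis=(1, 2))
        tr = np.abs(J[:, 0, 0] + J[:, 1, 1] + J[:, 2, 2])
        assert np.all(asym / scale < 1e-6)
        assert np.all(tr / scale < 1e-6)

    def test_far_field_decay_slope(self):
        # Jacobian of a dipole-like source decays as r^-4
        L = 2 * max(CUBE.half_lengths)
        rs = np.geomspace(10 * L, 100 * L, 12)
        mags = []
        for r in rs:
            J = grad_H((0.3 * r, 0.5 * r, r * 0.81), CUBE)
            mags.append(np.linalg.norm(J))
        slope = np.polyfit(np.log(rs), np.log(mags), 1)[0]
        assert slope == pytest.approx(-4.0, abs=0.05)


class TestSuperposition:
    def test_single_magnet_identity(self):
        p = (0.02, 0.015, -0.01)
        s = total_field(p, [CUBE])
        assert np.allclose(s.H, cuboid_H(p, CUBE))
        assert np.allclose(s.J, grad_H(p, CUBE))
        assert np.allclose(s.B, MU0 * s.H)

    def test_opposite_magnets_cancel(self):
        flipped = Magnet(center=CUBE.center, half_lengths=CUBE.half_lengths,
                         remanence=(0, 0, -1.2))
        p = (0.02, 0.015, -0.01)
        s = total_field(p, [CUBE, flipped])
        ref = np.linalg.norm(cuboid_H(p, CUBE))
        assert np.linalg.norm(s.H) / ref < 1e-10

    def test_two_magnets_sum_term_by_term(self):
        p = (0.03, -0.01, 0.02)
        s = total_field(p, [CUBE, SKEW])
        assert np.allclose(s.H, cuboid_H(p, CUBE) + cuboid_H(p, SKEW))
        assert np.allclose(s.J, grad_H(p, CUBE) + grad_H(p, SKEW))

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigurationError):
            total_field((0, 0, 0), [])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 5.0),
           y=st.floats(0.015, 0.08), z=st.floats(-0.08, -0.015))
    def test_linearity_in_remanence(self, scale, y, z):
        scaled = Magnet(center=CUBE.center, half_lengths=CUBE.half_lengths,
                        remanence=(0, 0, 1.2 * scale))
        p = (0.02, y, z)  # exterior by construction
        assert np.allclose(cuboid_H(p, scaled), scale * cuboid_H(p, CUBE),
                           rtol=1e-10)


class TestMagnetophoreticForce:
    props = ParticleProps(susceptibility=5.0)

    def test_uniform_field_no_force(self):
        s = FieldSample(H=np.array([1e5, -3e4, 2e4]), B=None,
                        J=np.zeros((3, 3)))
        F = magnetophoretic_force(s, self.props, mode="high_chi")
        assert np.allclose(F, 0.0)

    @pytest.mark.parametrize("chi", [0.1, 1.0, 3.0, 10.0, 1e3])
    def test_exact_to_highchi_ratio(self, chi):
        props = ParticleProps(susceptibility=chi)
        s = total_field((0.015, 0.005, 0.014), [CUBE])
        Fe = magnetophoretic_force(s, props, mode="exact")
        Fh = magnetophoretic_force(s, props, mode="high_chi")
        assert np.allclose(Fe, Fh * (chi / (chi + 3.0)), rtol=1e-14)

    def test_chi_ratio_monotone_to_one(self):
        chis = [3.0, 10.0, 100.0, 1e4]
        ratios = [c / (c + 3.0) for c in chis]
        assert ratios[0] == pytest.approx(0.5)
        assert all(a < b for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] == pytest.approx(1.0, abs=1e-3)

    def test_hand_computed_linear_gradient(self):
        # H = (0, 0, h (1 + z/L)): at z=0 the only J entry is dHz/dz = h/L
        hmag, L = 1e5, 0.01
        J = np.zeros((3, 3))
        J[2, 2] = hmag / L
        s = FieldSample(H=np.array([0.0, 0.0, hmag]), B=None, J=J)
        props = ParticleProps()
        F = magnetophoretic_force(s, props, mode="high_chi")
        Vp = 4.0 / 3.0 * np.pi * 7.5e-6**3  # independent volume evaluation
        assert Vp == pytest.approx(1.767e-15, rel=1e-3)
        expected = 3.0 * MU0 * Vp * hmag**2 / L
        assert F[2] == pytest.approx(expected, rel=1e-12)
        assert np.allclose(F[:2], 0.0)

    def test_force_quadratic_in_remanence(self):
        doubled = Magnet(center=CUBE.center, half_lengths=CUBE.half_lengths,
                         remanence=(0, 0, 2.4))
        p = (0.014, 0.006, 0.016)
        F1 = magnetophoretic_force(total_field(p, [CUBE]), self.props)
        F2 = magnetophoretic_force(total_field(p, [doubled]), self.props)
        assert np.allclose(F2, 4 * F1, rtol=1e-10)

    def test_gradient_energy_identity(self):
        # exterior H is curl-free, so (H.grad)H = 1/2 grad(H.H) = J^T H
        s = total_field((0.018, -0.009, 0.022), [SKEW])
        JH = s.J @ s.H
        JtH = s.J.T @ s.H
        assert np.linalg.norm(JH - JtH) / np.linalg.norm(JH) < 1e-8

    def test_exact_mode_requires_chi(self):
        s = total_field((0.02, 0, 0.02), [CUBE])
        with pytest.raises(ParameterError):
            magnetophoretic_force(s, ParticleProps(), mode="exact")
        with pytest.raises(ParameterError):
            magnetophoretic_force(s, ParticleProps(susceptibility=-3.0),
                                  mode="exact")


class TestProtocolLayouts:
    def test_protocol_magnet_dimensions(self):
        (m1,) = protocol_layout(1)
        (m3,) = protocol_layout(3)
        assert sorted(np.round(m1.half_lengths, 6)) == [0.005, 0.005, 0.02]
        assert sorted(np.round(m3.half_lengths, 6)) == [0.001, 0.015, 0.025]

    def test_protocols_1_2_related_by_quarter_turn(self):
        (m1,) = protocol_layout(1)
        (m2,) = protocol_layout(2)
        rel = m2.rotation_matrix @ m1.rotation_matrix.T
        # rotation about the septum normal (x): x axis fixed, angle 90 deg
        assert np.allclose(rel @ [1, 0, 0], [1, 0, 0], atol=1e-12)
        angle = np.degrees(np.arccos((np.trace(rel) - 1) / 2))
        assert angle == pytest.approx(90.0, abs=1e-9)

    def test_center_distance_and_remanence(self):
        for proto in (1, 2, 3):
            (m,) = protocol_layout(proto, distance=0.005)
            assert m.center[0] == pytest.approx(-0.005)
            assert np.linalg.norm(m.remanence) == pytest.approx(1.2, abs=1e-3)
            assert m.remanence[0] == 0.0

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ConfigurationError):
            protocol_layout(4)


class TestGradBMap:
    def test_cancelled_field_gives_zero_map(self, surrogate_domain):
        flipped = Magnet(center=CUBE.center, half_lengths=CUBE.half_lengths,
                         remanence=(0, 0, -1.2))
        _, _, g = grad_B_map(surrogate_domain, [CUBE, flipped])
        _, _, g1 = grad_B_map(surrogate_domain, [CUBE])
        assert g.max() < 1e-9 * g1.max()

    def test_matches_refined_finite_differences(self, surrogate_domain):
        from nasomag.geometry import SurrogateParams, build_surrogate
        from nasomag.magnetics import protocol_layout, total_field

        magnets = protocol_layout(1)
        y, z, g = grad_B_map(surrogate_domain, magnets, x_offset=0.0025)
        fine = build_surrogate(SurrogateParams(grid_spacing=4e-4))
        yf, zf, gf = grad_B_map(fine, magnets, x_offset=0.0025)
        # compare at an interior probe away from magnet edges
        iy = np.argmin(np.abs(y - 0.04))
        iz = np.argmin(np.abs(z - 0.044))
        iyf = np.argmin(np.abs(yf - y[iy]))
        izf = np.argmin(np.abs(zf - z[iz]))
        assert g[iy, iz] == pytest.approx(gf[iyf, izf], rel=0.05)
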