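"""Real harmonics, Legendre-function ratios, and basis assembly."""

import warnings

import numpy as np
import pytest
from scipy.special import assoc_legendre_p, lqmn, roots_legendre

import ammeg as am
from ammeg.harmonics import potential_value

A, C = 0.09, 0.05  # reference major semi-axis and focus used throughout


class TestRealSphHarm:
    def test_monopole_value(self):
        assert np.isclose(am.real_sph_harm(0, 0, 0.3, 1.1), 1 / np.sqrt(4 * np.pi))

    def test_dipole_at_pole(self):
        assert np.isclose(am.real_sph_harm(1, 0, 0.0, 0.0), np.sqrt(3 / (4 * np.pi)))

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            am.real_sph_harm(2, 3, 0.1, 0.1)

    def test_orthonormal_on_sphere(self):
        # Gauss-Legendre x trapezoid product quadrature, exact for this band
        nodes, wts = roots_legendre(32)
        theta = np.arccos(nodes)
        phi = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        th, ph = np.meshgrid(theta, phi, indexing="ij")
        w = np.broadcast_to(wts[:, None], th.shape) * (2 * np.pi / 64)
        pairs = [(l, m) for l in range(5) for m in range(-l, l + 1)]
        vals = {p: am.real_sph_harm(p[0], p[1], th, ph) for p in pairs}
        for i, p1 in enumerate(pairs):
            for p2 in pairs[i:]:
                got = np.sum(vals[p1] * vals[p2] * w)
                want = 1.0 if p1 == p2 else 0.0
                assert abs(got - want) < 1e-6, (p1, p2)


class TestRadialRatios:
    def test_unity_on_reference_surface(self):
        for l in (1, 4, 9):
            assert np.isclose(am.q_ratio(l, 1, A, C, A), 1.0, rtol=1e-13)
            assert np.isclose(am.p_ratio(l, 1, A, C, A), 1.0, rtol=1e-13)

    def test_spherical_limits(self):
        c = 1e-6 * A
        r = 0.13
        for l, m in ((1, 0), (5, 3), (9, 9)):
            assert np.isclose(am.q_ratio(l, m, r, c, A), (A / r) ** (l + 1), rtol=1e-8)
            assert np.isclose(am.p_ratio(l, m, r, c, A), (r / A) ** l, rtol=1e-8)

    def test_q00_closed_form(self):
        r = 0.12
        q0 = lambda x: 0.5 * np.log((x + 1) / (x - 1))
        assert np.isclose(am.q_ratio(0, 0, r, C, A), q0(r / C) / q0(A / C), rtol=1e-10)

    def test_p21_closed_form(self):
        r = 0.12
        p21 = lambda x: 3 * x * np.sqrt(x**2 - 1)
        assert np.isclose(am.p_ratio(2, 1, r, C, A), p21(r / C) / p21(A / C), rtol=1e-10)

    @pytest.mark.parametrize("l,m", [(l, m) for l in (1, 3, 6, 9, 11) for m in (0, 1, l)])
    def test_against_scipy_legendre(self, l, m):
        m = min(m, l)
        for r in (0.09, 0.11, 0.2):
            xi, xia = r / C, A / C
            qs = lqmn(m, l, xi)[0][m, l] / lqmn(m, l, xia)[0][m, l]
            assert np.isclose(am.q_ratio(l, m, r, C, A), qs, rtol=1e-9)
            ps = (np.asarray(assoc_legendre_p(l, m, xi, branch_cut=3)).item()
                  / np.asarray(assoc_legendre_p(l, m, xia, branch_cut=3)).item())
            assert np.isclose(am.p_ratio(l, m, r, C, A), ps, rtol=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            am.q_ratio(2, 3, 0.1, C, A)
        with pytest.raises(ValueError):
            am.p_ratio(2, -1, 0.1, C, A)
        with pytest.raises(ValueError):
            am.q_ratio(2, 1, 0.04, C, A)  # rmaj <= c


class TestPotential:
    FRAME = am.ReferenceSpheroid(np.zeros(3), np.array([0, 1.0, 0]), 0.09, 0.07)

    def test_families_agree_on_near_sphere(self, rng):
        near = am.ReferenceSpheroid(np.zeros(3), np.array([0, 1.0, 0]),
                                    0.09, 0.09 * np.sqrt(1 - 1e-12))
        pts = rng.standard_normal((20, 3))
        pts = 0.12 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        for kind in ("internal", "external"):
            for l, m in ((1, 0), (3, 2), (5, -4)):
                vs = potential_value(kind, "spheroidal", l, m, pts, near)
                vr = potential_value(kind, "spherical", l, m, pts, near)
                assert np.allclose(vs, vr, rtol=1e-5)

    def test_external_dipole_is_linear_in_z(self, rng):
        pts = rng.standard_normal((15, 3)) * 0.05
        v = potential_value("external", "spherical", 1, 0, pts, self.FRAME)
        zloc = pts @ self.FRAME.axis  # frame z-axis is the spheroid axis
        ratio = v / zloc
        assert np.allclose(ratio, ratio[0], rtol=1e-10)

    @pytest.mark.parametrize("kind,family", [("internal", "spheroidal"),
                                             ("external", "spheroidal"),
                                             ("internal", "spherical")])
    def test_harmonicity_by_stencil(self, kind, family, rng):
        # Laplace's equation: 7-point finite-difference Laplacian ~ 0
        h = 5e-5
        pts = rng.standard_normal((10, 3))
        pts = 0.13 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        for l, m in ((2, 1), (4, -3)):
            lap = np.zeros(len(pts))
            centre = potential_value(kind, family, l, m, pts, self.FRAME)
            for ax in range(3):
                e = np.zeros(3)
                e[ax] = h
                lap += (potential_value(kind, family, l, m, pts + e, self.FRAME)
                        + potential_value(kind, family, l, m, pts - e, self.FRAME))
            lap = (lap - 6 * centre) / h**2
            scale = np.abs(centre) + np.abs(centre).max()
            assert np.all(np.abs(lap) * self.FRAME.a**2 / scale < 1e-4)


class TestBasis:
    def test_column_counts(self, triaxial_basis, triaxial_array, head):
        assert triaxial_basis.internal.shape[1] == 99   # 9^2 + 2*9
        assert triaxial_basis.external.shape[1] == 8    # 2^2 + 2*2
        b11 = am.build_basis(triaxial_array, head, L_in=11, L_out=2)
        assert b11.internal.shape[1] == 143             # 11^2 + 2*11

    def test_columns_unit_norm_with_positive_scales(self, triaxial_basis):
        assert np.allclose(np.linalg.norm(triaxial_basis.matrix, axis=0), 1.0, atol=1e-12)
        assert np.all(triaxial_basis.scales > 0)

    def test_warns_when_sensors_inside_frame(self, triaxial_array, head):
        big = head.scaled(1.2)
        with pytest.warns(UserWarning, match="inside the reference spheroid"):
            am.build_basis(triaxial_array, big, L_in=2, L_out=1)

    def test_spherical_limit_equivalence(self, triaxial_array):
        # a near-spherical frame must reproduce the spherical basis
        # column-by-column up to positive scale
        near = am.ReferenceSpheroid(np.zeros(3), np.array([0, 1.0, 0]),
                                    0.085, 0.085 * np.sqrt(1 - 1e-12))
        bs = am.build_basis(triaxial_array, near, family="spheroidal",
                            external_family="spheroidal", L_in=5, L_out=2)
        br = am.build_basis(triaxial_array, near, family="spherical",
                            external_family="spherical", L_in=5, L_out=2)
        cos = np.abs(np.einsum("ij,ij->j", bs.matrix, br.matrix))
        assert np.all(1 - cos < 1e-5)

    def test_finite_difference_matches_symbolic_gradient(self, head):
        # independent oracle: sympy differentiates the solid harmonic
        sympy = pytest.importorskip("sympy")
        x, y, z = sympy.symbols("x y z", real=True)
        r = sympy.sqrt(x**2 + y**2 + z**2)
        names = list("abc")
        pos = np.array([[0.05, 0.08, -0.03]])
        for l, m in ((1, 0), (2, 1), (3, -2)):
            ct = z / r
            am_ = abs(m)
            leg = (-1) ** am_ * sympy.assoc_legendre(l, am_, ct)  # cancel CS phase
            norm = sympy.sqrt((2 * l + 1) / (4 * sympy.pi)) if m == 0 else \
                sympy.sqrt((2 * l + 1) / (2 * sympy.pi) *
                           sympy.factorial(l - am_) / sympy.factorial(l + am_))
            az = sympy.atan2(y, x)
            trig = 1 if m == 0 else (sympy.cos(am_ * az) if m > 0 else sympy.sin(am_ * az))
            V = (r / head.a) ** l * norm * leg * trig  # external solid harmonic
            grad = [sympy.lambdify((x, y, z), sympy.diff(V, s)) for s in (x, y, z)]
            for ori in (np.array([1.0, 0, 0]), np.array([0, 0.6, 0.8])):
                arr = am.SensorArray(names=names[:1], positions=pos, orientations=ori[None])
                # use the origin-centred frame so sympy's r matches
                frame = am.ReferenceSpheroid(np.zeros(3), np.array([0, 0, 1.0]),
                                             head.a, head.a * np.sqrt(1 - 1e-12))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    b = am.build_basis(arr, frame, family="spherical",
                                       external_family="spherical", L_in=1, L_out=max(l, 1))
                col = [i for i, c in enumerate(b.meta)
                       if c["kind"] == "external" and c["l"] == l and c["m"] == m][0]
                got = b.matrix[0, col] * b.scales[col]
                want = sum(g(*pos[0]) * o for g, o in zip(grad, ori))
                assert np.isclose(got, want, rtol=1e-6), (l, m, ori)

    def test_external_l1_spans_homogeneous_fields(self, triaxial_array, head):
        b = am.build_basis(triaxial_array, head, family="spherical", L_in=1, L_out=2)
        cols = [i for i, c in enumerate(b.meta) if c["kind"] == "external" and c["l"] == 1]
        H1 = b.matrix[:, cols]
        homog = triaxial_array.orientations  # columns: B0 = ex, ey, ez patterns
        from scipy.linalg import subspace_angles
        assert np.max(subspace_angles(H1, homog)) < 1e-6

    def test_rotation_invariance_of_span(self, head):
        from scipy.linalg import subspace_angles
        from scipy.spatial.transform import Rotation
        arr = am.generate_scalp_array(head, spacing=0.05, axes=2, seed=4)
        R = Rotation.from_rotvec([0.3, -0.5, 0.7]).as_matrix()
        rot_head = am.ReferenceSpheroid(R @ head.centre, R @ head.axis, head.a, head.b)
        rot = am.SensorArray(names=list(arr.names), positions=arr.positions @ R.T,
                             orientations=arr.orientations @ R.T,
                             axes_per_sensor=2, sensor_index=arr.sensor_index)
        b0 = am.build_basis(arr, head, L_in=3, L_out=2)
        b1 = am.build_basis(rot, rot_head, L_in=3, L_out=2)
        assert np.max(subspace_angles(b0.internal, b1.internal)) < 1e-7
        assert np.max(subspace_angles(b0.external, b1.external)) < 1e-7

    def test_duplicate_columns_rejected(self, triaxial_basis):
        meta = [dict(c) for c in triaxial_basis.meta]
        meta[1] = dict(meta[0])
        with pytest.raises(ValueError, match="duplicate"):
            am.HarmonicBasis(matrix=triaxial_basis.matrix, meta=meta,
                             scales=triaxial_basis.scales, frame=triaxial_basis.frame)
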