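import numpy as np
import pytest

import gipct as g
from gipct.operators import materialize


@pytest.fixture(scope="module")
def par32():
    geo = g.parallel_geometry(32, 48, pixel_size=0.1)
    return g.DPCOperatorPair(geometry=geo, scale=1.0)


@pytest.fixture(scope="module")
def fan16():
    geo = g.fan_geometry(16, 24)
    return g.DPCOperatorPair(geometry=geo, scale=1.0)


class TestLinearity:
    def test_forward_linear(self, par32, rng):
        x = rng.standard_normal(par32.geometry.image_shape)
        y = rng.standard_normal(par32.geometry.image_shape)
        a, b = 1.7, -0.3
        lhs = par32.forward(a * x + b * y)
        rhs = a * par32.forward(x) + b * par32.forward(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12 * np.abs(rhs).max())

    def test_zero_maps_to_zero(self, par32):
        assert np.all(par32.forward(np.zeros(par32.geometry.image_shape)) == 0)
        assert np.all(par32.adjoint(np.zeros(par32.geometry.sino_shape)) == 0)

    def test_ray_subset_independence(self, par32, breast32):
        """Rays are independent: any sinogram row equals the same row of
        the full computation (ray-driven contract)."""
        full = par32.forward(breast32.delta)
        sub_geo = g.ScanGeometry(
            mode="parallel", angles=par32.geometry.angles[5:6], n_det=par32.geometry.n_det,
            det_pitch=par32.geometry.det_pitch, pixel_size=par32.geometry.pixel_size,
            image_shape=par32.geometry.image_shape,
        )
        sub_op = g.DPCOperatorPair(geometry=sub_geo, kb=par32.kb, scale=1.0)
        np.testing.assert_allclose(sub_op.forward(breast32.delta)[0], full[5], atol=1e-14)


class TestAdjointness:
    def test_dot_product_matched_parallel(self, par32, rng):
        x = rng.standard_normal(par32.geometry.image_shape)
        y = rng.standard_normal(par32.geometry.sino_shape)
        lhs = np.sum(par32.forward(x) * y)
        rhs = np.sum(x * par32.adjoint_matched(y))
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_dot_product_matched_fan(self, fan16, rng):
        x = rng.standard_normal(fan16.geometry.image_shape)
        y = rng.standard_normal(fan16.geometry.sino_shape)
        lhs = np.sum(fan16.forward(x) * y)
        rhs = np.sum(x * fan16.adjoint_matched(y))
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_voxel_driven_equals_matched_in_parallel(self, par32, rng):
        y = rng.standard_normal(par32.geometry.sino_shape)
        a = par32.adjoint_matched(y)
        b = par32.adjoint_voxel_driven(y)
        np.testing.assert_allclose(b, a, atol=1e-12 * np.abs(a).max())

    def test_fan_voxel_driven_reported_not_constrained(self, fan16, rng):
        """Fan-beam voxel-driven backprojection is an unmatched adjoint;
        its dot-test error is reported (finite) but not bounded."""
        x = rng.standard_normal(fan16.geometry.image_shape)
        y = rng.standard_normal(fan16.geometry.sino_shape)
        lhs = np.sum(fan16.forward(x) * y)
        rhs = np.sum(x * fan16.adjoint_voxel_driven(y))
        assert np.isfinite(lhs) and np.isfinite(rhs)


class TestForwardPhysics:
    def test_single_blob_profile_is_derivative_lookup(self):
        """A unit Kaiser-Bessel coefficient at the isocenter projects to
        scale times the tabulated derivative at the detector offsets."""
        geo = g.parallel_geometry(33, 1, pixel_size=0.1)
        op = g.DPCOperatorPair(geometry=geo, scale=2.5)
        delta = np.zeros(geo.image_shape)
        delta[16, 16] = 1.0  # exactly at the isocenter (odd grid)
        sino = op.forward(delta)[0]
        s = geo.detector_coords()
        expected = 2.5 * op.kb.derivative(s - 0.0)
        np.testing.assert_allclose(sino, expected, atol=1e-12)

    def test_disk_matches_analytic_radon_derivative(self):
        """Relative L2 error against the analytic derivative of the disk's
        Radon transform decreases under grid refinement."""
        r = 1.0
        errs = []
        for side in (32, 64, 128):
            px = 3.2 / side
            geo = g.parallel_geometry(side, 1, pixel_size=px)
            op_ref = g.DPCOperatorPair(geometry=geo, scale=1.0)
            op = g.DPCOperatorPair(geometry=geo, scale=px**2 / op_ref.kb.window_integral)
            ph = g.make_disk_phantom((side, side), r, 1.0, pixel_size=px)
            sino = op.forward(ph.delta)[0]
            s = geo.detector_coords()
            inside = np.abs(s) < 0.9 * r
            dP = -2 * s[inside] / np.sqrt(r**2 - s[inside] ** 2)
            errs.append(np.linalg.norm(sino[inside] - dP) / np.linalg.norm(dP))
        assert errs[0] > errs[1] > errs[2]

    def test_antisymmetry_under_mirror(self, par32, breast32):
        """Mirroring the phantom along the differentiation direction flips
        the sign and detector order of the sinogram (odd kernel)."""
        mirrored = breast32.delta[:, ::-1]
        sino = par32.forward(breast32.delta)
        sino_m = par32.forward(mirrored)
        # at theta = 0 the detector coordinate is x itself
        np.testing.assert_allclose(sino_m[0], -sino[0][::-1], atol=1e-10 * np.abs(sino).max())

    def test_constant_image_in_null_space_plateau(self, par32):
        """A constant image refracts only at its (square) boundary: rays
        whose chord length is stationary — the central plateau of the
        square's projection profile — see a lattice sum of the odd compact
        kernel, which cancels to quadrature order."""
        geo = par32.geometry
        const = np.ones(geo.image_shape)
        sino = par32.forward(const)
        peak = np.abs(sino).max()
        half_w = geo.image_shape[0] * geo.pixel_size / 2
        s = geo.detector_coords()
        checked = 0
        for a, theta in enumerate(geo.angles):
            ct, st = abs(np.cos(theta)), abs(np.sin(theta))
            plateau = half_w * abs(ct - st)  # flat part of the trapezoid profile
            inside = np.abs(s) < 0.7 * plateau - 2 * par32.kb.w
            if inside.sum() >= 3:
                checked += 1
                assert np.abs(sino[a][inside]).max() <= 1e-2 * peak
        assert checked >= 10


@pytest.fixture(scope="module")
def fd32():
    geo = g.parallel_geometry(32, 48, pixel_size=0.1)
    return g.FDOperatorPair(geometry=geo, scale=1.0)


class TestFDBaseline:

    def test_zero_image(self, fd32):
        assert np.all(fd32.forward(np.zeros(fd32.geometry.image_shape)) == 0)

    def test_exact_transpose(self, fd32, rng):
        x = rng.standard_normal(fd32.geometry.image_shape)
        y = rng.standard_normal(fd32.geometry.sino_shape)
        lhs = np.sum(fd32.forward(x) * y)
        rhs = np.sum(x * fd32.adjoint(y))
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_agrees_with_kb_on_smooth_phantom(self):
        """Both operators discretize the same differential ray transform:
        on a smooth Gaussian blob at fine resolution they agree closely."""
        # 30 angles: avoids theta = 45 deg exactly, where the bilinear
        # pixel-driven ray sum aliases on the diagonal lattice
        side = 128
        geo = g.parallel_geometry(side, 30, pixel_size=0.05)
        kb_op = g.DPCOperatorPair(geometry=geo, scale=None, delta_unit=1.0)
        fd_op = g.FDOperatorPair(geometry=geo, scale=None, delta_unit=1.0)
        yy, xx = np.mgrid[0:side, 0:side].astype(float)
        c = (side - 1) / 2
        blob = np.exp(-(((xx - c) * 0.05) ** 2 + ((yy - c) * 0.05) ** 2) / (2 * 0.8**2))
        a = kb_op.forward(blob)
        b = fd_op.forward(blob)
        assert np.linalg.norm(a - b) / np.linalg.norm(a) < 0.05

    def test_fan_rejected(self):
        with pytest.raises(ValueError):
            g.FDOperatorPair(geometry=g.fan_geometry(16, 8), scale=1.0)


class TestSpectrum:
    def test_identity_stub_all_ones(self):
        class Identity:
            def __init__(self, side):
                self.geometry = g.parallel_geometry(side, side)

            def forward(self, x):
                return np.asarray(x).reshape(self.geometry.sino_shape).copy()

        spec = g.normal_matrix_spectrum(Identity(8))
        np.testing.assert_allclose(spec, 1.0, atol=1e-12)

    def test_invariant_to_basis_permutation(self, rng):
        geo = g.parallel_geometry(8, 12)
        op = g.DPCOperatorPair(geometry=geo, scale=1.0)
        a_mat = materialize(op)
        perm = rng.permutation(a_mat.shape[1])
        s1 = np.linalg.svd(a_mat, compute_uv=False)
        s2 = np.linalg.svd(a_mat[:, perm], compute_uv=False)
        np.testing.assert_allclose(s1, s2, rtol=1e-10)

    def test_size_cap_enforced(self):
        geo = g.parallel_geometry(128, 8)
        op = g.DPCOperatorPair(geometry=geo, scale=1.0)
        with pytest.raises(ValueError, match="iterative"):
            g.normal_matrix_spectrum(op)

    def test_kb_spectrum_dominates_fd_top_quartile(self, study32):
        """The analytic-derivative operator's normalized normal-matrix
        spectrum decays more slowly than the finite-difference one."""
        report = g.spectrum_report(study32.kb_op, study32.fd_op, 32)
        assert report.verdict == "kb decays slower"
        assert report.dominance_fraction > 0.5

    def test_spectrum_report_equal_operators(self):
        geo = g.parallel_geometry(8, 12)
        op = g.DPCOperatorPair(geometry=geo, scale=1.0)
        report = g.spectrum_report(op, op, 8)
        assert report.verdict == "equal"
        assert report.dominance_fraction == 1.0

    def test_csv_round_trip(self, tmp_path):
        geo = g.parallel_geometry(8, 12)
        report = g.spectrum_report(
            g.DPCOperatorPair(geometry=geo, scale=1.0),
            g.FDOperatorPair(geometry=geo, scale=1.0),
            8,
        )
        path = tmp_path / "spec.csv"
        report.write_csv(path)
        kb, fd = type(report).read_csv(path)
        np.testing.assert_array_equal(kb, report.spectrum_kb)
        np.testing.assert_array_equal(fd, report.spectrum_fd)
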