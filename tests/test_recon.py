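import numpy as np
import pytest

import gipct as g
from gipct.recon import LBFGSMemory, _loss_only


@pytest.fixture(scope="module")
def consistent_problem(study32):
    """Noise-free, consistent data: phi = A delta* exactly."""
    phantom = g.make_breast_phantom((32, 32), 3, seed=7, delta_range=(0, 1))
    phi = g.DPCSinogram(phi=study32.kb_op.forward(phantom.delta), geometry=study32.geometry)
    return phantom, phi


class TestDataFidelity:
    def test_exact_solution_zero_loss_zero_grad(self, study32, consistent_problem):
        phantom, phi = consistent_problem
        loss, grad = g.data_fidelity_and_grad(phantom.delta, phi, study32.kb_op)
        assert loss == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_gradient_matches_directional_derivative(self, study32, consistent_problem, rng):
        _, phi = consistent_problem
        x = rng.standard_normal((32, 32))
        loss, grad = g.data_fidelity_and_grad(x, phi, study32.kb_op)
        for _ in range(5):
            d = rng.standard_normal((32, 32))
            d /= np.linalg.norm(d)
            h = 1e-6
            lp, _ = g.data_fidelity_and_grad(x + h * d, phi, study32.kb_op)
            lm, _ = g.data_fidelity_and_grad(x - h * d, phi, study32.kb_op)
            numeric = (lp - lm) / (2 * h)
            assert numeric == pytest.approx(np.sum(grad * d), rel=1e-5)

    def test_midpoint_convexity_along_lines(self, study32, consistent_problem, rng):
        _, phi = consistent_problem
        for _ in range(5):
            a = rng.standard_normal((32, 32))
            b = rng.standard_normal((32, 32))
            la, _ = g.data_fidelity_and_grad(a, phi, study32.kb_op)
            lb, _ = g.data_fidelity_and_grad(b, phi, study32.kb_op)
            lm, _ = g.data_fidelity_and_grad(0.5 * (a + b), phi, study32.kb_op)
            assert lm <= 0.5 * (la + lb) + 1e-9

    def test_masked_elements_excluded(self, study32, consistent_problem, rng):
        phantom, phi = consistent_problem
        corrupted = phi.phi.copy()
        corrupted[0, 5] = 1e6
        mask = np.ones_like(corrupted, dtype=bool)
        mask[0, 5] = False
        sino = g.DPCSinogram(phi=corrupted, geometry=study32.geometry, mask=mask)
        loss, _ = g.data_fidelity_and_grad(phantom.delta, sino, study32.kb_op)
        assert loss == pytest.approx(0.0, abs=1e-18)


class TestLBFGSDirection:
    def test_empty_memory_is_steepest_descent(self, rng):
        gvec = rng.standard_normal((5, 5))
        d = g.lbfgs_direction(gvec, LBFGSMemory(5))
        np.testing.assert_array_equal(d, -gvec)

    def test_single_pair_matched_curvature_lands_on_quadratic_minimizer(self):
        """With H = c*I, one (s, y=H s) pair makes the two-loop recursion an
        exact Newton step for any gradient."""
        c = 4.0
        mem = LBFGSMemory(5)
        s = np.array([[1.0, 2.0], [0.5, -1.0]])
        mem.push(s, c * s)
        x = np.array([[0.3, -0.7], [2.0, 1.0]])  # current point, minimizer at 0
        gvec = c * x
        d = g.lbfgs_direction(gvec, mem)
        np.testing.assert_allclose(x + d, 0.0, atol=1e-12)

    def test_full_memory_matches_dense_bfgs_on_quadratic(self, rng):
        """Two-loop recursion against an explicit dense BFGS inverse-Hessian
        recursion on a 10-dimensional quadratic, memory >= dimension."""
        n = 10
        a_mat = rng.standard_normal((n, n))
        h_mat = a_mat @ a_mat.T + n * np.eye(n)
        mem = LBFGSMemory(capacity=n + 2)
        pairs = []
        x = rng.standard_normal(n)
        for _ in range(n):
            s = rng.standard_normal(n) * 0.1
            y = h_mat @ s
            mem.push(s.reshape(1, n), y.reshape(1, n))
            pairs.append((s, y))
        gvec = h_mat @ x
        d = g.lbfgs_direction(gvec.reshape(1, n), mem).ravel()
        # dense BFGS inverse-Hessian built with the same initial scaling
        s_last, y_last = pairs[-1]
        h_inv = np.eye(n) * (s_last @ y_last) / (y_last @ y_last)
        for s, y in pairs:
            rho = 1.0 / (y @ s)
            v = np.eye(n) - rho * np.outer(s, y)
            h_inv = v @ h_inv @ v.T + rho * np.outer(s, s)
        np.testing.assert_allclose(d, -(h_inv @ gvec), rtol=1e-8)

    def test_curvature_guard_rejects_negative_pairs(self, rng):
        mem = LBFGSMemory(5)
        s = rng.standard_normal((3, 3))
        assert not mem.push(s, -s)
        assert len(mem) == 0


class TestPnPLBFGS:
    def test_consistent_data_high_accuracy_identity_denoiser(self, study32, consistent_problem):
        phantom, phi = consistent_problem
        loss0 = 0.5 * float(np.sum(phi.phi**2))
        config = g.ReconConfig(k_max=15, epsilon_n=1e-9 * loss0, max_outer=100)
        res = g.pnp_lbfgs(phi, study32.kb_op, None, config)
        assert res.loss_trace[-1] / loss0 < 1e-8
        assert g.psnr(res.delta_reg, phantom.delta) > 50.0

    def test_trace_length_and_memory_structure(self, study32, consistent_problem):
        """Algorithm fidelity: each outer iteration contributes exactly
        k_max inner losses and restarts from an empty memory."""
        _, phi = consistent_problem
        config = g.ReconConfig(k_max=15, epsilon_n=0.0, max_outer=4)
        res = g.pnp_lbfgs(phi, study32.kb_op, None, config)
        assert res.outer_starts == [0, 15, 30, 45]
        assert len(res.loss_trace) == 4 * 15
        # memory reset at outer start: the first update of each outer block
        # is steepest descent, so the one-step loss drop ratio matches a
        # fresh start rather than continuing superlinear progress
        assert res.outer_count == 4

    def test_infinite_epsilon_returns_after_one_outer(self, study32, consistent_problem):
        _, phi = consistent_problem
        config = g.ReconConfig(k_max=5, epsilon_n=np.inf, max_outer=10)
        res = g.pnp_lbfgs(phi, study32.kb_op, lambda x: x * 1.0, config)
        assert res.outer_count == 0
        assert res.converged

    def test_deterministic(self, study32, consistent_problem):
        _, phi = consistent_problem
        config = g.ReconConfig(k_max=10, epsilon_n=0.0, max_outer=3)
        r1 = g.pnp_lbfgs(phi, study32.kb_op, None, config)
        r2 = g.pnp_lbfgs(phi, study32.kb_op, None, config)
        assert r1.loss_trace == r2.loss_trace

    def test_error_contraction_persists_through_late_iterations(self, study32, consistent_problem):
        """Noise-free convergence: the iterates keep strictly contracting
        toward the solver's limit point even in the late iterations of the
        inner quasi-Newton loop."""
        _, phi = consistent_problem
        config = g.ReconConfig(k_max=60, epsilon_n=0.0, max_outer=1)
        from gipct.recon import LBFGSMemory as Mem, _armijo, lbfgs_direction as direc_fn

        iterates = []
        delta = np.zeros((32, 32))
        mem = Mem(capacity=60)
        prev = None
        for k in range(60):
            loss, grad = g.data_fidelity_and_grad(delta, phi, study32.kb_op)
            if prev is not None:
                mem.push(delta - prev[0], grad - prev[1])
            d = direc_fn(grad, mem)
            prev = (delta, grad)
            _, delta, _ = _armijo(delta, d, loss, grad, phi, study32.kb_op, config)
            iterates.append(delta)
        ref = iterates[-1]  # converged limit of the data-term minimization
        errs = [np.linalg.norm(it - ref) for it in iterates[:45]]
        ratios = [errs[i + 1] / errs[i] for i in range(len(errs) - 1)]
        # strict contraction persists through the late iterations; the
        # early iterations contract fastest (dominant modes first), so a
        # monotone *decrease* of the ratio is not exhibited on this
        # ill-conditioned quadratic
        assert all(r < 1.0 for r in ratios[-5:])
        assert np.mean(ratios) < 0.95

    def test_bounded_iterates_with_nonexpansive_denoiser(self, study32, consistent_problem):
        _, phi = consistent_problem
        shrink = lambda x: 0.99 * x
        config = g.ReconConfig(k_max=5, epsilon_n=0.0, max_outer=100)
        res = g.pnp_lbfgs(phi, study32.kb_op, shrink, config)
        assert np.abs(res.delta_reg).max() < 1e3


class TestPnPGD:
    def test_lbfgs_needs_fewer_updates_than_gd(self, study32, consistent_problem):
        _, phi = consistent_problem
        loss0 = 0.5 * float(np.sum(phi.phi**2))
        threshold = 1e-6 * loss0
        config = g.ReconConfig(k_max=15, epsilon_n=threshold, max_outer=100)
        res_l = g.pnp_lbfgs(phi, study32.kb_op, None, config)
        res_g = g.pnp_gd(phi, study32.kb_op, None, config)

        def updates_to(trace):
            for i, l in enumerate(trace):
                if l < threshold:
                    return i
            return len(trace) + 1

        assert updates_to(res_l.loss_trace) < updates_to(res_g.loss_trace)

    def test_zero_gradient_start_stops_immediately(self, study32):
        phi = g.DPCSinogram(phi=np.zeros(study32.geometry.sino_shape), geometry=study32.geometry)
        config = g.ReconConfig(k_max=5, epsilon_n=1e-30, max_outer=10)
        res = g.pnp_gd(phi, study32.kb_op, None, config)
        assert res.converged and res.outer_count == 0

    def test_monotone_loss_under_backtracking(self, study32, consistent_problem):
        _, phi = consistent_problem
        config = g.ReconConfig(k_max=30, epsilon_n=0.0, max_outer=1)
        res = g.pnp_gd(phi, study32.kb_op, None, config)
        diffs = np.diff(res.loss_trace)
        assert np.all(diffs <= 1e-12)


class TestFBP:
    def test_zero_sinogram_zero_image(self, study32):
        img = g.fbp_hilbert(np.zeros(study32.geometry.sino_shape), study32.geometry)
        np.testing.assert_allclose(img, 0.0, atol=1e-15)

    def test_linearity(self, study32, rng):
        a = rng.standard_normal(study32.geometry.sino_shape)
        b = rng.standard_normal(study32.geometry.sino_shape)
        lhs = g.fbp_hilbert(a + 2 * b, study32.geometry)
        rhs = g.fbp_hilbert(a, study32.geometry) + 2 * g.fbp_hilbert(b, study32.geometry)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10 * np.abs(rhs).max())

    def test_disk_noise_free_reconstruction(self):
        """Self-consistency with the simulator: the noise-free disk comes
        back quantitatively (amplitude within 5%, PSNR above the sharp-edge
        Gibbs floor of ~20 dB at this resolution)."""
        geo = g.parallel_geometry(64, 360, pixel_size=0.1)
        op = g.DPCOperatorPair(geometry=geo, delta_unit=1e-7)
        ph = g.make_disk_phantom((64, 64), 2.0, 1.0, pixel_size=0.1)
        sino = op.forward(ph.delta)
        rec = g.fbp_hilbert(sino, geo, sensitivity=op.effective_sensitivity, window="none", kb=op.kb)
        assert g.psnr(rec, ph.delta) > 20.0
        yy, xx = np.mgrid[0:64, 0:64]
        interior = (xx - 31.5) ** 2 + (yy - 31.5) ** 2 < (1.5 / 0.1) ** 2
        assert rec[interior].mean() == pytest.approx(1.0, abs=0.05)

    def test_fan_rejected(self):
        geo = g.fan_geometry(16, 8)
        with pytest.raises(ValueError):
            g.fbp_hilbert(np.zeros(geo.sino_shape), geo)


class TestTV:
    def test_small_weight_close_to_unregularized(self, study32, consistent_problem):
        phantom, phi = consistent_problem
        config = g.ReconConfig(k_max=10, epsilon_n=0.0, max_outer=2)
        res_tv = g.tv_reconstruct(phi, study32.kb_op, tv_weight=1e-9, n_outer=2, config=config)
        res_un = g.pnp_lbfgs(phi, study32.kb_op, None, config)
        assert np.linalg.norm(res_tv.delta_reg - res_un.delta_reg) / np.linalg.norm(res_un.delta_reg) < 1e-3

    def test_prox_decreases_rof_energy(self, rng):
        """The Chambolle step solves the ROF problem: its output has lower
        ROF energy than the noisy input itself (checked on 8x8)."""
        from skimage.restoration import denoise_tv_chambolle

        x = rng.standard_normal((8, 8)) * 0.3 + 1.0
        w = 0.2

        def rof(u):
            gx = np.diff(u, axis=0)
            gy = np.diff(u, axis=1)
            tv = np.sum(np.sqrt(gx[:, :-1] ** 2 + gy[:-1, :] ** 2))
            return 0.5 * np.sum((u - x) ** 2) + w * tv

        u = denoise_tv_chambolle(x, weight=w)
        assert rof(u) < rof(x)

    def test_tv_result_flatter_than_fbp_on_noisy_piecewise_phantom(self, study32):
        phantom = g.make_breast_phantom((32, 32), 2, seed=5, delta_range=(0, 1))
        ret, _ = g.simulate_study_sinogram(phantom, study32, seed=3, noise=True)
        config = g.ReconConfig(k_max=15, epsilon_n=0.0, max_outer=8)
        import warnings as W

        with W.catch_warnings():
            W.simplefilter("ignore")
            res = g.tv_reconstruct(ret, study32.fd_op, tv_weight=0.1, n_outer=8, config=config)
        fbp = g.fbp_hilbert(ret, study32.geometry, sensitivity=study32.kb_op.effective_sensitivity, kb=study32.kb_op.kb)

        def total_variation(u):
            return np.abs(np.diff(u, axis=0)).sum() + np.abs(np.diff(u, axis=1)).sum()

        assert total_variation(res.delta_reg) < total_variation(fbp)

    def test_nonpositive_weight_rejected(self, study32, consistent_problem):
        _, phi = consistent_problem
        with pytest.raises(ValueError):
            g.tv_reconstruct(phi, study32.kb_op, tv_weight=0.0)


class TestNoiseLevel:
    def _flat_stacks(self, study, n, photons=None, noise=True):
        photons = photons or study.photons
        empty = g.PhantomImage(delta=np.zeros(study.geometry.image_shape))
        flats = []
        for seed in range(n):
            _, flat = g.simulate_phase_stepping(
                empty, study.geometry, flats=g.FlatFieldMaps.constant(
                    study.geometry.sino_shape, photons=photons, visibility=study.visibility),
                photons=photons, seed=900 + seed, noise=noise, operator=study.kb_op,
            )
            flats.append(flat)
        return flats

    def test_noiseless_flats_give_zero(self, study32):
        flats = self._flat_stacks(study32, 3, noise=False)
        assert g.estimate_noise_level(flats, study32.geometry) == pytest.approx(0.0, abs=1e-18)

    def test_inverse_photon_scaling(self, study32):
        lo = g.estimate_noise_level(self._flat_stacks(study32, 60, photons=30000.0), study32.geometry)
        hi = g.estimate_noise_level(self._flat_stacks(study32, 60, photons=60000.0), study32.geometry)
        assert lo / hi == pytest.approx(2.0, rel=0.2)

    def test_matches_ground_truth_loss_oracle(self, study32):
        """The flat-based estimate approximates the data loss at the true
        image (away from wrapped elements)."""
        phantom = g.make_breast_phantom((32, 32), 0, seed=2, delta_range=(0, 0.4))
        ret, phi_true = g.simulate_study_sinogram(phantom, study32, seed=5, noise=True)
        assert np.abs(phi_true).max() < np.pi  # no wraps: loss is pure noise
        oracle = 0.5 * np.sum((study32.kb_op.forward(phantom.delta) - ret.phi) ** 2)
        est = g.estimate_noise_level(self._flat_stacks(study32, 80), study32.geometry)
        assert est == pytest.approx(oracle, rel=0.25)

    def test_single_flat_requires_fallback(self, study32):
        flats = self._flat_stacks(study32, 1)
        with pytest.raises(ValueError):
            g.estimate_noise_level(flats[0], study32.geometry)
        with pytest.warns(UserWarning):
            val = g.estimate_noise_level(flats[0], study32.geometry, fallback=2.5)
        assert val == 2.5
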