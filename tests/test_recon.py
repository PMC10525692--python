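"""PGD Net: gradient step, proximal net, deep-equilibrium run, training contract."""

import numpy as np
import pytest

from jrsr.kspace import adjoint_AH, forward_A
from jrsr.nn import Parameter, Tensor, node_count, reset_node_count
from jrsr.recon import (
    DivergenceError,
    PgdConfig,
    ProxNet,
    grad_step,
    pgd_run,
    pgd_train_step,
)
from jrsr.synth import make_coil_maps, make_phantom, gaussian_1d_mask, lines_to_mask
from jrsr.util import from_planes, to_planes

from conftest import dense_forward_matrix


def _conditioned_instance(h=32, w=32, ncoils=4, seed=9):
    """Uniform 2x line mask + rough random coil maps: the positive spectrum
    of A^H A is bounded well away from zero, so plain gradient descent
    actually attains its least-squares limit within a few hundred steps."""
    rng = np.random.default_rng(seed)
    maps = rng.normal(size=(ncoils, h, w)) + 1j * rng.normal(size=(ncoils, h, w))
    maps /= np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))[None]
    mask = np.zeros((h, w))
    mask[:, ::2] = 1.0
    x = make_phantom(h, w, seed=seed)
    b = forward_A(x, maps, mask)
    return x, maps, mask, b


def _instance(h=8, w=8, ncoils=2, seed=0, full_mask=False, us=2.0):
    rng = np.random.default_rng(seed)
    x = make_phantom(max(h, 16), max(w, 16), seed=seed)[:h, :w]
    maps = make_coil_maps(h, w, ncoils, seed=seed)
    if full_mask:
        mask = np.ones((h, w))
    else:
        mask = lines_to_mask(gaussian_1d_mask(w, us, n_acs=2, seed=seed), h)
    b = forward_A(x, maps, mask)
    return x, maps, mask, b, rng


class TestGradStep:
    def test_zero_eta_is_identity(self):
        x, maps, mask, b, _ = _instance()
        assert np.array_equal(grad_step(x, b, maps, mask, 0.0), x)

    def test_noiseless_truth_is_fixed_point(self):
        x, maps, mask, b, _ = _instance()
        out = grad_step(x, b, maps, mask, 0.7)
        assert np.allclose(out, x, atol=1e-12)

    def test_matches_dense_operator(self):
        x, maps, mask, _, rng = _instance(seed=3)
        z = rng.normal(size=x.shape) + 1j * rng.normal(size=x.shape)
        b = forward_A(x, maps, mask)
        A = dense_forward_matrix(maps, mask)
        ref = z.ravel() - 0.5 * (A.conj().T @ (A @ z.ravel() - b.ravel()))
        assert np.allclose(grad_step(z, b, maps, mask, 0.5), ref.reshape(z.shape), atol=1e-8)

    def test_non_finite_eta_rejected(self):
        x, maps, mask, b, _ = _instance()
        with pytest.raises(ValueError):
            grad_step(x, b, maps, mask, np.nan)


class TestProxNet:
    def test_identity_at_initialization(self):
        cfg = PgdConfig(prox_channels=8, prox_blocks=1, growth=4)
        prox = ProxNet(cfg, rng=np.random.default_rng(0))
        s = np.random.default_rng(1).normal(size=(1, 2, 8, 8))
        out = prox(Tensor(s)).data
        assert np.array_equal(out, s)  # zero-initialized output conv

    def test_deterministic(self):
        cfg = PgdConfig(prox_channels=8, prox_blocks=1, growth=4)
        prox = ProxNet(cfg, rng=np.random.default_rng(5))
        # perturb away from the identity so the trunk actually acts
        prox.conv_out.weight.data += 0.01
        s = np.random.default_rng(2).normal(size=(1, 2, 8, 8))
        assert np.array_equal(prox(Tensor(s)).data, prox(Tensor(s)).data)

    def test_lipschitz_smoke_bound(self):
        cfg = PgdConfig(prox_channels=8, prox_blocks=1, growth=4)
        prox = ProxNet(cfg, rng=np.random.default_rng(3))
        prox.conv_out.weight.data += 0.01
        rng = np.random.default_rng(4)
        s = rng.normal(size=(1, 2, 16, 16))
        base = prox(Tensor(s)).data
        for _ in range(5):
            eps = rng.normal(size=s.shape) * 1e-3
            out = prox(Tensor(s + eps)).data
            ratio = np.linalg.norm(out - base) / np.linalg.norm(eps)
            assert ratio < 100


class TestPgdRun:
    def test_full_mask_one_iteration_exact(self):
        x, maps, mask, b, _ = _instance(full_mask=True)
        cfg = PgdConfig(eta_init=1.0, max_iter=1, tol=1e-12)
        x0 = adjoint_AH(b, maps, mask)
        x_rec, iters, res = pgd_run(x0, b, maps, mask, cfg, prox=None)
        assert iters == 1
        assert np.allclose(x_rec, x, atol=1e-8)
        assert res < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_mask_recovery_any_phantom(self, seed):
        x, maps, mask, b, _ = _instance(h=16, w=16, seed=seed, full_mask=True)
        cfg = PgdConfig(max_iter=3, tol=1e-12)
        x_rec, _, _ = pgd_run(adjoint_AH(b, maps, mask), b, maps, mask, cfg, None)
        assert np.allclose(x_rec, x, atol=1e-8)

    def test_max_iter_zero_returns_x0(self):
        x, maps, mask, b, _ = _instance()
        cfg = PgdConfig(max_iter=0)
        x0 = adjoint_AH(b, maps, mask)
        out, iters, _ = pgd_run(x0, b, maps, mask, cfg, None)
        assert iters == 0
        assert np.array_equal(out, x0)

    def test_identity_prox_matches_cg_least_squares(self):
        # gradient descent from x0 = A^H b stays in the row space of A, so
        # its limit is the solution CG reaches on the normal equations from
        # the same starting subspace
        from scipy.sparse.linalg import LinearOperator, cg

        x, maps, mask, b = _conditioned_instance()
        h, w = x.shape
        AH_b = adjoint_AH(b, maps, mask)
        op = LinearOperator(
            (h * w, h * w),
            matvec=lambda v: adjoint_AH(
                forward_A(v.reshape(h, w), maps, mask), maps, mask
            ).ravel(),
            dtype=complex,
        )
        ref, info = cg(op, AH_b.ravel(), x0=AH_b.ravel(), rtol=1e-12, maxiter=2000)
        assert info == 0
        cfg = PgdConfig(eta_init=1.0, max_iter=3000, tol=1e-14)
        x_rec, _, _ = pgd_run(AH_b, b, maps, mask, cfg, None)
        assert np.linalg.norm(x_rec.ravel() - ref) / np.linalg.norm(ref) < 1e-4

    def test_monotone_residual_noiseless(self):
        x, maps, mask, b, _ = _instance(h=16, w=16, seed=2)
        cfg = PgdConfig(eta_init=1.0, max_iter=40, tol=1e-14)
        xk = adjoint_AH(b, maps, mask)
        residuals = []
        for _ in range(cfg.max_iter):
            xn = grad_step(xk, b, maps, mask, 1.0)
            residuals.append(np.linalg.norm(xn - xk))
            xk = xn
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))

    def test_exit_residual_below_tol_when_converged(self):
        x, maps, mask, b, _ = _instance(h=16, w=16)
        cfg = PgdConfig(max_iter=2000, tol=1e-4)
        _, iters, res = pgd_run(adjoint_AH(b, maps, mask), b, maps, mask, cfg, None)
        assert iters < cfg.max_iter
        assert res <= cfg.tol

    def test_divergence_guard_raises(self):
        x, maps, mask, b, _ = _instance()
        cfg = PgdConfig(max_iter=50, tol=1e-14)
        with pytest.raises(DivergenceError):
            pgd_run(adjoint_AH(b, maps, mask), b, maps, mask, cfg, None, eta=50.0)


class TestJacobianFreeBackward:
    def _setup(self, max_iter=4):
        x, maps, mask, b, _ = _instance(h=8, w=8, seed=5)
        cfg = PgdConfig(max_iter=max_iter, tol=1e-10, prox_channels=6,
                        prox_blocks=1, growth=4)
        prox = ProxNet(cfg, rng=np.random.default_rng(7))
        prox.conv_out.weight.data += 0.005  # move off the exact identity
        eta = Parameter(np.asarray(0.8))
        x0 = adjoint_AH(b, maps, mask)
        return x0, b, maps, mask, cfg, prox, eta

    def test_eta_gradient_matches_surrogate_finite_difference(self):
        x0, b, maps, mask, cfg, prox, eta = self._setup()
        x_rec_t, _, _ = pgd_train_step(x0, b, maps, mask, cfg, prox, eta)
        loss = x_rec_t.square().mean()
        loss.backward()
        grad = float(eta.grad)

        # independent finite difference of the one-step surrogate at the
        # converged iterate (held fixed)
        from jrsr.recon import pgd_run as run

        x_star, _, _ = run(x0, b, maps, mask,
                           PgdConfig(max_iter=cfg.max_iter - 1, tol=cfg.tol,
                                     prox_channels=6, prox_blocks=1, growth=4),
                           prox, float(eta.data))
        r = adjoint_AH(forward_A(x_star, maps, mask) - b, maps, mask)

        def surrogate(ev):
            s = to_planes(x_star) - ev * to_planes(r)
            return float(prox(Tensor(s)).square().mean().data)

        eps = 1e-5
        fd = (surrogate(float(eta.data) + eps) - surrogate(float(eta.data) - eps)) / (2 * eps)
        assert abs(grad - fd) / max(abs(fd), 1e-12) < 1e-3

    def test_single_iteration_contract_equals_unrolled(self):
        x0, b, maps, mask, cfg, prox, eta = self._setup(max_iter=1)
        x_rec_t, iters, _ = pgd_train_step(x0, b, maps, mask, cfg, prox, eta)
        assert iters == 1
        x_rec_t.square().mean().backward()
        grad_contract = float(eta.grad)

        # fully unrolled single step built explicitly
        eta2 = Parameter(np.asarray(0.8))
        r = adjoint_AH(forward_A(x0, maps, mask) - b, maps, mask)
        s = Tensor(to_planes(x0)) + (-(eta2 * Tensor(to_planes(r))))
        prox(s).square().mean().backward()
        assert np.isclose(grad_contract, float(eta2.grad), rtol=1e-12)

    @pytest.mark.parametrize("max_iter", [2, 8, 32])
    def test_graph_size_independent_of_iteration_count(self, max_iter):
        x0, b, maps, mask, _, prox, eta = self._setup()
        cfg = PgdConfig(max_iter=max_iter, tol=1e-30, prox_channels=6,
                        prox_blocks=1, growth=4)
        reset_node_count()
        pgd_train_step(x0, b, maps, mask, cfg, prox, eta)
        if not hasattr(TestJacobianFreeBackward, "_node_baseline"):
            TestJacobianFreeBackward._node_baseline = node_count()
        assert node_count() == TestJacobianFreeBackward._node_baseline


class TestReconFeature:
    def test_feature_shape_and_purity(self):
        from jrsr.recon import ReconFeatureConv

        conv = ReconFeatureConv(n_features=6, rng=np.random.default_rng(0))
        x = Tensor(to_planes(make_phantom(16, 16, seed=0)))
        f1 = conv(x).data
        f2 = conv(x).data
        assert f1.shape == (1, 6, 16, 16)
        assert np.array_equal(f1, f2)

    def test_distinct_inputs_distinct_features(self):
        from jrsr.recon import ReconFeatureConv

        conv = ReconFeatureConv(n_features=6, rng=np.random.default_rng(0))
        fa = conv(Tensor(to_planes(make_phantom(16, 16, seed=1)))).data
        fb = conv(Tensor(to_planes(make_phantom(16, 16, seed=2)))).data
        assert not np.allclose(fa, fb)
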