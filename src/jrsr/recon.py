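"""Reconstruction module: unrolled proximal gradient descent (PGD Net).

The low-resolution reconstruction problem

    min_x  1/2 || A x - b ||_2^2 + R(x),      A = M F C

is solved by proximal gradient descent

    s_k     = x_k - eta * A^H (A x_k - b)        (data-consistency step)
    x_{k+1} = Gamma(s_k)                         (learned proximal step)

with a trainable scalar step size eta and an RRDB-based proximal network
Gamma operating on the two-real-plane representation.  The iteration is run
as a deep-equilibrium model: it repeats until the relative change of the
iterate falls below a tolerance, and the training gradient is taken
Jacobian-free — through exactly one application of Gamma(grad_step(.))
evaluated at the converged iterate, which is treated as a constant.  Memory
therefore does not grow with the iteration count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import RRDB
from .kspace import adjoint_AH, forward_A
from .nn import Conv2d, Module, Parameter, Tensor, no_grad
from .util import from_planes, to_planes

__all__ = [
    "PgdConfig",
    "ProxNet",
    "ReconFeatureConv",
    "DivergenceError",
    "grad_step",
    "pgd_run",
    "pgd_run_batch",
    "pgd_train_step",
    "pgd_train_batch",
]


class DivergenceError(RuntimeError):
    """Raised when the deep-equilibrium iteration blows up."""


@dataclass
class PgdConfig:
    """PGD Net hyperparameters.

    ``eta_init`` must lie in (0, 1]: with the orthonormal FFT and normalized
    coil maps the encoding satisfies ||A|| <= 1, so any eta <= 1 keeps the
    gradient step non-expansive.  ``tol`` is the relative fixed-point
    tolerance of the deep-equilibrium stopping rule.
    """

    eta_init: float = 1.0
    max_iter: int = 15
    tol: float = 1e-4
    prox_channels: int = 32
    prox_blocks: int = 2
    growth: int = 16
    extra_skips: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.eta_init <= 1):
            raise ValueError("eta_init must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


class ProxNet(Module):
    """RRDB proximal network Gamma on the two-plane representation.

    The output convolution is zero-initialized, so Gamma is the exact
    identity at initialization and training starts from plain gradient
    descent on the data-fidelity term.
    """

    def __init__(self, cfg: PgdConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c = cfg.prox_channels
        self.conv_in = Conv2d(2, c, rng=rng)
        self.blocks = [
            RRDB(c, cfg.growth, extra_skips=cfg.extra_skips, rng=rng)
            for _ in range(cfg.prox_blocks)
        ]
        self.conv_out = Conv2d(c, 2, rng=rng, init="zero")

    def forward(self, s: Tensor) -> Tensor:
        if not np.all(np.isfinite(s.data)):
            raise DivergenceError("non-finite activations entering the proximal net")
        h = self.conv_in(s)
        for blk in self.blocks:
            h = blk(h)
        return s + self.conv_out(h)

    def apply_numpy(self, s: np.ndarray) -> np.ndarray:
        """Inference-mode application on a complex image (no graph)."""
        with no_grad():
            return from_planes(self.forward(Tensor(to_planes(s))).data)


class ReconFeatureConv(Module):
    """Single convolution mapping the reconstructed LR image to the shared
    reconstruction feature broadcast to every SFT layer of the SR module."""

    def __init__(self, n_features: int = 32, rng: np.random.Generator | None = None):
        self.conv = Conv2d(2, n_features, rng=rng or np.random.default_rng(0))

    def forward(self, x_rec: Tensor) -> Tensor:
        return self.conv(x_rec)


def grad_step(
    x: np.ndarray,
    b: np.ndarray,
    maps: np.ndarray,
    mask: np.ndarray,
    eta: float,
) -> np.ndarray:
    """One data-consistency step ``x - eta * A^H (A x - b)``."""
    if not np.isfinite(eta):
        raise ValueError("eta must be finite")
    return x - eta * adjoint_AH(forward_A(x, maps, mask) - b, maps, mask)


def _residual(x_new: np.ndarray, x_old: np.ndarray) -> float:
    return float(
        np.linalg.norm(x_new - x_old) / max(np.linalg.norm(x_old), 1e-12)
    )


def pgd_run(
    x0: np.ndarray,
    b: np.ndarray,
    maps: np.ndarray,
    mask: np.ndarray,
    cfg: PgdConfig,
    prox: ProxNet | None = None,
    eta: float | None = None,
) -> tuple[np.ndarray, int, float]:
    """Deep-equilibrium PGD iteration (inference mode, no graph).

    Repeats ``x <- Gamma(grad_step(x))`` until the relative change drops
    below ``cfg.tol`` or ``cfg.max_iter`` iterations; ``prox=None`` means
    Gamma is the identity.  Returns (x_rec, iterations, final residual).
    Raises :class:`DivergenceError` if the residual grows 10x within five
    iterations.
    """
    eta = cfg.eta_init if eta is None else float(eta)
    x = x0.copy()
    res = np.inf
    history: list[float] = []
    iters = 0
    for iters in range(1, cfg.max_iter + 1):
        s = grad_step(x, b, maps, mask, eta)
        x_new = prox.apply_numpy(s) if prox is not None else s
        res = _residual(x_new, x)
        history.append(res)
        if len(history) >= 6 and history[-1] > 10.0 * history[-6]:
            raise DivergenceError(
                f"fixed-point residual grew 10x over 5 iterations (now {res:.3g})"
            )
        x = x_new
        if res < cfg.tol:
            break
    else:
        iters = cfg.max_iter
    if cfg.max_iter == 0:
        return x0.copy(), 0, np.inf
    return x, iters, res


def _batch_A(X: np.ndarray, maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Encoding applied to a batch of images: (N, H, W) -> (N, C, H, W)."""
    from .kspace import fft2c

    return mask * fft2c(maps[None] * X[:, None])


def _batch_AH(K: np.ndarray, maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    from .kspace import ifft2c

    return np.sum(np.conj(maps)[None] * ifft2c(mask * K), axis=1)


def _as_batch(z: np.ndarray) -> np.ndarray:
    return z[None] if z.ndim == 2 else z


def pgd_run_batch(
    b: np.ndarray,
    maps: np.ndarray,
    mask: np.ndarray,
    cfg: PgdConfig,
    prox: ProxNet | None,
    eta: float,
    max_iter: int | None = None,
) -> tuple[np.ndarray, int, float]:
    """Lockstep deep-equilibrium iteration over a batch (inference mode).

    ``x0 = A^H b`` per slice; stops when the worst per-slice relative change
    drops below ``cfg.tol``.  Returns (batch iterate, iterations, residual).
    """
    b = _as_batch(b)
    budget = cfg.max_iter if max_iter is None else max_iter
    X = _batch_AH(b, maps, mask)
    res, iters = np.inf, 0
    history: list[float] = []
    for iters in range(1, budget + 1):
        S = X - eta * _batch_AH(_batch_A(X, maps, mask) - b, maps, mask)
        if prox is not None:
            with no_grad():
                Xn = _as_batch(from_planes(prox(Tensor(to_planes(S))).data))
        else:
            Xn = S
        res = max(
            _residual(xn, x) for xn, x in zip(Xn, X)
        )
        history.append(res)
        if len(history) >= 6 and history[-1] > 10.0 * history[-6]:
            raise DivergenceError(
                f"fixed-point residual grew 10x over 5 iterations (now {res:.3g})"
            )
        X = Xn
        if res < cfg.tol:
            break
    return X, iters if budget else 0, res


def pgd_train_batch(
    b: np.ndarray,
    maps: np.ndarray,
    mask: np.ndarray,
    cfg: PgdConfig,
    prox: ProxNet,
    eta_param: Parameter,
) -> tuple[Tensor, int, float]:
    """Batched Jacobian-free training forward (see :func:`pgd_train_step`)."""
    b = _as_batch(b)
    eta = float(eta_param.data)
    X_star, iters, _ = pgd_run_batch(
        b, maps, mask, cfg, prox, eta, max_iter=max(cfg.max_iter - 1, 0)
    )
    R = _batch_AH(_batch_A(X_star, maps, mask) - b, maps, mask)
    s = Tensor(to_planes(X_star)) + (-(eta_param * Tensor(to_planes(R))))
    x_rec_t = prox(s)
    res = max(
        _residual(xn, x)
        for xn, x in zip(_as_batch(from_planes(x_rec_t.data)), X_star)
    )
    return x_rec_t, iters + 1, res


def pgd_train_step(
    x0: np.ndarray,
    b: np.ndarray,
    maps: np.ndarray,
    mask: np.ndarray,
    cfg: PgdConfig,
    prox: ProxNet,
    eta_param: Parameter,
) -> tuple[Tensor, int, float]:
    """Forward pass for training with the Jacobian-free backward contract.

    The fixed point is found without building any graph (``max_iter - 1``
    iterations at most), then exactly one application of
    ``Gamma(grad_step(.))`` is evaluated at the converged iterate through
    the autodiff graph, with the iterate held constant.  Gradients reach
    ``eta`` and the proximal-network parameters; activation storage is
    independent of the iteration count.  Returns the graph-connected
    reconstruction (1, 2, H, W planes), iterations used and the residual.
    """
    eta = float(eta_param.data)
    nograd_cfg = PgdConfig(
        eta_init=cfg.eta_init, max_iter=max(cfg.max_iter - 1, 0), tol=cfg.tol,
        prox_channels=cfg.prox_channels, prox_blocks=cfg.prox_blocks,
        growth=cfg.growth, extra_skips=cfg.extra_skips,
    )
    x_star, iters, _ = pgd_run(x0, b, maps, mask, nograd_cfg, prox, eta)
    # one graded application at the (constant) equilibrium:
    #   s = x* - eta * A^H (A x* - b),  x_rec = Gamma(s)
    r = adjoint_AH(forward_A(x_star, maps, mask) - b, maps, mask)
    x_const = Tensor(to_planes(x_star))
    r_const = Tensor(to_planes(r))
    s = x_const + (-(eta_param * r_const))
    x_rec_t = prox(s)
    res = _residual(from_planes(x_rec_t.data), x_star)
    return x_rec_t, iters + 1, res
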