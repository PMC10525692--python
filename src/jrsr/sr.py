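"""Super-resolution module and the joint generator.

The SR trunk follows the ESRGAN lineage: an initial convolution lifts the
two-plane LR image into feature space, a chain of RRDB blocks extracts deep
features under a long (global) residual connection, and a nearest-neighbor
upsampling stage followed by two convolutions recombines the features into
the SR image planes.

What distinguishes this generator from a plain SR network is the coupling
to the reconstruction module: every RRDB carries a spatial feature
transform (SFT) layer whose scale/shift maps are predicted from a single
shared reconstruction feature (one convolution applied to the PGD-Net
output).  The SR trunk is thereby conditioned, pixel by pixel, on the
data-consistent reconstruction rather than merely stacked after it.

Ablation modes of the joint model:

* ``proposed``      - SR input is the zero-filled image; SFT condition is
                      the reconstruction feature (interactive coupling).
* ``sr_only``       - no reconstruction module; the condition is computed
                      from the zero-filled input itself.
* ``recon_only``    - PGD Net alone; the LR reconstruction is returned and
                      lifted to the HR grid by bicubic interpolation at
                      evaluation time (outside the network).
* ``recon_plus_sr`` - sequential coupling: the SR trunk consumes the
                      reconstruction as its input image and self-conditions
                      on it; no interactive SFT path from a separate input.
* ``recon_sr_separate`` - same wiring as ``recon_plus_sr``; the training
                      loop optimizes the two modules in separate phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .blocks import DenseBlock
from .nn import Conv2d, Module, Parameter, Tensor, no_grad, upsample_nearest
from .recon import PgdConfig, ProxNet, ReconFeatureConv, pgd_run_batch, pgd_train_batch
from .util import from_planes, to_planes

__all__ = ["SrConfig", "SftLayer", "RRDBSFT", "UpsampleRecombine", "Generator", "Mode"]

Mode = Literal["proposed", "sr_only", "recon_only", "recon_plus_sr", "recon_sr_separate"]


@dataclass
class SrConfig:
    """SR-trunk hyperparameters.

    The reference configuration uses 23 RRDB-SFT blocks with residual
    scaling 0.2; ``desk`` profiles shrink ``n_blocks``/widths for CPU-scale
    runs.  ``upscale`` is the per-axis SR factor (the inverse of the k-space
    crop scale).
    """

    n_blocks: int = 23
    base_channels: int = 64
    growth: int = 32
    residual_scale: float = 0.2
    upscale: tuple[int, int] = (2, 2)
    cond_channels: int = 32
    extra_skips: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not (0 < self.residual_scale <= 1):
            raise ValueError("residual_scale must be in (0, 1]")


class SftLayer(Module):
    """Spatial feature transform: ``out = scale(cond) * feat + shift(cond)``.

    Scale and shift are produced by two small convolution stacks applied to
    the shared condition feature.  The final layers are zero-initialized
    with the scale head biased at 1, so the transform starts as the exact
    identity.
    """

    def __init__(self, cond_channels: int, channels: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        mid = channels
        self.scale_conv1 = Conv2d(cond_channels, mid, rng=rng)
        self.scale_conv2 = Conv2d(mid, channels, rng=rng, init="zero", bias_value=1.0)
        self.shift_conv1 = Conv2d(cond_channels, mid, rng=rng)
        self.shift_conv2 = Conv2d(mid, channels, rng=rng, init="zero")

    def forward(self, feat: Tensor, cond: Tensor) -> Tensor:
        if feat.data.shape[-2:] != cond.data.shape[-2:]:
            raise ValueError(
                f"spatial mismatch: feature {feat.data.shape} vs condition {cond.data.shape}"
            )
        scale = self.scale_conv2(self.scale_conv1(cond).leaky_relu())
        shift = self.shift_conv2(self.shift_conv1(cond).leaky_relu())
        return scale * feat + shift


class RRDBSFT(Module):
    """SFT modulation followed by three dense blocks under an outer
    residual scaled by ``beta`` (identity when SFT and blocks are
    identities, exactly the input when ``beta`` is zero)."""

    def __init__(self, channels: int, growth: int, cond_channels: int,
                 beta: float = 0.2, extra_skips: bool = True,
                 rng: np.random.Generator | None = None):
        self.beta = beta
        self.sft = SftLayer(cond_channels, channels, rng=rng)
        self.blocks = [
            DenseBlock(channels, growth, beta, extra_skips, rng=rng) for _ in range(3)
        ]

    def forward(self, feat: Tensor, cond: Tensor) -> Tensor:
        h = self.sft(feat, cond)
        for blk in self.blocks:
            h = blk(h)
        return feat + (h - feat) * self.beta


class UpsampleRecombine(Module):
    """Nearest-neighbor upsampling then two convolutions producing the
    output image planes (the convolutions suppress replication artifacts)."""

    def __init__(self, channels: int, upscale: tuple[int, int],
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if upscale[0] < 1 or upscale[1] < 1:
            raise ValueError("upscale factors must be >= 1")
        self.upscale = upscale
        self.conv1 = Conv2d(channels, channels, rng=rng)
        self.conv2 = Conv2d(channels, 2, rng=rng)

    def forward(self, feat: Tensor) -> Tensor:
        h = feat
        if self.upscale != (1, 1):
            h = upsample_nearest(h, *self.upscale)
        return self.conv2(self.conv1(h).leaky_relu())


class Generator(Module):
    """Joint reconstruction + super-resolution generator."""

    def __init__(self, sr_cfg: SrConfig | None = None, pgd_cfg: PgdConfig | None = None,
                 mode: Mode = "proposed", seed: int = 0):
        self.sr_cfg = sr_cfg or SrConfig()
        self.pgd_cfg = pgd_cfg or PgdConfig()
        self.mode: Mode = mode
        rng = np.random.default_rng(seed)
        c = self.sr_cfg.base_channels
        if mode != "sr_only":
            self.prox = ProxNet(self.pgd_cfg, rng=rng)
            self.eta = Parameter(np.asarray(self.pgd_cfg.eta_init))
        if mode != "recon_only":
            self.feat_conv = ReconFeatureConv(self.sr_cfg.cond_channels, rng=rng)
            self.conv_in = Conv2d(2, c, rng=rng)
            self.trunk = [
                RRDBSFT(c, self.sr_cfg.growth, self.sr_cfg.cond_channels,
                        self.sr_cfg.residual_scale, self.sr_cfg.extra_skips, rng=rng)
                for _ in range(self.sr_cfg.n_blocks)
            ]
            self.trunk_conv = Conv2d(c, c, rng=rng)
            self.up = UpsampleRecombine(c, self.sr_cfg.upscale, rng=rng)

    # -- reconstruction -----------------------------------------------------
    def _run_recon(self, b, maps, mask, train: bool) -> tuple[Tensor, int, float]:
        """PGD Net on a batch (lockstep DEQ); x0 = A^H b per slice."""
        b = np.asarray(b)
        if train:
            return pgd_train_batch(b, maps, mask, self.pgd_cfg, self.prox, self.eta)
        x_rec, iters, res = pgd_run_batch(
            b, maps, mask, self.pgd_cfg, self.prox, float(self.eta.data)
        )
        return Tensor(to_planes(x_rec)), iters, res

    def forward(self, x_lr_zf, b, maps, mask, train: bool = False
                ) -> tuple[Tensor | None, Tensor | None]:
        """Returns (x_sr planes, x_rec planes); entries are ``None`` for the
        modes that lack the corresponding branch."""
        if not train:
            with no_grad():
                return self._forward_impl(x_lr_zf, b, maps, mask, train=False)
        return self._forward_impl(x_lr_zf, b, maps, mask, train=True)

    def _forward_impl(self, x_lr_zf, b, maps, mask, train: bool
                      ) -> tuple[Tensor | None, Tensor | None]:
        zf_t = Tensor(to_planes(np.asarray(x_lr_zf)))
        x_rec_t: Tensor | None = None
        if self.mode != "sr_only":
            x_rec_t, _, _ = self._run_recon(b, maps, mask, train)
        if self.mode == "recon_only":
            return None, x_rec_t
        if self.mode == "proposed":
            sr_in, cond_src = zf_t, x_rec_t
        elif self.mode == "sr_only":
            sr_in, cond_src = zf_t, zf_t
        else:  # recon_plus_sr / recon_sr_separate: sequential coupling
            sr_in, cond_src = x_rec_t, x_rec_t
        cond = self.feat_conv(cond_src)
        t0 = self.conv_in(sr_in)
        h = t0
        for blk in self.trunk:
            h = blk(h, cond)
        h = self.trunk_conv(h) + t0
        return self.up(h), x_rec_t

    def reconstruct(self, x_lr_zf, b, maps, mask) -> tuple[np.ndarray | None, np.ndarray | None]:
        """Inference: complex SR image and complex LR reconstruction."""
        x_sr_t, x_rec_t = self.forward(x_lr_zf, b, maps, mask, train=False)
        x_sr = from_planes(x_sr_t.data) if x_sr_t is not None else None
        x_rec = from_planes(x_rec_t.data) if x_rec_t is not None else None
        return x_sr, x_rec
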