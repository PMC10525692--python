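"""Training objective: pixel, perceptual, reconstruction and adversarial terms.

The generator loss is the weighted sum

    L_G = L_Per + gamma_Pix * L_Pix + gamma_Rec * L_Rec + gamma_Adv * L_Adv

with reference weights gamma_Rec = 1, gamma_Pix = 1e-2, gamma_Adv = 5e-3.
L_Pix and L_Rec are mean absolute differences of the SR output against the
HR ground truth and of the LR reconstruction against the un-undersampled
LR ground truth, respectively.  L_Per compares feature maps of a frozen
feature network phi; L_Adv/L_Dis are the non-saturating GAN losses on
discriminator probabilities.

Pretrained perceptual backbones (VGG-19 / AlexNet) are not shipped; the
frozen feature extractor used for the perceptual term and the perceptual
metric is a seeded, randomly initialized convolution stack whose weights
never train.  Random frozen features preserve local-structure sensitivity
and make every run reproducible without downloads; ``phi=None`` selects the
identity map, reducing the perceptual term to a pixel loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Module, Tensor, avg_pool2x

__all__ = [
    "LossWeights",
    "FrozenFeatureNet",
    "Discriminator",
    "magnitude",
    "pixel_loss",
    "perceptual_loss",
    "rec_loss",
    "adversarial_losses",
    "total_generator_loss",
]

_PROB_EPS = 1e-7


@dataclass
class LossWeights:
    gamma_pix: float = 1e-2
    gamma_rec: float = 1.0
    gamma_adv: float = 5e-3
    gamma_per: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gamma_pix, self.gamma_rec, self.gamma_adv, self.gamma_per) < 0:
            raise ValueError("loss weights must be nonnegative")


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def magnitude(planes: Tensor) -> Tensor:
    """|z| from a two-plane (N, 2, H, W) tensor -> (N, 1, H, W)."""
    re = planes.narrow(0, 1)
    im = planes.narrow(1, 1)
    return (re.square() + im.square() + 1e-24).sqrt()


def pixel_loss(x_sr, x_gt) -> Tensor:
    """Mean absolute difference over all elements (and batch)."""
    x_sr, x_gt = _lift(x_sr), _lift(x_gt)
    if x_sr.data.shape != x_gt.data.shape:
        raise ValueError(f"shape mismatch: {x_sr.data.shape} vs {x_gt.data.shape}")
    return (x_sr - x_gt).abs().mean()


def rec_loss(x_rec, x_lr_gt) -> Tensor:
    """Mean absolute difference on the LR grid."""
    return pixel_loss(x_rec, x_lr_gt)


class FrozenFeatureNet(Module):
    """Seeded, frozen random convolution stack; exposes per-stage features.

    Three stages of (conv 3x3, leaky ReLU) with 2x average pooling between
    stages.  Weights are drawn once from the seed and never appear in any
    optimizer; gradients still flow through to the *input* so the perceptual
    term trains the generator.
    """

    def __init__(self, in_channels: int = 1, widths: tuple[int, ...] = (8, 16, 16),
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.convs = []
        c = in_channels
        for w in widths:
            self.convs.append(Conv2d(c, w, rng=rng))
            c = w

    def features(self, x: Tensor) -> list[Tensor]:
        feats = []
        h = x
        for i, conv in enumerate(self.convs):
            h = conv(h).leaky_relu()
            feats.append(h)
            if i < len(self.convs) - 1:
                h = avg_pool2x(h)
        return feats

    def parameters(self):  # frozen: expose no trainable parameters
        return []


def perceptual_loss(x_sr, x_gt, phi: FrozenFeatureNet | None = None) -> Tensor:
    """Mean absolute difference of phi's feature maps (identity phi allowed).

    Inputs are magnitude images shaped (N, 1, H, W) (or anything broadcast-
    free when phi is None).
    """
    x_sr, x_gt = _lift(x_sr), _lift(x_gt)
    if x_sr.data.shape != x_gt.data.shape:
        raise ValueError(f"shape mismatch: {x_sr.data.shape} vs {x_gt.data.shape}")
    if phi is None:
        return pixel_loss(x_sr, x_gt)
    fx = phi.features(x_sr)
    fy = phi.features(x_gt)
    total = (fx[0] - fy[0]).abs().mean()
    for a, b in zip(fx[1:], fy[1:]):
        total = total + (a - b).abs().mean()
    return total * (1.0 / len(fx))


def adversarial_losses(d_fake, d_real) -> tuple[Tensor, Tensor]:
    """Generator and discriminator losses from probabilities in (0, 1).

    ``l_g = -E log D(fake)``;
    ``l_d = -E log(1 - D(fake)) - E log D(real)`` with the fake branch
    detached so discriminator updates do not flow into the generator.
    """
    d_fake, d_real = _lift(d_fake), _lift(d_real)
    df = d_fake.clamp(_PROB_EPS, 1 - _PROB_EPS)
    dr = d_real.clamp(_PROB_EPS, 1 - _PROB_EPS)
    l_g = -(df.log().mean())
    df_det = df.detach().clamp(_PROB_EPS, 1 - _PROB_EPS)
    l_d = -((1.0 - df_det).log().mean()) - dr.log().mean()
    return l_g, l_d


def total_generator_loss(per, pix, rec, adv, w: LossWeights) -> Tensor:
    """``L_Per + gamma_Pix L_Pix + gamma_Rec L_Rec + gamma_Adv L_Adv``."""
    per, pix, rec, adv = _lift(per), _lift(pix), _lift(rec), _lift(adv)
    return (per * w.gamma_per + pix * w.gamma_pix
            + rec * w.gamma_rec + adv * w.gamma_adv)


class Discriminator(Module):
    """VGG-style convolutional discriminator with a scalar-probability head.

    Three (conv, leaky ReLU, 2x pool) stages on the magnitude image, global
    average pooling, a 1x1 convolution and a sigmoid.
    """

    def __init__(self, in_channels: int = 1, widths: tuple[int, ...] = (8, 16, 16),
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.convs = []
        c = in_channels
        for w in widths:
            self.convs.append(Conv2d(c, w, rng=rng))
            c = w
        self.head = Conv2d(c, 1, k=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu()
            if h.data.shape[-2] % 2 == 0 and h.data.shape[-1] % 2 == 0:
                h = avg_pool2x(h)
        h = self.head(h.mean_spatial())
        return h.reshape(h.data.shape[0]).sigmoid()
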