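"""Image-quality metrics: PSNR, SSIM and a learned-perceptual distance.

All metrics act on magnitude images (complex inputs are reduced by modulus
first — the universal MR convention).  MAX defaults to the per-slice
maximum of the ground-truth magnitude.

* PSNR = 10 log10(MAX^2 / MSE), with a +inf sentinel at zero MSE.
* SSIM uses C1 = (0.01 MAX)^2 and C2 = (0.03 MAX)^2.  ``mode="global"``
  evaluates the single-window formula with whole-image statistics;
  ``mode="windowed"`` (the reporting default) averages over 11x11 Gaussian
  windows (sigma 1.5) via scikit-image.
* The perceptual distance follows the LPIPS construction — channel-unit-
  normalized feature maps of a frozen network, squared differences weighted
  per channel, averaged over positions and summed over layers — computed
  here on a seeded frozen random feature stack with unit channel weights
  (no pretrained AlexNet is shipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .losses import FrozenFeatureNet
from .nn import Tensor

__all__ = ["psnr", "ssim", "lpips", "MetricReport", "to_magnitude"]


def to_magnitude(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    return np.abs(x) if np.iscomplexobj(x) else x.astype(float)


def psnr(x: np.ndarray, y: np.ndarray, max_val: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images coincide."""
    x, y = to_magnitude(x), to_magnitude(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    max_val = float(y.max()) if max_val is None else float(max_val)
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / mse))


def ssim(x: np.ndarray, y: np.ndarray, max_val: float | None = None,
         mode: str = "windowed") -> float:
    """Structural similarity; ``mode`` selects global or 11x11-windowed form."""
    x, y = to_magnitude(x), to_magnitude(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    max_val = float(y.max()) if max_val is None else float(max_val)
    c1 = (0.01 * max_val) ** 2
    c2 = (0.03 * max_val) ** 2
    if mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = ((x - mx) * (y - my)).mean()
        return float(
            ((2 * mx * my + c1) * (2 * cxy + c2))
            / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    if mode == "windowed":
        return float(
            structural_similarity(
                x, y, win_size=11, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=max_val,
                K1=0.01, K2=0.03,
            )
        )
    raise ValueError(f"unknown ssim mode {mode!r}")


_DEFAULT_LPIPS_NET: FrozenFeatureNet | None = None


def _default_net() -> FrozenFeatureNet:
    global _DEFAULT_LPIPS_NET
    if _DEFAULT_LPIPS_NET is None:
        _DEFAULT_LPIPS_NET = FrozenFeatureNet(seed=1234)
    return _DEFAULT_LPIPS_NET


def _unit_normalize(f: np.ndarray) -> np.ndarray:
    norm = np.sqrt(np.sum(f**2, axis=1, keepdims=True)) + 1e-10
    return f / norm


def lpips(x: np.ndarray, y: np.ndarray, net: FrozenFeatureNet | None = None,
          weights: list[np.ndarray] | None = None) -> float:
    """Perceptual distance: sum over layers of the position-averaged,
    channel-weighted squared distance between unit-normalized features.

    Inputs are scaled jointly by the ground-truth peak so the network sees
    a fixed range; symmetric in (x, y) for the default unit weights.
    """
    x, y = to_magnitude(x), to_magnitude(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    net = net or _default_net()
    scale = max(float(y.max()), float(x.max()), 1e-12)
    fx = net.features(Tensor((x / scale)[None, None]))
    fy = net.features(Tensor((y / scale)[None, None]))
    total = 0.0
    for layer, (fa, fb) in enumerate(zip(fx, fy)):
        da = _unit_normalize(fa.data)
        db = _unit_normalize(fb.data)
        d2 = (da - db) ** 2  # (1, C, H, W)
        if weights is not None:
            d2 = d2 * np.asarray(weights[layer]).reshape(1, -1, 1, 1)
        total += float(d2.sum(axis=1).mean())
    return total


@dataclass
class MetricReport:
    """Per-slice metric table with mean +/- sd aggregates."""

    psnr_values: list[float]
    ssim_values: list[float]
    lpips_values: list[float]

    @property
    def psnr_mean(self) -> float:
        return float(np.mean(self.psnr_values))

    @property
    def psnr_sd(self) -> float:
        return float(np.std(self.psnr_values))

    @property
    def ssim_mean(self) -> float:
        return float(np.mean(self.ssim_values))

    @property
    def ssim_sd(self) -> float:
        return float(np.std(self.ssim_values))

    @property
    def lpips_mean(self) -> float:
        return float(np.mean(self.lpips_values))

    @property
    def lpips_sd(self) -> float:
        return float(np.std(self.lpips_values))

    def summary(self) -> dict[str, float]:
        return {
            "psnr_mean": self.psnr_mean, "psnr_sd": self.psnr_sd,
            "ssim_mean": self.ssim_mean, "ssim_sd": self.ssim_sd,
            "lpips_mean": self.lpips_mean, "lpips_sd": self.lpips_sd,
        }
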