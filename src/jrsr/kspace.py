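"""Multi-coil Cartesian k-space encoding operators.

The forward model of accelerated super-resolution MRI is

    b = M F C x + delta

where ``x`` is the complex image, ``C`` multiplies by per-coil sensitivity
maps, ``F`` is the centered orthonormal 2D Fourier transform, ``M`` is a
binary undersampling mask and ``delta`` is measurement noise.  Cropping of
the high-frequency k-space block (the super-resolution degradation ``H``)
lives here too, together with its zero-padding adjoint.

Conventions (fixed once, relied on everywhere):

* FFTs are centered (DC at index ``n // 2`` on each axis, 0-based) and
  orthonormal (``norm="ortho"``), so ``F`` is unitary and the composite
  encoding ``A = M F C`` has operator norm <= 1 for sum-of-squares
  normalized maps.  This makes a gradient step size eta <= 1 stable.
* The centered crop window on an axis of length ``n`` down to ``m`` is
  ``[n//2 - m//2, n//2 + (m - m//2))``.
* Coil maps are sum-of-squares normalized inside their support
  (``sum_c |c_i|^2 = 1``), so ``C^H C`` is the identity there.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fft2c",
    "ifft2c",
    "coil_expand",
    "coil_combine",
    "crop_kspace",
    "pad_kspace",
    "apply_mask",
    "forward_A",
    "adjoint_AH",
    "validate_coil_maps",
]


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr.view(float) if np.iscomplexobj(arr) else arr)):
        raise ValueError(f"{name} contains non-finite entries")


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT over the last two axes.

    ``ifft2c`` is its exact inverse and adjoint (the transform is unitary).
    """
    _check_finite(img, "image")
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D inverse FFT over the last two axes."""
    _check_finite(k, "k-space")
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def coil_expand(x: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Apply the coil operator ``C``: image (H, W) -> coil images (C, H, W)."""
    x = np.asarray(x)
    maps = np.asarray(maps)
    if maps.ndim != 3 or x.shape != maps.shape[1:]:
        raise ValueError(
            f"shape mismatch: image {x.shape} vs maps {maps.shape} (want C x H x W)"
        )
    return maps * x[None]


def coil_combine(y: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Apply the adjoint coil operator ``C^H``: sum_c conj(c_i) * y_i."""
    y = np.asarray(y)
    maps = np.asarray(maps)
    if y.shape != maps.shape:
        raise ValueError(f"shape mismatch: coil data {y.shape} vs maps {maps.shape}")
    return np.sum(np.conj(maps) * y, axis=0)


def _crop_slices(shape: tuple[int, int], scale: tuple[int, int]):
    sh, sw = scale
    H, W = shape
    if sh < 1 or sw < 1 or sh != int(sh) or sw != int(sw):
        raise ValueError(f"scales must be positive integers, got {scale}")
    if H % sh or W % sw:
        raise ValueError(f"grid {shape} not divisible by scale {scale}")
    h, w = H // sh, W // sw
    r0 = H // 2 - h // 2
    c0 = W // 2 - w // 2
    return slice(r0, r0 + h), slice(c0, c0 + w)


def crop_kspace(k_hr: np.ndarray, scale: int | tuple[int, int]) -> np.ndarray:
    """Keep the centered low-frequency block, shrinking each axis by ``scale``.

    This is the super-resolution degradation operator ``H``: the high-frequency
    shell of k-space is discarded and the remaining block is interpreted on the
    low-resolution grid.  Raw k-space values are kept (no rescaling); see the
    methods note for the resulting amplitude convention.
    """
    scale = (scale, scale) if np.isscalar(scale) else tuple(scale)
    rs, cs = _crop_slices(k_hr.shape[-2:], scale)  # type: ignore[arg-type]
    return k_hr[..., rs, cs]


def pad_kspace(k_lr: np.ndarray, scale: int | tuple[int, int]) -> np.ndarray:
    """Adjoint of :func:`crop_kspace`: zero-pad back onto the HR grid center."""
    scale = (scale, scale) if np.isscalar(scale) else tuple(scale)
    sh, sw = scale
    h, w = k_lr.shape[-2:]
    H, W = h * sh, w * sw
    out = np.zeros(k_lr.shape[:-2] + (H, W), dtype=k_lr.dtype)
    rs, cs = _crop_slices((H, W), scale)
    out[..., rs, cs] = k_lr
    return out


def apply_mask(k: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Apply the binary undersampling mask ``M`` (idempotent)."""
    if k.shape[-2:] != mask.shape:
        raise ValueError(f"grid mismatch: k-space {k.shape} vs mask {mask.shape}")
    return k * mask


def forward_A(x: np.ndarray, maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The encoding ``A x = M F C x`` on the (LR) acquisition grid."""
    if x.shape != maps.shape[1:] or x.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: image {x.shape}, maps {maps.shape}, mask {mask.shape}"
        )
    return apply_mask(fft2c(coil_expand(x, maps)), mask)


def adjoint_AH(k: np.ndarray, maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The adjoint ``A^H k = C^H F^H M k``."""
    if k.shape != maps.shape or k.shape[-2:] != mask.shape:
        raise ValueError(
            f"grid mismatch: k-space {k.shape}, maps {maps.shape}, mask {mask.shape}"
        )
    return coil_combine(ifft2c(apply_mask(k, mask)), maps)


def validate_coil_maps(maps: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Check sum-of-squares normalization of coil maps inside the support.

    Returns the boolean support (pixels with any nonzero sensitivity).
    Raises ``ValueError`` where the normalization is violated.
    """
    sos = np.sum(np.abs(maps) ** 2, axis=0)
    support = sos > 0
    if not np.allclose(sos[support], 1.0, atol=atol):
        raise ValueError("coil maps are not sum-of-squares normalized on the support")
    return support
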