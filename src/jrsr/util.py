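"""Small shared helpers: complex <-> two-real-plane carriage."""

from __future__ import annotations

import numpy as np

__all__ = ["to_planes", "from_planes"]


def to_planes(x: np.ndarray) -> np.ndarray:
    """Complex (H, W) or (N, H, W) -> real (N, 2, H, W) [real, imag] planes."""
    x = np.asarray(x)
    if x.ndim == 2:
        x = x[None]
    return np.stack([x.real, x.imag], axis=1).astype(np.float64)


def from_planes(t: np.ndarray) -> np.ndarray:
    """Real (N, 2, H, W) planes -> complex (N, H, W) (squeezed if N == 1)."""
    z = t[:, 0] + 1j * t[:, 1]
    return z[0] if z.shape[0] == 1 else z
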