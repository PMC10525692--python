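"""Shared fixtures and independent dense-matrix oracles."""

from __future__ import annotations

import numpy as np
import pytest


def centered_dft_matrix(n: int) -> np.ndarray:
    """Closed-form centered orthonormal 1D DFT matrix.

    D[k, x] = exp(-2*pi*i (k - n//2)(x - n//2) / n) / sqrt(n); independent of
    any FFT routine.
    """
    idx = np.arange(n)
    k = (idx - n // 2)[:, None]
    x = (idx - n // 2)[None, :]
    return np.exp(-2j * np.pi * k * x / n) / np.sqrt(n)


def dense_forward_matrix(maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Explicit dense matrix of the encoding A = M F C (per coil, stacked)."""
    C, H, W = maps.shape
    F2 = np.kron(centered_dft_matrix(H), centered_dft_matrix(W))
    m = np.diag(mask.ravel())
    blocks = [m @ F2 @ np.diag(maps[c].ravel()) for c in range(C)]
    return np.vstack(blocks)


def dense_crop_matrix(H: int, W: int, sh: int, sw: int) -> np.ndarray:
    """Explicit dense matrix of the centered k-space crop."""
    h, w = H // sh, W // sw
    r0, c0 = H // 2 - h // 2, W // 2 - w // 2
    out = np.zeros((h * w, H * W))
    for i in range(h):
        for j in range(w):
            out[i * w + j, (r0 + i) * W + (c0 + j)] = 1.0
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_training_runs():
    """Desk-profile training runs shared by the recovery and mode-comparison
    tests: proposed-mode models for three seeds, plus the held-out test set
    and the zero-filled + bicubic baseline PSNR."""
    from jrsr.metrics import psnr, to_magnitude
    from jrsr.synth import desk_protocol, make_dataset, make_training_pair
    from jrsr.train import baseline_zf_interp, desk_config, evaluate, train

    proto = desk_protocol(seed=0)
    train_data = make_dataset(proto, 24)
    test_data = [make_training_pair(proto, 1000 + i) for i in range(16)]
    baseline = float(np.mean([
        psnr(baseline_zf_interp(p), to_magnitude(p.x_gt)) for p in test_data
    ]))
    proposed = {}
    for seed in (0, 1, 2):
        res = train(desk_config(mode="proposed", seed=seed, steps=500), train_data)
        report, _ = evaluate(res.generator, test_data)
        proposed[seed] = report
    return {
        "train_data": train_data,
        "test_data": test_data,
        "baseline_psnr": baseline,
        "proposed_reports": proposed,
    }


@pytest.fixture
def small_case(rng):
    """Random 3-coil 8x8 image/maps/mask with normalized maps."""
    from jrsr.synth import make_coil_maps

    x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
    maps = make_coil_maps(8, 8, ncoils=3, seed=7)
    mask = (rng.uniform(size=(8, 8)) < 0.6).astype(float)
    mask[3:5, 3:5] = 1.0
    return x, maps, mask
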