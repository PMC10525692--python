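"""Synthetic paired LR/HR multi-coil acquisition.

No public dataset accompanies the reconstruction + super-resolution problem
this package addresses, so training and evaluation pairs are simulated end
to end:

1. a piecewise-smooth ellipse phantom with band-limited texture and a smooth
   phase ramp stands in for the fully sampled HR image;
2. smooth complex Gaussian-lobe coil sensitivities (sum-of-squares
   normalized) provide the coil operator ``C``;
3. the fully sampled HR k-space ``F C x`` is centrally cropped by the SR
   scale factor (only phase-encode-direction cropping accelerates the scan;
   frequency-encode cropping merely shortens the readout);
4. the cropped k-space is undersampled by a 1D Gaussian-density line mask
   (2D brain protocol) or a 2D variable-density Poisson-disc mask (3D
   vessel-wall protocol), and circularly symmetric complex Gaussian noise is
   added.

Both mask generators place exactly ``round(n / us_factor)`` samples so the
acceleration bookkeeping is deterministic: the brain protocol reaches
2 (PE crop) x 2.5 (undersampling) = 5x, the vessel-wall protocol
2 x 2 (PE/SPE crop) x 4 (undersampling) = 16x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .kspace import coil_combine, coil_expand, crop_kspace, fft2c, ifft2c

__all__ = [
    "SamplingProtocol",
    "TrainingPair",
    "make_phantom",
    "make_coil_maps",
    "gaussian_1d_mask",
    "poisson_2d_mask",
    "poisson_candidate_pattern",
    "lines_to_mask",
    "make_mask",
    "simulate_pair",
    "make_training_pair",
    "make_dataset",
    "acceleration_of",
    "brain_protocol",
    "vwi_protocol",
    "desk_protocol",
]

MaskKind = Literal["gaussian1d", "poisson2d", "full"]


@dataclass(frozen=True)
class SamplingProtocol:
    """Acquisition protocol: HR grid, SR crop scales, undersampling scheme.

    ``hr_shape`` is (H, W).  For the 1D Gaussian scheme axis 0 is the
    frequency-encode (FE) axis and axis 1 the phase-encode (PE) axis; for the
    2D Poisson scheme both axes are phase encodes (PE x SPE).  ``acs`` is the
    fully sampled central region: a line count for 1D masks, the side of the
    square calibration block for 2D masks.
    """

    hr_shape: tuple[int, int]
    sr_scale: tuple[int, int] = (2, 2)
    us_factor: float = 1.0
    mask_kind: MaskKind = "full"
    acs: int = 0
    noise_sigma: float = 0.0
    seed: int = 0
    n_coils: int = 4

    def __post_init__(self) -> None:
        H, W = self.hr_shape
        sh, sw = self.sr_scale
        if H % sh or W % sw:
            raise ValueError(f"hr_shape {self.hr_shape} not divisible by {self.sr_scale}")
        if self.us_factor < 1:
            raise ValueError("us_factor must be >= 1")

    @property
    def lr_shape(self) -> tuple[int, int]:
        return self.hr_shape[0] // self.sr_scale[0], self.hr_shape[1] // self.sr_scale[1]

    @property
    def accel_nominal(self) -> float:
        """Product of per-PE-axis reduction factors; FE cropping is free."""
        sh, sw = self.sr_scale
        if self.mask_kind == "poisson2d":
            return sh * sw * self.us_factor
        # 1D scheme: axis 0 is FE (no acceleration), axis 1 is PE.
        return sw * self.us_factor


@dataclass
class TrainingPair:
    """One simulated slice: measurements, operators and ground truths."""

    b: np.ndarray            # undersampled LR k-space, coils x h x w
    mask: np.ndarray         # binary LR-grid mask, h x w
    maps_lr: np.ndarray      # LR coil maps, coils x h x w
    x_lr_zf: np.ndarray      # zero-filled LR image A^H b (network input)
    x_lr_gt: np.ndarray      # coil-combined image of the un-undersampled LR k-space
    x_gt: np.ndarray         # HR ground-truth image
    protocol: SamplingProtocol | None = None


# ---------------------------------------------------------------------------
# phantom and coil maps
# ---------------------------------------------------------------------------

def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    y = (np.arange(h) - h / 2) / (h / 2)
    x = (np.arange(w) - w / 2) / (w / 2)
    return np.meshgrid(y, x, indexing="ij")


def make_phantom(
    h: int,
    w: int,
    n_ellipses: int = 6,
    texture_amp: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Random piecewise-smooth complex phantom with unit peak magnitude.

    Overlapping ellipses of random position/size/orientation/intensity are
    summed, low-amplitude band-limited texture is added inside the support,
    the magnitude is normalized to max 1, and a smooth low-order polynomial
    phase is applied (MR images are complex; coil combination and the
    forward model act on the complex signal).
    """
    if h < 16 or w < 16:
        raise ValueError("phantom grid must be at least 16 x 16")
    if n_ellipses < 1:
        raise ValueError("n_ellipses must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = _grid(h, w)
    mag = np.zeros((h, w))
    for i in range(n_ellipses):
        # first ellipse is a large head-like support, later ones internal detail
        if i == 0:
            cy, cx = rng.uniform(-0.1, 0.1, size=2)
            ay, ax = rng.uniform(0.55, 0.8, size=2)
            amp = 1.0
        else:
            cy, cx = rng.uniform(-0.45, 0.45, size=2)
            ay, ax = rng.uniform(0.08, 0.35, size=2)
            amp = rng.uniform(-0.5, 0.9)
        th = rng.uniform(0, np.pi)
        yr = (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
        xr = -(yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
        inside = (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0
        mag = mag + amp * inside
    mag = np.clip(mag, 0.0, None)
    support = mag > 0
    if texture_amp > 0:
        noise_k = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
        fy = np.fft.fftshift(np.fft.fftfreq(h))
        fx = np.fft.fftshift(np.fft.fftfreq(w))
        fyy, fxx = np.meshgrid(fy, fx, indexing="ij")
        lowpass = np.exp(-((fyy**2 + fxx**2) / (2 * 0.08**2)))
        texture = np.fft.ifft2(np.fft.ifftshift(noise_k * lowpass)).real
        texture = texture / (np.abs(texture).max() + 1e-12)
        mag = mag + texture_amp * texture * support
        mag = np.clip(mag, 0.0, None)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    # smooth spatial phase: linear ramp plus a gentle quadratic term
    a, b, c = rng.uniform(-np.pi / 4, np.pi / 4, size=3)
    q = rng.uniform(-np.pi / 8, np.pi / 8)
    phase = a * yy + b * xx + c + q * (yy**2 - xx**2)
    return (mag * np.exp(1j * phase)).astype(np.complex128)


def _coil_params(ncoils: int, seed: int) -> dict[str, np.ndarray]:
    # draw a grid-size-independent parameter set so maps can be evaluated
    # consistently at any resolution
    rng = np.random.default_rng(seed)
    ang = 2 * np.pi * np.arange(ncoils) / ncoils + rng.uniform(0, 2 * np.pi)
    return {
        "cy": 1.15 * np.sin(ang) + rng.uniform(-0.05, 0.05, ncoils),
        "cx": 1.15 * np.cos(ang) + rng.uniform(-0.05, 0.05, ncoils),
        "sigma": rng.uniform(0.7, 0.9, ncoils),
        "phase0": rng.uniform(0, 2 * np.pi, ncoils),
        "phase_gy": rng.uniform(-0.5, 0.5, ncoils),
        "phase_gx": rng.uniform(-0.5, 0.5, ncoils),
    }


def _coil_profile(params: dict[str, np.ndarray], h: int, w: int) -> np.ndarray:
    yy, xx = _grid(h, w)
    ncoils = len(params["cy"])
    maps = np.empty((ncoils, h, w), dtype=np.complex128)
    for c in range(ncoils):
        r2 = (yy - params["cy"][c]) ** 2 + (xx - params["cx"][c]) ** 2
        amp = np.exp(-r2 / (2 * params["sigma"][c] ** 2))
        ph = params["phase0"][c] + params["phase_gy"][c] * yy + params["phase_gx"][c] * xx
        maps[c] = amp * np.exp(1j * ph)
    return maps


def make_coil_maps(h: int, w: int, ncoils: int = 4, seed: int = 0) -> np.ndarray:
    """Smooth Gaussian-lobe coil sensitivities, sum-of-squares normalized.

    The underlying analytic profile depends only on ``(ncoils, seed)``, so
    evaluating at a lower resolution yields maps consistent with the HR ones.
    The lobes are strictly positive everywhere, hence the support is the full
    grid and ``C^H C = I`` holds at every pixel.
    """
    if ncoils < 1:
        raise ValueError("ncoils must be >= 1")
    maps = _coil_profile(_coil_params(ncoils, seed), h, w)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / sos[None]


# ---------------------------------------------------------------------------
# undersampling masks
# ---------------------------------------------------------------------------

def gaussian_1d_mask(n_pe: int, us_factor: float, n_acs: int = 12, seed: int = 0) -> np.ndarray:
    """1D Gaussian-density phase-encode line mask with exact line count.

    Exactly ``round(n_pe / us_factor)`` lines are selected: the ``n_acs``
    central auto-calibration lines always, the rest drawn without replacement
    with probability proportional to a Gaussian density (sigma = n_pe / 6)
    centered at DC.  Returns a 1D {0,1} array over PE lines.
    """
    if us_factor < 1:
        raise ValueError("us_factor must be >= 1")
    target = int(round(n_pe / us_factor))
    if n_acs > target:
        raise ValueError(f"n_acs={n_acs} exceeds the sampled-line budget {target}")
    mask = np.zeros(n_pe)
    center = n_pe // 2
    acs_lo = center - n_acs // 2
    mask[acs_lo : acs_lo + n_acs] = 1
    remaining = target - n_acs
    if remaining > 0:
        rng = np.random.default_rng(seed)
        idx = np.arange(n_pe)
        free = idx[mask == 0]
        sigma = n_pe / 6.0
        p = np.exp(-((free - center) ** 2) / (2 * sigma**2))
        p = p / p.sum()
        chosen = rng.choice(free, size=remaining, replace=False, p=p)
        mask[chosen] = 1
    return mask


def poisson_candidate_pattern(
    h: int, w: int, r_center: float, r_edge: float, seed: int = 0
) -> np.ndarray:
    """Variable-density Poisson-disc dart throwing on the integer grid.

    The exclusion radius grows linearly with normalized distance from the
    k-space center, from ``r_center`` at DC to ``r_edge`` at the corners.
    Every accepted point respects the radius evaluated at its own location.
    """
    rng = np.random.default_rng(seed)
    yy, xx = _grid(h, w)
    dist = np.sqrt(yy**2 + xx**2) / np.sqrt(2)
    radius2 = (r_center + (r_edge - r_center) * dist) ** 2
    order = rng.permutation(h * w)
    rm = int(np.ceil(r_edge))
    # padded occupancy grid; candidates inspect only their local window
    occ = np.zeros((h + 2 * rm, w + 2 * rm), dtype=bool)
    dy, dx = np.mgrid[-rm : rm + 1, -rm : rm + 1]
    d2 = (dy * dy + dx * dx).astype(float)
    for flat in order:
        i, j = divmod(int(flat), w)
        window = occ[i : i + 2 * rm + 1, j : j + 2 * rm + 1]
        if np.any(window & (d2 < radius2[i, j])):
            continue
        occ[i + rm, j + rm] = True
    return occ[rm : rm + h, rm : rm + w].astype(float)


def poisson_2d_mask(h: int, w: int, us_factor: float, calib: int = 16, seed: int = 0) -> np.ndarray:
    """2D variable-density Poisson-disc mask with an exact sample count.

    A dart-throwing candidate pattern is adjusted by randomly adding/removing
    points outside the fully sampled ``calib x calib`` central block until
    exactly ``round(h * w / us_factor)`` locations are sampled.
    """
    if us_factor < 1:
        raise ValueError("us_factor must be >= 1")
    target = int(round(h * w / us_factor))
    if calib * calib > target:
        raise ValueError(f"calibration block {calib}^2 exceeds sample budget {target}")
    rng = np.random.default_rng(seed)
    r0 = np.sqrt(us_factor)
    mask = poisson_candidate_pattern(h, w, 0.55 * r0, 1.55 * r0, seed=seed)
    # fully sampled central calibration block
    r0y = h // 2 - calib // 2
    c0x = w // 2 - calib // 2
    calib_sel = np.zeros((h, w), dtype=bool)
    calib_sel[r0y : r0y + calib, c0x : c0x + calib] = True
    mask[calib_sel] = 1
    count = int(mask.sum())
    flat = mask.ravel()
    movable = ~calib_sel.ravel()
    if count > target:
        on = np.flatnonzero((flat == 1) & movable)
        off_idx = rng.choice(on, size=count - target, replace=False)
        flat[off_idx] = 0
    elif count < target:
        off = np.flatnonzero((flat == 0) & movable)
        on_idx = rng.choice(off, size=target - count, replace=False)
        flat[on_idx] = 1
    return flat.reshape(h, w)


def lines_to_mask(lines: np.ndarray, n_fe: int) -> np.ndarray:
    """Broadcast a 1D PE-line mask to a 2D grid, constant along the FE axis."""
    return np.broadcast_to(lines[None, :], (n_fe, lines.shape[0])).copy()


def make_mask(protocol: SamplingProtocol) -> np.ndarray:
    """The LR-grid binary mask prescribed by a protocol."""
    h, w = protocol.lr_shape
    if protocol.mask_kind == "full":
        return np.ones((h, w))
    if protocol.mask_kind == "gaussian1d":
        lines = gaussian_1d_mask(w, protocol.us_factor, protocol.acs, protocol.seed)
        return lines_to_mask(lines, h)
    if protocol.mask_kind == "poisson2d":
        return poisson_2d_mask(h, w, protocol.us_factor, protocol.acs, protocol.seed)
    raise ValueError(f"unknown mask kind {protocol.mask_kind!r}")


def acceleration_of(protocol: SamplingProtocol, mask: np.ndarray) -> tuple[float, float]:
    """(nominal, measured) acceleration of a protocol/mask combination.

    Nominal multiplies the per-PE-axis crop factors by the undersampling
    factor (FE cropping contributes no acceleration).  Measured divides the
    HR phase-encode grid size by the number of actually sampled PE points
    (lines for 1D masks, PE x SPE locations for 2D masks).
    """
    sh, sw = protocol.sr_scale
    nominal = protocol.accel_nominal
    if protocol.mask_kind == "poisson2d":
        hr_points = protocol.hr_shape[0] * protocol.hr_shape[1]
        sampled = float(mask.sum())
    else:
        hr_points = protocol.hr_shape[1]
        sampled = float((mask[0] if mask.ndim == 2 else mask).sum())
    measured = hr_points / sampled if sampled else np.inf
    return float(nominal), float(measured)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def simulate_pair(
    x_hr: np.ndarray,
    maps_hr: np.ndarray,
    maps_lr: np.ndarray,
    protocol: SamplingProtocol,
    mask: np.ndarray | None = None,
    noise_seed: int | None = None,
) -> TrainingPair:
    """Crop + undersample a fully sampled HR slice into a training pair.

    ``k_hr = F C x``; the centered crop keeps raw k-space values; the mask
    and circular complex Gaussian noise (sigma = ``protocol.noise_sigma``)
    produce the measurements ``b``.  ``x_lr_gt`` coil-combines the
    un-undersampled cropped k-space; ``x_lr_zf`` is the zero-filled adjoint.
    """
    if x_hr.shape != protocol.hr_shape or maps_hr.shape[1:] != x_hr.shape:
        raise ValueError("HR image/maps inconsistent with protocol grid")
    if maps_lr.shape[1:] != protocol.lr_shape:
        raise ValueError("LR maps inconsistent with protocol grid")
    if mask is None:
        mask = make_mask(protocol)
    if mask.shape != protocol.lr_shape:
        raise ValueError("mask inconsistent with protocol LR grid")
    k_hr = fft2c(coil_expand(x_hr, maps_hr))
    k_lr = crop_kspace(k_hr, protocol.sr_scale)
    b = k_lr * mask
    if protocol.noise_sigma > 0:
        rng = np.random.default_rng(protocol.seed if noise_seed is None else noise_seed)
        s = protocol.noise_sigma / np.sqrt(2)
        noise = rng.normal(0, s, b.shape) + 1j * rng.normal(0, s, b.shape)
        b = b + noise * mask
    x_lr_gt = coil_combine(ifft2c(k_lr), maps_lr)
    x_lr_zf = coil_combine(ifft2c(b), maps_lr)
    return TrainingPair(
        b=b, mask=mask, maps_lr=maps_lr, x_lr_zf=x_lr_zf, x_lr_gt=x_lr_gt,
        x_gt=x_hr, protocol=protocol,
    )


def make_training_pair(protocol: SamplingProtocol, slice_seed: int) -> TrainingPair:
    """Phantom + coil maps + simulation for one slice, fully seeded."""
    H, W = protocol.hr_shape
    ss = np.random.SeedSequence([protocol.seed, slice_seed])
    phantom_seed, noise_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    x_hr = make_phantom(H, W, seed=phantom_seed)
    maps_hr = make_coil_maps(H, W, protocol.n_coils, seed=protocol.seed)
    maps_lr = make_coil_maps(*protocol.lr_shape, protocol.n_coils, seed=protocol.seed)
    return simulate_pair(x_hr, maps_hr, maps_lr, protocol, noise_seed=noise_seed)


def make_dataset(protocol: SamplingProtocol, n_slices: int) -> list[TrainingPair]:
    """A list of independent slices under one protocol (shared mask/maps)."""
    return [make_training_pair(protocol, i) for i in range(n_slices)]


# ---------------------------------------------------------------------------
# protocol presets
# ---------------------------------------------------------------------------

def brain_protocol(seed: int = 0, noise_sigma: float = 0.0, n_coils: int = 12) -> SamplingProtocol:
    """2D brain protocol: 256x232 HR (FE x PE), 2x crop, 2.5x 1D Gaussian -> 5x."""
    return SamplingProtocol(
        hr_shape=(256, 232), sr_scale=(2, 2), us_factor=2.5,
        mask_kind="gaussian1d", acs=12, noise_sigma=noise_sigma,
        seed=seed, n_coils=n_coils,
    )


def vwi_protocol(seed: int = 0, noise_sigma: float = 0.0, n_coils: int = 18) -> SamplingProtocol:
    """3D vessel-wall protocol: 336x280 PE grid, 2x2 crop, 4x Poisson -> 16x."""
    return SamplingProtocol(
        hr_shape=(336, 280), sr_scale=(2, 2), us_factor=4.0,
        mask_kind="poisson2d", acs=16, noise_sigma=noise_sigma,
        seed=seed, n_coils=n_coils,
    )


def desk_protocol(seed: int = 0, noise_sigma: float = 0.01, n_coils: int = 4) -> SamplingProtocol:
    """Small-grid profile for CPU-scale experiments: 64x64 HR, 2x crop, 2x Gaussian."""
    return SamplingProtocol(
        hr_shape=(64, 64), sr_scale=(2, 2), us_factor=2.0,
        mask_kind="gaussian1d", acs=6, noise_sigma=noise_sigma,
        seed=seed, n_coils=n_coils,
    )
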