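"""Training loop, evaluation harness, baseline and checkpointing.

Training alternates generator and (when the adversarial weight is active)
discriminator Adam updates 1:1, with the step-decay learning-rate schedule
(halved after each milestone).  Two profiles are provided:

* ``paper``: the reference hyperparameters — Adam(0.9, 0.999, 1e-8),
  lr 1e-4 halved after 50k/100k/200k/300k steps, batch 4, 23 RRDB-SFT
  blocks, weights gamma_Rec 1, gamma_Pix 1e-2, gamma_Adv 5e-3.
* ``desk``: a single-CPU profile (2 RRDB-SFT blocks, 2 PGD iterations,
  16-channel trunk, batch 2, lr 1e-3, adversarial weight 0, fidelity-
  weighted losses) sized for runs of a few hundred steps.

Everything is seeded; identical seeds give identical checkpoints and
evaluation tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from .losses import (
    Discriminator,
    FrozenFeatureNet,
    LossWeights,
    adversarial_losses,
    magnitude,
    perceptual_loss,
    pixel_loss,
    rec_loss,
    total_generator_loss,
)
from .metrics import MetricReport, lpips, psnr, ssim, to_magnitude
from .nn import Adam, Tensor, lr_at_step
from .recon import DivergenceError, PgdConfig
from .sr import Generator, Mode, SrConfig
from .synth import TrainingPair
from .util import to_planes

__all__ = [
    "TrainConfig",
    "TrainResult",
    "desk_config",
    "paper_config",
    "train",
    "evaluate",
    "baseline_zf_interp",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    mode: Mode = "proposed"
    lr: float = 1e-4
    lr_halve_at: list[int] = field(default_factory=lambda: [50_000, 100_000, 200_000, 300_000])
    batch: int = 4
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    steps: int = 1000
    adv_warmup: int = 0          # pixel-only steps before the GAN terms engage
    checkpoint_every: int = 0    # 0: only at the end
    sr: SrConfig = field(default_factory=SrConfig)
    pgd: PgdConfig = field(default_factory=PgdConfig)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


def paper_config(mode: Mode = "proposed", seed: int = 0, steps: int = 400_000) -> TrainConfig:
    """Reference-scale configuration (not runnable on a desk CPU)."""
    return TrainConfig(mode=mode, seed=seed, steps=steps)


def desk_config(mode: Mode = "proposed", seed: int = 0, steps: int = 500) -> TrainConfig:
    """CPU-scale profile: small trunk, fidelity-weighted losses, no GAN."""
    return TrainConfig(
        mode=mode,
        lr=3e-3,
        batch=2,
        weights=LossWeights(gamma_pix=1.0, gamma_rec=1.0, gamma_adv=0.0, gamma_per=0.1),
        seed=seed,
        steps=steps,
        sr=SrConfig(n_blocks=2, base_channels=12, growth=6, cond_channels=12),
        pgd=PgdConfig(max_iter=2, prox_channels=12, prox_blocks=1, growth=6),
    )


@dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator | None
    config: TrainConfig
    log: list[dict]

    @property
    def final_loss(self) -> float:
        return self.log[-1]["loss"] if self.log else float("nan")


def _stack_batch(pairs: list[TrainingPair]):
    x_zf = np.stack([p.x_lr_zf for p in pairs])
    b = np.stack([p.b for p in pairs])
    gt = np.stack([p.x_gt for p in pairs])
    lr_gt = np.stack([p.x_lr_gt for p in pairs])
    return x_zf, b, gt, lr_gt


def train(cfg: TrainConfig, data: list[TrainingPair]) -> TrainResult:
    """Optimize a generator (and optionally a discriminator) on paired data.

    All pairs must share coil maps and mask (one protocol).  A non-finite
    loss aborts with :class:`DivergenceError`, with the generator restored
    to the last finite-loss state.
    """
    if not data:
        raise ValueError("empty dataset")
    maps, mask = data[0].maps_lr, data[0].mask
    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg.sr, cfg.pgd, mode=cfg.mode, seed=cfg.seed)
    use_adv = cfg.weights.gamma_adv > 0 and cfg.mode != "recon_only"
    disc = Discriminator(seed=cfg.seed + 1) if use_adv else None
    d_opt = Adam(disc.parameters(), lr=cfg.lr) if disc else None
    phi = FrozenFeatureNet(seed=0)

    named = dict(gen.named_parameters())
    if cfg.mode == "recon_sr_separate":
        rec_keys = [k for k in named if k.startswith(("prox", "eta"))]
        sr_keys = [k for k in named if not k.startswith(("prox", "eta"))]
        phases = [
            (cfg.steps // 2, Adam([named[k] for k in rec_keys], lr=cfg.lr), True),
            (cfg.steps - cfg.steps // 2, Adam([named[k] for k in sr_keys], lr=cfg.lr), False),
        ]
    else:
        phases = [(cfg.steps, Adam(gen.parameters(), lr=cfg.lr), cfg.mode == "recon_only")]

    log: list[dict] = []
    last_good = gen.state_dict()
    step = 0
    for phase_steps, g_opt, rec_phase in phases:
        for _ in range(phase_steps):
            step += 1
            lr_now = lr_at_step(cfg.lr, cfg.lr_halve_at, step)
            g_opt.lr = lr_now
            idx = rng.choice(len(data), size=min(cfg.batch, len(data)), replace=False)
            pairs = [data[int(i)] for i in idx]
            x_zf, b, gt, lr_gt = _stack_batch(pairs)
            x_sr_t, x_rec_t = gen.forward(x_zf, b, maps, mask, train=True)

            rec_only = rec_phase or cfg.mode == "recon_only"
            zero = Tensor(np.asarray(0.0))
            if x_rec_t is not None and cfg.mode != "sr_only":
                l_rec = rec_loss(x_rec_t, Tensor(to_planes(lr_gt)))
            else:
                l_rec = zero
            if rec_only or x_sr_t is None:
                l_per = l_pix = l_adv = zero
                loss = l_rec * cfg.weights.gamma_rec
            else:
                gt_planes = Tensor(to_planes(gt))
                l_pix = pixel_loss(x_sr_t, gt_planes)
                l_per = perceptual_loss(magnitude(x_sr_t), magnitude(gt_planes), phi)
                if use_adv and step > cfg.adv_warmup:
                    d_fake = disc(magnitude(x_sr_t))
                    d_real_det = disc(magnitude(gt_planes).detach())
                    l_adv, l_d = adversarial_losses(d_fake, d_real_det)
                else:
                    l_adv, l_d = zero, None
                loss = total_generator_loss(l_per, l_pix, l_rec, l_adv, cfg.weights)

            if not np.isfinite(loss.data):
                gen.load_state_dict(last_good)
                raise DivergenceError(
                    f"non-finite loss at step {step}; last good state restored"
                )
            gen.zero_grad()
            if disc:
                disc.zero_grad()
            loss.backward()
            g_opt.step()

            if use_adv and step > cfg.adv_warmup and l_d is not None:
                # 1:1 discriminator update on a fresh graph
                disc.zero_grad()
                d_fake2 = disc(magnitude(x_sr_t.detach()))
                d_real2 = disc(magnitude(Tensor(to_planes(gt))))
                _, l_d2 = adversarial_losses(d_fake2, d_real2)
                l_d2.backward()
                d_opt.lr = lr_now
                d_opt.step()

            log.append({"step": step, "lr": lr_now, "loss": float(loss.data),
                        "pix": float(l_pix.data), "per": float(l_per.data),
                        "rec": float(l_rec.data), "adv": float(l_adv.data)})
            if cfg.checkpoint_every and step % cfg.checkpoint_every == 0:
                last_good = gen.state_dict()
        last_good = gen.state_dict()
    return TrainResult(generator=gen, discriminator=disc, config=cfg, log=log)


def baseline_zf_interp(pair: TrainingPair, upscale: tuple[int, int] | None = None) -> np.ndarray:
    """Zero-filled + bicubic baseline on the HR grid.

    The magnitude of the zero-filled LR image is bicubically interpolated to
    the HR grid and divided by sqrt(s_h * s_w) to undo the amplitude gain of
    the raw-value k-space crop (see the methods note), making the baseline
    gain-consistent with the HR ground truth.
    """
    if upscale is None:
        upscale = pair.protocol.sr_scale if pair.protocol else (1, 1)
    sh, sw = upscale
    mag = to_magnitude(pair.x_lr_zf)
    if (sh, sw) == (1, 1):
        return mag
    hr_shape = (mag.shape[0] * sh, mag.shape[1] * sw)
    up = resize(mag, hr_shape, order=3, mode="edge", anti_aliasing=False)
    return up / np.sqrt(sh * sw)


def _model_output_hr(gen: Generator, pair: TrainingPair) -> np.ndarray:
    """HR-grid magnitude output of a generator for one slice."""
    x_sr, x_rec = gen.reconstruct(pair.x_lr_zf, pair.b, pair.maps_lr, pair.mask)
    if x_sr is not None:
        return to_magnitude(x_sr)
    # recon_only: lift the LR reconstruction bicubically, undoing the crop gain
    sh, sw = pair.protocol.sr_scale if pair.protocol else (1, 1)
    mag = to_magnitude(x_rec)
    up = resize(mag, (mag.shape[0] * sh, mag.shape[1] * sw), order=3,
                mode="edge", anti_aliasing=False)
    return up / np.sqrt(sh * sw)


def evaluate(gen: Generator, data: list[TrainingPair],
             out_csv: str | None = None) -> tuple[MetricReport, pd.DataFrame]:
    """Deterministic per-slice metrics plus a mean +/- sd summary table."""
    rows = []
    for i, pair in enumerate(data):
        out = _model_output_hr(gen, pair)
        gt = to_magnitude(pair.x_gt)
        max_val = float(gt.max())
        rows.append({
            "slice_id": i,
            "psnr": psnr(out, gt, max_val),
            "ssim": ssim(out, gt, max_val, mode="windowed"),
            "lpips": lpips(out, gt),
        })
    df = pd.DataFrame(rows)
    report = MetricReport(
        psnr_values=df["psnr"].tolist(),
        ssim_values=df["ssim"].tolist(),
        lpips_values=df["lpips"].tolist(),
    )
    summary = pd.DataFrame([
        {"slice_id": "mean", "psnr": report.psnr_mean, "ssim": report.ssim_mean,
         "lpips": report.lpips_mean},
        {"slice_id": "sd", "psnr": report.psnr_sd, "ssim": report.ssim_sd,
         "lpips": report.lpips_sd},
    ])
    table = pd.concat([df, summary], ignore_index=True)
    if out_csv:
        table.to_csv(out_csv, index=False)
    return report, table


# ---------------------------------------------------------------------------
# checkpoints (self-describing: the resolved config travels with the weights)
# ---------------------------------------------------------------------------

def _config_to_yaml(cfg: TrainConfig) -> str:
    d = asdict(cfg)
    return yaml.safe_dump(d)


def _config_from_yaml(text: str) -> TrainConfig:
    d = yaml.safe_load(text)
    d["weights"] = LossWeights(**d["weights"])
    d["sr"] = SrConfig(**{**d["sr"], "upscale": tuple(d["sr"]["upscale"])})
    d["pgd"] = PgdConfig(**d["pgd"])
    return TrainConfig(**d)


def save_checkpoint(path: str, gen: Generator, cfg: TrainConfig) -> None:
    """NPZ checkpoint holding every parameter (eta included) plus the YAML
    config and the iteration settings in force at save time."""
    state = gen.state_dict()
    np.savez(path, __config__=np.array(_config_to_yaml(cfg)), **state)


def load_checkpoint(path: str) -> tuple[Generator, TrainConfig]:
    with np.load(path, allow_pickle=False) as z:
        cfg = _config_from_yaml(str(z["__config__"]))
        state = {k: z[k] for k in z.files if k != "__config__"}
    gen = Generator(cfg.sr, cfg.pgd, mode=cfg.mode, seed=cfg.seed)
    gen.load_state_dict(state)
    return gen, cfg
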