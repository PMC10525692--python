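# jrsr — joint MR image reconstruction and super-resolution

Accelerated MRI acquires less k-space data than Nyquist requires.  Two
complementary shortcuts exist: **undersampling** (skip phase-encode
samples; reconstruction must remove the aliasing) and **low-resolution
acquisition** (omit the high-frequency k-space shell; super-resolution must
restore the detail).  Combining both multiplies the accelerations — e.g. a
2× k-space crop with 2.5× Gaussian line undersampling gives a 5× faster
brain scan, and a 2×2 crop with 4× Poisson-disc undersampling gives 16× for
3D vessel-wall imaging — but the image restoration problem becomes jointly
ill-posed.  `jrsr` implements a multi-task deep network that solves both
problems *interactively* rather than sequentially, for researchers working
on model-based deep MR image restoration.

## Model

The forward model is `b = M F C x + δ`: coil sensitivities `C`, centered
orthonormal Fourier transform `F`, binary undersampling mask `M` (the crop
`H` acts beforehand in the simulator, `P = MH`), and complex Gaussian noise
δ.  The generator has two coupled modules:

* **Rec module (PGD Net).**  The LR reconstruction
  `min_x ½‖Ax − b‖² + R(x)`, `A = MFC`, is solved by unrolled proximal
  gradient descent, `s_k = x_k − η A^H (A x_k − b)`, `x_{k+1} = Γ(s_k)`,
  with a trainable step size η and an RRDB network as the learned proximal
  operator Γ.  The iteration runs as a **deep-equilibrium model**: it stops
  at a relative fixed-point tolerance, and backpropagation is
  **Jacobian-free** — gradients flow through a single application of
  `Γ(grad_step(·))` at the equilibrium, so training memory is independent
  of iteration count.
* **SR module.**  An ESRGAN-style trunk of RRDB blocks (23 at reference
  scale, residual scaling β = 0.2, two extra skip connections per dense
  block) in which every block carries a **spatial feature transform (SFT)**
  layer: scale and shift maps predicted from a shared *reconstruction
  feature* (one convolution of the PGD-Net output) modulate the SR features
  pixel-by-pixel.  Nearest-neighbor upsampling plus two convolutions emit
  the SR image.

Training minimizes
`L_G = L_Per + γ_Pix L_Pix + γ_Rec L_Rec + γ_Adv L_Adv`
(reference weights γ_Rec = 1, γ_Pix = 10⁻², γ_Adv = 5·10⁻³) with Adam and
a halving learning-rate schedule.  Quality is reported as PSNR, SSIM
(C₁ = (0.01·MAX)², C₂ = (0.03·MAX)²) and an LPIPS-style frozen-feature
perceptual distance.

No scanner data ships with the package: the `synth` module simulates the
full acquisition (ellipse phantoms, smooth normalized coil maps, k-space
cropping, Gaussian-1D / Poisson-disc-2D masks with exact sample counts,
complex noise), so every stage is exercisable end to end.

All trainable components run on a compact NumPy reverse-mode autodiff
engine (`jrsr.nn`) written for this package; no deep-learning framework is
required.

## Worked example

```python
import numpy as np
from jrsr.synth import desk_protocol, make_dataset, make_training_pair
from jrsr.train import desk_config, train, evaluate, baseline_zf_interp
from jrsr.metrics import psnr, to_magnitude

proto = desk_protocol(seed=0)                  # 64x64 HR, 2x crop, 2x Gaussian
train_data = make_dataset(proto, 24)
test_data = [make_training_pair(proto, 1000 + i) for i in range(16)]

res = train(desk_config(mode="proposed", seed=0, steps=500), train_data)
report, _ = evaluate(res.generator, test_data)
baseline = np.mean([psnr(baseline_zf_interp(p), to_magnitude(p.x_gt))
                    for p in test_data])
print(f"model {report.psnr_mean:.2f} dB vs zero-filled+bicubic {baseline:.2f} dB")
```

Output:

```
model 25.59 dB vs zero-filled+bicubic 23.25 dB
```

i.e. after a 500-step desk-scale run the joint model recovers the held-out
phantoms about 2.3 dB more faithfully than zero-filling plus bicubic
interpolation.  (The desk profile shrinks the trunk to 2 RRDB-SFT blocks
and 2 PGD iterations so this runs in minutes on one CPU; exact numbers vary
slightly with the training seed.)

The same pipeline is scriptable:

```bash
jrsr simulate --protocol brain --n-slices 4 --seed 7 --out brain.h5
jrsr train --protocol desk --steps 500 --seed 7 --ckpt g.npz
jrsr evaluate --ckpt g.npz --data desk.h5 --out metrics.csv
jrsr reconstruct --ckpt g.npz --in desk.h5 --out slice.nii.gz
```

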