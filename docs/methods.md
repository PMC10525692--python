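# Methods

## Forward model and conventions

The multi-coil super-resolution acquisition is modeled as `b = M F C x + δ`
on the low-resolution (LR) grid, where the crop `H` (together with `M`
forming the sampling operator `P = MH`) has already been applied to the
fully sampled high-resolution (HR) k-space by the simulator.

Fixed numerical conventions:

* **FFT**: centered (DC at 0-based index `n//2` on each axis) and
  orthonormal.  `F` is therefore unitary, and with sum-of-squares
  normalized coil maps the encoding satisfies `‖A‖ ≤ 1` (verified by power
  iteration in the tests).  Any step size η ≤ 1 keeps the data-consistency
  step non-expansive.
* **Crop window**: an axis of length `n` cropped to `m` keeps
  `[n//2 − m//2, n//2 + (m − m//2))`.  Zero-padding back onto the HR grid
  at the same window is the exact adjoint.
* **Crop amplitude convention**: cropping keeps raw k-space values.  Under
  the orthonormal FFT, Parseval then makes the LR image *energy* equal to
  the HR energy minus the discarded high-frequency energy, and smooth-image
  *amplitude* scales by about `√(s_h·s_w)` (×2 for a 2×2 crop).  The SR
  network learns this gain; the zero-filled + bicubic baseline divides by
  `√(s_h·s_w)` so baseline comparisons are gain-fair.
* **Complex carriage**: operator mathematics is done in true complex
  arithmetic; trainable layers see two real planes (real, imaginary).
  Magnitude is taken only for metrics, the perceptual term and the
  discriminator.
* **Coil-map support**: pixels whose sensitivities all vanish are
  background and excluded from the `C^H C = I` identity; the synthetic
  Gaussian-lobe maps are strictly positive, so their support is the full
  grid.

## Reconstruction module

PGD Net iterates `x_{k+1} = Γ(x_k − η A^H (A x_k − b))` from
`x0 = A^H b` (the zero-filled adjoint; this standard choice makes
full-mask noiseless recovery exact in one iteration).  η is a trainable
scalar initialized at 1.0.  Γ is an RRDB stack on the two-plane
representation whose output convolution is zero-initialized, so Γ is the
exact identity at the start of training and PGD Net begins as plain
gradient descent on the data-fidelity term.

**Deep equilibrium.**  The iteration stops when the relative change of the
iterate falls below `tol = 1e-4` (training default `max_iter = 15`,
inference 30; the desk profile uses 2).  A divergence guard aborts with an
explicit error if the residual grows tenfold within five iterations,
rather than returning NaNs.

**Jacobian-free backward.**  The fixed point is computed without building
any autodiff graph; one final application of `Γ(grad_step(·))` is then
evaluated through the graph with the equilibrium held constant.  Gradients
reach η and all Γ parameters, and the recorded graph size is independent of
the iteration count (asserted by counting graph nodes at 2/8/32
iterations).  With `max_iter = 1` the contract reduces exactly to the
fully unrolled single step.

## SR module

Initial 3×3 convolution → `n_blocks` RRDB-SFT blocks → trunk convolution
with a long (global) residual from the post-initial-conv feature
(ESRGAN-style; the coupling diagram is ambiguous on this, so the long skip
is this package's choice) → nearest-neighbor upsampling → two
convolutions producing the output planes.

* **SFT**: `out = scale(cond) ⊙ feat + shift(cond)`; each head is two
  convolutions on the shared reconstruction feature.  Final head layers
  are zero-initialized with the scale bias at 1, so every SFT starts as the
  identity (stabilizes early training).  A consequence worth knowing: at
  the exact initialization point the condition branch carries zero
  gradient; it engages as soon as the heads move, which the optimizer does
  on the first steps.
* **Dense blocks**: five 3×3 convolutions with dense concatenative
  connectivity and leaky-ReLU (slope 0.2), residual-scaled by β = 0.2.  The
  two extra skip connections are implemented as additive shortcuts from the
  first activation onto the third and from the second onto the fourth
  (growth-channel tensors; the blueprint states their existence but not
  their placement — this placement is the package's decision, behind the
  `extra_skips` flag so its effect can be ablated).
* **RRDB residual form**: a block returns `x + β(h − x)` where `h` is the
  three-dense-block trunk output, so identity sub-blocks give an exact
  identity block.
* The reconstruction feature (one convolution of the PGD-Net output) is
  computed once and broadcast to every SFT layer.
* The Rec-module RRDBs and the SR trunk do not share weights.

Ablation wiring: `proposed` feeds the zero-filled image to the trunk and
conditions on the reconstruction feature; `sr_only` self-conditions on the
zero-filled input; `recon_plus_sr` (and `recon_sr_separate`, trained in two
phases with the Rec module frozen in the second) consumes the
reconstruction as the trunk input and self-conditions on it; `recon_only`
returns the LR reconstruction, lifted bicubically (with the crop-gain
correction) only for HR-grid evaluation.

## Objective and metrics

`L_G = L_Per + γ_Pix L_Pix + γ_Rec L_Rec + γ_Adv L_Adv` with reference
weights γ_Pix = 1e-2, γ_Rec = 1, γ_Adv = 5e-3.  L_Pix/L_Rec are mean
absolute errors on the HR output and LR reconstruction (against the
coil-combined un-undersampled LR k-space image).  The adversarial pair is
the non-saturating form on discriminator probabilities (clamped at 1e-7),
with the fake branch detached in the discriminator loss; the discriminator
is a VGG-style convolution stack with a scalar-probability head, updated
1:1 with the generator after an optional pixel-only warm-up.

No pretrained VGG-19/AlexNet weights are shipped.  The perceptual term and
the perceptual metric use a seeded, frozen, randomly initialized
convolution stack: reproducible everywhere without downloads, sensitive to
local structure, but *not* calibrated to human judgments — perceptual
numbers are comparable within this package only.  The LPIPS-style metric
follows the standard construction (channel-unit-normalized features,
squared distance, position average, layer sum) with unit channel weights.

Metrics operate on magnitude images with MAX = the per-slice ground-truth
maximum.  PSNR returns +inf when the images coincide.  SSIM offers a
`global` mode (whole-image statistics; used by formula-level tests) and
the reporting default `windowed` (11×11 Gaussian windows, σ = 1.5, via
scikit-image, constants (0.01·MAX)² and (0.03·MAX)²).

## Synthetic data

The simulator emulates the acquisition protocol exactly at the operator
level: fully sampled HR multi-coil k-space of a random ellipse phantom
(piecewise-smooth magnitude in [0, 1], band-limited texture, smooth
low-order polynomial phase), centrally cropped by the SR scale, then
undersampled and perturbed by circular complex Gaussian noise.

* **Gaussian 1D mask**: exactly `round(n_pe / us)` lines; the ACS block
  (default 12 lines; 6 at desk scale) is always sampled; the rest are drawn
  without replacement with probability ∝ a Gaussian of σ = n_pe/6 centered
  at DC.  The mask varies along PE and is constant along FE, because FE
  cropping cannot accelerate the scan.
* **Poisson-disc 2D mask**: variable-density dart throwing (exclusion
  radius growing linearly from 0.55·√us at DC to 1.55·√us at the corners),
  a fully sampled central calibration block (default 16×16), then random
  add/remove outside the block to reach exactly `round(h·w / us)` samples.
  All sampled points are counted toward the measured acceleration,
  calibration included.
* Exact-count masks make the acceleration bookkeeping deterministic:
  brain 2 × 2.5 = 5×, vessel-wall 2 × 2 × 4 = 16× (= 94080/5880 measured).
* Coil maps are Gaussian lobes placed around the field of view with random
  smooth phase, drawn from grid-size-independent parameters (so LR maps are
  consistent subsamples of HR maps) and sum-of-squares normalized.

What the phantoms do **not** emulate: anatomy, contrast mechanisms,
g-factor noise amplification, motion, off-resonance, imperfect coil-map
estimation.  Passing tests therefore demonstrate the correctness of the
operators, solver, training contract and pipeline — not clinical image
quality on scanner data.

## Profiles and problem sizes

The `paper` profile records the reference hyperparameters (23 blocks,
64-channel trunk, Adam lr 1e-4 halved after 50k/100k/200k/300k steps,
batch 4, the γ weights above); it is configuration, not something a desk
CPU can run.  The `desk` profile is the package's CPU-scale choice used by
tests and the acceptance script: 64×64 HR phantoms (2× crop, 2× Gaussian
undersampling, σ = 0.01 noise, 4 coils), trunk of 2 RRDB-SFT blocks at 12
channels (growth 6), 1-block proximal net, 2 PGD iterations, batch 2,
500 steps, Adam lr 3e-3, weights (pix 1, rec 1, per 0.1, adv 0).  The
desk learning rate and fidelity-oriented weights were chosen for
few-hundred-step runs, where the reference schedule has not even reached
its first decay milestone; with no calibrated perceptual network there is
no reason to let the perceptual term dominate.  Training 24 slices and
evaluating 16 held-out slices keeps a full desk run at a few minutes of
one CPU.  The mode-comparison check (proposed vs sequential coupling on
mean PSNR over seeds) runs the same 500-step protocol with 2 seeds; at
a few hundred steps the coupling advantage is still emerging — the SFT
heads start at the identity — so per-seed differences are noisy while the
seed mean favors the interactive wiring.

## Known limitations

* 2D only; 3D volumes are treated slice-wise.
* Cartesian sampling only; no non-Cartesian trajectories, partial Fourier
  or field-inhomogeneity correction.
* The NumPy autodiff engine is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not for the reference-scale 23-block model.
* Perceptual values from the frozen random feature stack are internally
  consistent but not comparable to published LPIPS numbers.
* ESPIRiT map estimation and coil compression are out of scope; the
  simulator's analytic maps stand in for them.
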