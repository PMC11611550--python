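# smartpet

Denoising of low-count (10 %-dose) brain FDG-PET with a self-similarity-aware
attention GAN, packaged together with everything needed to study it without
patient data: a digital brain-phantom simulator with correct counting
statistics, the preprocessing chain and its exact inverse, volumetric image
quality metrics, and SUV/SUVr/asymmetry quantification with nonparametric
cohort statistics.

It is aimed at PET methods researchers who want a reproducible, desk-scale
test bed for count-reduction denoising: every stage runs on synthetic
phantoms, on one CPU, with no downloads.

## The model

A conditional GAN in the pix2pix lineage maps a preprocessed low-count
volume LD ∈ [-1, 1]^(D×H×W) to a denoised volume DN = G(LD):

* **Generator** — 3D U-Net: 7×7×7 input convolution, stride-2 encoder,
  transposed-convolution decoder with skip connections, tanh output.  At
  chosen encoder levels a **self-similarity-aware attention block (SSAB)**
  transforms the feature map F: the sum of (i) SAGAN-style self-attention
  (softmax over flattened positions, zero-initialised residual gain),
  (ii) similarity attention — a sigmoid gate built from the pixel-wise
  self-similarity score (2·ConvF + c₂)/(2·(ConvF)² + c₂) with ConvF a
  sliding-window mean and c₂ = (k₂L)², k₂ = 0.03 — and (iii) channel→spatial
  (CBAM-style) attention, fused by a 1×1×1 convolution.
* **Discriminator** — conditional 3D patch discriminator on (LD, candidate).
* **Objective** — L_G = λ₁·L_adv + λ₂·‖SD − G(LD)‖₁ with λ₁ = 1, λ₂ = 100;
  Adam(0.5, 0.999), batch size 1, lr 10⁻⁴ constant then linearly decayed to
  zero.  Ablations: BCE vs least-squares adversarial loss, an optional
  differentiable Fréchet-distance penalty, discriminator off, attention
  type/position, input convolution removed.

The low-dose arm of the simulator thins each detected standard-dose event
independently with probability p = 0.10 (binomial thinning), the
count-statistics equivalent of reconstructing 10 % of the list-mode frames.

The networks run on a compact NumPy reverse-mode autodiff engine included in
the package (`smartpet.grad`), with im2col/FFT 3D convolutions — no deep
learning framework is required.

## Worked example

```python
import numpy as np
from smartpet import PhantomSpec, Lesion, make_cohort
from smartpet.metrics import ssim
from smartpet.quantify import suv_map, smooth, suvr, zai_map, hypometabolic_roi

spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size_mm=(5.0, 5.0, 5.0),
                   total_counts_standard=2_000_000,
                   lesion_list=[Lesion(center=(8, 16, 16), radius_mm=15.0,
                                       multiplier=0.6)],
                   seed=0)
subjects, manifest = make_cohort(1, spec)
pair, labels = subjects[0]
print("low/standard detected events:",
      round(pair.low.extra["counts"].sum() / pair.standard.extra["counts"].sum(), 4))
print("SSIM(low, standard):", round(ssim(pair.low.voxels, pair.standard.voxels), 3))

suv = smooth(suv_map(pair.standard, pair.meta))
tab = suvr(suv, labels, reference="cerebellum")
print(tab[tab.region.isin(["occipital", "hippocampus", "lesion_0"])]
      .round(3).to_string(index=False))
z = zai_map(suv, labels.brain_mask())
roi = hypometabolic_roi(z, threshold=-2.0)
sizes = sorted(roi.volumes_mm3.values(), reverse=True)
print(f"hypometabolic components: {len(sizes)}, largest = {sizes[0]:.0f} mm^3 "
      f"(lesion truth {labels.mask('lesion_0').sum() * 125.0:.0f} mm^3)")
```

prints

```
low/standard detected events: 0.0998
SSIM(low, standard): 0.919
     region  mean_suv  suvr  n_voxels
  occipital     6.937 1.005      1404
hippocampus     6.906 1.000        68
   lesion_0     1.946 0.282        93
hypometabolic components: 162, largest = 11844 mm^3 (lesion truth 11625 mm^3)
```

The thinning retains 9.98 % of the detected events; region SUV sits in a
physiological range and the SUVr of the reference-normalised healthy regions
is ≈1, while the 0.6× lesion (further diluted by the point-spread blur)
drops to 0.28.  The largest connected component below zAI = −2 recovers the
planted lesion's volume within ~2 %; the remaining components are
single-voxel noise speckles at this count level.

## Command line

A `smartpet` CLI orchestrates the pipeline stage by stage or in one run:

```bash
smartpet simulate --out run/ --subjects 10 --seed 0
smartpet preprocess --out run/
smartpet train --out run/ --epochs 30
smartpet denoise --out run/
smartpet evaluate --out run/
smartpet quantify --out run/ --reference cerebellum
# or equivalently
smartpet run --out run/ --seed 0
```

Each stage writes NIfTI volumes / CSV reports under `run/` and appends
provenance to `run/manifest.json`.

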