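# Methods

`smartpet` implements an end-to-end study of low-count brain-PET denoising
with a self-similarity-aware attention GAN, made fully testable on synthetic
digital brain phantoms.  This note records the models, the choices that were
genuinely open, and what the phantom experiments do and do not show.

## Phantom and counting statistics

The phantom is a nested-ellipsoid brain: a ventricular CSF core, a white
matter shell, a grey matter rim, bilateral deep-grey nuclei (caudate,
putamen, thalamus, hippocampus) and cortical territories (cerebellum,
occipital, frontal, parietal, temporal, insula) carved from the rim by
geometric predicates.  It is deliberately geometric rather than atlas-based
so the whole study runs with no external data.  Default tissue activity is
GM:WM:CSF = 4:1:0.3 (textbook FDG contrast).  Focal lesions multiply the
underlying tissue activity inside a sphere; a hemispheric asymmetry factor
can scale the left side.  The construction is mirror-symmetric about the
midsagittal plane unless lesions/asymmetry are requested, which makes the
asymmetry-index pipeline exactly testable.

Counting statistics are modelled at the image level:

* **standard dose** — the activity map is normalised to an expected-count
  map summing to `total_counts_standard` and each voxel draws independent
  Poisson counts; a Gaussian point-spread blur (default FWHM 4 mm,
  matching the 2–5 mm post-filters of clinical reconstructions) stands in
  for reconstruction resolution.  Sinogram-space effects (attenuation,
  scatter, scanner geometry) are out of scope.
* **low dose** — each detected event is retained independently with
  probability `thinning_fraction` (default 0.10): binomial thinning of the
  standard-dose counts, the count-statistics equivalent of reconstructing
  10 % of the list-mode frames.  Thinning preserves the Poisson character
  and gives the expected 1/sqrt(p) growth of relative noise.  The thinned
  image is divided by p so both arms share an intensity scale, as dividing
  by frame duration does for a short reconstruction.  Temporal correlation
  between selected frames is not modelled.

Cohorts add per-subject jitter in voxel size and tissue ratios, draw
injected dose (150–250 MBq) and body weight (50–90 kg) uniformly, and
calibrate counts to activity concentration (kBq/mL) so that mean brain SUV
is ~5, a typical FDG figure.  All randomness flows through one seeded
generator per subject; identical seeds give bit-identical cohorts.

## Preprocessing

Per volume, in a fixed order: (1) background stripping — the hole-filled
largest connected component above an Otsu threshold, an automated surrogate
for manual background removal, with the mask exported for audit; (2)
trilinear resampling to the network grid, preserving physical extent; (3)
z-scoring of in-mask intensities; (4) an affine map of the volume's
[min, max] onto [-1, 1] (per-volume extrema; a per-cohort option was
considered and rejected to keep subjects independent).  Every constant is
stored in a record that supports two inversions: an exact inverse of the
full chain, and the approximate "(v+1)/2 times a study scale constant" form
that the denoised outputs go through before SUV computation.  The study
scale constant defaults to the volume's own pre-normalisation maximum, with
a cohort-average option.

## Networks

The autodiff substrate is a compact NumPy reverse-mode engine inside the
package (`smartpet.grad`): a define-by-run tape with im2col 3D convolutions
(an FFT branch handles the large stride-1 input convolution), transposed
convolutions, and the elementwise/reduction primitives the models need.
Gradients of every primitive are finite-difference tested.

The generator is a pix2pix-lineage 3D U-Net: a 7x7x7 input convolution
(ablation removes it), a stride-2 convolution encoder, attention applied to
the feature maps of chosen encoder levels, and a transposed-convolution
decoder with skip connections plus a 1x1x1 head that fuses the
full-resolution stem features; tanh bounds the output to [-1, 1].  Exact
widths/depths are not prescribed by the architecture's sources; defaults
are 4 levels at base 32 for 128^3 inputs, and the smoke configuration is 2
levels at base 8 for 32^3.  The discriminator is a 3D patch discriminator
(stride-2 stack producing per-patch logits), conditioned on the low-count
input by channel concatenation; an unconditional variant exists.

### Self-similarity-aware attention block (SSAB)

Three units act in parallel and are summed, then fused by a 1x1x1
channel-preserving convolution:

* **similarity attention** — the per-channel score map
  `(2m + c2) / (2m^2 + c2)`, with `m` a sliding-window box mean and
  `c2 = (k2 L)^2`, `k2 = 0.03`; the window defaults to
  `max(3, nearest odd to min(spatial)/8)`.  The score map and the feature
  map each pass a 7-wide convolution to a single-channel logit map whose
  sigmoid gates all channels.  The printed score formula is implemented
  literally; a more SSIM-like variant comparing features with their local
  mean is available behind `canonical_sssim`.  The dynamic range L is the
  per-channel max-min (clamped at 1e-3), treated as constant under
  differentiation; a fixed L=2 option matches [-1, 1] data.  A pairwise
  pixel-by-pixel similarity matrix would be infeasible at volume scale; the
  per-pixel map is the implemented reading.
* **self-attention** — SAGAN-style: 1x1x1 query/key/value with key/query
  channels C/8, row-softmax over flattened positions, and a learnable
  residual gain initialised to zero, so the unit starts as the identity.  A
  position budget (default 4096) rejects placements whose attention matrix
  would be too large, directing the block to a deeper level.
* **channel->spatial attention** — CBAM ordering: average- and max-pooled
  channel descriptors through a shared two-layer MLP, sigmoid-gated; then a
  7-wide convolution over the channel mean/max maps gates positions.

All attention multipliers are sigmoids, hence strictly inside (0, 1), and
every unit preserves shape.

## Objectives and training

`L_G = lambda1 * L_adv + lambda2 * mean|SD - G(LD)|` with lambda1 = 1 and
lambda2 = 100; `L_D` is the standard real/fake cross-entropy on patch
logits.  The non-saturating generator form (-log D(fake)) is the default;
the saturating log(1 - D) form is available behind a flag.  The L1 term is
counted once.  Ablation variants: MSE (least-squares) adversarial form, an
optional differentiable Fréchet-distance penalty between feature Gaussians
of the denoised and reference batches (gradient via the symmetric matrix
square root, flowing only to the denoised volumes), discriminator off
(reducing to supervised L1), attention type/position, and removal of the
input convolution.

Optimisation is Adam with betas (0.5, 0.999), batch size 1, learning rate
1e-4 held constant for the first 100 epochs (smoke: the first third) and
decayed linearly to zero at the final epoch; 400 epochs at full scale, ~30
in the smoke profile.  Splits are subject-level 70/15/15.  The retained
checkpoint is the highest-validation-SSIM state — no selection criterion is
prescribed by the sources of this architecture, and validation SSIM is the
quantity the evaluation leads with.  Non-finite losses abort the epoch and
the last good state is kept.

## Metrics

SSIM (Gaussian window, sigma 1.5, width 11, k1=0.01, k2=0.03, data range
from the reference), PSNR (reference range), NRMSE (RMSE over the
reference's RMS).  FID uses a fixed-architecture, fixed-seed
random-projection convnet over axial slices as the feature extractor —
random projections keep the distance internally comparable across methods
and noise levels, but the absolute values are not comparable to
Inception-feature FIDs.  SNR = mean(GM)/sd(WM) and
CNR = (mean(GM)-mean(WM))/sd(WM) are reported as relative absolute
deviations from the reference volume, so 0 is perfect agreement and lower
is better; the deviation form is a reconstruction from the direction
convention and reported magnitudes, the weakest-anchored definition in the
package.

## Quantification

SUV = C x BW / Dose in the g/mL convention (C in kBq/mL, BW in kg, Dose in
MBq).  Denoised outputs are rescaled by the approximate "(v+1)/2 x study
constant" inversion before SUV.  SUV maps are smoothed with a 2 mm FWHM
Gaussian (reflective boundaries: constants invariant, interior mass
conserved).  SUVr divides region means by a reference region (cerebellum
for epilepsy-style analyses, occipital otherwise).  The asymmetry index is
`AI = 200 (I - I_mirror)/(I + I_mirror)` with mirroring by index reflection
about the midsagittal plane — no nonlinear hemispheric registration — and
is z-scored against the in-mask AI distribution (a perfectly symmetric
volume is defined to have a zero map); the normalisation population choice
is self-referential because the phantom has no healthy-cohort reference.
Hypometabolic ROIs are connected components below zAI = -2, the
conventional z cutoff (configurable), with sizes in mm^3.  Cohort arms are
compared per region with the two-sided Mann-Whitney U test at alpha 0.05,
alongside the absolute percent SUVr deviation per region.

## Problem sizes and what the phantom study shows

The desk-scale study uses 10 subjects at 32^3 (5 mm voxels, 2e6 standard
counts, so ~250 counts per brain voxel at standard dose and ~25 at low
dose) and ~30 training epochs — sizes chosen so the entire study, including
replicate seeds, runs in minutes on one CPU.  Under these conditions the
smoke GAN reliably and substantially improves held-out SSIM over its noisy
input (≈0.5–0.7 vs ≈0.03–0.14 across seeds).

Region-mean SUVr behaves differently, and this is a real property of the
statistics, not an implementation artefact: binomial thinning is unbiased,
so low-dose *region means* deviate from standard dose by only ~0.6–1.3 %
at these count levels (noise averages out over regions of 50–1800 voxels),
while a briefly trained generator carries ~20 % regional bias (a perfect
generator run through the same inversion chain shows ~0.03 %, excluding
the preprocessing as the cause).  Beating the unbiased low-dose baseline on
region means requires near-perfect voxel-wise reconstruction, beyond what
scaled-down training can reach; the corresponding test documents this
expectation gap rather than hiding it.

What passing tests show about real data is therefore limited: the phantom
validates the statistical machinery (count statistics, inversion exactness,
metric and test correctness, asymmetry mapping, lesion recovery) and the
direction of the denoising effect, not clinical image quality, anatomical
realism, scanner physics, or the full-scale quantitative claims.

## Numerical notes

* All network arithmetic is float32; metrics and quantification use
  float64.
* Strided convolutions use zero padding; the PSF and SUV smoothing kernels
  are true Gaussians specified by FWHM = 2 sqrt(2 ln 2) sigma.
* Fréchet distances are computed through symmetric eigendecompositions
  (`(Sb^1/2 Sa Sb^1/2)^1/2`) with eigenvalue clipping at zero; results are
  floored at 0.
* Degenerate inputs raise rather than propagate NaN: empty masks, constant
  volumes, empty regions, zero reference energy, non-finite losses.
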