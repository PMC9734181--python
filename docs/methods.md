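# Methods

## Scientific setting

Medical image classifiers degrade when deployed on data whose acquisition
conditions differ from the training data's, even when the patient population
and labeling are held fixed. The acquisition conditions of projectional
radiography — tube current, exposure, dose, positioner angle, compressed
tissue thickness, and so on — are machine-logged per image in SI units
(physical imaging parameters, *PIPs*) and enter the image through a
well-understood generative process. `pipshift` implements that process as a
controllable simulator and measures how a classifier's generalization gap
(target error minus source error, ε_T − ε_S) grows with distance in a
standardized PCA space over the per-image PIP vectors.

Because the hospital mammography data that motivates this analysis is under
restricted license, the package's quantitative claims are property-based on
synthetic data: the simulator *is* the study population, and its defaults
are the study conditions.

## Forward model

A grayscale projection is generated by a discretized Beer–Lambert model:

    G(i,j) = Σ_k  w_k · E₀ · cos²θ · exp( −μ_mix(E_k, i, j) · r(i, j) )  [+ η]

- **Spectrum.** A triangular (Kramers-like) bremsstrahlung approximation:
  bin centers E_k = E_peak·(k+½)/n on (0, E_peak), weights ∝ (E_peak − E_k),
  normalized; 16 bins by default, n = 1 degenerates to a monoenergetic beam.
  In generated datasets the per-image peak is the tube-current PIP, linking
  beam quality to the metadata.
- **Attenuation.** Two-tissue power laws μ(E) = a·E^(−b) per mm (E in keV)
  with a_glandular = 1.8, a_adipose = 0.7, b = 1.5. These are package
  conventions chosen so a ~50 mm column transmits an appreciable and
  composition-sensitive fraction of the beam; they are not dosimetric claims.
- **Entrance intensity.** E₀ = 10⁻³ · exposure_µAs. The relative-exposure,
  organ-dose and entrance-dose fields are sampled as noisy linear functions
  of exposure ("derived links"), mirroring how real machines derive them —
  this redundancy is what makes a PCA of the metadata meaningful.
- **Path length.** The path integral collapses to a homogeneous column per
  pixel: μ_mix·r with r the phantom thickness map rescaled by the
  body-thickness PIP against a 50 mm reference.
- **Noise.** Additive Gaussian η with sd scaling as √(600 ms / exposure_time);
  optional Poisson photon noise. Because η is *not* proportional to E₀, the
  signal-to-noise ratio rises with exposure — the physical channel through
  which the exposure PIP reaches the final image.
- **Obliquity.** The printed model carries cos²θ only; an optional
  inverse-square factor over the source distance is available behind a flag
  (off by default, matching the printed formula).

**Display transform.** Raw intensities are flat-fielded by the computed air
level and inverted, x = 255·clip(1 − G/G_air, 0, 1), so tissue is bright on a
dark background as in clinical display. This deliberately cancels the E₀ and
cos²θ scale — real detectors auto-calibrate the same way — leaving exposure
to act through SNR and thickness/beam-quality through contrast.

## Phantoms and the label proxy

Each image gets a half-elliptical "compressed breast" attached to the left
edge: a flat thickness plateau with edge roll-off, and a glandular-fraction
field built from seeded low-pass-filtered Gaussian noise, multiplicative
around a class base level. The binary latent class is the label proxy
(dense "young" vs fatty "old" tissue, base fractions 0.50 vs 0.35; the 0.15
margin is configurable). The texture correlation length is also
class-dependent (coarse confluent patches for dense tissue, fine strands for
fatty tissue, σ = L/10 vs L/28). This matters: contrast equalization removes
per-image global brightness, so a class signal carried *only* by mean
density would largely vanish in preprocessing; the spatial-structure
difference survives equalization, as real parenchymal patterns do. Labels
are assigned by row position while PIP rows are drawn i.i.d. from the
hospital profile, so label ⊥ PIP holds by construction (verified by a
binned-MI permutation test and by the random-forest control).

## Preprocessing chain

Applied in order, all deterministic: reject if mean gray > 150 (strict);
binarize at gray > 50 (a pixel of exactly 50 is background); keep the
largest 8-connected component (ties broken by smallest row-major
coordinate); multiply the original image by the mask; CLAHE; mirror
horizontally if the right half holds strictly more mask mass than the left;
area-average resample and map 0→−1, 255→+1. CLAHE uses scikit-image's
`equalize_adapthist` with an 8×8 tile grid and a normalized clip limit of
0.01 (the common OpenCV setting clipLimit = 2.0 with 256 bins corresponds to
a relative clip of 2/256 ≈ 0.008). The resampler is an exact area-average
(integral-image construction), so integer-factor downsampling is exact block
averaging. The reference output size is 244×244; desk-scale experiments use
64×64.

## PIP space

The 12 PIP columns are z-scored per column (population sd) on the combined
all-domain table, then projected by PCA. Components are eigenvectors of the
sample covariance, ordered by decreasing eigenvalue, with each component's
sign fixed so its largest-magnitude loading is positive (backend-independent
reproducibility). Distances are Euclidean in the first k = 2 components by
default (configurable upward; the scree output shows when more are needed).
Test regions are half-open annuli [r_i, r_{i+1}) around the training
centroid; demo radii are distance quantiles so every ring is populated. A
train-only standardizer fit is available for leakage-free workflows but the
combined fit is the default, matching the reference protocol. Biplot
vectors are correlation-scaled loadings (loading·√eigenvalue), length ≤ 1 on
standardized data.

## Independence control

A random forest (100 trees) is fit on the PIP columns alone over repeated
stratified 70/30 splits. The 95% CI uses the Nadeau–Bengio variance
correction for repeated random splits, halfwidth = 1.96·sd·√(1/n + test/train):
the repeats share rows, so the naive sd/√n scaling understates the
estimator's variance and undercovers on label-independent data. With 2000
rows and 20 repeats the halfwidth is ≈ 2 percentage points.

## Shift experiment

A small convolutional classifier ((3×3 conv → ReLU → 2×2 max-pool) blocks,
global average pooling, sigmoid head) is implemented in numpy with manual
backpropagation and trained by seeded mini-batch SGD on the binary
cross-entropy. Reference protocol defaults (learning rate 5×10⁻⁴, batch 32,
50 epochs) sit on `TrainConfig`; momentum 0.9 is the package's addition for
from-scratch training. The desk-scale demo uses 64×64 inputs, channels
(6, 12, 24), learning rate 0.02, 35 epochs, 200 training images per class
drawn from the innermost disk, and 5 balanced test sets of 50 per class per
region, pooled over 3 training seeds. The I.I.D point is the disk's held-out
remainder; each region's distance is the mean member distance from the
training-sample centroid (equal to the ring radius for annuli and to the
centroid separation for distant clusters). The gap-versus-distance trend is
summarized by Spearman's ρ with a permutation p-value (exhaustive over
orderings for ≤ 7 regions), chosen for distribution-freeness.

Training is deterministic given (config, seed) on a fixed platform; across
BLAS implementations only statistical, not bitwise, reproducibility of
accuracies is guaranteed.

## Null control

`null_shift_hospitals()` defines two domains whose image-relevant PIPs share
one tight distribution while detector temperature, padding limit,
compression force and focal spot — fields that never enter the forward
model's pixels — separate the clusters. Metadata distance there is real but
image statistics are unchanged, so no gap trend should (and does not)
appear. This separates "distance in metadata space" from "image-statistic
shift" as explanations of the main result.

## What the synthetic study does and does not show

Passing tests demonstrate that the pipeline detects a monotone
gap-versus-distance relationship when acquisition parameters causally drive
image statistics, at chance-level metadata→label leakage, and detects no
trend when they do not. The simulator omits scatter, heel effect, detector
response curves, 3-D anatomy, pectoral muscle and implants; the absolute
accuracies and gap magnitudes are properties of the chosen fixture (noise
scale 1.5, hospital profiles in `default_hospitals()`) and are not claimed
to match any particular clinical dataset. Real-data mode (DICOM harvesting
via a user-supplied tag map) exercises only the metadata path and is not
covered by the synthetic acceptance runs.

## Numerical choices and degenerate inputs

Cross-entropy clips probabilities at 10⁻⁷. Standardization rejects
zero-variance columns (tolerance 10⁻¹² relative to the column mean).
Strictly positive physical fields get small floors when sampling profiles so
tail draws cannot produce zero-intensity acquisitions. A constant image
passes CLAHE unchanged. An empty mask makes orientation a warned no-op.
Class-imbalanced training sets, empty test sets, non-monotone radii and
region shortfalls raise typed errors naming the offender.
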