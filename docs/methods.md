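# Methods

## Model

One case is four co-registered phase volumes (T1, T2, T1ce, FLAIR) of
shape N × M × L and a tumor label mask on the same grid.  The transform
assumes the inputs are already registered, bias-corrected and
skull-stripped (BraTS-style preprocessing); it performs no resampling and
uses the NIfTI affine only to bring the slice axis to the third array
axis, since slice order is the only geometric property the method needs.

The mask's sub-region labels (conventionally 1, 2, 4) are collapsed to a
single binary volume of interest: the tumor is treated as one region, so
intensity texture — not sub-region anatomy — carries the signal.

Per phase the pipeline is: mask multiplication → null-slice cleaning →
volume-wide gray-level quantization → per-slice feature extraction →
12 × L matrix → row normalization; the four phase matrices are stacked
vertically (T1, T2, T1ce, FLAIR) to the 48 × L identity image.  The
transform is a pure function of (inputs, config); a config hash is
written into every exported artifact.

## Null-slice cleaning

After masking, slices that merely graze the tumor (or numerical residue
in nominally empty slices) can hold a handful of near-zero values whose
histogram is noise.  Any slice whose population standard deviation is
below τ is replaced by an all-zero slice and its 0-based index recorded.
Masking precedes cleaning.  τ defaults to 1e−6 × (masked volume maximum):
the criterion must be scale-invariant because MR intensities have no
absolute units, and 1e−6 of the dynamic range is far below any real
texture while safely above float64 rounding.  τ is configurable
(`TransformConfig.tau_rel`).

## Quantization and the histogram convention

Each masked phase volume is quantized once, volume-wide, by
`level = floor(x / max · G)` clipped to G−1, with G = 256 by default.
One range per phase keeps the columns of a phase matrix on a common gray
scale, and exact zeros (background) always map to level 0.  The map is
monotone and reduces to the identity on 8-bit-range data.

Background zeros are **included** in every slice histogram, and the full
slice area enters the pixel count.  This is deliberate: the fraction of
level-0 pixels encodes the tumor's cross-sectional area in that slice, so
size and location information flows into the features rather than being
normalized away.  Both G and the inclusion convention are configurable in
principle (FOS-only operation via `include_glrlm=False` is the supported
degenerate mode; an interior-only histogram is not offered because the
area signal is part of the design).

## First-order features

From the slice PDF p(i): mean, population standard deviation, skewness,
excess kurtosis (the −3 form, so a degenerate and a Gaussian-like
histogram sit at 0), energy Σp², and entropy in bits (log base 2, with
0·log 0 := 0).  When σ = 0 — cleaned or single-level slices — skewness
and kurtosis are defined as 0 so every column of the feature matrix is
finite.  For integer slices with G = max+1 these equal the standardized
pixel moments exactly (tested to 1e−9).

## Run-length features

A run is a maximal constant segment along a scan line.  Runs are counted
per direction into a G × R matrix (R = longest observed run; features
are invariant to zero-padding of R).  Features use 1-based gray-level
values (quantized level + 1) inside the i² and 1/i² weights so level 0 is
well defined.  All seven features (SRE, LRE, GLN, RLN, LGRE, HGRE, RP)
are computed and exportable; HGRE is excluded from the identity image's
row block, which keeps the retained set at six in the fixed order SRE,
LRE, GLN, RLN, RP, LGRE.

Direction policy: features are computed at 0°, 45°, 90° and 135° and
averaged feature-wise (not by summing matrices), giving a
rotation-robust default; a single-direction configuration is supported.
The run-length block shares the FOS quantization G by default.  An
all-zero (cleaned) slice produces one level-0 run per line, so its
features are finite deterministic constants; a truly empty run set maps
to all-zero features by convention.

## Normalization and stacking

Normalization acts on each feature row independently, per phase, before
stacking: none, min-max (x−min)/(max−min), or z-score (x−μ)/σ with
population σ.  A constant row maps to zeros in both normalizing modes —
necessary because rows of cleaned-slice-dominated phases can be constant.
Z-score rows carry negative values; they are informative, which is why
the exact float `.npz` container is the primary export and the 8-bit PNG
(full-matrix min→0, max→255) is documented as lossy visualization only.
Row normalization before stacking means each phase is standardized
against its own slice profile; normalizing the stacked 48 × L matrix
instead would couple the phases and is demonstrably different (tested).

## Synthetic phantoms

The phantom generator emulates the *structure* of a two-class multi-phase
tumor dataset, not its anatomy or MR physics.  A case is an ellipsoid in
an otherwise zero volume; the label volume marks three concentric shells
with labels 1/4/2 to exercise mask collapsing.  Interior texture per
phase is mean + gradient·(1−r) + smoothed unit-variance Gaussian noise ×
noise_std, clipped at 0.  The two class presets differ in smoothing
length (3 vs 1 voxels — longer runs for class A, separating the classes
through the run-length block) and gradient strength (≈45–55 vs ≈15–18
intensity units — heavier histogram tails for class A, separating them
through the first-order block).  Contrast was deliberately injected
through exactly the two feature families the transform measures, so the
discrimination tests exercise both blocks; intensity means (100–160
arbitrary units) and noise std (8–9) are in the range of normalized
brain-MR tumor intensities.  Default test shape is 64 × 64 × 32 for
speed; one smoke test runs the full 240 × 240 × 155 geometry.

What passing phantom tests do *not* show: robustness to registration
error, bias fields, scanner heterogeneity, real glioma texture, or
imbalanced cohorts — real data carry all of these and the phantom none.

## Grading harness

Two-fold cross-validation, stratified per class with a seeded shuffle;
an odd class count places the extra case in the first fold.  Accuracy is
correct/total per test fold, reported per fold and as the unweighted mean
of the two folds.  The built-in reference classifier is a closed-form
L2-regularized linear model (ridge) on flattened identity images —
chosen for determinism and desk-scale speed; any object with
`fit`/`predict` can be plugged in, including adapters around 2D deep
networks (resizing/channel replication for a specific input geometry is
the adapter's concern, not the core's).  The hyperparameter grid of the
reference deep-learning protocol (epoch 100 fixed; mini-batch 16/32,
learning rate 1e−3/1e−4, LRDF 0.2/0.4/0.6/0.8, Adam/RMSprop/SGDM) is
enumerable for orchestration — 48 settings — but running a deep model
over it is explicitly out of scope here.

## Numerical choices and problem sizes

- All feature arithmetic in float64; oracle agreements asserted at 1e−9,
  PDF normalization at 1e−12.
- Feature-oracle checks use 200 random slices (≤64×64 for the first-order
  family, ≤32×32 with G ∈ {2,4,8} for run lengths, all four directions);
  the cross-validated discrimination check uses a 20-case cohort at
  64 × 64 × 32.  These sizes make the whole suite run in well under a
  minute per module while leaving the checks exact (the oracles are
  equality tests, not approximations).
- Ties in quantization are impossible by construction (floor map);
  degenerate inputs (all-zero volumes, constant rows, empty run sets,
  σ = 0 histograms) all have defined, tested conventions listed above.

## Known limitations

- The identity image is L-dependent; cases with different slice counts
  produce different widths, and any resize to a fixed classifier input
  geometry is the consumer's policy.
- Volume-level (3D) first-order features and other texture families
  (GLCM, GLSZM, NGTDM) are out of scope.
- The std-threshold form of null-slice cleaning is a design choice; other
  emptiness criteria (e.g. mask-area thresholds) are not implemented.
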