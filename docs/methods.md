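# Methods

`fbrseg` automates three measurements of the foreign-body response (FBR) to
an implanted polymer scaffold, as seen by intravital multiphoton microscopy:
(1) multiclass semantic segmentation of immune-infiltrating cells,
(2) instance segmentation of fibroblasts with boundary-aware training, and
(3) scaffold-relative collagen orientation by directional convolution
filtering.  This note records the models, their assumptions, the defaults
and the numerical choices, in the order the pipeline runs.

## Imaging domain and preprocessing

Input slices are 2D grayscale channels (GFP for immune cells, RFP for
fibroblasts, SHG for collagen + scaffold, THG for scaffold) acquired at
1064 × 1064 px over a 360 × 360 µm field (0.3383 µm/px).  Because exposure
varies between volumes, each image is min–max normalized to [0, 1].  The
fibroblast and collagen channels additionally get a gamma correction
(`gamma = 0.5`, expanding dim structures) and a histogram stretch: the
lowest and highest of 256 uniform intensity levels holding more than 50
pixels are mapped to 0 and 1 and everything outside saturates.  The
256-level convention follows 8-bit practice; the stretch threshold of 50 px
treats sparser levels as outliers.  Degenerate inputs are defined away
rather than erroring: a constant image normalizes to zeros, and a stretch
with a single dense level returns zeros, with no dense level at all the
image passes through unchanged.

Images are resized to the 512 × 512 network input with bicubic
interpolation; label masks use nearest neighbour only (bicubic would
invent fractional class codes), and predicted masks are restored to
1064 × 1064 by nearest neighbour before any quantification.  Coordinates
are (row, col), 0-based, row 0 at the top; angle 0° runs along image rows
and increases counterclockwise, all orientations reported modulo 180°.

## Data augmentation and splitting

Datasets are split at the source-image level (the study used 25 training /
11 validation) and only then augmented eightfold with the full dihedral
group of the square: four 90° rotations of the image and of its left–right
mirror, as exact index permutations.  No elastic deformation, rescaling or
noise injection is used — shape and scale are diagnostic in this domain,
and low signal-to-noise is not expected at inference.  Weight maps are
transformed together with their labels.

## The U-Net variant

A classic U-Net (two 3 × 3 convolutions per block, max-pool downsampling,
skip concatenation) with two modifications: batch normalization between
every convolution and its ReLU — which prevents the early loss saturation
seen without it — and learnable 2 × 2 transposed convolutions for
upsampling.  Filter counts double per level from `base_filters` (default
16, five encoder/decoder levels, so a 256-filter bottleneck); padding is
"same" so output size equals input size.  The output head is a 1 × 1
convolution with softmax for ≥ 2 classes or sigmoid for binary tasks.

The engine is a compact NumPy implementation: convolutions are lowered to
BLAS matrix multiplies via `sliding_window_view` (im2col) with explicit
backward passes, verified against central finite differences.  Tensors are
float32; initialization is He-style from a seeded generator, and a fixed
seed reproduces a training history bit-for-bit on the same backend.

Training minimizes the task loss plus an L2 penalty `(λ/2)‖ω‖²` with
λ = 0.01 applied to convolution and transposed-convolution kernels only
(not biases or batch-norm parameters), under Adam with default moments and
a sigmoid-decaying base learning rate

    lr(E) = (lr0 − lr∞) / (1 + exp(s(E))) + lr∞,
    s(E)  = (E − (E∞ − E0)/2) / ((E∞ − E0)/10),

falling from lr0 = 0.001 to lr∞ = 0.0001 with saturation around E∞ = 200;
the reference schedule trains 300 epochs with mini-batches of 8.

## Objectives and metrics

**Class-balanced multiclass Dice** (immune task).  Per class C the standard
Dice term is computed against all remaining classes and weighted by a
coefficient α_C; the loss is `1 − Σ_C α_C · 2⟨y_C, p_C⟩ / (|y_C| + |p_C|)`,
averaged over the mini-batch.  The α_C are inverse pixel frequencies
normalized to sum to 1, so pixel-rich classes (background, typically ~90 %)
do not dominate.  A smoothing term ε = 1e−6 in numerator and denominator
keeps the loss differentiable when a class is absent from a sample.

**Boundary-weighted BCE** (fibroblast task).  Each binary label yields a
weight map: foreground pixels weigh 0; a background pixel at Euclidean
distances d1 ≤ d2 from the two nearest 8-connected cells weighs
`a · exp(−(d1+d2)² / 2σ²)` with a = 100, σ = 5 px, so the narrow background
ridges between adjacent cells carry weights up to 100 and the network is
forced to learn separations.  Distances come from one distance transform
per cell (O(n_cells · n_pixels), acceptable at 512²); with a single cell
d2 = d1, with none the map is zero.  A class-importance offset is then
added: background pixels get w_B + i_B where i_B is the mean of (w_B + 1)
over all training-set background pixels, while foreground importance is
exactly 1 because w_B vanishes there — giving unitary weights on
foreground.  The loss is the weight-normalized mean of per-pixel binary
cross-entropy, with probabilities clipped at 1e−7.

**Likelihood metric M.**  Because the weight amplitude is arbitrary, IoU
understates border quality; M is the weighted mean of per-pixel likelihoods
`y·p + (1−y)(1−p)`, bounded in [0, 1]: 1 for a perfect prediction, 0 for an
inverted one, 0.5 for maximal uncertainty, and symmetric under joint label
flip.  IoU is also provided; two empty masks have IoU 1.

## Quantification

Hard masks come from per-pixel argmax (multiclass) or a 0.5 threshold
(binary).  At the restored 1064 resolution, fibroblast instances are
8-connected components (corner contact merges), and components with area
strictly below 200 px are discarded — a 200-px component survives.
Instance ids follow the raster order of each component's topmost-leftmost
pixel for reproducible reports.  Per-class areas are pixel counts times
pixel_size²; centroids are unweighted pixel-coordinate means; all n(n−1)/2
pairwise centroid distances are reported in µm (pixel units derivable from
the stored pixel size).

## Collagen orientation

**Kernel bank.**  The 8-direction compass-mask edge detector is generalized
to 360 kernels at 1° spacing, 33 × 33 px each (an 11.2 µm neighbourhood at
native resolution).  For angle θ each coefficient starts as the
perpendicular distance from the pixel center to the line through the kernel
center at θ; distances in [0, 1] are kept as-is, [1, 2] ramp linearly back
to 0, beyond 2 is zero — a double triangular ridge hugging the line.
Coefficients on the clockwise side (negative cross product with the line
direction) are negated, support is clipped to a 15-px radius, and positive
and negative coefficients are normalized to +1 and −1, so every kernel sums
to 0 and responses are comparable across angles.  Exact identities:
K(θ+180°) = −K(θ), and K(θ+90°) is the quarter-turn rotation of K(θ).

**Response engine.**  Responses are zero-padded linear correlations
computed by FFT.  Thanks to the half-turn antisymmetry only 180 kernels are
convolved; the maximum absolute response over those equals the signed
maximum over all 360.  Each pixel gets the angle of its maximum-response
kernel if the magnitude exceeds a threshold — 0.5 for binary scaffold
skeletons, 0.06 for preprocessed collagen — ties to the smallest angle, and
the width-4 image border is forced unoriented.

**Scaffold reference.**  The predicted THG scaffold mask is opened once
with a 20 × 20 elliptical element (removing spurious objects), dilated 20
times with a 3 × 3 element (smoothing jagged fiber boundaries), thinned
with Lee's skeletonization, and the skeleton re-dilated 3 times with a
2 × 2 element for directional robustness.  "Elliptical" elements are filled
discrete ellipses inscribed in the bounding box; at 2 × 2 and 3 × 3 the
ellipse degenerates to the full square.

**Collagen filtering.**  The collagen orientation map is pruned in a fixed
order that only ever removes oriented pixels: (1) a variance filter —
pixels whose population variance over their top-36 response magnitudes is
below 0.35 × 10⁻³ responded similarly to many kernels and carry no reliable
direction; (2) exclusion of pixels covered by the dilated (non-skeletonized)
scaffold mask, since scaffold edges contaminate the SHG channel (a switch
restores the literal outside-discarding variant); (3) removal of
8-connected oriented clusters smaller than 15 px.

**Histograms.**  Oriented pixels are counted into 180 one-degree bins.  The
preferential orientation is the bin with the most pixels (ties to the
smallest angle).  A 7-bin circular moving average — no external padding,
angles are periodic — is attached for presentation and plotting; the mode
is deliberately taken on the raw counts because box-smoothing a sharp peak
produces a 7-bin plateau whose argmax is ill-conditioned.  Scaffold-relative
histograms shift every angle by the scaffold's preferential orientation,
modulo 180; an unoriented scaffold is an error, not a silent default.

### Angular resolution limit

The bank's nominal spacing is 1°, but a 33 × 33 kernel with a 15-px radius
cannot separate orientations closer than about atan(1/15) ≈ 3.8° by a
single response, and the 0° and 90° kernels are special: their coefficient
ridges fall exactly on grid rows/columns, making them slightly sharper
matched filters than their ±1–3° neighbours.  On synthetic parallel
stripes this snaps planted angles within ±2° of an image axis onto the
axis: over all 180 integer angles the preferential orientation is exact at
164 and within 1° except at {2°, 88°, 92°, 178°}, where the error is 2°.
The effect is phase-independent and survives anti-aliased rendering,
blurring and alternative kernel discretizations; it is an intrinsic
property of the construction, not of the implementation.  Away from the
axes the recovery is 1°-accurate, and 90°-rotation equivariance holds
exactly.

## Synthetic fixtures

No public dataset exists for this imaging domain, so the package ships
generators whose ground truth is the rendering input itself; all are
deterministic in (parameters, seed), and every fixture spans the study's
360-µm field of view so physical sizes translate to pixels at any
resolution.

* `scaffold_grid` — orthogonal bright bars of the 35-µm filament width,
  Gaussian-blurred, optional additive noise (THG-like).
* `immune_cells` — a bright, dense cell layer carved (by thresholded
  smoothed noise) out of the ≤ 30 µm band around scaffold fibers (class 1),
  plus dim non-overlapping discs planted far from the scaffold (class 2).
* `fibroblasts` — elongated irregular blobs made by dragging a disc along
  a persistent random walk on a jittered grid; isolated cells keep a 2-px
  clearance, a requested number of pairs is grown adjacent to exercise the
  boundary weights, and optional sub-200-px discs plant area-filter fodder.
* `oriented_fibers` — parallel stripes at an exact angle (default 2-px
  fibers every 8 px ≈ 2.8 µm fibrils at 11 µm spacing), crossed stripe
  families, or uniformly random short segments ("chaotic").  Stripes are
  rendered 3× supersampled and box-averaged so edge pixels carry sub-pixel
  fiber position, as band-limited microscopy intensities do.

What the fixtures do not emulate: optical PSF anisotropy, depth-dependent
attenuation, autofluorescence bleed-through, and the morphological
diversity of real cells.  Passing tests therefore demonstrate correctness
of the algorithms under controlled truth, not clinical-grade performance on
real tissue.

## Scaled-down validation sizes

The reference training configuration (16 base filters, depth 5, 512²
inputs, 300 epochs) is exercised end-to-end at reduced size in the test
suite: 8 base filters, depth 3, 128² fibroblast fixtures, 20 training and 8
held-out images, 50 epochs, fixed seeds.  This configuration reaches a
held-out IoU of ~0.94 while the epoch-mean training loss falls from ~0.86
to ~0.31.  With only three mini-batches per epoch the epoch means are
stochastic, so the monotonicity check uses a 5-epoch moving average.  The
orientation sweep covers all 180 integer angles at 256² — roughly three
minutes on one core via the cached-FFT response engine.

## Known limitations

* The near-axis ±2° orientation snap described above.
* The NumPy engine targets desk-scale experiments; full-scale 512²/300-epoch
  training is possible but slow compared to GPU frameworks.
* 2D only: volumetric stacks are processed slice-wise; no 3D interpolation,
  fiber tracing, or capsule-thickness measurement.
* Immune-cell subtypes are not distinguished, and blood-vessel analysis is
  out of scope.
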