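# Methods

This note documents the model, the numerical choices, the synthetic data
the package is tested on, and the limits of what those tests show.

## State-space core

Each channel of a feature sequence is an independent single-input
single-output state-space system with a **diagonal** state matrix `A`
(N real entries per channel). Diagonal state is standard structured-SSM
practice; it makes the zero-order-hold (ZOH) discretization elementwise

```
A̅ = exp(ΔA),    B̅ = (exp(ΔA) − 1) / A · B
```

and keeps the naive sequential recurrence affordable. Numerics:

* `B̅` is evaluated with `expm1` and switches to its analytic limit `ΔB`
  when `|ΔA| < 1e−8`, avoiding catastrophic cancellation near `A = 0`.
* `Δ` must be strictly positive; the selective variant produces it through
  a softplus, and non-finite projected values abort with the offending
  index.
* Defaults: state dimension N = 16 in the core API, Δ initialized
  log-uniform in `[1e−3, 1e−1]`, `A` initialized to `−(1…N)` per channel
  (real negative, so `A̅ ∈ (0, 1]` and the recurrence is stable).
* All recurrences are explicit sequential loops over the sequence (numba-
  compiled); there is no parallel prefix scan. Correctness is checked
  against the global-convolution form (`K̅ = (CB̅, CA̅B̅, …)`) to 1e−5
  over random stable parameter draws, and the selective scan against a
  step-by-step rediscretization loop.
* The selective scan's training-mode kernel stores the full state
  trajectory for backpropagation through time; the inference kernel keeps
  only a rolling state.

## Scanning orders

A `(B, C, D, H, W)` feature volume is unfolded to 1D sequences by index
permutations (0-based, row-major; depth = anisotropic axis; "row-forward"
advances x, "col-forward" advances y). Unfold/fold are exact permutation
bijections, tested exactly, not to a tolerance.

* **2D expanded**: the four planar directions per depth slice, processed
  independently and **averaged** — the mean keeps activation scale
  independent of the direction count. Each direction has its own selective-
  scan parameters (independent parameters are the more expressive default;
  sharing across directions would be a valid, smaller variant).
* **3D expanded**: whole-volume sequences in depth-major (`dhw`) or
  width-major (`whd`) order; the bottleneck's two cascaded units use one
  order each, so the two passes traverse the volume differently.
* **Bidirectional**: forward and backward recursions over the z-major
  (depth-outermost) unfolding with separate Δ/B/A parameters and a shared
  output projection C, summed: `y_t = C(s_t→ + s_t←)`.

## Blocks and network

The residual visual state-space block is
`H = VSSM(LN(Z)) + Z; Z' = CA(LN(H)) + H`. The VSSM interior follows the
established gated design: 1×1×1 input projection to 2× expanded width,
split into main/gate paths, depthwise 1×3×3 convolution, SiLU, the
configured directional scan, gating with `SiLU(gate)`, 1×1×1 output
projection. Channel attention is squeeze-excite style with reduction 4
(kept small because stage widths are small). Normalization is layer
normalization over channels; the activation is SiLU repo-wide.

The anisotropic adaptation (SAA) module runs a planar branch
(2D-expanded scan → 1×3×3 conv → 1×3×3 residual block) and an axial branch
(bidirectional z scan → 3×1×1 conv → 3×1×1 residual block), concatenates to
2C channels and maps back to C with a **bare** 1×1×1 convolution (whether
that projection carries norm/activation is unspecified; bare linear is the
conservative choice). The isotropic adaptation (SIA) module cascades two
(3D-expanded scan → 3×3×3 conv → 3×3×3 residual block) units with distinct
scan orders.

The network is U-shaped: stem conv → three SAA stages with downsampling
strides `[1,2,2], [1,2,2], [1,1,1]` → bottleneck (`[2,2,2]` downsample, two
SIA modules, trilinear upsample, isotropic-conv module, residual fusion
with the deepest skip) → three decoder stages (trilinear upsample, skip
concatenation, 1×3×3 anisotropic-conv module) → 1×1×1 head. Notes:

* The third encoder stride is `[1,1,1]` exactly as configured — that stage
  changes width but not resolution. The schedule is taken as given and the
  stride-1 stage is flagged in the build log. Channel widths follow
  `stage_widths` regardless of stride.
* Default widths are `(12, 24, 48, 64)` with network state dim N = 8,
  giving 2.38 M parameters — this architecture class sits at roughly the
  3 M-parameter scale, and the default lands near it while keeping a CPU
  forward pass proportionate. Both are configurable.
* Heads: `affinity` = 3 sigmoid channels (z/y/x nearest-neighbour
  affinities — the field's standard offsets); `mask_boundary` = 2 sigmoid
  channels (semantic mask, instance boundary).
* Downsampling uses strided convolutions (kernel 1×3×3 when the depth
  stride is 1, 3×3×3 otherwise); upsampling is endpoint-aligned separable
  trilinear interpolation (constants and affine ramps are preserved
  exactly) followed by a 1×1×1 channel adjustment.
* Input extents must satisfy the stride-schedule divisibility
  (D % 2, H % 8, W % 8 for the default schedule), checked before compute.

## Autodiff engine

No GPU tensor framework is used; the network runs on a small reverse-mode
autodiff engine over numpy arrays with numba kernels for the scan
recurrences. Primitives: broadcasting arithmetic, sigmoid/softplus/SiLU,
reductions, reshape/transpose/gather/slice/concat, matmul, same-padded 3D
convolution (dense and depthwise, implemented as shifted strided slices so
memory stays flat), fixed linear interpolation maps, and the selective-scan
node. Every primitive's gradient is finite-difference tested; a
whole-network input gradient matches central differences to ~1e−4 in
float32. Backward closures form reference cycles, so the engine frees each
node's state eagerly during the backward walk — without this, repeated
training steps accumulate garbage faster than the collector reclaims it.

## Losses

`L = α·Dice + β·WBCE` with α = β = 1 by default (the weighting
coefficients are free parameters; equal weights are the neutral choice),
Dice smoothing ε = 1e−6, predictions clamped to `[1e−7, 1 − 1e−7]` inside
the BCE. The WBCE weight map follows the branch form

```
W_f > 0.5:   W_i = G_i + W_f/(1−W_f) · (1−G_i)
W_f ≤ 0.5:   W_i = W_f/(1−W_f) · G_i + (1−G_i)
```

which is continuous at `W_f = 0.5` (all-ones). The two branches treat the
minority class asymmetrically (up-weighted when background is the
minority, down-weighted when foreground is); the form is implemented
as written and pinned by a unit test rather than "corrected".
`W_f` is computed from the ground-truth patch, not the predictions —
prediction-derived weights would be non-stationary during training and
would contradict reading `W_f` as a foreground proportion. A
`weight_source` switch selects the prediction-derived variant instead.
Single-class patches fall back to unit weights with a warning.

Affinity training takes one composite loss over the three stacked
channels; mask+boundary training sums a mask term and a boundary term.

## Targets and post-processing

* Affinity channel k is 1 where a voxel and its −1 neighbour along axis k
  share a nonzero label; boundary voxels (no neighbour) are 0.
* Instance boundaries are computed **per z-slice** (in-plane min/max filter
  within the thickness window, default 1 voxel) because the z sampling is
  several times coarser than x–y; a 3D boundary would be dominated by
  between-slice label changes.
* Marker-controlled watershed: markers = 6-connected components of
  `(mask > 0.9) ∧ (boundary < 0.1)`; elevation = `boundary − mask`; region
  = `mask > 0.8`; components under `min_size` (default 128) removed;
  deterministic for fixed inputs. The thresholds are package choices
  exposed in the config.
* The affinity agglomerator is union-find over edges above a merge
  threshold, processed in decreasing-affinity order with lexicographic tie-
  breaks. Because every above-threshold edge is merged, the result equals
  the connected components of the thresholded affinity graph — it is a
  documented, deterministic stand-in for external C++ agglomerators, and
  externally produced segmentations can be evaluated directly instead.

## Inference

Sliding windows (default patch 8×256×256, stride 4×128×128) clamp to the
volume edge; volumes smaller than one patch are reflect-padded. Each
window's sigmoid probabilities are accumulated with a separable Gaussian
weight, σ = extent/8 per axis (a free parameter; /8 keeps the corner
weight small without starving edge coverage), peak 1, strictly
positive, then normalized by the accumulated weight in float64. A constant-
logit model therefore blends to an exactly constant probability volume.

## Metrics

All metrics derive from the sparse contingency table of the two labelings.

* **VOI**: `voi_split = H(seg|gt)`, `voi_merge = H(gt|seg)`, base-2 logs by
  default (the log base is configurable). The naming follows the
  conventional split = H(seg|gt) mapping; because the literature is not
  consistent about which component is "split", the report keeps the
  conditional entropies explicit.
* **ARAND**: 1 − F-score of pairwise Rand precision/recall over unordered
  voxel pairs, ignoring ground-truth background (challenge convention;
  configurable). Verified against an O(n²) pair-counting loop to 1e−10.
* **AP-75**: ground-truth instances are greedily matched to predictions by
  descending IoU (one-to-one); matches at IoU ≥ 0.75 are TPs. Predictions
  rank by voxel count (watershed emits no scores). AP is the step-wise
  area under the precision-recall curve, without interpolation — pinned by
  an exhaustive enumeration test rather than assuming a particular
  detection-benchmark convention. Strata: small < 5 000 voxels,
  large > 30 000, medium between; a stratum with no ground-truth instance
  is reported absent, not zero.

## Synthetic data

The generators emulate what matters for exercising the pipeline, not EM
appearance:

* anisotropic voxels, default (30, 6, 6) nm — the 5× z/x-y ratio of
  serial-section EM benchmarks;
* `tube`: random-walk neurite-like cylinders spanning the z-stack, carved
  so distinct instances keep a one-voxel dark "membrane" gap (hence ideal
  affinities never cross instances);
* `ellipsoid`: mitochondria-like bodies, physically near-isotropic so
  squashed ~5× along z in voxel space; the size law targets all three
  AP-75 strata (one instance below 5 k voxels, one above 30 k) when the
  volume is large enough. Placement is by rejection; in crowded volumes a
  bounded carve-around fallback keeps generation from failing, at the cost
  of non-convex shapes.
* intensities: piecewise base levels + smoothed texture + Gaussian noise,
  clipped to [0, 1]; all randomness flows from one seed, and output is
  bitwise reproducible.

Augmentations: rotation (90° in-plane multiples — free 3D rotation is
meaningless at this anisotropy), in-plane scaling, flips, in-plane elastic
deformation (geometric ops applied identically to image and labels,
nearest-neighbour for labels), and image-only degradations: missing parts
(zeroed random in-plane rectangles), missing slices (whole z-slices
zeroed), motion blur (in-plane line kernel), dislocation (one slice rolled
in-plane). "Missing parts" and "dislocation" are loosely-specified
section-artifact names; the definitions above are this package's
interpretations.

What passing tests on this data does **not** show: robustness to real EM
texture, section artifacts beyond the modeled ones, imaging noise
statistics, or benchmark-scale accuracy. The synthetic volumes establish
that the machinery — targets, optimization, inference, post-processing,
metrics — is internally consistent end to end.

## Problem sizes and runtimes

Chosen so the whole suite runs comfortably on one CPU: the overfit check
trains a reduced-width network (widths (8, 16, 24, 32), N = 4, lr 2e−3 —
a single-patch overfit converges much faster than the 1e−4 benchmark
rate, which remains the CLI default) for 200 steps on one 8×64×64 patch
(~6 min); the full-resolution shape-contract check runs one 8×256×256
forward pass (~40 s); the acceptance pipeline trains on random patches of
a 12×96×96 volume. Training at realistic scale (hundreds of thousands of
iterations, benchmark volumes) is out of scope.

## Known limitations

* The naive sequential scan is O(L) per direction with Python/numba
  constant factors; full-resolution forward passes are seconds, not
  milliseconds.
* The union-find agglomerator is a single-threshold connected-components
  merge, not an agglomeration schedule with a merge function.
* Checkpoints store parameters + config only (no optimizer state).
* The watershed round trip is voxel-perfect only when every instance
  yields exactly one marker component (well-separated, near-convex
  instances); carved instances can fragment markers and shed `min_size`
  crumbs.
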