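# Methods

`fetomosaic` reconstructs a placental panorama from fetoscopic video and
recovers from tracking loss. This note documents the models, the defaults
and the design decisions, in the spirit of a methods section.

## Problem setting

Fetoscopic laser surgery for twin-to-twin transfusion syndrome is performed
through an endoscope with a small circular field of view (FoV), under
amniotic-fluid turbidity, strong centre-bright vignetting, sparse vascular
texture and transient occlusions. Mosaicking expands the effective FoV by
registering consecutive frames with projective homographies and blending
them onto a common canvas; a navigation-grade pipeline must additionally
*relocalize* after the inevitable tracking losses.

The scene is modelled as rigid and near-planar, so the map between two
views is a 3×3 homography. Convention used everywhere: matrices act on
homogeneous pixel coordinates (0-based pixel centres, x right, y down);
`H` maps frame coordinates into texture/world coordinates; the global
registration `G_i` maps frame *i* into the anchor (first) frame, composed
as `G_i = G_{i-1} · R_i` with `R_i` the relative map from frame *i* into
frame *i−1*. All stored homographies are normalized to `H[2,2] = 1`.

## Feature extraction and matching

Matching is dense and detector-free. A pluggable backend produces, per
frame, a *coarse* descriptor grid (stride 8 px) for candidate matching, a
*fine* grid (stride 2 px) for sub-pixel refinement, and a pooled global
descriptor for keyframe logic.

Given coarse descriptor sets of a frame pair, the score matrix is
`S(i,j) = ⟨d_i^A, d_j^B⟩ / τ` and the dual-softmax confidence
`P(i,j) = softmax(S(i,·))_j · softmax(S(·,j))_i`. Mutual nearest
neighbours of `P` above the threshold `θ_c = 0.5` become coarse matches;
each is refined by taking, in a 5×5 fine-cell window of B re-centred on
the local similarity peak, the softmax-expectation of fine-cell centres
weighted by similarity to A's central fine descriptor.

### The built-in `dense-grid` backend

A deterministic, training-free stand-in for a learned encoder, built so
that the matching mathematics above operates in the regime it expects:

* **Local contrast normalization (LCN).** Vignetting is multiplicative and
  the turbidity veil is additive, and both are stationary in frame
  coordinates; left in place they bias every correlation toward zero
  radial displacement, which compounds into a systematic scale drift of
  the panorama. Subtracting a local mean (Gaussian, σ = 12 px) and
  dividing by the local contrast removes smooth shading of either kind.
  Pixels outside the FoV are first filled with their nearest interior
  value so the black border contributes no artificial edges.
* **Coarse descriptors.** Soft-binned gradient-orientation channels
  (8 bins, linear interpolation between bins), smoothed at σ = 4 px so a
  descriptor tolerates displacements anywhere within its 8-px cell, pooled
  over 4×4 blocks of fine cells together with mean intensity (144
  dimensions). Descriptors are centred by the per-frame mean and
  ZCA-whitened across the frame's valid cells before L2 normalization:
  raw orientation histograms are all-positive and highly collinear, and
  without whitening the dual softmax drowns genuine matches in
  near-duplicate competitors.
* **Fine descriptors.** Normalized 5×5-px luminance patches; their inner
  product behaves like a local normalized cross-correlation, which
  localizes displacement far better at this scale than pooled histograms.
* **Cell validity.** Coarse cells need ≥ 50% coverage of an FoV mask
  eroded by 4 px, so border-smear content never enters matching.
* **Equivariance.** All filters use circular (wrap) boundary modes and
  gradients are circular central differences, so the whole backend
  commutes exactly with cyclic translation — a property the test suite
  checks to 1e-6.

Temperatures: `τ = 0.05` for the coarse dual softmax. The whitened
handcrafted descriptors carry genuine-match similarities of ~0.7–0.9
rather than a learned encoder's near-1.0, and at `τ = 0.1` the dual
softmax dilutes those below `θ_c = 0.5`; 0.05 is the operating point at
which the standard `θ_c = 50%` gate separates true from spurious matches
for this backend. The fine softmax uses `τ_f = 0.02`.

## Homography estimation

The relative homography is fitted in three stages, all seeded and
deterministic:

1. **RANSAC** (projective, 8 d.o.f.; reprojection threshold 3 px, ≤ 2000
   trials, confidence 0.995) on the descriptor-driven matches, refit on
   all inliers by least squares. An affine model is configurable.
2. **Guided re-matching.** Every valid coarse cell of A is projected into
   B by the current estimate and re-refined locally; this sidesteps the
   grid descriptors' blind spot at displacements near half a coarse cell.
3. **Patch correlation.** Each cell's 19×19-px LCN-luminance patch is
   correlated at 1-px steps in a ±3-px window around its prediction, with
   the local plane projected out of every patch and parabolic sub-pixel
   peak interpolation; the resulting correspondences (correlation ≥ 0.5,
   clear of the FoV border) drive the final robust fit, run twice.

Only stage 3 is *discriminative*: stages 1–2 construct candidates around
their own prediction, so a refined estimate is trusted only if the patch
stage confirms it with at least the minimum inlier count. A
constant-motion prior (the previous accepted relative homography) seeds
the same chain whenever the descriptor-driven fit fails or is implausible;
occluded or unrelated frames still fail because no prior can conjure
correlation peaks.

Tracking is declared lost when estimation fails, the confirmed inlier
count falls below 10, or the relative corner displacement exceeds 40% of
the frame width (an implausible single-step jump).

## Mosaic construction and blending

Global homographies are chained from the accepted relatives (first frame
anchors the canvas; the anchor is configurable). Each frame is warped
bilinearly onto an auto-growing canvas and accumulated with per-pixel
exposure-fusion weights: local contrast × well-exposedness (a Gaussian of
intensity around 0.5, σ = 0.2) × a radial taper falling to zero at the FoV
border. The panorama is `accum / weight` where weight > 0. Single-scale
weighted accumulation keeps the mosaic incremental while suppressing the
dark circular seams that endoscopic vignetting would otherwise leave at
frame borders.

## Keyframes and relocalization

While tracked, a keyframe store summarizes the visited placenta. The first
frame is the first keyframe; a new keyframe is added when the fraction of
the last keyframe's descriptors still MNN-matched in the current frame
falls below `T_discard = 10%` (a fraction of the keyframe's descriptor
count, making the rule frame-size-free). Consecutive keyframes whose
pooled global features lie closer than `T_KF = 1300` are deduplicated,
keeping the earlier one.

The global feature is the mean of the raw (pre-whitening) coarse
descriptors over valid cells, multiplied by a backend calibration factor
(`global_scale = 6e5`). The 1300 threshold is inherited from a learned
backbone's feature scale; the calibration was set once, from the measured
distance distributions of the synthetic reference scene (near-duplicate
views ≈ 600, distinct views ≈ 2400 after scaling), so the threshold
operates in the regime it was designed for. With a different backend both
numbers should be recalibrated together.

After a loss, each incoming frame is ranked against the store by
global-feature distance; the top 3 candidates are fully re-matched
(with a relaxed `θ_c = 0.2`, since a returning frame may be rotated,
scaled or corrupted) and the candidate whose registration gathers the most
confirmed inliers — at least 10 — re-registers the frame as
`G_lost = G_keyframe · H_{lost→keyframe}`. The pooled global feature ranks
views only coarsely, so the geometric verification, not the ranking, makes
the final choice; accepting the first candidate that merely clears the
minimum occasionally latched onto a vessel-pattern alias. On failure the
frame stays lost and the next frame is tried.

## Evaluation

* **SSIM** uses the canonical parameters (11×11 Gaussian window, σ = 1.5,
  C1 = (0.01 L)², C2 = (0.03 L)², L = 1) on the luminance channel,
  averaged over the evaluation mask eroded by the window radius.
* **SSIM_5** warps frame *i* into frame *i+5* through
  `G_{i+5}^{-1} · G_i` and evaluates SSIM on the intersection of the FoV
  masks (pairs spanning a lost frame, or with fewer than 1000 overlap
  pixels, are skipped and reported). Consecutive fetoscopic frames barely
  move, so the 5-frame gap is what makes the measure drift-sensitive.
* **Success rate** is `100 · #correct / #total` over relocalization
  trials. On synthetic data a recovery is *correct* when the recovered
  global homography lands within 5 px mean corner reprojection error of
  the simulator's ground truth — an explicit operationalization of what
  is otherwise judged by visual inspection.
* **Drift** (synthetic only) is the mean corner reprojection error of the
  composed global homographies against the ground-truth chain.
* A paired Wilcoxon signed-rank helper is provided for comparing two
  methods' SSIM_5 lists; it is routine statistics, not part of the
  pipeline.

## Synthetic scenes

No fetoscopy videos are publicly deposited, so the generator emulates the
named challenges with exact ground truth. A reddish low-frequency placental
background with mid-frequency detail and fine villous speckle is threaded
by darker branching vessel walks (density 5% by default, grown until the
vessel mask reaches the requested coverage, each tree capped at 0.8% of
the raster). The camera follows a momentum-smoothed Gaussian random walk
(translation σ = 2 px/frame, momentum 0.85, rotation σ = 0.2°, zoom
σ = 0.2%, tiny perspective drift, optional one-frame jumps), reflected at
the texture bounds so the footprint always stays inside. Rendering applies,
in order: bilinear texture sampling under the ground-truth homography, a
quadratic radial vignette (default strength 0.6), a turbidity veil with
Gaussian noise (default 0.3), a drifting saturated laser dot (2% of frame
width), the circular FoV mask, and occlusion intervals ("full": uniform
gray + noise; "partial": a dark occluder covering ≥ 65% of the FoV). One
integer seed drives texture, trajectory and rendering.

What the generator does **not** emulate: tissue deformation (maternal
breathing, fetal movement), specular highlights and floating particles,
lens distortion, rolling shutter, compression artifacts, and genuinely
non-planar geometry beyond a small perspective term. Passing the synthetic
benchmarks therefore demonstrates the pipeline's geometric and algorithmic
correctness under the listed photometric challenges, not clinical-grade
performance on in-vivo video.

## Problem sizes and defaults

The reference fixtures are 100-frame sweeps of 256-px frames over a
1024-px texture (80 frames for the occlusion fixture, with a full
occlusion at frames 45–49); the relocalization benchmark runs 20 seeded
trials, alternating pristine and distorted (±10° rotation, ±10% scale,
σ = 0.02 intensity noise) copies of random non-keyframe frames. On these
fixtures the pipeline typically tracks every frame with a mean corner
drift of 1–2 px clean and ~2 px under full artifacts, mean SSIM_5 ≈ 1.0
clean and ≈ 0.87 with artifacts, and a 100% relocalization success rate.
`scripts/acceptance.py` recomputes all of these from scratch for any seed.

## Known limitations

* Sub-pixel refinement by softmax expectation has a floor of a few
  hundredths of a pixel set by fine-descriptor correlation; per-keypoint
  identity is exact only to ~0.1 px (the homography, averaged over
  hundreds of correspondences and polished by patch correlation, is far
  tighter).
* The handcrafted backend is rotation-tolerant only to ~10–15°; a learned
  backend can be plugged in through the registry for more.
* No bundle adjustment or loop closure: drift grows with sweep length as
  a random walk and revisiting a region does not correct it.
* The rigid-planar model is an approximation; deformable registration is
  out of scope.
* The 5-px recovery-correctness budget is shared with the mosaic's own
  drift: on long sweeps a geometrically fine relocalization can still
  score as incorrect when the keyframe's global registration has drifted
  a few pixels, and distorted copies near the rotation limit occasionally
  fail outright.
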