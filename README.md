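# fetomosaic

Mosaicking and occlusion recovery for fetoscopic video.

Fetoscopic laser surgery for twin-to-twin transfusion syndrome (TTTS) is
performed through an endoscope with a tiny circular field of view, under
turbid amniotic fluid, uneven illumination and sparse vascular texture.
`fetomosaic` stitches such video into a placental panorama and — unlike a
plain stitcher — keeps a keyframe map of the visited placenta so that after
an occlusion or a tracking loss the camera can be *relocalized* and the
mosaic resumed. It is a library first (with a thin `fetomosaic` CLI), aimed
at surgical-vision researchers who need a reproducible, fully synthetic
testbed with exact ground truth.

## Method in brief

Consecutive frames *A, B* are matched densely and detector-free. A backend
extracts coarse (stride 8 px) and fine (stride 2 px) descriptor grids; the
temperature-scaled score matrix

    S(i,j) = ⟨d_i^A, d_j^B⟩ / τ

is turned into dual-softmax confidences
`P(i,j) = softmax(S(i,·))_j · softmax(S(·,j))_i`, mutual nearest neighbours
with `P ≥ θ_c = 0.5` become matches, and a local softmax-expectation over
fine cells refines them to sub-pixel. RANSAC fits the relative homography
`H_A^B`, which is polished by geometry-guided re-matching and pixel-level
patch correlation; relatives are chained into global maps
`G_i = G_{i-1}·R_i` and frames are blended onto an auto-growing canvas with
exposure-fusion weights (contrast × well-exposedness × radial taper), which
suppresses the dark vignette seams at frame borders.

In parallel a keyframe store is maintained (first frame is a keyframe; a
new one is added when fewer than `T_discard = 10%` of the last keyframe's
descriptors still match; near-duplicates closer than `T_KF = 1300` in
global-feature distance are pruned). After a loss, incoming frames are
ranked against the store by global-feature distance and re-registered
against the best-supported candidate: `G_lost = G_KF · H_{lost→KF}`.

Registration quality is scored with `SSIM_5` (structural similarity between
frame *i* and frame *i+5* after warping through the estimated homographies)
and recovery with the success rate `100 · #correct / #total`; on synthetic
data a recovery is correct when its mean corner reprojection error against
the simulator's ground truth is below 5 px. A built-in generator renders
placenta-like sequences — circular FoV, vignetting, turbidity, laser dot,
vessel trees, occlusions — with exact ground-truth homographies, so every
stage is testable without any data download. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

```bash
python examples/03_build_mosaic.py
```

```
panorama: 326 x 322 px -> scratch/panorama.png
tracked 60/60 frames, 0 lost
mean SSIM_5: 0.8629 over 55 pairs
mean corner drift vs ground truth: 2.28 px
```

Sixty 256-px frames with default artifacts (vignetting 0.6, turbidity 0.3,
laser dot) were stitched into a 326×322 panorama with no tracking loss; a
mean `SSIM_5` of 0.86 under these artifacts and ~2 px corner drift against
the simulator's exact homographies means the registration chain is accurate
to a small fraction of the 256-px field of view. The other examples show
sequence simulation (`01`), pair matching (`02` — the refined homography
reaches 0.34 px corner error on a 2-px camera step) and occlusion recovery
(`04` — five occluded frames are declared lost, the first clean frame is
relocalized and tracking resumes).

The same workflows are scriptable from the shell:

```bash
fetomosaic simulate --n-frames 60 --occlusions "45-49:full" --seed 7 --out seq/
fetomosaic mosaic --frames seq/ --out out/ --recovery
fetomosaic evaluate --mosaic-manifest out/mosaic_manifest.json --gt-manifest seq/ --k 5
```

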