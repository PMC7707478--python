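# Methods

## Scope and model of the data

`octametrics` quantifies en face OCT angiography (OCTA) images of the three
macular vascular slabs — superficial capillary plexus (SCP), deep capillary
plexus (DCP) and choriocapillaris (CC) — and compares two acquisition modes
of the same eye: a single scan volume (V1) and the merged average of four
independently acquired volumes (V4). Images are square 8-bit grayscale
grids, by default 304×304 px covering 3×3 mm (≈9.87 µm/px), with the flow
(decorrelation) signal bright on a dark background. Device-side processing
(flow computation, motion correction, projection-artifact removal, slab
segmentation) is out of scope: the package starts from exported en face
images.

## Vessel binarization (SCP/DCP)

The chain mirrors the widely used ImageJ-style dual-path protocol:

1. **White top-hat**, disk radius 12 px: background flattening. The radius
   is set just above the largest expected SCP vessel caliber (~12 px ≈
   118 µm) so that vessels survive while slowly varying background is
   removed. Borders are edge-replicated; output is guaranteed in
   `[0, input]`.
2. **Path A — Hessian vesselness + Huang threshold.** Frangi tubularity
   (β = 0.5, γ auto = half the maximal Hessian norm, bright-on-dark), max
   over scales {0.5, 1, 2, 3} px, rescaled to [0, 255], then a global
   threshold minimizing the Huang–Wang fuzzy entropy over all 256 histogram
   levels (ties → smallest threshold; foreground strictly above it). The
   sub-pixel 0.5 scale matters: without it the vesselness response inside
   capillary cores and large-vessel interiors falls below the global
   threshold and recall collapses on phantoms with known truth.
3. **Path B — median local threshold.** Foreground where a pixel exceeds
   the median of its (2·15+1)² edge-replicated square neighborhood minus an
   offset (default 0). This path assumes vessels are the local minority;
   where the local vessel fraction exceeds ~50% the window median sits on
   the vessel intensity and recall drops — one reason the path is never
   used alone.
4. **Combination.** Pixelwise AND (configurable OR). AND suppresses the
   single-path false positives: path B marks ~half of any textured
   background, path A is blind to non-tubular structure; their intersection
   keeps only agreed vessel pixels.

All radii, scales, levels and the combination rule live in
`BinarizationParams`; every step and parameter is recorded in the output's
`method_chain`.

## Vascular metrics

* **PD (%)** = 100 · |mask| / |frame|.
* **VLD (%)** = 100 · |skeleton| / |frame|, where the skeleton is
  Zhang–Suen topology-preserving thinning of the mask. Length is measured
  in skeleton pixels (the ImageJ convention); a Euclidean variant (√2 per
  diagonal link) is available but non-default.
* **VDI (px)** = |mask| / |skeleton| — mean caliber in pixels; identical to
  PD/VLD because both share the frame denominator, and this identity is
  asserted in tests. Optional µm conversion uses the image scale.

The analyzed area is always the full frame: no foveal avascular zone or
large-vessel exclusion.

## Choriocapillaris flow deficits

The CC image is binarized with the Phansalkar local threshold — designed
for bright, low-contrast textures — with the standard constants k = 0.25,
r = 0.5, p = 2, q = 10 and a circular radius-15 window on intensities
normalized to [0, 1] (edge-replicated borders). The complement of the flow
mask is the signal-void map; its 8-connected components are the flow
deficits. No minimum-size floor is applied by default (a configurable floor
exists for sensitivity analyses). Reported: deficit count, per-deficit
areas (px² and %), and total void area as a percent of the frame; flow% +
FD% = 100 exactly.

## Agreement statistics

Differences are oriented V1 − V4 throughout.

* **Paired test**: Shapiro–Wilk on the differences at α = 0.05 gates
  between the paired t-test (normal) and the Wilcoxon signed-rank test.
  All-zero differences return p = 1 with a degeneracy flag; constant
  nonzero differences short-circuit to p = 0 (the t statistic diverges).
* **Lin's CCC**: ρc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with biased (1/n)
  moments; precision ρ (Pearson) and accuracy C_b = ρc/ρ; 95% CI via
  Fisher z with Lin's corrected asymptotic variance. Categories: poor
  < 0.90 ≤ moderate < 0.95 ≤ substantial ≤ 0.99 < perfect (boundaries 0.90
  and 0.95 are left-closed; exactly 0.99 is substantial).
* **Bland–Altman**: bias = mean difference, limits of agreement
  bias ∓ 1.96·s_d (sample SD), bias 95% CI via Student t; the bias is
  flagged significant when zero lies outside its CI.

The report builder pairs arms by `eye_id` (row order is irrelevant),
excludes eyes missing one arm per metric with a logged count, and skips
metrics entirely absent from the cohort.

## Synthetic phantoms

No public OCTA dataset accompanies the quantification protocol, so the
package ships a seeded generator whose outputs are pure functions of
(spec, seed):

* **SCP**: a handful (default 6) of thick, gently curved vessels crossing
  the frame (calibers 6–12 px) plus a meandering capillary mesh (1–3 px)
  added tube by tube until the mask fraction reaches the density target.
* **DCP**: thin capillaries only, their random walks steered toward the
  image center, emulating the radially converging vortex arrangement of
  that plexus.
* **CC**: band-limited granular bright texture (mean 150, SD 30) with
  irregular dark elliptical patches, smoothed and re-thresholded, as
  ground-truth flow deficits.

Tubes are rendered along random-walk centerlines with two fields: an exact
anti-aliased edge field re-thresholded at 0.5 (the boolean ground-truth
mask, so `mask ⇔ distance ≤ caliber/2` exactly) and a rounded
circular-cross-section intensity profile (vessels peak at 230 over a
20-level background). The rounded profile matters: flat-plateau tubes have
zero interior Hessian response and defeat any vesselness filter, which real
smooth vessel profiles do not. Ground-truth PD/VLD/VDI are recomputed from
the stored masks (centerline = skeleton of the mask), so truth is
self-consistent by construction.

**Density targets** default to 0.30 for both plexuses. This is deliberately
below the published PD of real cohorts (~57–70%): those numbers describe
pipeline *output* on noisy images, not a tissue ground-truth area fraction,
and the median-local path structurally requires vessels to be the local
minority. The CC void-fraction target defaults to 0.25.

**Noise.** Acquisition is simulated per frame as multiplicative speckle
`pixel · (1 + ε)`, ε ~ N(0, σ²) with σ = 0.35 (relative), plus an additive
Gaussian floor of SD 8 intensity levels so dark background is noisy too;
a V-mode image is the pixelwise mean of `n_volumes` independent frames
(V1: one, V4: four — halving the noise SD), clipped to [0, 255]. A pure
additive Gaussian model is available for analytic tests. The σ default is a
calibration knob, not an instrument claim: it was fixed once at a level
where a single volume visibly fragments capillaries (mean Dice against
truth ~0.80 vs ~0.83 for V4) and then frozen. Under it, averaging
reproduces the qualitative clinical findings — PD and VDI rise, VLD and CC
flow-deficit area fall — through the expected mechanism: speckle breaks
vessels (PD↓), ragged fragment boundaries spawn skeleton spurs (VLD↑),
hence VDI = PD/VLD drops, and dark speckle in the CC texture creates
spurious signal voids (FD↑).

**Cohorts** jitter each eye's density and caliber targets by ±10% relative
so paired statistics see between-eye variance; per-eye seeds derive from a
master seed via `SeedSequence`.

What the phantoms do **not** emulate: true coherent speckle statistics
(Rayleigh/K-distributed), inter-frame registration error, motion or
projection artifacts, a foveal avascular zone, flow-velocity-dependent
signal, or anatomically calibrated vessel topology. Passing recovery and
direction tests therefore shows the pipeline is internally correct and
responds to noise the way the clinical comparison reports — not that its
absolute outputs match any particular device.

## Numerical choices and degenerate inputs

* Huang threshold: candidates are every histogram level with non-empty
  classes on both sides; S(0) = S(1) = 0; constant images raise (no
  threshold exists). Thresholding is strict (`> t`), making an all-zero
  image after top-hat/vesselness an explicit failure rather than an
  arbitrary mask.
* Phansalkar on an all-zero image yields t = 0 everywhere and hence all
  void; on a uniform image of normalized value c it reduces to the closed
  form t = c·(1 + p·e^(−qc) − k).
* Empty skeleton makes VDI undefined and raises; empty mask gives PD = 0.
* CCC requires both arms non-constant; |ρc| = 1 collapses the CI to a
  point. Bland–Altman with zero-variance differences collapses the limits
  onto the bias.
* Phantom generation fails loudly, naming achieved vs requested fraction,
  if the density target is not reached within ±20% relative after a
  bounded number of tubes/blobs.

## Problem sizes

Default test and reproduction runs use 304×304 px images, 28-eye cohorts
(168 images), 100-image oracle sweeps on 16×16 px inputs, 1000-replicate
type-I-error simulation at n = 28, and n = 10⁴ for limits-of-agreement
coverage. A full simulate–quantify–report cycle on the default cohort takes
a few minutes on one core; smaller `image_size` (≥64 px) scales everything
down for quick experiments.
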