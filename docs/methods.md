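# Methods

`dielgrow` quantifies plant growth from grey-value time-lapse stacks of a
seedling's leaf and root, and aggregates the resulting series into
day/night (diel) statistics. This note documents the models, the numerical
choices, what the synthetic scenes do and do not emulate, and the problem
sizes used by the test suite and the acceptance script.

## Optical flow by the spatiotemporal structure tensor

Leaf growth is measured from dense 2-D velocity fields estimated under the
brightness-constancy assumption: a material point keeps its grey value, so
`g_x·u + g_y·v + g_t = 0` at every pixel. Gradients are Gaussian
derivatives at scale `grad_sigma` (default 1.0 px and 1.0 frame). The
per-pixel 3×3 structure tensor `J = ⟨∇g ∇gᵀ⟩`, averaged over a Gaussian
window (`window_sigma`, default 4.0 px spatially and 1.5 frames
temporally), is eigendecomposed; the eigenvector of the smallest
eigenvalue is the spatiotemporal direction of least intensity change,
i.e. the direction of motion `∝ (u, v, 1)`. This total-least-squares
solution treats all three derivatives symmetrically, unlike local
least-squares variants that single out `g_t`.

Quality gates, all applied before a pixel enters any downstream average:

* coherence `(λ₂ − λ₃)/(λ₂ + λ₃ + ε)` must reach `confidence_threshold`
  (default 0.3); `ε = 1e-12` throughout;
* the aperture-problem gate: if `λ₂ − λ₃ < 1e-3·λ₁` the pixel's full
  velocity is unrecoverable (image structure varies in one direction only)
  and it is marked invalid rather than assigned the normal flow, which
  would bias divergence estimates;
* a border margin of `⌈3·window_sigma⌉` px is always invalid — no
  extrapolation past the image edge;
* a globally constant stack yields an all-invalid field and a warning,
  never silent numbers.

A two-level coarse-to-fine pyramid with inter-frame warping recovers
displacements beyond the ~1 px/frame linearisation range. Coarse levels
engage only when they detect significant motion (90th-percentile level
displacement ≥ 0.3 px/frame at full scale): for sub-pixel motion the
coarse pass contributes nothing but warping/resampling error, which
measurably biased divergence estimates of slow expansions before this
gate existed.

## Leaf relative growth rate

The areal relative growth rate (RGR, h⁻¹) over a polygonal area of
interest (AOI) is computed two independent ways and reported side by side:

* **divergence method** — mean of `∂u/∂x + ∂v/∂y` (central differences on
  the confidence-masked, lightly smoothed field; pixels adjacent to an
  invalid pixel are excluded) over the AOI interior, converted from
  frame⁻¹ to h⁻¹. For isotropic expansion at areal rate `r` the divergence
  equals `r` exactly.
* **area method** — `(ln A₁ − ln A₀)/t` from the areas of the AOI polygon
  advected vertex-by-vertex along the flow across the analysis window.

Windows tile the stack from frame 0 (default ≈ 15 min; overlapping windows
available via an option). Requiring the two estimators to agree (within 2%
of the truth scale on clean renders, 5% under noise) is the module's
self-check: they share the flow but differ in everything after it.
Vertex displacements at invalid pixels are filled from the nearest valid
pixel — leaf edges routinely fail the confidence gate. A self-intersecting
advected polygon is repaired by a zero-width buffer (convex hull as the
last resort) with a logged warning; a degenerate one stops the series with
a tracking-lost error and the failing frame index.

## Root tip velocity

Root elongation is defined as the speed at which the tip moves away from
the mature, spatially fixed part of the root — a point-tracking notion, so
it is measured geometrically rather than from the flow field (flow at the
advancing tip edge is unreliable: the background pixels there violate
brightness constancy). Per frame:

1. **Segmentation**: Otsu threshold after a 1-px Gaussian denoise;
   polarity (dark root on bright background or the inverse) is
   auto-detected by testing which side of the threshold produces an
   elongated largest component (major/minor axis ratio ≥ 3).
2. **Provisional tip**: the skeleton endpoint at maximal geodesic
   (along-skeleton) distance from the anchor, found by Dijkstra over
   skeleton pixels — Euclidean distance would pick the wrong end of a
   C-shaped root. Short spurs (skeletonisation artifacts) are pruned;
   two endpoints at indistinguishable geodesic distance raise an
   ambiguity error listing both candidates (lateral-root case).
3. **Sub-pixel apex**: an axial grey profile through the provisional tip
   fixes the plateau levels (as plateau means, not percentile extremes,
   whose order-statistic noise would shift every measurement of the
   frame at once) and a first apex estimate; a perpendicular profile just
   behind the apex gives the local half-width; finally a soft-edged
   capsule model (axis segment dilated by a radius, logistic edge) is fit
   to the raw grey values of the whole tip patch by least squares, and
   the apex is the cap-circle point farthest along the growth tangent.
   Fitting every pixel of the cap edge, rather than a handful of 1-D
   profiles, is what brings the per-frame localisation noise to a few
   hundredths of a pixel. The growth tangent comes from a PCA of the
   skeleton near the tip, averaged over ~31 frames — the tip direction
   rotates at curvature × tip speed, which is slow against that span.
4. **Anchor registration**: the anchor patch is tracked against frame 0 by
   upsampled phase cross-correlation; the shift series is smoothed
   (rig drift is slow — smoothing keeps correlation noise out of the
   verdict) and, if the drift exceeds 2 px, subtracted from the tips.
5. **Windows**: tips are Savitzky–Golay smoothed (13 frames; the series
   ends are re-estimated by a longer linear fit because polynomial
   endpoint extrapolation amplifies noise exactly at the first and last
   window boundaries). Per 5-min window, frame steps are projected on the
   window's net growth direction (so noise perpendicular to growth
   cancels), steps beyond 5× the window median are clamped to the median,
   and the summed path over the window duration gives mm h⁻¹ via the
   pixel calibration. When the net displacement is below the noise floor
   the projection direction falls back to the skeleton tangent, keeping
   the static-root estimate zero-mean instead of rectified-positive.
   The straight-line (chord) velocity is reported alongside the
   along-path value; for curved roots the path is the meaningful number.

Unsegmentable frames leave gaps that are interpolated over when they stay
under 10% of the stack (with a logged quality warning); more than half
unsegmentable aborts with a quality error.

## Diel statistics

A sample is diurnal iff its clock time lies in `[light_on, light_off)` —
half-open, light-on inclusive. Windowed series are assigned by their
centre time (unbiased for symmetric windows). An experimental "day" starts
at light-on and comprises one light period plus the following dark period,
pairing each day with its subsequent night. Period means are arithmetic
means per (day, period) cell; an empty cell is an explicit missing marker,
never zero. Daily normalisation reports shares that sum to exactly 100
(`diurnal_share = 100 − nocturnal_share` by construction). Standard errors
are across replicate plants — time windows are first averaged per plant
within each cell — using the n−1 sample standard deviation over √n, with
n < 2 marked undefined. Treatment effects are `100·(T − C)/C` per matched
cell. No hypothesis testing is performed.

## Synthetic scenes and ground truth

Frames are always derived from continuous analytic ground truth, never by
iterated resampling, so no cumulative blur corrupts the truth:

* **Leaf**: a band-limited speckle texture (Gaussian-filtered white noise,
  supersampled ×2, contrast s.d. 35 grey on a mean of 120) sampled at the
  pulled-back coordinates of the material map
  `x → c + exp(S(t)/2)·(x − c)` with `S(t) = ∫ r dτ`; the true AOI area is
  `A₀·e^{S}` exactly and the inter-frame displacement field is closed-form.
* **Root**: a thick smooth curve (arclength-parameterised, constant
  curvature) whose tip advances along the tangent by `v(t)·Δt/pixel_size`;
  intensity is a logistic profile of the distance to the sub-pixel-exact
  centreline, so the grey values encode the tip position below the pixel
  grid. The mature region is pixel-identical across frames by
  construction.
* Additive Gaussian sensor noise only, seeded (`numpy` Generator);
  identical seeds give bit-identical stacks. Photon/shot noise, optical
  blur drift, vignetting and 3-D projection effects are not modelled —
  passing tests therefore demonstrate correct recovery of the stated
  motion models under sensor-like noise, not robustness to every artifact
  of real imagery (specular highlights, condensation, leaf flutter).

**Treatment presets** encode the study conditions as generator settings,
12 h : 12 h light-dark, lights on at 08:00:

* *control*: root velocity 0.6 mm h⁻¹ with a small transient light-on dip
  (depth 0.15 mm h⁻¹, 30 min);
* *cooling*: constant 0.3 mm h⁻¹ (root growth suppressed but arrhythmic);
* *illumination*: a morning trough (0.25 mm h⁻¹ base rising by smoothstep
  from 1 h to 9 h after light-on to 0.48) plus a post-dusk dip (depth
  0.15, 2 h) on a 0.43 mm h⁻¹ night base — diel mean ≈ 0.40 mm h⁻¹ with
  day and night means within ~10% of each other.
* The leaf RGR profile is identical across presets (leaf growth was
  treatment-insensitive): diurnal plateau 0.012 h⁻¹, nocturnal 0.036 h⁻¹
  (3×), a sharp light-on transient (150% of the nocturnal level over
  20 min, briefly negative — leaves transiently shrink at light-on) and a
  ×0.85 day-by-day decline. With the dip, the realised nocturnal:diurnal
  ratio is ≈ 3.2 and the nocturnal share ≈ 76%.

Dip depths and recovery constants are artifact choices shaped to the
qualitative phenomenology; only the period means above are fixed design
values. Pixel calibrations default to 0.02 mm/px (leaf) and 0.01 mm/px
(root) — plausible bench values, flagged as arbitrary since no
calibration is inherent to the method.

## Problem sizes and tolerances

The test suite and the acceptance script run on deliberately scaled
scenes chosen to exercise every code path at full fidelity:
flow oracles on 256×256×20 translations; leaf RGR recovery on a 4-h,
90-s-cadence expansion at 160×160 (`r = 0.015 h⁻¹`; both estimators within
5% of truth, 2% of each other); root recovery on 30–40-min slices at the
native 30-s cadence (per-window error ≤ 5%, ≤ 10% at SNR 10); and a full
simulate → analyze → summarize chain over a 2-h light-off-straddling
excerpt per preset. The acceptance script covers complete 24-h diel
cycles by coarsening the cadence (root: 180 s at 0.02 mm/px with 15-min
windows and a gentler path curvature so the tip stays in frame; leaf:
300 s with 30-min windows) — the estimators are cadence-agnostic, and the
coarsened runs keep the whole script under ten minutes on one CPU.

## Known limitations

* The flow engine is local; it will underestimate displacements past
  ~2 px/frame at the default two pyramid levels (raise `pyramid_levels`).
* Tip tracking assumes a single unbranched root; lateral roots surface as
  ambiguity errors rather than being resolved.
* The capsule apex model assumes a rounded tip of roughly constant width;
  strongly tapered or damaged tips degrade to the axial-profile estimate.
* Diel aggregation assumes the light schedule is exact; no attempt is
  made to infer light transitions from the imagery.
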