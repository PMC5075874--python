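# Methods

This note documents the models and procedures implemented in `wormchip`, the
parameters that matter, the design decisions taken where the problem was
genuinely open, and what the synthetic benchmarks do and do not demonstrate.

Throughout, *darkness* means `1 − normalized intensity`, so "darker" is
always a larger value; coordinates are row-major and 0-based.

## Imaging model and segmentation

Bright-field frames of a shallow micro-pillar chamber show worms as dark
elongated bodies on a light background (fluorescence frames show them
bright). The chamber height prevents worms from crawling over one another,
so worm pixel sets never overlap — the single most important constraint in
the whole analysis.

**Masking.** The local background is estimated with a large-window
low-percentile rank filter (window 101 px, 25th percentile, on uint8). A
median was rejected: where a cluster of worms covers most of the window the
median tracks the worms and erodes the cluster interior; the 25th percentile
stays on the background as long as worms cover less than ~75% of the window.
A pixel is a worm pixel when its darkness exceeds the local background by
`max(k·σ, min_contrast)` with `k = 3`, σ the MAD-based robust SD of the
residual, and `min_contrast = 0.04` (an absolute floor so noiseless images
do not degenerate to a zero threshold). Components below a speck floor of
16 px are dropped unconditionally; a debris cutoff of 0.2× the typical
component area (the mass-weighted median, so numerous small progeny blobs
cannot drag it down) removes eggs and progeny that pass the chamber's worm
filters. Holes are filled (worm gut interiors can be bright), and components
are 8-connected. Boundaries are traced with a Moore-neighbor walk, clockwise
from the topmost-leftmost pixel, terminated by Jacob's criterion.

**Area model.** With 30–35 worms per chamber, single-worm components
dominate the component-area distribution, so the single-worm area is
estimated as a robust center of the dominant low-area mode: the median of
areas below 1.6× the overall median. (An earlier histogram-mode variant with
0.25×-median bins proved unstable at the handful-of-components scale — bin
ties and 25% worm-size dispersion could shift the estimate by 40%.) The
single-worm length ruler is the mean skeleton arclength of components within
±30% of the area estimate, and the single-worm half-width is the median
medial distance-transform value over those same components. A component of
area *A* holds `max(1, round(A / single_worm_area))` worms.

## Separating touching worms

The separation cascade turns one multi-worm component into per-worm pixel
sets:

1. **Body parts.** The component is skeletonized; skeleton pixels whose
   medial half-width (Euclidean distance transform) is at most
   `width_factor = 1.3`× the single-worm half-width and that are not branch
   points form *body parts* — narrow stretches that can only belong to one
   worm. The remaining skeleton pixels (thick zones and branch points) form
   *junctions*. Part endpoints within 2 px of a junction are attached to it.
   The 1.3 factor tolerates posture-driven width variation while excluding
   two-body contact zones (width ≈ 2×).
2. **Turn-angle prohibition.** The signed turn angle at boundary pixel *i*
   is the angle between the chords `(i−w)→i` and `i→(i+w)` with window
   `w = 5 px`; turns above 70° are flagged sharp. A worm's bending radius is
   bounded by its body stiffness — genuine silhouettes rarely exceed ~60°
   over such a window — so sharp turns mark worm–worm contact notches. The
   contour is partitioned into runs owned by the nearest body part; for two
   parts adjacent along the boundary (their runs separated only by a gap
   near the junction), the pairing of their endpoints is prohibited when
   every connecting gap contains a sharp turn. A *smooth* gap is recorded as
   positive evidence instead: one silhouette continuing past the junction.
3. **Endpoint matching.** At each junction, non-prohibited endpoint pairs
   are scored by ½·(tangent continuity) + ½·(alignment of the displacement
   with the tangents) − 0.6·(relative body-width mismatch), plus a bonus of
   1.0 for smooth-gap pairs. The width term is anatomical: width varies
   slowly along a body, so joining a tapered tip to a mid-body part is
   implausible. The maximum-total-score partial matching is found by
   exhaustive enumeration (junctions have ≤ 10 endpoints; more endpoints
   flag the junction unresolved). A junction with exactly two attached parts
   cannot be resolved by turn angles at all — the end-to-end case — so its
   parts are connected whenever the continuation is minimally plausible and
   the length ruler decides later. Matched parts are walked into medial
   *chains*, bridging junction gaps with straight segments; cycles are
   broken at their weakest bridge, and chains shorter than 0.35× the ruler
   are dropped as junction debris.
4. **Worms per chain.** Each chain's worm count uses the stronger of two
   signals: medial length / ruler (robust for end-to-end strings of small
   worms) and territory area / single-worm area (robust for side-by-side
   contacts, whose merged skeleton is shorter than the sum of the midlines).
   Rounding is biased slightly downward (`floor(x + 0.4)`) because junction
   pixels inflate single-worm chains. A chain that is substantially wider
   than one body over a sustained stretch holds at least two worms
   regardless of the noisy counts, and a component whose area-based count
   says "one" still enters the cascade when its skeleton is much longer than
   the ruler or locally much wider than one body (two small touching worms
   can have the area of one average worm).
5. **Cutting and pixel assignment.** Component pixels are assigned to their
   geodesically nearest chain by multi-source BFS inside the mask (never
   Euclidean, so assignment cannot leak across a worm lying between). Chains
   holding *n* > 1 worms are cut into *n* pieces of equal medial arclength,
   with each cut snapped to the narrowest point within a ±15% window —
   worm–worm contacts are width constrictions, which also makes the cut
   insensitive to unequal worm lengths. Interior constrictions deeper than
   0.65× the chain's own body width override the counts outright for
   near-single-width chains (they are direct observations of tip-to-tip
   contacts). A sustained double-width chain counted as two is instead split
   *across* its midline (left/right of the medial path), since for a
   side-by-side pair the merged midline runs along the contact. Each chain's
   territory is finally subdivided among its pieces by a second BFS.

Single-worm components skip the cascade and return their exact pixel set
with confidence `isolated`; other instances carry `resolved`, `chain_split`
or `unresolved`. Failures are flags, never exceptions, and
`render_debug_overlay` exports the parts / junctions / sharp-turn picture
for any component.

On the benchmark conditions (200 clusters of 2–5 worms, mixed side and end
contacts, length 100 ± 15 px, width 10 ± 2 px, default configuration) the
cascade recovers 82–88% of clustered worms at IoU ≥ 0.7 depending on seed;
`scripts/acceptance.py` recomputes this. Failures concentrate in 4–5-worm
piles, where junction matching is over-constrained and worm-size dispersion
makes counts ambiguous — consistent with the method's known failure mode of
many worms clumped in one component.

## Viability and time of death

A worm's *opacity* is the mean darkness over its pixel set. The default
adaptive threshold is the mean darkness of a dilation ring around the
instance (width 10 px ≈ one worm width, excluding all worm pixels; if the
ring is fully occupied the frame's non-worm mean is used and flagged) plus
the standard deviation of the whole frame's darkness. `opacity ≤ threshold`
means dead — the boundary convention makes the dead set closed and ties
deterministic. A fixed-scalar mode (`viability.fixed_threshold`, default
0.30) sits behind a config switch; the band 0.25–0.40
(`viability.threshold_range`) is the range over which the dead/alive call is
expected to be robust, bracketing the adaptive rule's typical value in the
generator's default scenes.

Time of death is the first observation from which the worm stays dead
(missing-from-mask counts as dead — a fully degraded cadaver is not
segmentable). A dead→alive flicker is logged as an anomaly and the last
alive→dead transition used. Because a cadaver's contrast halves every hour
(below), any threshold in the configured band is crossed within ~2 frames of
the true death hour; the benchmark verifies ≤ 2 h error for ≥ 95% of 50
simulated worms across the whole band.

## Fluorescence, motility, population statistics

Total fluorescence per worm is the sum over the instance's pixels of
(intensity − background), clamped at zero per pixel, with background the
median of non-worm pixels. Motility is measured literally from a ~1-s frame
pair: the fraction of the worm's pixels in the *later* frame not covered by
worm pixels in the earlier frame (the later-frame area is the denominator;
instances of the later frame are paired to primary-frame instances by
overlap, which is unambiguous at 1-s displacements). Population summaries
give per-time empirical CDFs, means and SDs, and pairwise two-sample
Kolmogorov–Smirnov tests between time points; groups under 3 worms carry a
low-n flag.

## Survival curves

Chip mode: S(t) = alive(t)/n₀ with binomial SE (Greenwood's formula reduces
to this with no censoring). Counts that transiently rise from segmentation
jitter are corrected with a pool-adjacent-violators isotonic fit. Death
times are interval-censored by the 1-h imaging interval; an event is
assigned to the frame at which the dead call first holds (right endpoint).
Plate mode: the hand-rolled product-limit estimator with Greenwood SE;
subjects censored at time *t* remain at risk for deaths at *t*, and
assay-end survivors are censored at the final frame. With zero censoring the
two estimators agree to floating-point precision (an acceptance identity).
Both binomial and Greenwood errors are available since published plate-assay
error bars rarely state which was used. Curve comparison reports median
survival (first S ≤ 0.5 with linear interpolation; a curve never reaching
0.5 reports the sentinel `>Tmax`) and, when event records exist, the
log-rank test (via lifelines, which also serves as the independent oracle
for the estimator in the test suite).

## The synthetic generator

The generator is first-class, tested code: it defines the conditions under
which every claim above is measured.

- **Worm bodies**: damped-sinusoid heading `θ(s) = θ₀ + A·d(s)·sin(2πfs/L + φ)`
  (A ∈ [0.1, 0.5] rad, f ∈ [0.8, 1.5], amplitude decaying 40% toward the
  tail) integrated into a midline, swept into a tube of width *w* with
  elliptic end tapers over `max(w, 0.12·L)`. Self-intersecting draws are
  rejected and retried. Defaults: length 100 ± 15 px, width 10 ± 2 px.
- **Placement**: cluster members are placed in side or end contact with a
  random already-placed member by stepping along an approach line until
  8-adjacent (never overlapping — the device-height constraint); non-cluster
  worms keep a ≥ 2 px gap. Placement failures raise an error naming the
  cluster after bounded retries.
- **Appearance**: background darkness 0.08; alive worm darkness 0.65 ± 0.04;
  hexagonal pillar lattice (pitch 55 px, radius 6 px, darkness 0.11 —
  slightly dark disks, drawn beneath worms since in projection a worm
  occludes the pillars it crawls over); additive Gaussian noise, SD 0.02.
  Thresholding the noiseless image at the alive/background midpoint recovers
  ≥ 99% of live-worm pixels.
- **Death**: a cadaver's darkness decays exponentially toward background
  with a 1-h half-life, leaving 6% of the contrast after 4 h — dramatic
  fading within hours, and fast enough that every threshold in the
  configured band is crossed within ~2 frames of death. (A 2-h half-life
  was considered and rejected: it leaves a quarter of the contrast at 4 h
  and delays the dead call by 3–4 h at plausible thresholds, contradicting
  the ≤ 2 h robustness the workflow is built around.)
- **Time lapse**: hourly frames; each hour renders a ~1.3-s pair in which
  live worms translate by a per-worm speed (2–5 px) with collision-checked
  moves; dead worms stop. Optional debris blobs (< 20% of a worm's area)
  exercise the size filter. Identical specs (including seed) render
  bit-identical outputs.

**What the generator does not emulate** — and hence what passing benchmarks
do not show about real data: optics (no point-spread function, defocus,
vignetting or anti-aliased edges), within-worm texture (gut granules are
reduced to a per-worm mean darkness), worm locomotion between hours (bodies
jitter but do not crawl, so contact topology is more static than reality),
bacterial suspension, biofilm, and stage-stitching artifacts. Pixel
calibration is arbitrary: no µm/px scale is implied.

## Benchmark problem sizes

Chosen so each suite runs comfortably on one CPU: 200 clusters (≈ 620
worms) for the separation benchmark; 5 scenes × 10 worms × 30 hourly frames
for time-of-death robustness; 20 thirty-worm scenes for area-model recovery
(mean relative error ≤ 10%; individual scenes scatter ±6% from 30-worm
sampling alone); 50 seeds × 30 worms for exponential-death recovery; a
5-worm 12-frame assay for determinism. The full test suite runs in about
two minutes.

## Known limitations

- Worm identity is not tracked across hourly frames; per-worm time series in
  the benchmarks use generator ground truth for correspondence, and survival
  counting is population-based (exact on a chip, where worms cannot leave).
- Dense piles (≥ 5 worms in one component) often leave unresolved junctions;
  the result is flagged, not guessed.
- The area-based worm count is noisy at ±1 when worm sizes vary by ±25%,
  which bounds the separation success rate more than junction resolution
  does for 2-worm clusters.
- Frames are assumed pre-stitched and registered; proprietary microscope
  formats and OME metadata are out of scope.
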