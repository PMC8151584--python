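# Methods

## Normalized cross-correlation matching

The similarity between the template `T` (W×H, nominally 200×144) and the
image window with top-left corner (x, y) is

    r(x, y) = Σ_{x',y'} T'(x', y') · I'(x + x', y + y')

with both patches mean-centered and scaled to unit sum of squares:

    P'(x', y') = (P(x', y') − mean(P)) / sqrt(Σ (P(x'', y'') − mean(P))²).

This is the Pearson correlation of the two pixel vectors.  The
mean-centered denominator is essential: it is what bounds every coefficient
in [−1, 1] (Cauchy–Schwarz) and makes the score invariant under affine
intensity changes `a·I + b` (a > 0) of the window — the property that makes
matching robust to the trap's uneven top illumination.  A variant that
divides by the root of the *raw* squared sums has neither property; this
package uses the mean-centered form in both factors.

Two code paths compute the map.  `match_template_naive` is the literal
double loop over all placements and defines the contract.
`match_template` is algebraically identical but vectorized: the numerator
`Σ T_c · window` (with `T_c` the centered template; centering the window is
unnecessary in the numerator because `Σ T_c = 0`) is a cross-correlation,
evaluated directly for small problems and by FFT above ~2·10⁶ multiply–adds;
per-window means and energies come from integral images, whose cumulative
sums are exact in double precision for 8-bit-scale data.  The two paths
agree to better than 1e−9, and both agree with
`skimage.feature.match_template`, which the tests use as an independent
oracle only.

Degenerate windows (zero variance, e.g. inside a constant padded border)
carry no match evidence; their coefficient is defined as 0 — below any
sensible threshold, and finite so the map's min/max remain well defined.  The
flatness test is relative (`window energy ≤ 1e−9 · Σ window²`), so it is
stable under intensity rescaling.  A constant *template* is an error.  All
correlation math is in float64 regardless of input bit depth.

## Padding

Before matching, the frame is enlarged by the template's dimensions —
⌊W/2⌋ columns left, W−⌊W/2⌋ right, ⌊H/2⌋ rows top, H−⌊H/2⌋ bottom — so a
1280×960 frame becomes 1480×1104 and the correlation map covers
(1480−200+1)×(1104−144+1) placements.  Symmetric placement gives border
targets context on all four sides; it also makes the coordinate bookkeeping
trivial (a padded-map peak at (x, y) *is* the target center (x, y) in
original coordinates, since the half-template shift and the padding offset
cancel).  The border fill is the frame's median intensity by default — a
robust estimate of the dark-cloth background that avoids the spurious
high-contrast edges a zero fill would create; constant and edge-replicate
fills are available.  Whether the original imaging rig padded symmetrically
or on two sides only is not knowable from the outside; symmetric is this
package's choice.

## Multi-target extraction (covering)

The map's global minimum is recorded once, before any covering.  Then,
iteratively: take the global maximum (ties broken in raster order — smallest
row, then column — for determinism); stop if it is below the threshold;
otherwise emit a detection and overwrite the cover_width×cover_height map
region centered on the peak (defaults: the template dimensions, clipped at
map borders) with the recorded minimum.  Using the pre-covering minimum, not
a per-iteration recomputed one, keeps the fill strictly below threshold
whenever any value is, so each iteration strictly removes the current
maximum and the loop terminates; `max_detections` (default 100, far above
plausible per-frame insect counts) guards the pathological all-above-threshold
case.  With covering disabled the detector returns at most one target —
the single-template baseline of the ablation.

The correlation threshold defaults to 0.4, the best rate/accuracy trade-off
among {0.4, 0.45, 0.5} in the original trap study; the optimum on other
data is unknown, so it is an exposed config knob.

## ROI shape classification

Each detection's template-sized window (shifted inward at borders so it is
always full size) passes through:

1. **Normalization** — linear rescale to [0, 255]; constant windows map to
   zeros.
2. **Binarization** — Otsu's threshold; the *minority* pixel side is the
   insect.  The trap scene is dominated by background, so this holds for
   both bright-on-dark and dark-on-bright contrast, making the mask
   polarity-invariant.  Exact ties take the brighter side.
3. **Morphology** — binary opening then closing, 3×3 square element, one
   iteration each.  Deliberately minimal: larger elements erase the one/
   two-pixel leg and wing structures that drive the features.  (The 3×3
   opening already removes 1-px-wide legs; the body and narrow wings retain
   enough thinness for the features to separate the classes.)
4. **Largest component** — 8-connected (thin diagonal appendages stay
   connected); area ties go to the component earliest in raster order.
5. **Features** — `area` = all pixels of the hole-filled component;
   `perimeter` = filled pixels with an 8-neighbor in the background,
   pixels outside the window counting as background (equivalently, the
   pixels an 8-connected erosion removes).  These are pixel *counts*, not
   polygonal arc lengths.  Note the discretization consequence: for
   rasterized disks `perimeter²/area` converges to ≈ π/2 · 4π rather than
   the continuum 4π, while thin shapes approach `perimeter ≈ area`; the
   ordering the classifier relies on is preserved.
6. **Decision** — mosquito iff `perimeter/area ≥ θ₁` **and**
   `perimeter²/area ≥ θ₂` (inclusive).  The dimensionless ratio captures
   shape alone; adding the size-sensitive ratio sharpens the separation.

θ₁ = 0.2165 and θ₂ = 38.0 are the midpoints between the per-class mean
features of 200 seeded synthetic insects at the default generator settings
(`scripts/calibrate_thresholds.py` reproduces them; the class ranges are
disjoint — mosquito ratio1 ≈ [0.24, 0.32] vs. bee ≈ [0.14, 0.17] — so the
midpoint sits in a wide margin).  They are stand-ins for an operating point
that would be re-calibrated on real captures, and live in the config.

## Evaluation

Greedy one-to-one matching by center distance, closest pairs first, within
`tol` (default W/2 = 100 px), which makes the counts independent of
detection order; on well-separated targets it coincides with optimal
assignment (tested against `scipy.optimize.linear_sum_assignment`).  TP = a
mosquito-labeled detection matched to a mosquito; FN = a mosquito annotation
without one; FP = a mosquito-labeled detection matched to a non-mosquito or
to nothing.  Recall, precision and the F-measure follow; zero denominators
raise rather than silently reporting 0.  Counting is per insect, not per
image.  Percentages are displayed to one decimal; internal values are exact.
The ablation table reports the label-blind detection rate (matched
annotations / all annotations) for single-template, +covering, and
+covering+padding modes.

## Synthetic scenes

The generator emulates the trap's imaging conditions: background intensity
30 with a +40 top-to-bottom linear gradient (the illuminator sits above),
additive Gaussian noise σ = 5 clipped to [0, 255], insects at +140 contrast
(negative contrast supported), all in 8-bit intensity units.  Mosquitoes are
a 60×8 px body ellipse with six 1-px legs and two narrow wing ellipses at
scale 1; bees a 44×28 px body ellipse plus a round head.  Benchmarks sample
orientation uniformly, scale in [0.9, 1.1], and a mosquito fraction of
71/122 ≈ 0.58 by default.  Difficulty regimes: `easy` (interior placements,
center separation ≥ the template diagonal), `edge-cases` (first insect
straddling a frame border, 5–25 px inside), `noisy` (σ = 12, contrast 90).
Everything derives from `numpy.random.default_rng(seed)`: identical specs
give bit-identical scenes.

What the generator does *not* emulate: motion blur, defocus, occlusion and
overlapping insects, specular glints, debris, species variety beyond the
two silhouette classes, and template/insect appearance mismatch beyond pose
and scale.  Passing results on these scenes therefore demonstrate that the
algorithmic chain is correct and self-consistent, not that the operating
point transfers to arbitrary field imagery; thresholds would be
re-calibrated on real captures.

## Problem sizes and numerical choices

The test suite runs most detection batches at half scale (640×480 frames,
100×72 template, insect scale 0.5) — the pipeline is size-parametric, and
those batches exercise the identical code paths the full-resolution spot
checks cover.  `scripts/acceptance.py` uses a 40-scene full-resolution easy
benchmark, 50 half-scale edge scenes, a 30-scene mixed ablation batch and
200 feature samples; all sizes are constants at the top of the script.
Tolerances: the fast and naive correlation paths must agree to 1e−9;
map values must lie in [−1, 1] ± 1e−9; flat-patch energy cutoff 1e−12
(absolute) and 1e−9 (relative to raw energy).

## Known limitations

- A single fixed template: no multi-scale or rotation-invariant matching.
  Rotated synthetic mosquitoes still correlate ≈ 0.45–0.55 against the
  canonical template — above the 0.4 threshold, but with less margin than
  aligned ones.
- The covering region is a fixed rectangle; two targets closer than half a
  template can suppress each other.
- Shape thresholds are size-sensitive through ratio1, so classification
  assumes the roughly constant imaging distance the trap geometry enforces.
- No texture, color or learned features; species beyond the
  mosquito/other dichotomy are out of scope.
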