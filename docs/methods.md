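# Methods

This note documents the models behind `lvstrain`: the synthetic phantom
and its error models, the two contour-measurement chains, the clinical
metrics, the agreement statistics, the numerical choices, and what the
validation on the phantom does and does not demonstrate about real data.

## Phantom geometry

The cavity is the cap of a prolate ellipsoid.  Slice `s` (0 = most
basal) sits at long-axis offset `z_s = (s + ½)·d` with `d` the effective
slice spacing; its resting (end-diastolic) radius is

    r0(s) = R · sqrt(1 − (z_s / c)²)

with `R` the maximal cavity radius (`base_radius`) and `c` the cap
semi-axis (`cap_half_height`).  Contraction follows a raised-cosine
half-cycle `g(f) = (1 − cos(π f / (F−1))) / 2`, so frame 0 is exactly ED
(`g = 0`) and the last frame exactly ES (`g = 1`); any monotone 0→1
profile would serve, the raised cosine is chosen for smoothness at both
ends.  The radius of slice `s` at frame `f` is

    r(s, f) = r0(s) · (1 + ε_region(s) · g(f)),

with per-region peak strains `ε` (negative).  Because every
cross-section is a circle, the per-slice perimeter strain equals the
radius strain exactly, and perimeters, areas, volumes, LVEF and all
regional strains have closed forms against which the measurement chain
is tested.

Defaults (9 slices × 10 mm, 16 frames, `R = 28 mm`, `c = 100 mm`, peak
strains −0.30 / −0.20 / −0.12 for base / mid / apex) emulate a dilated
ventricle on the scale of the porcine heart-failure studies this
pipeline targets: EDV 162 mL, ESV 97 mL, LVEF 40%, GCS −20.7%.  The
long-axis positions of the slices within the cap are a free parameter of
the model; the half-spacing offset schedule used here keeps the most
apical slice well inside the cap so no slice degenerates.

## Reader error model

Simulated tracing error has two components, both radial:

1. **Session offset** (`reader_bias_sd`, default 0.6 mm): one normal
   draw per (reader, software, repetition) session, added to every
   contour of that session.  This is the dominant error mode in human
   contouring — a reader who traces tight on one image tends to trace
   tight everywhere — and it is what gives the simulated groups a
   realistic between-reader spread (≈ 4–6 % of the mean for the volumes
   at the default setting, matching the scale reported in multi-reader
   CMR studies).  Because the offset is shared by the ED and ES frames
   of a session, it largely cancels in LVEF and the strains, which is
   the mechanism that makes the relative metrics reproducible.
2. **Angular noise** (`reader_noise_sd`, default 0.5 mm;
   `reader_noise_modes`, default 3): a smooth zero-mean perturbation
   `δ(θ) = Σ_k a_k cos kθ + b_k sin kθ` (k = 1..modes) drawn
   independently per contour, with the realized field rescaled so its
   angular SD is exactly `reader_noise_sd`.  Human tracing errors are
   spatially correlated, hence a few low-order Fourier modes rather than
   per-marker white noise.  The field has no k = 0 term, so it does not
   bias the perimeter to first order.

The automated session is rendered with both components set to zero: an
algorithm is assumed perfectly repeatable, and downstream the single run
is duplicated into both repetition slots (flagged `duplicated`).

Not modelled: slice-position dependence of reader difficulty (real
readers disagree most at the apex), motion/through-plane artefacts,
papillary muscles and trabeculation, and any greyscale image content.
Passing tests therefore demonstrate that the measurement and statistics
chain is correct and that it propagates biases the way the model
predicts — not that any particular software package behaves like the
simulated one.

## Software length bias

Each simulated package carries a contour-length offset in cm.  Two modes:

- **proportional** (default): the radius is scaled by
  `1 + bias_cm · 10 / (2π · r̄)`, where `r̄` is the grand mean of the
  noise-free radius over all slices and frames, so the length offset
  averaged over the study equals the configured value exactly while
  individual contours are offset in proportion to their size.  This is
  the behaviour real package comparisons show — Bland–Altman differences
  that grow with the mean — and it leaves the size-normalised metrics
  (strains, LVEF) invariant, reproducing the observed pattern of large
  volume differences with preserved relative metrics.
- **additive**: a uniform radial offset `bias_cm · 10 / 2π` mm,
  identical for every contour.  Useful as the textbook constant-bias
  case (it yields zero-width limits of agreement in the noise-free
  Bland–Altman), but a full-strength uniform offset also shifts LVEF by
  several points and inflates apical strain, because a constant does not
  cancel in a ratio of unequal lengths.

Defaults: 0 cm for the reference manual package, −1.9 cm for the second
manual package, −0.6 cm for the automated one, reproducing the three
pairwise biases such comparisons report (−1.9, +0.6, −1.3 cm).

## Randomness and reproducibility

Every contour's noise stream is keyed on
(seed, reader, repetition, CRC32(software), slice, frame), and each
session offset on (seed, tag, reader, repetition, CRC32(software)), via
`numpy.random.SeedSequence`.  Sessions are therefore independent,
insensitive to generation order, and bit-reproducible from the master
seed; regenerating a study reproduces every mask bit-exactly.
Replicated experiments derive per-replicate seeds from
`SeedSequence([base_seed, replicate])`.

## Measurement chains

**Spline chain** (marker contours).  A closed periodic C² cubic spline
is interpolated through the markers with uniform chord-length
parameterization (the vendor dialects are unspecified, so the dialect is
a documented choice; the closed-polygon fallback handles collinear
degenerate frames, and three markers are reported as their triangle
since they carry no curvature information).  The reference evaluator
densely resamples the interpolant (200 samples per segment; relative
arc-length error ≪ 1e−4) and applies the shoelace formula for the area.
A batched evaluator solves the same periodic spline system for a whole
contour stack at once (cyclic tridiagonal solve with a Sherman–Morrison
correction) and integrates the arc length with 8-point Gauss–Legendre
quadrature per segment and the enclosed area with the exact
Green's-theorem integral of the cubic segments.  The two agree to ~1e−7
relative; the batched path is what the replicated simulations use.

**Hull chain** (binary masks).  Foreground pixels are taken at their
centers, `(i + ½)·spacing` (the pixel-corner lattice is available as an
alternative convention; the two differ by about one pixel of
perimeter), and the convex hull polygon of those points provides both
the perimeter and the area.  Degenerate masks (< 3 non-collinear
pixels) report zero with a warning rather than aborting a batch; an
empty mask is an error.  For any convex shape the hull of an interior
point set is shorter than the curve it approximates, so the hull chain
systematically underestimates perimeters relative to the spline chain —
the representation-level component of inter-software bias, asserted as
an invariant on the phantom.

All lengths are converted mm → cm (and areas → cm²) once, at
measurement time.

## Clinical metrics

Volumes use composite midpoint integration (area × effective slice
spacing, summed).  ED and ES are the frames of maximum and minimum total
volume, earliest frame on ties.  The strain reference length `L0` is
taken at the single global ED frame for every slice, since ED is defined
from the summed volume curve.  Regional curves average slice strains
within equal thirds of the stack; with equal regions the global curve is
identically the mean of the three regional curves (a property that holds
frame-wise, not for the peaks: the extremum of a mean is not the mean of
extrema).  Reported peaks take the regional curve first and its minimum
second; the alternative order (per-slice peak, then average) is exposed
as `peak_mode="per_slice_peak"`.  The two coincide for the phantom's
monotone curves and differ under noise; which one a published "peak"
value means is generally ambiguous, so the default is documented rather
than asserted.

## Agreement statistics

Group summaries use the sample SD (n−1) and t-based 95% CIs.  Paired
comparisons report the mean of attempts (mean of the two per-reader
averages), the paired mean difference (identical to the difference of
group means, by pairing), its SD, SD as % of the mean of attempts, and
the two-sided paired-t p-value; zero-variance differences are flagged
degenerate with an undefined p rather than a fabricated one.  Sign
conventions: repetition 1 − repetition 2 within a package, first-listed
package − second-listed between packages, and Bland–Altman "A vs B"
reports mean(A − B) so a negative bias reads "towards A".  The
Bonferroni divisor defaults to the number of metrics (7 ⇒ threshold
0.05/7, reported as 0.007 after the 3-decimal reporting convention);
limits of agreement use the fixed 95% multiplier 1.96.  Bland–Altman
analyses are run per repetition and pooled, since an automated package
duplicated across repetitions makes the per-repetition split the
conservative view.

No mixed-effects or ICC analysis is attempted; the schema (long tables
keyed by reader/software/repetition) does not preclude adding one.

## Validation experiments and problem sizes

- **Bias recovery**: 200 replicated default studies (28 manual sessions,
  4032 contours each) with the −1.9 cm injection; the pooled
  Bland–Altman bias estimate is unbiased to within three standard
  errors.  The residual second-order interaction between angular noise
  and arc length (shorter contours accumulate slightly more noise length
  per unit radius) is of order 0.005 cm ≈ 0.3 % and sits well inside the
  Monte-Carlo spread contributed by the session offsets.
- **Cancellation**: standardized shifts (paired Cohen's d of the
  per-reader software differences) pooled over 20 replicated studies;
  the smaller of the EDV/ESV shifts exceeds the larger of the LVEF/GCS
  shifts by well over 5×. Pooling is needed because seven readers give
  an unstable SD estimate on their own.
- **Type-I control**: with no injected bias, the Bonferroni-flagged
  fraction over replicated reduced studies stays below the family-wise
  α = 0.05 (checked at 3 slices × 5 frames × 3 readers × 60 studies to
  keep the suite fast; the t-tests' validity does not depend on the
  stack size).
- **Geometry oracles**: spline perimeter of a sampled circle to 0.1 %;
  hull perimeter/area of a rasterized 20 mm disc at 0.5 mm spacing to
  1 % / 2 %; the 11×11-pixel square hull is exact by construction; hull
  error decreases monotonically with pixel spacing from 2 mm to 0.25 mm.

## Known limitations

- Circular cross-sections only; no short-axis eccentricity, so the
  spline dialect differences between vendors (tension, parameterization)
  are exercised only weakly.
- The proportional bias model applies one scale factor per package; real
  inter-software differences also vary by slice level (apex vs base).
- Strain is endocardial circumferential only — no radial, longitudinal,
  or mid-wall strain, and no feature-tracking analogue.
- The NIfTI dialect stores one 4-D volume per session with an axis-
  aligned affine; oblique orientations are out of scope.
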