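# Methods

## Scope and model

`bronchoquant` measures a single airway on one axial CT slice in Hounsfield
units (HU).  All geometry is in physical millimetres; pixel (row r, col c)
has its centre at `origin + (c·s, r·s)` for spacing `s`, and continuous
positions are defined by bilinear interpolation between pixel centres.
Out-of-image queries clamp to the edge value and taint the consuming
profile, which is later discarded.  The user supplies a seed point inside
the lumen; a 3-D airway tree or centerline is out of scope, and measurements
are purely in-plane.

From the (iteratively refined) centre, 128 equally spaced rays sample the
slice at 0.1 mm steps out to 15 mm — enough to cover airways up to ~12 mm
total diameter plus the outer plateau.

### The blurred-edge model

Along a ray the ideal airway is lumen (air), wall (soft tissue), parenchyma.
The scanner blur is modelled as an isotropic Gaussian of SD `σ`.  Because
the airway borders are closed curves, the profile of each blurred border is
not the 1-D error function but the radial profile of a blurred disc of
radius `c`:

    D(x; c, σ) = P(|x·e + z| ≤ c),  z ~ N(0, σ²I₂)

— a Marcum-Q function, evaluated as the noncentral chi-square CDF with two
degrees of freedom.  This matters: for a lumen of radius 1.3 mm at
σ ≈ 0.65 mm, fitting the planar (CDF) limit instead mis-measures wall
thickness by over 40%.  The planar model is retained as the
`curvature_correction=False` limit and as the analytic oracle in tests.
Under curvature correction the lumen level is fixed at air (−1000 HU): the
sampled centre of a small lumen is itself raised by blur and no longer
measures the lumen density.

### Effective blur

The profiles do not see the scanner PSF alone: pixel-box integration adds
variance `s²/12` and bilinear resampling adds about `s²/6`, so detection
uses `σ_eff² = σ_psf² + s²/12 + s²/6`.  Free-σ fits on noiseless renders
(0.649 mm at σ_psf = 0.6, s = 0.5) agree with this to better than 1%.

### Integral-based edge localization

Starting from FWHM edge estimates (or a pooled per-airway starting pair,
see below), the inner and outer border are alternately solved by bisection
so that the model's trapezoidal integral over the lumen-side window
`[c_in − 4σ, peak]`, respectively the outer-side window
`[peak, c_out + 4σ]`, equals the measured profile's integral over the same
window.  Window integrals are monotone in the edge position, so each 1-D
equation has a unique bracketed root; the alternation stops when both edges
move < 0.01 mm (at most 5 rounds).  Brackets extend one blur width past the
peak sample because the peak position is only grid-accurate.  The integral
criterion is blur-invariant, which is why thin walls are not overestimated
the way half-maximum placement overestimates them.

### Wall density

The model needs a wall density `W`.  For walls thinner than the blur, the
density and the thickness are jointly unidentifiable — all integral
relations (1-D window integrals and the exact 2-D polar identity
`2∫(y−HU_p)·x dx = (W−HU_p)c_out² + (HU_l−W)c_in²`) constrain essentially
the product `(W − HU_l)·WT`, and shape differences fall below raster
systematics.  The default therefore **fixes W at 0 HU** (water-like soft
tissue), the standard assumption of this method family; the resulting
thickness bias is approximately `WT·(W_true − W)/(W − HU_l)`, i.e. ~5% per
50 HU of true deviation from soft tissue.  Two estimating modes remain
available: `auto_model` (least-squares fit of the edge model on the
ray-pooled median profile with the density concentrated out and a weak
soft-tissue ridge prior, 0 ± 75 HU) and `auto_max_peak` (tallest eligible
wall peak, clamped to [−300, 200] HU — reliable only for walls several
blur widths thick).

### Ray validity and vessel handling

A ray is untrusted when it left the image (`border_taint`), its outer
plateau is missing or brighter than −500 HU — parenchyma cannot be that
bright, so the ray runs into a vessel or mediastinum (`bright_outside`) —
its wall peak rises less than 100 HU above the outer plateau
(`low_prominence`), or the integral solve fails (`order_violation`).
Prominence is referenced to the outer plateau because contrast with the
surrounding tissue is what failure depends on; once the airway-level
(pooled-profile) prominence passes the threshold, the per-ray cut is halved
so that rays at the detection margin are not selected on their noise, which
would bias the thickness median.

On `bright_outside` rays the outer border is unrecoverable, but an
inner-only solve is still attempted — with the ideal model's belief (the
airway-level parenchyma plateau) on the far side.  Enhancement smeared into
the wall inflates the measured window integral relative to that model and
drags the detected inner point toward the lumen; heavy contrast defeats the
solve entirely and the ray has no detectable inner point.  This reproduces
the characteristic failure of the method next to vessels, graded by the
vessel's attenuation, and it is the mechanism behind the contrast-phase
bias study.

### Contour completion and metrics

The two algorithms differ only here.  The *standard* rule fits a
least-squares ellipse (direct conic fit) through **all** detected inner
points — including contaminated vessel-adjacent ones — and intersects each
pointless ray with it.  The *modified* rule takes the median attenuation at
the trusted inner points and walks every untrusted ray outward to the first
position reaching that median (linear interpolation between samples),
falling back to the ellipse for rays that never reach it.  A third
algorithm, `fwhm`, uses half-maximum edges with ellipse completion, so the
three differ only in the edge/completion mathematics.

Missing outer points are completed as inner point + median wall thickness
along the ray.  Metrics: lumen area = shoelace area of the inner 128-gon;
wall area = outer polygon area − lumen area; total diameter = mean distance
between the 64 antipodal outer-point pairs (an equivalent-circle diameter is
available behind `td_mode`); wall thickness = median border distance over
fully trusted rays only — completed rays contribute to contours and areas
but never to thickness.  The centre is refined to the inner-polygon centroid
(at most 5 rounds, 0.1 mm tolerance).

## The phantom

The generator renders parenchyma (−850 HU), an optional vessel disc, a wall
annulus (0 HU) and an air lumen (−1000 HU), supersamples 8× per pixel edge,
convolves with the Gaussian PSF **at the supersampled resolution** (blurring
on the coarse grid would alias edge positions by up to ±0.04 mm with
sub-pixel alignment), box-averages to the pixel grid, and adds white
Gaussian noise from a seeded generator — rendering is a pure function of the
spec.  Defaults mirror the in-vivo setting: 0.5 mm pixels, σ = 0.6 mm for a
soft kernel, 20 HU noise.  Vessel attenuation presets per contrast phase:
non-enhanced 32 HU, pulmonary-arterial 725 HU, systemic-arterial 503 HU,
venous 96 HU.  A negative vessel gap presses the vessel into the wall band
(the wall is painted over it), producing the extended shared contact arc of
a bronchus–artery pair; the phase-study default embeds it by half the wall
thickness.  Vessels reaching the lumen are rejected.

What the phantom does **not** emulate: non-circular airway cross-sections,
oblique airway orientation, cardiac motion, beam hardening, correlated CT
noise, and the textured parenchyma of a real lung.  Passing tests therefore
demonstrate correctness of the measurement machinery and the direction and
ordering of contrast-induced biases — not the in-vivo bias magnitudes,
which depend on contact geometry and airway shape.

## Studies

* **Accuracy sweep** — vessel-free phantoms over the realizable grid of
  wall thickness 0.3–2.5 mm × total diameter 2.6–9.0 mm (a lumen of more
  than 0.5 mm radius must remain), blur 0.6 mm, noise 20 HU, three seeded
  repeats per point; reports the per-point mean relative wall-thickness
  error of the standard method and its grid maximum.  The sweep relaxes the
  seed-point lumen check to −300 HU because small blurred lumina never reach
  the default −900 HU while remaining measurable.
* **Phase study** — one airway of the in-vivo size (total diameter 11.5 mm,
  wall 1 mm) with a comparable vessel in contact, rendered per phase ×
  noise repeat (seed + repeat index), measured with both algorithms;
  reports per-phase means and differences from the non-enhanced baseline
  (Δ, Δ%).  Inferential statistics are deliberately not reproduced.

## Numerical choices

Supersampling 8×; blur truncated at 4 SD with reflective padding; disc
profiles tabulated over a 0.02 mm radius grid per measurement and linearly
interpolated; bisection depth 40; peak ties resolved to the innermost
sample; crossings located by linear interpolation so reported positions are
continuous millimetres.  Degenerate inputs raise: seeds outside a dark
lumen, vessels overlapping the lumen, fewer than five points for a conic
fit, inverted contours.

## Known limitations

Wall densities far from soft tissue bias the default fixed-density
thickness estimate proportionally.  Wall-area is the metric most sensitive
to raster orientation near a vessel (completion sector size quantizes to
whole rays).  Airways below ~2 mm total diameter approach the information
limit of 0.5 mm pixels; accuracy there rests on the curvature-aware model
being exactly right for circular cross-sections.
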