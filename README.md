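# bronchoquant

Quantitative CT airway morphometry on single axial slices, built around an
integral-based wall-segmentation method (IBM) and a modified contour
completion rule that reduces the bias caused by adjacent — especially
contrast-enhanced — pulmonary vessels.

## The problem

Airway dimensions measured on chest CT (lumen area, wall thickness, wall
area, total diameter) inform studies of COPD, asthma and cystic fibrosis.
Two things corrupt these measurements:

1. **Blur.** Scanner optics and soft reconstruction kernels smear the thin
   airway wall; the common full-width-at-half-maximum (FWHM) edge rule then
   overestimates wall thickness badly for sub-millimetre walls.
2. **Adjacent vessels.** Where an artery runs in contact with the bronchus
   there is no parenchyma behind the wall; wall detection fails there, and
   with iodinated contrast in the vessel the smeared enhancement drags the
   detected lumen border toward the airway centre, shrinking every metric.

## The methods

From a user-supplied lumen seed point, 128 radial density profiles are cast.
Along each ray the wall is described by an ideal two-edge model: lumen level
`HU_l`, wall density `W`, outer level `HU_p`, edges at `c_in` and `c_out`,
each blurred by a Gaussian point-spread function of SD `σ`:

```
f(x) = HU_p + (W − HU_p)·D(x; c_out, σ) + (HU_l − W)·D(x; c_in, σ)
```

where `D(x; c, σ)` is the radial profile of a disc of radius `c` under 2-D
Gaussian blur (a Marcum-Q function; it tends to the normal CDF `Φ((c−x)/σ)`
for radii much larger than `σ`).  Starting from FWHM estimates, `c_in` and
`c_out` are solved by **integral matching**: bisection adjusts each edge
until the model's integral over a window on the lumen (resp. outer) side of
the wall peak equals the measured profile's integral over the same window.
Because integrals are preserved under blur, the estimate is insensitive to
`σ` — the property that lets the method resolve walls thinner than the blur.

Rays that run into a vessel or leave the image carry no trusted measurement.
The two algorithms under comparison differ only in how the inner (lumen)
contour is completed there:

* **standard IBM** — a least-squares ellipse through all detected inner
  points (including contrast-contaminated ones near the vessel);
* **modified IBM** — the median attenuation at the trusted inner points is
  taken as a threshold, and each untrusted ray's lumen border is placed at
  the first position (from the centre outward) reaching that threshold.

Metrics: `LA` = shoelace area of the inner polygon, `WA` = outer polygon
area − LA, `TD` = mean antipodal outer-point distance, `WT` = median
per-ray border distance over trusted rays only.

The package also contains a synthetic phantom generator (air lumen at
−1000 HU, soft-tissue wall at 0 HU, parenchyma at −850 HU, an optional
vessel disc pressed against the wall, Gaussian blur, Gaussian noise) with
closed-form ground truth, and two scripted studies: a contrast-phase bias
study (vessel at 32/725/503/96 HU for the NE/PA/SA/VE phases) and a
wall-thickness accuracy sweep.

## Worked example

```python
from bronchoquant import PhantomSpec, render_phantom, ground_truth, measure_airway

spec = PhantomSpec(lumen_radius_mm=4.75, wall_thickness_mm=1.0,
                   vessel_radius_mm=5.0, vessel_gap_mm=-0.5,
                   vessel_hu=725.0, noise_sd_hu=20.0, seed=1)
img = render_phantom(spec)
truth = ground_truth(spec)                      # TD 11.50, LA 70.88, WT 1.00
for alg in ("standard_ibm", "modified_ibm"):
    m = measure_airway(img, spec.airway_center, alg)
    print(f"{alg}: TD={m.TD_mm:.2f} LA={m.LA_mm2:.2f} "
          f"WA={m.WA_mm2:.2f} WT={m.WT_mm:.3f} valid_rays={m.n_valid_rays}")
```

prints (pulmonary-arterial enhancement, vessel at 725 HU):

```
standard_ibm: TD=11.06 LA=65.31 WA=31.26 WT=0.995 valid_rays=105
modified_ibm: TD=11.45 LA=70.38 WA=32.53 WT=0.994 valid_rays=105
```

The true lumen area is 70.88 mm²: the bright vessel pulls the standard
ellipse completion inward (−7.9% LA), while the modified median-HU rule
stays within 0.8%.  On the same scene with a non-enhanced vessel (32 HU)
the two algorithms differ far less.

The same operations are available from the shell:

```
bronchoquant simulate --config phantom.yaml --seed 1 --out slice.nii
bronchoquant measure slice.nii --seed-point 20,20 --algorithm standard_ibm,modified_ibm
bronchoquant experiment phases --outdir reports/
bronchoquant experiment accuracy --outdir reports/
```

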