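# Methods

This note documents the models, conventions and numerical choices
behind `ctstrain`: what is computed, under which assumptions, and what
the phantom validation does and does not demonstrate.

## Geometry conventions

Label volumes carry a 4×4 voxel-to-world affine in mm with a
**voxel-centre** convention: the affine maps 0-based voxel indices to
the world coordinates of voxel centres, and a world point belongs to
the voxel whose centre is nearest. Reslicing samples labels with
nearest-neighbour lookup only — interpolating integer labels is
meaningless — so a resliced boundary is exact up to half a voxel. The
default in-plane pixel spacing equals the smallest voxel dimension (no
resolution is lost at the boundary, which feeds directly into
perimeter accuracy); the slice extent defaults to the labelled
bounding box plus a 12 mm margin.

## Contour extraction and the three perimeter methods

A boundary pixel is an LV pixel with at least one non-LV 4-neighbour;
the boundary of the largest 8-connected LV component (holes filled) is
ordered into a closed chain by a Moore-neighbourhood walk and reduced
to exactly the 4-boundary pixels. The mitral interface is the run of
boundary pixels with an LA pixel in their 8-neighbourhood; removing it
opens the contour between the two mitral insertions. If a slice
contains no LA the contour stays closed and the view is flagged
non-compliant rather than failing the study.

* **naive** — polyline through the chain's pixel centres; diagonal
  steps contribute √2·spacing. This metric has an intrinsic staircase
  bias: for smooth convex shapes it overestimates the true length by
  ≈4–5.5% depending on shape and sampling phase (the theoretical mean
  for circles is 5.48%). The bias largely cancels in the LS ratio but
  not in the presence of phase-varying artefacts.
* **hull** — the LV mask is closed with a Euclidean disk structuring
  element (default radius 10 px) and filled to its convex hull; the
  perimeter is the boundary chain of that mask, measured like the
  naive one. Measuring the chain (not the hull polygon) keeps the
  digitisation/texture sensitivity that the spline is then shown to
  remove, and makes the hull and naive lengths agree on convex regions.
  The closing is computed as two distance-transform thresholds
  (dilate = EDT(¬M) ≤ r, erode = EDT(·) > r), which is exactly
  equivalent to the disk structuring element but ~100× faster at these
  slice sizes. The radius is specified in pixels, so the physical
  smoothing scale follows the slice resolution; both are configurable.
* **spline** — the hull-mask chain is opened at the mitral interface
  with the two insertion pixels retained as end knots, downsampled by
  keeping every 5th point (both endpoints always kept), and fit with a
  cubic spline parameterised by cumulative chord length. End
  conditions are natural (zero second derivative) at the insertions;
  a contour with no mitral opening uses a periodic spline instead.
  Arc length is evaluated on a dense sampling (≥20× the knot count).
  Fewer than 8 knots after downsampling falls back to the hull length
  with a warning.

Opening order: the hull is built on the full LV mask first and opened
afterwards, so the hull can never bridge the mitral gap with a
spurious chord.

## ED/ES selection and the strain quantities

ED and ES are chosen once per study as the phases with the largest and
smallest 3D LV voxel volume (earliest phase on ties; a per-view
slice-area option exists behind a flag). LS = (P_ES − P_ED)/P_ED is a
pure ratio, hence invariant to isotropic rescaling of all spatial
units. FAC uses the raw LV pixel area of the slice (not the
hull-filled area). Classification uses the spline LS by default.

## Classification and statistics

Predicted abnormal means LS ≥ τ, with equality counted abnormal
(conservative toward detection). ROC candidate thresholds are the
midpoints between consecutive sorted unique scores plus ±∞, so the
chosen τ is well-defined between classes; the optimum minimises the
Euclidean distance to (0, 1) in (1−specificity, sensitivity) space,
ties resolved toward higher specificity. AUC is the trapezoid over the
ROC points, which equals the Mann–Whitney concordance.

Rates are reported with 95% Wald intervals p ± 1.96·√(p(1−p)/n) on
each rate's own denominator, clipped to [0, 100]%; an undefined rate
(zero denominator) is reported absent rather than NaN. Cohen's kappa
is computed via scikit-learn and Fleiss's kappa via statsmodels; the
two-proportion z-test uses the pooled variance; the R² comparison uses
the plain independent-samples Fisher r-to-z transform, which is an
approximation when both correlations are measured on the same sample
(no dependent-sample adjustment is applied). The linear-fit confidence
band is the pointwise 95% interval of the mean prediction from OLS.

The 16-segment AHA → view mapping ships as an editable table; the
default sends anterior/inferior walls to 2CH, anteroseptal/
inferolateral to 3CH, septal/lateral to 4CH, with apical segments
(13–16) following their wall's view. Segment consensus requires ≥2 of
3 readers non-normal (hypokinetic/akinetic/dyskinetic pooled); a view
is abnormal with ≥1 abnormal mapped segment, a study with ≥1 abnormal
view.

## The phantom

The LV blood pool is a half-ellipsoid (default semi-axes 25×25×45 mm,
flat top = mitral plane) that contracts by an isotropic linear scale
s(t) about the centre of the mitral annulus, so the mitral plane stays
fixed and every long-axis contour scales exactly by s: true
LS = s(ES) − 1, FAC = 1 − s², EF = 1 − s³ under uniform contraction.
The default profile is s(t) = 1 − (1 − s_ES)·sin²(πt/n) over n = 10
phases (10% RR intervals), s_ES = 0.8. A fixed half-ellipsoidal LA
(base 27 mm, covering the mitral orifice at all phases) sits above the
plane; LV/LA voxels can only meet face-on across it. The default grid
is 72×72×88 voxels at 1.25 mm isotropic — coarser than a clinical
0.625 mm reconstruction, chosen as the default problem size; finer
grids are configurable and used where sub-voxel artefacts matter.

Three artefact generators emulate the failure modes the smoothing
corrects, with defaults chosen to look like segmented clinical data:

* **papillary muscles** — inward spherical-cap bites (default 2, depth
  6 mm, chord width 14 mm) carved at mid-ventricular level in the
  tissue frame, so they move with the contraction. A cap of depth d
  and width w is a sphere of radius (d² + w²/4)/(2d) centred
  (radius − d) outside the surface along the outward normal.
* **tissue texture** — band-limited random radial perturbation fixed
  in the tissue frame (24 random cosine modes on the sphere, RMS
  0.8 mm, correlation ≈12°, the scale of trabecular structure).
* **frame noise** — an independent perturbation per phase (RMS 0.6 mm,
  about one clinical voxel), emulating each phase being reconstructed
  and segmented independently. Without it, artefacts are coherent
  between ED and ES and cancel in the LS ratio, which no real pipeline
  enjoys.

Regional hypokinesis multiplies the contraction deficit 1 − s(t) by a
reduction factor inside an azimuthal sector (raised-cosine shoulders,
15°), with a polar fade-out of the deficit between 10° and 35° from
the apex: all azimuths meet at the apex, so without the taper the
deformed surface is discontinuous there and leaves a spurious spike in
rendered volumes. Ground truth for regional phantoms is integrated
numerically along the deformed contour (the scale varies along it);
uniform phantoms keep closed forms. With s_ES = 0.8 and deficit factor
0.25 the abnormal wall reaches s = 0.95 at ES — a wall-scale deficit
of 0.15 against the normal wall.

All randomness derives from a single integer seed through spawned
`SeedSequence` children; identical specs produce bit-identical
volumes.

### What the phantom does and does not show

Passing the phantom suites shows the measurement chain is unbiased and
well-ordered under controlled artefacts of realistic magnitude: the
spline LS recovers analytic truth within 0.02 over seeds, R²(FAC, LS)
increases strictly naive → hull → spline on a 100-study population,
and ROC-fitted cutoffs recover separable hypokinesis with
sensitivity/specificity ≥0.9. It does not show clinical performance:
the phantom has no segmentation topology errors, no through-plane
motion of the mitral annulus, no LV outflow tract or trabecular
compaction changes, and its abnormality model is a smooth sector
rather than a coronary territory. Clinical threshold values fitted on
phantoms are not transferable to patients.

## Validation problem sizes

The validation suites use 100-study populations for the R² trend,
20 seeds for strain recovery, 20-study cohorts for cutoff recovery,
and 1.0 mm grids for the per-slice accuracy comparison (at 1.25 mm
parts of the contracted-phase texture fall below the voxel size and
the comparison against the naive method is not meaningful). These are
the package's chosen problem sizes; all are parameters of the
functions in `ctstrain.validation`.

## Known limitations

* The naive chain metric's staircase bias (≈5%) is inherent to the
  pixel-centre polyline definition; no Freeman-style length correction
  is applied because the naive method exists precisely to exhibit the
  uncorrected measurement.
* The convex hull underestimates the true wall where it bridges a
  papillary indentation with a chord — visible as a small negative
  bias of hull/spline perimeters on indented phantoms.
* MAPSE, strain rate, per-segment strain and three-class (hypo- vs
  akinetic) grading are out of scope, as are DICOM ingestion and the
  upstream segmentation/plane-prediction model.
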