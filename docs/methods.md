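# Methods

## Signed surface distance

All discrepancy metrics reduce to signed distances from the vertices of a
*source* mesh to the surface of a *target* mesh. The magnitude is the exact
Euclidean distance to the closest point on the triangle soup (Ericson's
closest-point-on-triangle region test, vectorised over candidate faces). The
sign comes from the angle-weighted pseudonormal at the closest feature
(face, edge or vertex): negative inside the target, positive outside, zero on
the surface. For closed, consistently outward-oriented targets this
classification is exact; targets are therefore *required* to pass a
closed-orientation check (every edge shared by exactly two faces with
opposite traversal, positive enclosed volume) and behaviour on open targets
is undefined by design. Sources may be open (e.g. plane-split halves or guide
walls); only targets must be watertight.

The acceleration index prunes candidate faces with a nearest-vertex upper
bound (kd-tree over mesh vertices) and a per-face bounding-sphere lower bound
(kd-tree over face centroids). Both bounds are conservative, so the candidate
set always contains every face attaining the minimum; ties are broken by
lowest face index in both the pruned and the exhaustive path, and every
arithmetic step is elementwise, which makes the two paths bit-identical —
a property the test suite asserts rather than assumes.

Comparisons are one-directional (source = model under test, target =
reference) and no registration is performed anywhere: real models share the
CT frame, synthetic models share the phantom frame, and any alignment step
would absorb part of the discrepancy being measured.

### Metrics

* **negative HDF** — minimum signed distance over source vertices: the
  deepest penetration of the source into the reference. The raw minimum is
  returned even when positive (no clamping), so means over many comparisons
  keep their sign and their arithmetic stays interpretable.
* **absolute ADE** — mean |signed distance| over source vertices.
* Guide comparisons use the full guide mesh (contact surface, offset outer
  surface, stitched walls) by default; outer vertices only increase the
  maximum distance and cannot affect the negative extremum of a guide that
  fits. A contact-only restriction is available.
* Distal/proximal radius metrics restrict the per-vertex field by the side of
  a plane perpendicular to the reference bone's principal axis, placed
  0.5 mm below the proximal edge of the guide base (configurable offset;
  0.5 mm is below the native slice thickness, keeping the guide footprint
  wholly distal). The restriction filters vertices — the source is never
  re-meshed, since the metrics are vertex-wise.

## Volumes and reslicing

A `VoxelVolume` is a scalar grid with anisotropic spacing; the third axis is
the slice axis. Reslicing to thickness *t* keeps the in-plane grid untouched
and interpolates along the slice axis only, with an interpolating spline of
order 3 (default; order 1 available for sensitivity checks). The new slice
grid is anchored at the first native slice (configurable offset), covers only
the native z-range (no extrapolation), and any new slice coinciding with a
native position copies it verbatim — reslicing at the native thickness is
exactly the identity, a property several tests rely on. Surfaces are
extracted with marching cubes at an iso-level of the continuous field;
reslice-then-extract mirrors the reslice-then-segment order of a clinical
workflow. Thresholding exists for mask-style segmentation but the surface
pipeline extracts the smooth field directly, standing in for semi-automatic
segmentation plus surface generation of commercial tools.

## The synthetic phantom

The bone is an implicit surface `f > 0` inside, `f = 0` on the surface,
designed to be approximately a signed distance near the surface (unit
gradient), which makes field-level perturbation amplitudes read directly in
millimetres:

* an elliptical tube along z (shaft radius 9 mm, cross-section eccentricity
  0.35, with the volar half-width exactly the shaft radius at mid-shaft);
* a smooth distal flare (factor 1.8 over the distal 25 mm);
* rounded superellipse end caps, the distal cap extended axially by a
  Gaussian azimuthal lobe (amplitude 6 mm) — a styloid-like process
  protruding along the long axis, which is exactly the kind of feature most
  sensitive to slice thickness;
* a malunion tilt of the distal segment (15° about an in-plane axis,
  smoothly blended at the hinge);
* per-participant smooth cross-section irregularities (low-order azimuthal
  sine modes, SD 0.4 mm) seeded deterministically.

Default grid spacing is 0.39 × 0.39 × 0.625 mm (clinical-protocol pixel size
and native slice thickness). Two further per-participant variations emulate a
real cohort: bone length varies ±7%, and the sampling grid carries a random
sub-slice phase — scanner slices are arbitrary relative to the anatomy, and
without this phase all phantoms would share one slice-alignment artifact and
per-thickness averages would not converge the way patient averages do.

**Guides.** The guide base's contact surface is the subset of bone faces
whose centroids fall in an axial/azimuthal window on the volar aspect
(35 mm × 120° by default), with vertex coordinates copied bit-for-bit; the
outer surface is the patch offset 3 mm along outward angle-weighted vertex
normals, and side walls stitch the two into a closed mesh. By construction
every contact vertex has signed distance exactly 0 to its source bone — the
test suite asserts literal zeros, not tolerances.

**Raters.** Rater variability is modelled at the field level: white noise
smoothed by a squared-exponential kernel (correlation length 8 mm), centred
and scaled over the near-surface shell so the induced surface displacement
has SD `sigma` (default 0.04 mm), added to the field before isosurface
extraction. Field-level perturbation means each synthetic rater has an
independent tessellation, as real raters segmenting independently do. The
default `sigma` is a calibration: it places the synthetic inter-rater
absolute ADE in the observed few-hundredths-of-a-millimetre range
(bracket 0.015–0.06 mm is asserted, not a point value). Shell-local
normalisation is needed because with an 8 mm correlation length only a
handful of Fourier modes survive on a bone-sized grid, so regional variance
of the smoothed field differs substantially from the global variance.

**Seeds.** Every artifact's seed derives as
`master*10^6 + participant*10^4 + rater*10^2 + thickness_index`
(1-based, 0 = not applicable), so any single artifact is reproducible in
isolation and whole cohorts are bit-reproducible.

## Statistics

* Interval estimates are classical t intervals; the P·R·(R−1) pooled
  inter-rater values are treated as independent although they share
  participants and raters — a deliberate simplification of the design this
  package replicates, noted here rather than corrected silently.
* Bland–Altman per slice thickness: the inter-rater side is each
  participant's mean over its R(R−1) guide HDF values; the lower-resolution
  side is the mean HDF of that participant's degraded guide against the R
  reference radii. Difference = inter-rater − lower-resolution, so a
  more-overlapping degraded guide gives a *positive* difference. Limits of
  agreement are bias ± 1.96 SD; the bias CI uses t(n−1), each LoA CI the
  classical large-sample variance 3s²/n with a t multiplier.
* Normality of the differences is operationalised as the probability-plot
  correlation coefficient with Blom positions (i − 3/8)/(n + 1/4) at
  α = 0.05. The embedded critical values are Monte-Carlo estimates (200 000
  normal samples per n, seeded) that agree with the standard published table
  to about 0.001; they are interpolated in n.
* Verdicts: *acceptable* when both limits of agreement lie within ±limit
  (limit = |mean inter-rater HDF| unless overridden); otherwise *borderline*
  when the bias CI reaches into ±limit; otherwise *poor*. The rule is
  monotone in the limit (tested).
* No multiple-testing correction is applied, matching the study design the
  package implements.

## Problem sizes and determinism

Test and acceptance runs use a scaled-down phantom — 70 mm bone on a
0.78 × 0.78 × 0.625 mm grid (half the default in-plane resolution, native
slice thickness unchanged) — chosen so a full 12-participant, 3-rater,
5-thickness study (504 mesh comparisons) completes in a few CPU-minutes.
Every studied effect survives the scaling: guide-fit exactness is exact by
construction at any resolution, rater calibration depends on `sigma` rather
than grid density, and the degradation mechanism (information lost between
coarser slices) is driven by the slice axis, which keeps its native 0.625 mm
resolution. All randomness flows through explicit integer seeds; repeated
runs are bit-identical.

## Known limitations

* The phantom is radius-*like*, not anatomically exact: no intra-articular
  deformity, no cortical/trabecular intensity structure, no scanner noise or
  reconstruction artifacts. Reslicing the noiseless analytic field cannot
  reproduce noise-level differences between acquisition protocols, so
  passing tests demonstrate the geometry/statistics pipeline, not claims
  about scanner physics.
* The rater model is a stated assumption (smooth zero-mean surface
  perturbation); it is validated only at the metric level, through the
  calibration bracket.
* Degradation magnitudes on the smooth phantom are smaller than on real
  bone at the same thickness (real surfaces carry high-frequency detail the
  phantom lacks); trends and orderings, not absolute millimetre values, are
  the transferable quantities.
* STL stores float32; cohorts written to disk and reloaded preserve exact-fit
  zeros (bone and guide quantise identically) but carry ~1e-5 mm coordinate
  quantisation relative to the in-memory meshes.
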