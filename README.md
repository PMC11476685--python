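# guidefit

Surface-discrepancy analysis of patient-specific surgical guides (PSSGs) and
virtual bone models under CT slice-thickness degradation.

PSSGs for corrective osteotomy of the distal radius carry a base whose
bone-contact surface exactly replicates the patient's virtual bone model, so
the guide seats in one designed pose. That replication is only as good as the
bone model, which in turn depends on who segments the CT and on the scan's
slice thickness. `guidefit` implements the quantitative machinery to answer
two questions:

1. **How much do experienced raters disagree?** Each rater's guide is compared
   against every other rater's radius model; the pooled *negative Hausdorff
   distance* (HDF) — the most negative signed vertex-to-surface distance,
   i.e. the deepest penetration of the guide into the bone — quantifies
   inter-rater variability. Radius-to-radius variability is quantified by the
   *absolute average distance error* (ADE), the mean |signed distance| over
   vertices, for the whole bone and its distal/proximal parts (split by a
   plane perpendicular to the long axis just below the guide's proximal edge).
2. **When does lower resolution stop being acceptable?** The native volume is
   resliced along the slice axis only (cubic-spline interpolation, in-plane
   pixels untouched) to thicknesses 1, 1.25, 1.5, 1.875 and 2.5 mm; guides
   designed on the degraded models are compared to the reference radii, and
   per-participant averages enter a Bland–Altman analysis
   (bias = mean difference, limits of agreement = bias ± 1.96 SD, t-based
   CIs). A three-tier verdict — acceptable / borderline / poor — compares the
   limits of agreement with the inter-rater variability, taken as the
   clinically acceptable limit.

Everything runs either on STL models from disk (sharing one CT frame; no
registration is ever performed, since aligning the models would hide the
effect under study) or on a fully synthetic cohort of distal-radius phantoms:
implicit bone surfaces with shaft, distal flare, axially protruding styloid
lobe and malunion tilt; guide bases whose contact patch copies the bone
surface bit-for-bit; smooth zero-mean Gaussian-random-field perturbations
emulating independent raters; and slice-axis reslicing emulating degraded
scans.

Signed distances use exact closest-point queries against the triangle mesh
with inside/outside signs from angle-weighted pseudonormals; the accelerated
spatial index is guaranteed (and tested bit-for-bit) to match exhaustive
search over all faces.

## Worked example

```python
from guidefit import BonePhantomParams, generate_study, run_full_study

bone = BonePhantomParams(length=70.0, field_grid_spacing=(0.78, 0.78, 0.625))
cohort = generate_study(4, 3, [1.0, 2.5], master_seed=7, bone_template=bone)
report = run_full_study(cohort)

hdf = report.inter_rater_guide_hdf
print(f"inter-rater guide overlap (negative HDF): "
      f"{hdf.mean:.3f} mm [95% CI {hdf.ci_low:.3f}, {hdf.ci_high:.3f}], n={hdf.n}")
ade = report.inter_rater_radius_ade["whole"]
print(f"inter-rater radius ADE: {ade.mean:.3f} mm [95% CI {ade.ci_low:.3f}, {ade.ci_high:.3f}]")
for t in cohort.thicknesses:
    ba, v = report.bland_altman[t], report.verdicts[t]
    print(f"slice thickness {t} mm: bias {ba.bias:+.3f} mm, "
          f"LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}] -> {v.category}")
```

prints

```
inter-rater guide overlap (negative HDF): -0.081 mm [95% CI -0.100, -0.061], n=24
inter-rater radius ADE: 0.042 mm [95% CI 0.040, 0.044]
slice thickness 1.0 mm: bias +0.024 mm, LoA [-0.132, +0.180] -> borderline
slice thickness 2.5 mm: bias +0.106 mm, LoA [+0.039, +0.173] -> borderline
```

Reading this: the three synthetic raters' guides penetrate each other's bone
models by 0.08 mm on average — that magnitude becomes the acceptability
limit. Guides designed on 1 mm slices sit within a few hundredths of a
millimetre of the raters' own disagreement (small bias), while 2.5 mm slices
produce a clearly larger systematic overlap; with only four participants the
confidence intervals are wide, so both land on the borderline tier here. A
12-participant cohort (the default study size) separates the tiers.

The same pipeline is scriptable from the shell:

```sh
guidefit simulate --participants 12 --raters 3 --seed 1 --out cohort/
guidefit study --manifest cohort/manifest.json --out results/
guidefit compare --source guide.stl --target radius.stl --report cmp.json --colored cmp.ply
```

`study` writes `summary.json` (interval estimates, Bland–Altman blocks,
Q-Q normality statistics, verdicts), `metrics_raw.csv` (one row per
comparison) and `per_participant.csv`; `compare` can attach per-vertex signed
distances to a PLY for distance-coloured surface views.

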