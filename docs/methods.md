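# Methods

`cervimetry` measures the late-gestation uterocervix from 3D multi-label
segmentations and relates the resulting biometry to demographics and
birth outcomes.  This note records the models, conventions and numerical
choices behind each stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Label scheme and coordinates

Input volumes are NIfTI label maps with integer codes 0 background,
1 outer stroma, 2 inner stroma, 3 cervical canal, 4 canal cyst
(optional), 5 lower-uterine-segment reference region (optional).  Any
other value is a validation error.  All geometry is computed in world
millimetres through the affine, with the voxel-centre convention (the
world position of integer index *i* is the affine image of *i*), so
anisotropic and oblique volumes are handled uniformly.  Canal or cyst
voxels that are not 6-adjacent to inner stroma raise a warning, not an
error: the configuration is anatomically suspicious but measurable.

The in-house label encoding of clinical segmentations is a repository
convention (it follows the segmentation-protocol region list plus the
cyst and uterine-reference extensions); the mapping is explicit in
`volume_io` and can be remapped upstream if a dataset differs.

## Canal centerline

The centerline is the backbone of every 2D measurement.  It is computed
on the largest 26-connected component of canal∪cyst voxels (components
under 20 voxels are rejected as unmeasurable):

1. **Geodesic diameter.** Build the 26-neighbourhood graph over
   component voxels.  Two farthest-point Dijkstra sweeps with *metric*
   edge weights (world gap lengths) select the endpoint pair, which for
   a tubular region sits on the two end faces.  A thinning skeleton was
   rejected here: on blunt or oblique tube ends voxel thinning erodes
   up to one tube radius of length from each end, which is material when
   total length is ~30 mm.
2. **Axial routing.** The path between the endpoints is the shortest
   path under *penalized* weights — gap length divided by
   (EDT + h/2)², where EDT is the Euclidean distance transform of the
   component and h the voxel size — so the path hugs the medial axis
   instead of hopping between wall voxels.  Endpoint selection and
   routing deliberately use different weights: penalized costs are not
   lengths, and maximizing them would park endpoints inside thin
   structures such as cyst walls.
3. **Re-centring.** The voxel-resolution path is smoothed (5-point
   moving average, endpoint-preserving), resampled at one voxel
   arc-length spacing, and twice snapped to the centroid of its local
   orthogonal cross-section (slab of half a voxel, radial window 12 mm
   to exclude re-entrant arms of strongly curved canals).
4. **End repair.** The raw geodesic terminates at end-face *corners*;
   the last `r_max + 1.5·diag` of arc at each end (r_max = maximum
   inscribed radius, diag = voxel diagonal) is trimmed and regrown by a
   step-and-recentre march: advance half a voxel along the local secant
   tangent, snap laterally to the cross-section centroid (correction
   capped at one step), stop on leaving the component or if the march
   direction rotates more than 45° from the end tangent (which happens
   when a march starts curling back inside a wide canal).  The march
   follows curved canals and terminates on the end-face axis.

On voxelized phantoms this recovers arc length to well under a voxel
and endpoint positions to a fraction of a voxel (see the acceptance
script's recovery metrics).

## Measurements

* **Os landmarks.** Internal os = centerline endpoint nearer the
  uterine reference line (anatomically the internal os abuts the
  uterine cavity; no automated rule is established in the imaging
  literature, so proximity is the convention here).  External os = the
  other endpoint.  Canal midpoint = interpolated point at half arc
  length.
* **Cervical length.** 2-point: straight internal→external distance.
  3-point: sum of the two chords via the canal midpoint.  By the
  triangle inequality 2-point ≤ 3-point ≤ arc length always.
* **Os diameters.** At the centerline point one voxel diagonal inward
  from the endpoint (the end cross-section itself is degenerate), the
  canal∪cyst voxels within a 1-voxel slab orthogonal to the local
  tangent are collected; in-plane clusters other than the one
  containing the os are discarded (a strongly curved canal can re-enter
  the cutting plane); the diameter is the maximum Feret diameter
  (largest pairwise world distance).  "Diameter" has no formalised
  definition in the available imaging protocols; max-Feret of an
  orthogonal section is this package's documented convention.
* **Utero-cervical angle.** Angle at the internal os between the
  uterine axis direction oriented away from the cervix and the straight
  internal→external os line, in [0, 180]°.  The 2-point line (not the
  canal tangent) is used because the angle is interpreted against the
  2-point length construct.
* **Volumes.** Voxel count × |det| of the affine 3×3 block, reported in
  cm³ (mm³ available via configuration).  Stroma = labels {1,2}, canal
  = {3}, cyst = {4}, total = their sum; the uterine reference region is
  never counted.  The partition total = stroma + canal + cyst is exact
  by construction.  Cysts are reported separately rather than merged
  into the canal because the segmentation protocol treats them as a
  distinct region.

The uterine reference line comes from a JSON sidecar (two world-mm
points) or, failing that, from the first principal axis of the label-5
voxel cloud oriented toward the canal.  The sidecar wins because an
explicitly placed landmark is more reliable than a PCA fit of a region
whose extent varies between raters.

## Phantoms

`phantom_gen.make_phantom` voxelizes nested tubes (canal, inner stroma,
outer stroma) around a straight or circular-arc centerline, with linear
canal-radius taper, an optional annular cyst sphere centred on the
canal, and a bar-shaped uterine reference at a prescribed angle to the
2-point line.  Every panel quantity has a closed form: frustum volumes
∫πr(s)²ds, circular-arc chords 2R sin(θ/2) and 4R sin(θ/4), the
specified angle, and the cyst as sphere minus coaxial-cylinder
intersection, (4π/3)(R²−r²)^{3/2}.

Boundary voxels are assigned by **ordered dithering**: the analytic
coverage fraction of each boundary voxel (3³ subsamples) is compared
against a fixed low-discrepancy threshold pattern (Roberts R3 sequence
over voxel indices).  Pure voxel-centre inclusion was measured to bias
voxel-count volumes by up to ±18% for grid-aligned tubes at 0.8 mm —
the bias depends on how the tube phase-aligns with the lattice —
whereas dithering is unbiased for any alignment (observed ≤ ~2.5%
worst case, ~1% typical, at the default geometry).  The pattern is a
pure function of voxel indices: voxelization is deterministic and
seed-independent, and the nesting canal ⊂ inner ⊂ outer is preserved
because all interfaces share one threshold per voxel.

Defaults follow the study conditions: 0.8 mm isotropic resolution,
canal length ~20–40 mm, canal radii 1.6–3.5 mm, walls 2–5 mm,
utero-cervical angle 60–160°, gentle curvature (radius 30–120 mm) in
half of the randomized suite, an annular cyst in ~30%.  The cyst
ground-truth volume uses the local-cylinder approximation on curved or
tapered canals; suite cysts are small relative to taper and curvature,
keeping that error well under measurement tolerance.

What phantoms do **not** emulate: segmentation errors (boundary noise,
label leakage), partial-volume smoothing of real annotations,
non-tubular canal shapes (funnelling beyond a linear taper), and MR
intensity content.  Passing the recovery suite therefore demonstrates
the correctness of the measurement geometry, not robustness to
segmentation failure modes.

## Synthetic cohorts

`make_cohort` draws demographics uniformly within the study ranges
(age 19–42 y, BMI 18–32, gestational age 35.7–40.1 weeks; ethnicity
mix with a White majority) and biometry from linear models with
Gaussian noise: stroma volume rises with age and cervical length, os
diameters and utero-cervical angle fall with length, canal volume
rises weakly with length.  The os-diameter pair is built as external +
difference, with the difference normal with mean 3.5 mm and SD chosen
as mean/Φ⁻¹(0.818) so the internal>external fraction matches its
target in expectation.  Binary outcomes follow logistic models:
caesarean log-odds increase by ln(1.09) per cm³ of total volume above
its expected value; induction log-odds change by ln(0.83) per mm of
external os diameter.  Effect magnitudes without a published value
(slopes, baselines, noise SDs) are generator defaults chosen to be
physiologically plausible, and must not be read as literature claims.
`CohortSimParams.null()` zeroes every effect for calibration runs.

## Statistics

* **Normality**: Shapiro–Wilk (scipy), 3 ≤ n ≤ 5000, constant samples
  rejected.
* **Outlier removal**: values outside Q1 − 1.5·IQR, Q3 + 1.5·IQR with
  type-7 (linear interpolation) quartiles, applied to the response
  before linear fits, matching the cohort-analysis protocol.  Fences
  are computed once per call; refiltering already-kept toy data removes
  nothing, but on continuous heavy-tailed samples a second pass with
  recomputed fences can remove further points — that is a property of
  recomputed quantiles, not a bug.  Note that trimming a genuinely
  Gaussian response slightly attenuates regression slopes (informative
  tails are removed); recovery tests therefore run unfiltered.
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement,
  single rater — from the mean-squares decomposition, with the
  F-based Satterthwaite-df 95% CI.  The form is a documented default
  (the agreement analyses this mirrors do not state one); the
  implementation is cross-checked in tests against both a brute-force
  ANOVA oracle and pingouin's ICC(A,1).
* **GLMs**: Gaussian-identity OLS for continuous responses and
  binomial-logit (IRLS, tol 1e-8, ≤100 iterations) for binary
  outcomes, via statsmodels behind the module surface; Wald 95% CIs
  (profile likelihood not used, matching mainstream GLM reporting);
  rank-deficient designs raise an error naming the collinear terms;
  (quasi-)complete separation raises rather than returning divergent
  estimates.  Raw p-values, no multiplicity correction, matching the
  reporting style of the analyses this reproduces.
* **Association battery**: a fixed model list — each volume/diameter/
  angle against 2-point cervical length, stroma volume against age,
  caesarean against total volume adjusting for age and ethnicity
  (dummy-coded, unrepresented levels dropped), induction against
  external os diameter adjusting for gestational age.  "Cervical
  volume" in the caesarean model is total volume in cm³ by default;
  the odds ratio is therefore per cm³.  Output is a tidy table plus an
  optional forest plot (log-scaled odds-ratio axis).

## Pipeline determinism and problem sizes

All randomness flows from one root seed (`numpy.random.default_rng`);
`cmd_full_demo` is byte-identical across runs with the same seed.  The
default validation sizes — 50 randomized phantoms for geometry
recovery, 10⁵ subjects for odds-ratio recovery, 200 null replicates of
n=500 for calibration — were chosen so each check's Monte-Carlo error
is small against its tolerance while the whole battery runs in minutes
on a single CPU.

## Known limitations

* Endpoint-dependent measurements (angle, 2-point length) are the most
  sensitive outputs; residual endpoint error is a fraction of a voxel
  on clean phantoms but will grow with segmentation noise at the os.
* The formal landmark definitions used by the clinical protocol this
  mirrors are not public; slab thickness, Feret convention, the
  2-point angle reference and the proximity rule for internal/external
  disambiguation are package conventions, flagged for revision if the
  protocol tables become available.
* The cohort generator is a structural emulation for pipeline
  validation, not a population model; only the explicitly configured
  targets (odds ratios, os-difference distribution, ranges) are
  calibrated.
* Quality grades are recorded and used for exclusion bookkeeping only;
  the visual rating itself is human judgement and out of scope.
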