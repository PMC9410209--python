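# Methods

## The measurement

Axial loading compresses the intervertebral discs. Given two T2-weighted
volumes of the same lumbar spine — one unloaded, one under axial load —
the internal (voxel-wise) deformation of each disc is estimated by
deformable image registration: the loaded volume is registered to the
unloaded one, and the Jacobian determinant of the recovered mapping
gives the local volume-change ratio. Values are reported in the
compression-positive convention `D = 1 / det(J)`, so `D > 1` marks
compression and `D < 1` expansion under load. `D` is averaged over each
disc, over five equal-length anterior→posterior subregions of the three
mid-sagittal slices, and over nine left→right mid-slice profiles. Disc
morphometrics (height from the segmentation; tilt and disc angles from
endplate landmark segments) feed a statistical layer of Pearson
correlation, Kruskal–Wallis tests, uni-/multivariable linear regression
with backward elimination, and ICC(A,1) reliability.

On `f = T`, the mapped coordinate field: its Jacobian is `J = I + ∇u`
with `u` the displacement. Differentiating the raw displacement alone
would give `∇u`, whose determinant cannot carry the stated "greater than
one = compression" semantics; the full mapping is therefore
differentiated, and the reciprocal of the forward (unloaded→loaded)
determinant is reported so that compressed tissue reads above one. The
raw determinant is stored alongside.

## Registration

Two stages, both authored here in numpy/scipy:

1. **Rigid Euler** (Z-Y-X angles + translation about the fixed-image
   centre), optimized by Powell's method on a two-level pyramid
   (stride-4 and stride-2 sampling of the fixed grid). The moving image
   is never decimated — decimating it aliases the interpolant and biases
   the recovered rotation — and is sampled as a prefiltered cubic
   spline.
2. **Cubic B-spline free-form deformation** composed additively with the
   rigid stage, parameterized over the fixed-image domain. Three
   pyramid levels (downsampling 4/2/1, Gaussian smoothing 2/1/0.7
   voxels) with knot-spacing schedule 4×/2×/1× the final control
   spacing. The cost is mean squared intensity difference plus a
   thin-plate bending energy approximated by second differences of the
   control lattice. Optimization is L-BFGS-B with an analytic gradient,
   restarted with a fresh Hessian approximation when its line search
   aborts; accepted iterates are monotone in cost. An adaptive-step
   steepest-descent optimizer was tried first and reliably stalled far
   from the optimum on this noisy, ill-conditioned objective.

**Interpolation model.** The single most consequential numerical choice.
Trilinear sampling of an image containing voxel-scale noise or
fine-scale texture damps that signal at fractional offsets, so the MSD
metric is *lower* off-grid than on-grid. This displaces the rigid
optimum by about half a voxel and pushes the FFD toward spurious smooth
wiggles and a dome-shaped over-deformation inside the discs. The moving
image is therefore modelled as a C² cubic B-spline (edge-padded,
prefiltered once per level) whose value and spatial derivative are
evaluated together by a fused kernel (numba-jitted with a pure-numpy
fallback), making the supplied gradient exactly consistent with the
sampled cost — which the quasi-Newton line search depends on. The light
(0.7 voxel) smoothing retained at the finest level correlates the
remaining noise so the interpolant can reproduce it.

**Folding control.** After optimization the dense forward determinant is
computed at every fixed voxel; if any value is non-positive the fit is
retried with the bending weight doubled (up to four retries) and
otherwise fails naming the folded voxel fraction. All shipped
configurations pass on the first attempt with minimum determinants
around 0.8.

**Defaults.** Final knot spacing (12, 12, 8) mm — anisotropic, finer
along the head–feet (loading) axis. The axial strain under loading
localizes over roughly the blend width of the disc–vertebra transition
(~6 mm); a 16 mm axial lattice smears the recovered strain into the
adjacent vertebral bodies, flattening the anterior→posterior regional
gradient and biasing per-disc means toward 1, while in-plane variation
(the wedge) is nearly linear and needs no fine lattice. Refining beyond
this fits noise before it adds signal at these resolutions. Bending
weight 3000 (in units of
intensity² per (1/mm)²; chosen on the validation phantom as the smallest
weight at which zero-load runs stay within ±0.003 of unity while
compressed-disc amplitudes are preserved to ~0.02), 100 L-BFGS-B
iterations per level. Similarity is MSD by default; histogram mutual
information is available for the rigid stage only (the loaded/unloaded
pair shares contrast, so MSD is appropriate; an MI gradient for the FFD
stage was deliberately left out of scope). Resampling to 1 mm isotropic
before registration is available (`resample_to_isotropic`) but off by
default: the phantom grid is already near-isotropic and registering at
native spacing keeps the validation suite fast.

## The synthetic phantom

No study data are deposited, so every stage is validated against a
generated lumbar-spine phantom with closed-form ground truth:

- **Scene**: five discs (L1/L2…L5/S1) as soft-edged elliptic cylinders
  (bright nucleus ellipsoid inside darker annulus) stacked between dark
  vertebral bodies; background/bone/annulus/nucleus intensities
  20/60/100/200 on a 96×64×160 grid at 1.5 mm.
- **Texture**: a material-attached, band-limited random-phase cosine
  field (relative amplitude 0.12, dominant wavelength 12 mm) modulates
  the signal above background. Real T2 tissue is never homogeneous, and
  without interior structure the intradiscal deformation is invisible to
  any intensity metric (the aperture problem) — a textureless phantom
  made the task ill-posed in a way real images are not.
- **Deformation**: purely axial displacement whose strain is a sum of
  per-disc Gaussian lobes with anterior–posterior wedge and
  left–right gradients (see `phantom.py` docstring for the closed
  form). The forward determinant is exactly `1 + ε`, the displacement
  has an error-function closed form, and the loaded image is the scene
  evaluated at the Newton-inverted warp — no interpolation touches the
  ground truth. Rician noise (σ = 5) is added to both volumes
  independently, mimicking two acquisitions.
- **Default loading**: compression factors 0.98/0.96/0.93/0.90/0.88
  from L1/L2 to L5/S1 (the caudal spine deforms most, matching the
  reported in-vivo pattern) and wedge angles −2°…+2°. No displacement
  magnitudes are published for the loading device, so these are
  plausible choices, not calibrated values.

What the phantom does *not* emulate: MR physics (bias fields,
relaxometry), facet joints, muscle, CSF, through-plane anisotropy of
clinical sagittal stacks (3.5 mm slices), scoliosis beyond the lateral
strain term, and any in-plane or rotational patient motion beyond what
the rigid stage is separately tested on. Passing the suite therefore
shows the machinery is correct and self-consistent at clinically
plausible deformation scales — not that in-vivo accuracy equals phantom
accuracy.

## Regional analysis choices

- Subregions are equal-length intervals of the anterior→posterior
  extent ("evenly distributed" read geometrically), along the principal
  axis of the mid-sagittal voxel cloud; equal-count binning would be the
  alternative and is configurable at the call site.
- Subregion means use the three mid-sagittal slices; the nine-slice
  left→right profile is kept separate (slice 1 = leftmost). Both counts
  are configuration defaults.
- Disc height is the extent of the mask's voxel centres along the
  least-squares disc-plane normal; single-layer masks return one voxel
  height with a warning.
- Endplate landmarks are explicit inputs (the phantom emits them;
  clinical use implies manual annotation). Tilt angle = angle between
  the superior endplate of L1 and the disc's inferior endplate; disc
  angle = angle between the endplates bounding the disc; both unsigned
  acute.
- Pfirrmann grade is consumed as metadata (a radiologist's ordinal
  input, numeric 1–5 in regressions); it is never computed.

## Statistics

Pearson and the tie-corrected Kruskal–Wallis H wrap scipy (an exact
permutation p-value is computed for pooled n ≤ 10); OLS wraps
statsmodels with rank-deficiency detection that names collinear columns.
Backward elimination refits iteratively, dropping the largest p-value
above α = 0.05 (column order breaks ties). ICC(A,1) — single measure,
absolute agreement, two-way — is computed from the ANOVA mean squares
with the standard F-based confidence interval, and is cross-checked
against pingouin in the test suite. Correlation strengths use the Chan
(2003) scale (|R| ≥ 0.8 very strong, 0.6–0.8 moderately strong, 0.3–0.6
fair, otherwise poor). Discs are treated as independent observations in
all models, replicating the original analysis; no clustering adjustment
or multiple-testing correction is applied.

## Validation suite problem sizes

The suite registers the full default phantom once (shared across
recovery, positivity and overlap-QC tests), one zero-load phantom
(compression 1.0, noise on — any recovered deformation is spurious), one
pure-wedge phantom (compression 1.0, the default −2°…+2° wedge grading,
standard resolution and noise), and a ten-member graded-wedge family
(wedge 0.2°–2.0° uniform across discs, compression 0.97, 72×48×120 grid
at 2 mm). The pure-wedge phantom carries the regional-monotonicity
check: strict anterior→posterior monotonicity with the matching sign
for its ±2° discs, sign of the region 1 − region 5 difference for its
±1° discs (their per-region gaps approach the noise floor of the region
means, ≈ ±0.005 in D). The family carries the angle-change correlation
check and uses one-signed wedges because the disc angle is unsigned: a
symmetric ± family would null the angle-change/region-difference
correlation by construction.

## Known limitations

- Deformation in image regions without intensity structure (air, deep
  interior of homogeneous tissue) is determined by the bending-energy
  prior, not by data; inverse-consistency and accuracy claims apply to
  tissue.
- The FFD stage supports MSD only; cross-contrast registration would
  need the rigid stage's MI generalized to the FFD gradient.
- The B-spline lattice low-passes the recovered strain; per-disc means
  are accurate to ≈ 0.015 while voxel-wise extremes are attenuated.
- Angles are reported unsigned, so wedge direction must be inferred from
  the regional gradient, exactly as in the original sub-analysis.
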