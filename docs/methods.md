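# Methods

This note documents the models behind `dosewarp`, the parameters that matter,
and the choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Geometry and conventions

All volumes live on axis-aligned grids with identity orientation; voxel
`(i, j, k)` is centred at `origin + (i, j, k)·spacing`, all distances and
displacements are physical millimetres, indexing is 0-based.  Readers reject
oblique volumes rather than resampling them silently — the workflow's images
are axis-aligned CT volumes and this removes a large error surface.

Displacement fields are **pull-backs**: a field `u` warps a moving volume by
sampling it at `x + u(x)` on the output grid.  The `direction_tag`
(`mod_to_plan` / `plan_to_mod`) records which way a map reads; a field and
its inverse carry opposite tags, and dose accumulation refuses a field with
the wrong tag.  Masks are warped/resampled as real-valued fractions and
thresholded at ≥ 0.5, which staircases less than nearest-neighbour on
anisotropic grids.  Out-of-extent samples take physically motivated fills:
−1000 HU (air), 0 Gy, 0 mask fraction.

## Synthetic pelvic phantom

The phantom emulates the features of a pelvic planning CT that the
validation methodology actually exercises: closed organ boundaries with
realistic HU contrast, a target with CTV/PTV margins, bone that must not
deform, and soft-tissue texture for intensity registration.  Geometry is
analytic — an elliptic-cylinder body (fat ring under the skin), ellipsoidal
bladder and target (prostate or uterus), a rectal tube with a gas core,
spherical femoral heads, and for the cervix-like site a bowel compartment
with derived `bowel_bag` and `bowel_minus_ctv` masks.  The target centroid
sits at the grid's geometric centre, emulating CBCT acquisition centred on
the isocentre.  Default grid 128×128×64 at 2×2×2.5 mm (a 96×96×48,
2.5×2.5×3 mm validation grid is used in the test suite and parts of the
acceptance script to keep runtimes at desk scale); prescriptions 60 Gy/20 fx
(prostate-like) and 45 Gy/25 fx (cervix-like); PTV margin 7 mm by default.

Correlated Gaussian texture (12 HU SD, 6 mm correlation length) is added to
soft tissue so a mono-modal intensity registration has features away from
organ boundaries.  The correlation length matters: much finer texture
aliases under trilinear warping and dominates image-similarity scores.

**What the phantom does not emulate:** CBCT artifacts and noise, HU-density
calibration, inter-patient anatomical variability, contouring variability,
and sliding interfaces.  Passing tests therefore demonstrate that the
*measurement chain* (authoring → inversion → accumulation → metrics) is
correct and discriminating, not that any particular clinical system is
accurate on real patients.

## Plan-like fraction dose

The per-fraction dose is analytic, not transported:

    D(x) = (Rx/n_fx) · [ 0.65·P(x) + 0.35·M̂(x) ] · 1_body(x)

where `P` is a PTV plateau with Gaussian penumbra `exp(−d²/2σ²)` of the
Euclidean distance `d` outside the PTV (σ = 4 mm default — a free parameter,
as clinical falloff characteristics vary), and `M̂` is the entrance-fluence
bath: per gantry angle, a PTV-shaped aperture (3 mm margin, 2 mm sigmoid
edge softness) times exponential attenuation `exp(−μ·depth)` (μ = 0.004/mm)
along the analytic ray depth through the body, averaged over angles and
normalised to mean 1 over the PTV.  `imrt9` uses nine discrete angles with
±5 % seeded weight modulation (visible beam-edge steps near the surface);
`vmat` integrates 72 angles (no discrete edges).  The dose is pinned to the
per-fraction prescription at the PTV centroid, is zero outside the body, and
its PTV maximum stays within 100–107 % of prescription.  The point of this
construction is to produce dose *gradients and beam edges* in the right
places, since DIR errors only become dosimetric errors in steep-gradient
regions.

For deformed scenarios the fraction dose is the *scheduled-plan* analogue:
apertures stay frozen on the planning PTV while the body is taken from the
modified anatomy; re-optimisation is deliberately out of scope so the
accumulation comparison has no confounder.

## Deformation authoring

Fields are authored directly in the `mod_to_plan` pull-back direction, so
image synthesis needs no inversion and the ground truth for accumulation is
exactly the numerical inverse of the applied field.  Per organ:

* **expand** by `m` mm: a radial map about the organ centroid, linear inside
  the expanded radius `R+m` (so the radial Jacobian is the constant
  `R/(R+m) > 0`) and Gaussian-decaying outside with length
  `decay = max(decay_mm, 0.8·m)`;
* **shrink**: the analogous contraction, refused when `m ≥ 0.6·R`;
* **shift**: a translation windowed by distance to the organ.

The raw field is multiplied by smoothstep windows that force it to zero at
the body surface, at the grid faces (a target-centred field of view carries
no deformation at its border, and a boundary-zero field inverts cleanly) and
inside the femoral heads; the taper length scales with magnitude
(`max(12, 0.9·m)` mm) so the window itself cannot introduce extreme
gradients.  After a light Gaussian blur the field is rescaled to the target
peak, backing off in deterministic 0.85 steps while either the
central-difference Jacobian determinant of `x + u(x)` dips below 0.05 or the
largest singular value of `∇u` exceeds 2.5 (the Lipschitz bound that
guarantees the damped fixed-point inversion below converges).  Consequently
the bladder "large expansion" preset, authored at 30 mm, realises a ~13 mm
peak on this phantom — the anatomy simply has no room for more — which still
sits firmly in the "large" class (> 10 mm).  Multi-organ scenarios compose
by map composition (not addition), first-listed organ outermost.

Magnitude classes follow the conventional thresholds on peak displacement
over a mask: < 5 mm small, 5–10 mm medium (both boundaries inclusive to
medium), > 10 mm large.

## Field inversion

The inverse displacement solves `v(x) = −u(x + v(x))` by damped fixed-point
iteration `v ← v − α·(v + u(x+v))` with `α = 0.5`, starting from `v₀ = −u`,
stopping when the max composition residual `|u(x+v)+v|` falls below
`tol = 0.05` mm (at most 80 iterations; failure above `5·tol` raises).  The
damping matters: the plain iteration (`α = 1`) requires `‖∇u‖ < 1`, while
`α = 0.5` tolerates gradients up to 3, which the authored fields reach near
their taper bands.  Every shipped scenario inverts with residual < 0.1 mm
over the body.  Double inversion recovers a field to within the tolerance
plus the trilinear sampling error of a curved field at the voxel pitch
(~0.3 mm max at 2.5–3 mm voxels), which is why the repeatability test bounds
the maximum at 0.5 mm and the mean at 0.1 mm.

## Dose accumulation

Pure direct dose mapping: `D_acc(y) = D_fx(y + v(y))` by trilinear sampling,
out-of-extent → 0 Gy, no energy or mass rescaling — matching how integrated
OART systems deform dose.  DDM is linear in dose and, by trilinear
convexity, cannot extend the dose range.  Fields stored on coarser grids
(the registration output defaults to 4× the CT voxel size, mirroring the
resolution asymmetry between an authored truth field at CT resolution and a
clinical system's coarser estimate) are upsampled trilinearly at evaluation
time.

## Registration under test

The reference system under test is a Gaussian-regularised multi-resolution
demons registration (SimpleITK fast symmetric forces inside a 3-level
pyramid; 60/30/15 iterations coarse→fine; update smoothing 1 mm, field
smoothing 3 mm, both expressed in voxels per level).  A mutual-information
B-spline model would add nothing on mono-modal synthetic pairs; the
framework's point is that *any* plug-in honouring the
`(fixed, moving, params) → field` interface can be evaluated, including
external executables through the CLI adapter.  Image similarity is scored
over the body eroded by ~3 voxels: the air/skin interface has ~360 HU/mm
gradients, so sub-voxel surface motion otherwise dominates the score.

`degrade_factor g ∈ [0,1]` blends the estimate with a smooth seeded random
field (10 mm correlation, RMS matched to the estimate but at least 2 mm):
`(1−g)·u + g·noise`.  It gives the pipeline a controlled bad-DIR arm —
estimation error grows monotonically in `g`, and at `g = 1` is provably no
better than not registering at all — so the validation metrics' power to
*detect* a poor registration can be demonstrated without any commercial
system.  The perfect-DIR control arm (`registration="oracle"`) returns the
inverted true field and must drive gamma pass rates to ≥ 99.5 % and goal
flips to zero; both arms bracket any real system.

## Gamma analysis

For every reference voxel at or above 10 % of the reference global maximum,

    γ(r) = min over candidates p of sqrt(|p−r|²/Δd² + (D_eval(p)−D_ref(r))²/ΔD²)

with ΔD a percentage of the reference global maximum (global normalisation)
and candidates on a subvoxel lattice of pitch `interp_step` (default Δd/10)
within `search_cap` (default 2·Δd) of `r`, evaluated trilinearly; candidates
outside the evaluated volume are skipped.  The threshold applies to the
reference only and excludes voxels from numerator and denominator — the most
common convention.  The search walks candidates in order of increasing
distance and abandons a voxel once the pure-distance term exceeds its
running minimum, which is an *exact* minimisation over the candidate lattice
(the unit tests and the acceptance script verify bit-level agreement with an
exhaustive-search oracle) while making near-agreeing distributions cheap.
Pass rate is the percentage of evaluated voxels with γ ≤ 1; tightening
either criterion can only raise γ, and rescaling both doses together leaves
it unchanged.

## DVH metrics and clinical goals

`D` metrics (dose to the hottest v % or v cc) interpolate linearly on the
descending-sorted dose-volume curve with each voxel placed at the midpoint
of its volume increment, so sub-voxel volumes such as 0.03 cc are
grid-independent.  `V` metrics count voxels with dose ≥ d (reported as % of
structure volume or absolute cc).  Goals are written in the planning-system
grammar (`D0.03cc < 105% (109%)`, `V60Gy < 3% (10%)`, `V45Gy < 50cc`);
relative-dose thresholds resolve against the prescription total.
Inequalities are strict — a value exactly at threshold fails — and values
are compared at full floating precision.  Per-fraction doses are scaled by
the prescribed fraction number before goal evaluation; a summed course of
`F` simulated fractions is scaled by `n_fx/F`.

The goal-discrepancy statistic counts `a` (passed on the system dose, failed
on the truth) and `b` (the reverse) over all `G·F` goal evaluations of a
course and reports `round(100·(a+b)/(G·F))` as an integer percentage.
Pass/fail for this count uses the primary goal threshold; a variation-based
variant is available behind a flag, since audit conventions differ.  "Worst
per goal" across fractions takes the maximum for `<` goals and the minimum
for `>` goals.

## Contour and displacement metrics

Dice is `2|A∩B|/(|A|+|B|)` with two empty masks defined as 1.  The
Hausdorff distance is the maximum (100th-percentile) symmetric surface
distance in mm — unqualified "HD" conventionally means the maximum; a
percentile variant (e.g. 95) is available.  Surfaces are single-voxel
erosion differences; distances use anisotropic Euclidean distance
transforms.  Per-structure displacement statistics (max and mean magnitude)
are reported over the planning structure set; the max indicates range of
motion but similar maxima do not imply agreement, which is what the
voxel-wise field-error operation measures.

## Determinism and problem sizes

Every stochastic element (phantom texture, beam-weight modulation,
degradation noise) is driven by explicit integer seeds; re-running a YAML
course config reproduces every CSV byte for byte, and the acceptance script
asserts this.  The test suite runs the full anatomy on a 96×96×48 (2.5 mm)
validation grid and the perfect-registration control course at the default
128×128×64 grid; the exhaustive gamma oracle runs on 48³ volumes — sizes
chosen so the whole validation is a desk-scale computation.

## Known limitations

* The authored radial deformations are smooth and volumetric; they do not
  model sliding organ interfaces, bladder-wall incompressibility or
  biomechanics, and the spatial profile of any particular commercial
  deformation tool is not reproduced — only magnitude classes and
  invertibility are controlled.
* The analytic dose has no scatter, build-up or heterogeneity corrections;
  conclusions about accumulation accuracy transfer only insofar as gradient
  structure matters.
* The degradation knob models "worse DIR" generically (less signal, more
  smooth noise), not any specific algorithm change.
* Energy/mass-transfer dose mapping is deliberately excluded; the framework
  validates DDM-based systems.
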