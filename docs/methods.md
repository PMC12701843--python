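# Methods

## Scope and model

The package quantifies aortic conduit function from a 3-component
velocity field on a regular voxel grid over the cardiac cycle, a
triangulated lumen surface, and a centerline with five anatomic
landmarks (aortic valve plane, brachiocephalic artery, left subclavian
artery, the descending-aorta level aligned with the valve, and the
diaphragm). The landmarks split the vessel into four half-open
arc-length segments — AA, TA, DA1, DA2, distal endpoint closed — plus
the combined TA+DA1 transition; half-open intervals make the partition
exact by construction.

All conduit metrics are evaluated at **peak systole**, defined as the
frame maximizing the lumen-integrated momentum-magnitude proxy
Σ ρ|v| dV. The scalar proxy is used instead of the vector momentum sum
because flow direction reverses spatially around the arch and a vector
sum can self-cancel; ties resolve to the earliest frame.

### Advective pressure drop (SAW)

At a station the cross-section is sampled on a regular in-plane grid
(default step 1 mm, ≤ voxel spacing; 0.5 mm in worked examples),
velocities by trilinear interpolation, the lumen mask by a
point-in-contour test against the closed surface section enclosing the
centerline point. Then

    Q    = Σ (v·n) dA
    PD_A = ρ / (2Q) · Σ |v|² (v·n) dA,

converted Pa → mm Hg (÷ 133.322) only at the reporting boundary. The
1/Q prefactor is singular at low flow, so stations whose |Q| falls below
5% of the profile's maximum are carried as undefined rather than
propagated; if over 20% of stations are undefined a warning is recorded.
Closed forms used as oracles: plug profile → ρV²/2; parabolic
(Poiseuille) → ρV²; a general profile → ρ·α·V²/2 with shape factor
α = ⟨v³⟩/V³ (α = 2 + 0.6·e² for the skewed profile with eccentricity e).

The per-segment increment ΔPD_A defaults to **end-minus-start** (distal
minus proximal defined station), which can be negative — e.g. across an
aneurysmal segment where the section widens — matching how negative
regional increments arise in cohort tables; a max-minus-start variant
(always ≥ 0) is computed alongside and both are reported with the mode
recorded in provenance. Peak PD_A ties resolve to the most proximal
station.

### Comparators

*Simplified Bernoulli*: exact mode ρ·v_max²/2 in mm Hg; clinical mode
4·v_max² (v in m/s), the bedside coefficient that absorbs ρ/2 and the
unit conversion. Exact-mode Bernoulli ≥ PD_A for any profile (the peak
speed bounds the flux-weighted mean), with equality only for plug flow;
for parabolic flow the ratio is exactly 2, which grounds the
threshold-conversion utility (guideline threshold × corrective factor
0.65, e.g. 20 → 13 mm Hg).

*Wall shear stress*: at each surface vertex, velocity is sampled at
inward-normal offsets {h, 2h} (default h = half the voxel spacing,
trading truncation against interpolation error); with no-slip v(0) = 0
the tangential derivative is the second-order one-sided difference
(4v(h) − v(2h))/(2h) and WSS = μ·|·|. The stencil is exact for a
quadratic profile, so the Poiseuille oracle 4μV/R isolates
interpolation error. Vertices whose offsets leave the lumen are flagged
invalid, never imputed.

*Viscous dissipation*: strain rate e_ij = (∂ᵢv_j + ∂_jv_i)/2 by central
differences on the voxel grid, Φ = 2μ Σ e_ij², integrated over lumen
voxels. The velocity array is differentiated **as acquired**: at the
radial wall the stencil reaches one voxel outside where voxelized data
is (noise around) zero, encoding no-slip one-sidedly, while open flow
boundaries stay smooth. Zero-masking the field before differentiating
would instead create an artificial jump at the open ends whose spurious
dissipation grows ~1/h under refinement; with the as-acquired scheme the
Poiseuille oracle 8πμV²L converges monotonically (relative error 0.27 →
0.14 → 0.07 at 2/1/0.5 mm on the reference tube).

### Geometry

Diameter is measured where the plane perpendicular to the local tangent
cuts the surface, as the **equivalent-circle diameter** 2√(A/π) of the
enclosing contour — rotation invariant and stable on non-circular
sections; a point-pair variant (mean vertex distance to the contour
centroid, doubled) is available behind a flag since the averaging
convention in clinical practice is not standardized. Stations whose
plane exits the vessel are flagged missing, excluded from summaries,
never imputed. Curvature is the three-point Menger estimator (inverse
circumradius, 4·area/(|a||b||c|)) after uniform resampling (default
2 mm, matching acquisition resolution) and local quadratic smoothing
over a 5-point window (Savitzky–Golay), because raw three-point
curvature on voxel-derived centerlines is noise dominated; smoothing is
configurable and off in analytic oracles. Body-size indexing: value/BSA
or value/height^2.7; BSA by Mosteller √(height_cm·weight_kg/3600),
recorded in configuration since cohort conventions vary.

### Statistics

Per metric and group pair: Shapiro–Wilk per group (normal iff p ≥ α,
default 0.05); both normal → two-sided Student *t* (equal variances);
either non-normal (or degenerate) → two-sided Mann–Whitney U, exact by
enumeration for min(n) ≤ 8 without ties, normal approximation with tie
and continuity correction otherwise. The nonparametric path on a single
failing group is the conservative reading of "variables that did not
follow a normal distribution". No multiple-testing correction is
applied — p values are reported per metric as in clinical cohort
tables — a deliberate fidelity-over-orthodoxy choice. Box descriptors:
quartiles by linear interpolation, Tukey 1.5·IQR fences, whiskers at the
extreme non-outliers clamped to the box so the ordering invariant
survives degenerate small samples, mean reported separately.

## Phantom generator

The generator emulates the acquisition regimes of pediatric 4D-flow
studies: isotropic voxels 2.0–2.2 mm, 20 frames/cycle (~35–39 ms),
VENC 120–150 cm/s, free-breathing Gaussian velocity noise. Defaults:
ρ = 1060 kg/m³, μ = 4 mPa·s (standard blood values), noise sd = 5% of
VENC per component (acquisition noise is rarely reported; 5% is a
realistic free choice, fixed once), raised-cosine systolic pulse peaking
at frame 7 of 20 (any unimodal pulse suffices for peak-systole logic;
cycle-mean/peak ratio 0.35, so peak flow ≈ 2.86 × cardiac output,
consistent with peak-to-mean ratios of aortic flow curves).

Centerlines are integrated from an analytic planar curvature profile:
straight (κ = 0), arch (half-turn arc of radius R between straight
limbs, tangent continuous), gothic arch (arch plus a localized
raised-cosine curvature bump whose analytic peak is specified exactly —
the angular reconstructed-arch morphology). Surfaces are lofted tubes on
parallel-transported frames, watertight with end caps; lofts where local
radius × curvature ≥ 1 (rings crossing) are rejected. Radius profiles
compose a base radius, linear taper, and raised-cosine stenoses and
aneurysms, so the analytic extrema (min ring radius = (1−depth)·base)
are exact.

The analytic velocity field is tangent-aligned with cross-sectional
mean speed V(s) = Q/A(s) — flux through every perpendicular section
equals the specified Q — with plug, parabolic, or skewed profiles (apex
displaced toward the inner-curvature direction by eccentricity × radius;
the added term is odd in the in-plane angle so Q is preserved
analytically). Beyond the centerline ends the field continues as a
straight extension, avoiding artificial velocity jumps at the open
boundaries of the voxel box. Voxelization samples voxel centers, scales
per frame, adds i.i.d. Gaussian noise everywhere (background voxels are
static tissue: noise only), is bit-reproducible from the seed, and warns
(not fails) if the noise-free speed exceeds VENC since aliasing is not
simulated.

**What the phantoms do not emulate:** k-space physics, partial-volume
and aliasing effects, respiratory motion, eddy-current offsets,
segmentation error (the lumen is known exactly from the surface), and
branch vessels — flow is constant along the phantom aorta, whereas real
aortic flow decreases distally as head and neck branches take their
share. Passing tests therefore validate the estimators against known
ground truth at realistic resolution and noise, not robustness to
segmentation or reconstruction artifacts.

### Synthetic cohorts

`make_cohort` draws per-group anthropometrics (height, BMI → weight,
BSA by Mosteller), cardiac output, and the height-indexed
ascending-aorta diameter from group distributions whose default moments
are the published characteristics of healthy-control and post-Fontan
child/adolescent groups (e.g. cardiac output 3.7 ± 0.8 / 2.7 ± 0.7 /
6.8 ± 2.8 L/min; control transition increment 1.0 ± 1.2 mm Hg vs child
2.3 ± 1.4, adolescent ≈ 4.0 ± 1.7 from the reported ~74% further
increase). Conduit inefficiency is imposed constructively: a target
ΔPD_A is drawn per segment span and realised geometrically by solving
V_end² = V_start² + 2·ΔP/(ρα) for the distal radius, with the TA/DA1
split fixed at 40/60 of the combined increment and draws truncated at
physiologic floors. The emitted ground-truth manifest (diameter,
curvature, Q, PD_A per station; per-region scalars) is what downstream
tests and cohort statistics consume, so the full voxel pipeline can be
run on any subject but the 93-subject statistical studies stay at desk
scale.

## Numerical choices and problem sizes

Trilinear interpolation everywhere (matches data smoothness at 2 mm; no
spline option in v1). In-plane Riemann sums on the masked grid; the
plug-flow PD_A is exact under this quadrature because area errors cancel
between numerator and flux. Reference problem sizes: tubes of radius
10 mm and length 120–160 mm, voxelized at 0.5–2 mm (≤ ~3·10⁵ voxels);
curvature oracles at 2 mm resampling; cross-sections at 0.25–1 mm
in-plane steps; cohorts of 78 + 15 (+7) subjects; 10–50 noise seeds for
stochastic checks. Point-in-mesh tests use a slice-wise even-odd rule on
plane sections (exact on voxel grids, quantized to half a wall-step for
scattered points).

## Noise robustness: what holds and what does not

Under this noise model (i.i.d. Gaussian per component, fixed lumen mask,
fixed resolution), the fragility of the gradient-based comparators
appears as **bias**, not variance: at 5% VENC noise the integrated
dissipation of the reference taper phantom is inflated ~33% (the
squared noise gradient σ²/h² enters every voxel) and its truncation
error is strongly resolution dependent, while PD_A's quadratic noise
bias cancels in ΔPD_A differences. Across noise seeds, however, the
volume-integrated dissipation averages over every lumen voxel
(~10³–10⁴), so its seed-to-seed coefficient of variation
(~√(2/(9N)) × bias share ≈ 0.5%) is *smaller* than that of a regional
ΔPD_A, which rests on two cross-sections (~6% CV on the same phantom).
A variance-based ranking of the two metrics therefore does not hold in
this model and the corresponding check in the acceptance suite fails by
design of the model, honestly; the bias-based superiority of PD_A is
what the oracle tests demonstrate.

## Known limitations

- Only the advective term of the work–energy relative pressure is
  computed; transient and viscous terms, turbulence-resolving
  dissipation, and catheter peak-to-peak simulation are out of scope.
- Real-data ingestion accepts NIfTI velocity (5-D or per-component),
  STL/PLY surfaces and CSV centerlines; DICOM, segmentation, and
  centerline extraction from masks are not provided.
- Diameter and cross-section sampling assume a surface whose
  perpendicular sections yield a single enclosing contour; pathological
  geometries (planes grazing caps, kinks tighter than the lumen radius)
  are flagged or rejected rather than repaired.
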