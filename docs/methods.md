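# Methods

This note records the models implemented in the package, the choices made
where the design was genuinely open, and what the synthetic tests do and
do not establish.

## Orientation distributions and the SH basis

All orientation distributions (FODs from constrained spherical
deconvolution, tract orientation distributions from streamlines, the
atlas) are antipodally symmetric functions on the sphere, represented in
a real, even-order-only SH basis: for order $m>0$ the basis function is
$\sqrt2\,\mathrm{Re}\,Y_l^m$, for $m<0$ it is $\sqrt2\,\mathrm{Im}\,Y_l^{|m|}$,
and $m=0$ is the standard $Y_l^0$; degrees run over even $l$ only.
Coefficients are stored l-major with $m$ ascending ($j = l(l+1)/2 + m$),
giving $(l_{max}+1)(l_{max}+2)/2$ coefficients — 45 at the default
$l_{max}=8$. On disk this is a 4D NIfTI with the coefficient index on the
fourth axis and `lmax=<n>;basis=real-sym` in the header description.

This basis is orthonormal (verified against dense quadrature in the test
suite to 1e-6), which is what makes the final map cheap: the spherical
integral of a product of two band-limited functions is the dot product of
their coefficient vectors. Interoperability caveat: other diffusion tools
use real symmetric bases that differ in the sign/ordering conventions of
the $m\neq 0$ terms; coefficients produced elsewhere should be checked
against the convention above before being fed in, since the package's
documented ordering is the contract, not an assumption that all tools
agree.

A streamline direction enters as the band-limited expansion of a
unit-mass symmetric delta, whose coefficients are simply the basis row
evaluated at the direction. An optional per-degree apodization hook
exists for tapering Gibbs ringing but is off by default — the plain
truncated delta integrates to exactly 1 for every axis, which is what the
mass-conservation and normalisation properties rely on.

## Atlas construction

Each streamline segment contributes its delta, weighted by segment
length, to the voxel containing its midpoint. Midpoint assignment (rather
than exact polyline-voxel clipping) is first-order accurate at the 1-2 mm
segment lengths used here and keeps the accumulation a single vectorised
scatter-add. Per-voxel normalisation to unit spherical integral discards
streamline count/density; voxels whose integral is below 1e-8 of the
image maximum are zeroed rather than amplified. Subject maps are
normalised first and averaged second (the reverse is not equivalent), so
a voxel's integral in the atlas equals the fraction of training subjects
whose tract traverses it.

Registration resampling (`apply_affine`) moves coefficient vectors
spatially with per-coefficient trilinear interpolation and by default
does **not** reorient them: registration affines are near-rigid, the
atlas is deliberately spatially tolerant, and the inner product degrades
gracefully under small orientation error. A `reorient=True` path applies
the affine's polar rotation to each voxel's distribution via a
coefficient-space rotation operator obtained by re-fitting rotated point
samples (exact for band-limited functions; no Wigner machinery).

## Radial tumour deformation

The lesion is modelled as grown radially from its centre of mass $S$
(voxel-count centroid of the tumour mask, world mm). Displacement is
purely radial with magnitude $k\,D_t\,s$, where
$k = (1-c)e^{-\lambda D_p/D_b} + c$ and $c = e^{-\lambda}/(e^{-\lambda}-1)$
pins $k(0)=1$ and $k(D_b)=0$: the brain surface is a fixed set, and the
whole field is parameterised by one decay rate $\lambda$ and one scale
$s$.

Parameters and defaults:

- $\lambda$ (dimensionless, default `auto`): decay of displacement with
  relative depth $D_p/D_b$. Small lesions that barely disturb distant
  tissue warrant $\lambda \gtrsim 3$; `auto` uses the per-ray
  non-infiltrative ceiling $\lambda_{max}$, and a numeric $\lambda$ is
  capped per ray at $\lambda_{max}$ (policy `clamp`; `strict` raises
  instead, naming the ceiling).
- $s$ (dimensionless, default 1): multiplies $D_t$, i.e. radially rescales
  the effective lesion; $s=0.8$ models a partially debulked tumour when
  reusing a preoperative deformation, $s=0$ disables the warp. Because
  $s$ rescales the effective tumour, $\lambda_{max}$ is computed against
  $s\,D_t$, keeping the evacuation guarantee consistent with the scaled
  boundary.
- ray step (mm, default half the smallest voxel dimension): sampling step
  of the surface-distance marching.

$\lambda_{max}$ solves the implicit equation
$\lambda(1-c(\lambda)) = D_b/D_t$; since $1-c = 1/(1-e^{-\lambda})$ this
is the fixed point $\lambda = (D_b/D_t)(1-e^{-\lambda})$, iterated from
$\lambda_0 = D_b/D_t$ with internal stopping well below the 1e-10
relative target and a 200-iteration cap (non-convergence raises; the
iteration only degrades as $D_b/D_t \to 1$, i.e. a tumour touching the
brain surface, which the mask validation already forbids for the
synthetic phantoms). With $\lambda = \lambda_{max}$,
$k(D_p) \ge 1 - D_p/D_t$ on $[0, D_t]$, so every interior point lands on
or outside the lesion boundary.

Geometry is computed in world mm. $D_t$ and $D_b$ are found by marching
along each ray from $S$ in half-voxel steps, sampling the (binarised)
masks with trilinear interpolation and locating the first 0.5-crossing by
linear interpolation between steps — sub-voxel surface localisation that
the tests hold to within half a voxel of analytic ray-quadric
intersections. Both distances are functions of direction only, so the
forward and inverse maps of a given ray use identical values; the
in/out-of-brain gate is likewise the ray criterion $D_p < D_b$ (not an
independent pointwise mask test), which is why forward-then-inverse round
trips hit machine precision rather than disagreeing in the thin shell
where two different surface estimates would differ. For non-convex masks
the first exit is used and $k$ clamps to zero beyond it; displacement at
$S$ itself (direction undefined) is zero.

The inverse uses the closed form with the principal Lambert-W branch
(SciPy's `lambertw`). Target points strictly inside the effective lesion
surface have no forward preimage — the warp's image on each ray is
$[s D_t, D_b]$ — so volume pull-back leaves those voxels empty (no source
tissue exists), while the point-level inverse clamps the recovered
distance to the centre. Image deformation is pull-back with
per-coefficient trilinear interpolation, driven by the cached per-voxel
$D_p/D_t/D_b$ tables. The tables are float32 — their on-disk cache format
(three NIfTI volumes plus a JSON sidecar with $S$ and mask checksums) —
and are held in float32 in memory too, so a warm-cache run is
bit-identical to a cold one; the cache invalidates itself when the mask
checksums change. The warped atlas is *not* reoriented by the local
Jacobian rotation of the warp: displacement fields here are smooth and
radial, their local rotations small, and the method's tolerance to small
orientation error makes spatial-only deformation the default (the same
reasoning as for registration).

## Tract map

Per voxel, the map is the coefficient dot product of deformed atlas and
FOD (zero-padding reconciles differing band limits exactly). Truncated SH
expansions take small negative values, so the raw product can dip below
zero away from genuine overlap; these truncation artefacts are clamped to
zero by default (`clamp_negative=False` preserves the signed values). The
map is left on its raw overlap scale — no calibrated probability exists
for it — with an optional max-normalisation for display. Binarisation
uses `threshold_map`; the pipeline's default threshold is 0.1 of the map
maximum, a display-style relative cut chosen because the raw scale varies
with atlas sharpness and FOD amplitude.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (spec, seed). The phantom is an
ellipsoidal brain (default semi-axes 40x30x30 mm on a 64-cubed 2 mm grid)
with a spherical tumour (default radius 10 mm at (12, 4, 0) mm), both
defined by analytic quadrics so oracle distances exist in closed form.
Bundles are tubes of circular-arc or straight streamlines: per-streamline
Gaussian cross-sectional offsets (default 2 mm) around an analytic
centreline, so vertex tangents stay analytic. FOD fields are built from
bundle tangents exactly as TODs are, optionally summing a crossing bundle
and adding seeded Gaussian coefficient noise at a stated fraction of the
mean c0 (default 5% in the end-to-end scene) — a stand-in for CSD fitting
noise with no claim to its spectral structure.

The end-to-end scene displaces the patient bundle with the *same* forward
model later used to deform the atlas, so it tests the pipeline's internal
consistency — geometry, inversion, interpolation, SH algebra,
thresholding — not the biological fidelity of the radial model. Passing
it shows the machinery recovers a known displacement; it says nothing
about infiltrative lesions, oedema, tissue-stiffness differences, or how
well a single-parameter radial push approximates real mass effect, all of
which are outside the model by construction. Likewise the synthetic
"subjects" share a centreline distribution far tighter than real
anatomical variability, so the reported Dice (~0.75 at desk scale with a
4-subject atlas) is a pipeline-consistency figure, not a clinical
accuracy estimate.

Problem sizes used throughout tests and examples — 64-cubed grids, 10^4
round-trip points, 4 training subjects of ~24 streamlines — were chosen
as the smallest scale at which every geometric effect (off-centre lesion,
curved bundle, crossing region, sub-voxel surfaces) is still present;
each stage runs in seconds on one CPU.

## Numerical notes and limitations

- Fixed-point $\lambda_{max}$ is vectorised over rays; `auto` solves it
  per ray, matching the spatially varying ceiling.
- The Lambert argument is clipped to $[-1/e, 0]$ after the strict-policy
  domain check; without clipping, floating-point noise at the exact
  domain boundary (reached at $\lambda=\lambda_{max}$, $D_p'=sD_t$) would
  produce NaNs.
- Ties at mask value exactly 0.5 resolve to "inside" (crossings are
  localised by linear interpolation, so exact ties are measure-zero).
- Single lesion with a defined boundary only; no multi-focal tumours, no
  infiltration, no brain-shift model beyond the $s$ rescaling.
- TOD mapping assigns whole segments to midpoint voxels; bundles much
  coarser than the voxel grid would need resampling before mapping.
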