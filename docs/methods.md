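# Methods

## Problem and model

`fibray` quantifies the local 3D orientation of straight, fiber-like
structures (electrospun scaffold fibers, reinforcing fibers, trabeculae) in
volumetric grayscale images such as μCT reconstructions.  An orientation is
an (azimuth θ, elevation φ) pair in degrees: φ ∈ [0°, 90°] is the
inclination from the Z axis (the stack axis), θ ∈ [−90°, 90°) the in-plane
angle; a fiber along Z has (0°, 0°).  The unit axis vector is

    d(θ, φ) = (sin φ cos θ, sin φ sin θ, cos φ)   in (x, y, z) components.

Fibers are undirected axes: d and −d are the same orientation, which is why
elevation is restricted to the upper hemisphere and azimuth to a 180°-wide
interval.  Note that this printed range covers only half of undirected-axis
space — an axis with upper-hemisphere azimuth outside [−90°, 90°) is not
representable.  The synthetic generator draws its ground truth from the same
ranges so that estimates and truth live in the same space, and azimuth
errors are computed modulo 180° (see *Error convention*).

## Ray-casting estimator

At a query voxel p the ray-sum in direction (θ, φ) is the discretized
bidirectional line integral

    R(p, θ, φ) = Σ_{l=-⌊L/2⌋}^{+⌊L/2⌋} V(nearest_voxel(p + l·d(θ, φ)))

and the estimated orientation is the argmax of R over a discrete angular
grid (default θ: −90..89°, φ: 0..89°, 1° steps).  Choices that matter:

- **Sampling** is nearest-voxel (per-component round-half-up of the offset
  l·d; the rule separates exactly into integer site + precomputed integer
  offset, which is what the JIT kernel exploits).  Trilinear interpolation
  is deliberately not used: integer sampling keeps the kernel exactly
  reproducible by a naive reference implementation, which the test suite
  asserts sample-for-sample.
- **Ray length** defaults to L = round(√2·N_W) for an analysis window of
  side N_W voxels, i.e. the ray spans the window diagonal; samples may
  leave the window (the ray is limited by a sphere of radius L/2, not the
  window cube).  Out-of-volume samples contribute 0 rather than clamping,
  avoiding a bias toward volume-edge directions.
- **Scan order and ties**: elevation outer ascending, azimuth inner
  ascending; the first direction attaining the maximum wins.  This makes
  results bitwise reproducible.  Near the degenerate angles (azimuth 0°,
  ±90° combined with low elevation) ray-sums tie exactly and symmetrically
  about the truth, so the reported angle can sit anywhere in the tie set —
  this is the method's documented error-prone region and the angular
  resolution limit arcsin(1/(L/2·sin φ)) of a length-L ray.
- **Pole convention**: if the winning elevation is 0° the azimuth is
  reported as 0° (all azimuths are equivalent on the pole).
- **Indeterminate sites**: if the best ray-sum does not exceed the value at
  the site itself (an isolated voxel), the estimate carries no directional
  evidence and is flagged; downstream statistics exclude these sites.
- **Ray input**: rays are cast through the skeleton volume by default — the
  maxima are sharp because only medial-axis voxels accumulate — with the
  segmented binary volume selectable.

## Structure-tensor baseline

The baseline sums gradient outer products over the uniform (unweighted)
N_W³ cube centered on the site, clipped to the volume; the eigenvector of
the smallest eigenvalue of that 3×3 tensor is the axis of least intensity
variation, i.e. the fiber direction.  The eigenvector is canonicalized to
z ≥ 0 and converted to angles with the azimuth folded into [−90°, 90°).
If the two smallest eigenvalues agree within a 1e-9 relative tolerance the
window is isotropic and the site is flagged instead of reporting a spurious
axis.

Gradients are central differences (one-sided at borders).  On hard-edged
binary segmentations the raw differences concentrate on grid-aligned facet
normals and bias the recovered axis by up to ~5° on oblique cylinders, so
field estimation regularizes the gradient with a derivative-of-Gaussian at
scale 1 voxel by default (`gradient_sigma`); this restores ≤1.5° accuracy
on ideal cylinders while the window weighting itself stays uniform.  Field
estimation evaluates all windows in O(1) each via 3D summed-area tables
over the six gradient-product volumes; a naive per-window accumulator is
kept and the two paths are asserted equal in the tests.

## Synthetic phantoms

Phantoms are binary volumes of rasterized straight circular cylinders with
exact continuous ground-truth angles per fiber.  Defaults mirror the
validation regime this package replicates: radii uniform in 3–20 voxels,
surface-to-surface gaps 3–10 voxels, azimuth uniform in [−90°, 90°),
elevation uniform in [0°, 90°].  Fibers traverse the volume (half-length =
cube diagonal / 2, clipped), since partially spanning fibers are not part
of the modeled regime.  Placement is rejection sampling — orientation,
radius, gap and center drawn uniformly; a candidate is accepted iff the
minimum distance between clipped axis segments minus both radii is at least
the larger of the two sampled gaps — with 100 attempts per fiber and a
logged warning when fewer fibers fit.  Everything is driven by one seed.

Contamination models detector noise as additive i.i.d. Gaussian noise of
standard deviation σ_agn on a float copy of the binary volume (signal
amplitude 1, no clipping), followed by Gaussian smoothing of width σ_smooth
— in that fixed order.  What the phantom does **not** model: curved or
touching fibers, radius variation along a fiber, beam hardening, ring or
streak artifacts, partial-volume gray levels.  Passing the synthetic
experiments therefore demonstrates correctness of the estimators on the
straight-separable-fiber regime, not robustness to every real μCT artifact.

## Workflow

Real and synthetic volumes run the same chain: 3×3×3 median filter (edge
replication at borders, so no artificial dark rim perturbs the subsequent
threshold) → Otsu threshold over a 256-bin histogram (global by default;
per-slice selectable for stacks with slice-to-slice illumination drift) →
topology-preserving 3D thinning (Lee-style removal of simple border points,
via scikit-image) to a 1-voxel medial axis → orientation estimation at
every skeleton voxel.

A quirk of the thinning stage worth knowing: a perfectly grid-aligned tube
whose cross-section has no unique center voxel (even diameter, fractional
axis position) can thin to nothing; randomly placed phantom fibers are
essentially never in this degenerate position, but synthetic fixtures
should use odd-diameter, voxel-centered cylinders.

## Error convention and evaluation

Elevation error is |Δφ|.  Azimuth error is min(|Δθ|, 180° − |Δθ|): the
azimuth of an undirected axis is defined modulo 180°, so −88° vs +88° is a
4° error, not 176°.  Both errors lie in [0°, 90°].

Estimated skeleton sites are matched to ground truth by nearest rasterized
fiber-axis voxel within 2 voxels (k-d tree); unmatched sites — mostly
noise-debris skeleton fragments under heavy contamination — are counted
separately and excluded from the error means, as are indeterminate sites.
Reports carry per-component mean, standard deviation and sum, the site
count and the exclusion count.

The harness provides: a σ_agn ladder (noiseless rows use the raw phantom;
noisy rows add smoothing σ_smooth = 1.0) with tensor-minus-raycast
difference columns; window sweeps (even windows map to the next odd, since
a centered cube needs a center voxel) returning the summed-error-minimizing
window; 5°-bin polar error heatmaps over ground-truth (θ, φ) with empty
cells marked NaN (distinct from zero error, for log display); 5°-bin
orientation histograms; and closed-form per-site operation counts,
(N_θ·N_φ)·√(2·N_W²) for ray casting and N_W²·(10/3·N_d³+N_d²)+(6·N_d²+N_d)
for the tensor — the latter formula is reproduced verbatim as printed in
its source including the N_W² (rather than N_W³) window term.

## Scaled validation experiment and what it shows

The packaged replication runs at desk scale: 256³ voxels and 20 fibers
(the published experiment used 512³ and 70 fibers — the same fiber density
per volume within 2×), 2° angular steps instead of 1°, three phantom
seeds, window 33.  On one CPU the five-σ ladder takes roughly 10 minutes
and the two-σ acceptance run about 5.

Representative results (seeds 0–2, this package):

| σ_agn | ray az | ray el | tensor az | tensor el |
|-------|--------|--------|-----------|-----------|
| 0.0   | ~3.0°  | ~0.9°  | ~1.0°     | ~0.7°     |
| 1.0   | ~3.9°  | ~1.3°  | ~1.5°     | ~0.8°     |
| 2.0   | ~16.7° | ~9.6°  | ~3.5°     | ~1.9°     |

Two deviations from the published comparison deserve explanation, both
consequences of evaluation-protocol choices made deliberately here:

1. **Absolute errors are smaller than the published table.**  The period-180
   azimuth wrap removes the catastrophic ±90°-boundary penalty (an estimate
   of −88° against a truth of +88° scores 4°, not 176°), and excluding
   unmatched debris sites keeps noise-induced skeleton fragments from being
   scored against fibers they do not belong to.  Under heavy noise most of
   the published error growth is attributable to exactly such sites (at
   σ_agn = 2.0 the over-segmented skeleton here carries ~30× more unmatched
   debris voxels than matched fiber voxels).
2. **The tensor baseline is not uniformly worse than ray casting at this
   scale.**  With wrap-corrected azimuth scoring, gradient regularization,
   and debris exclusion, the tensor's continuous eigenvector output beats
   the 2°-quantized ray scan at low noise; ray casting's remaining error is
   concentrated at low-elevation fibers where its azimuth resolution
   collapses (see the tie analysis above).  The published superiority of
   ray casting re-emerges at high noise only partially here.  The
   acceptance tests record this honestly: the error-magnitude targets pass
   (smaller error than published is acceptable), while the
   sign-of-difference expectation is asserted as published and fails under
   this protocol.

## Numerical and degenerate-input policy

- Even analysis windows are rounded up to the next odd; window ≥ 3.
- Constant volumes have no Otsu threshold and raise; a constant slice in
  per-slice mode is left empty with a warning.
- Empty site sets return empty fields with a warning, not an error.
- The Otsu threshold may fall anywhere on an exactly tied plateau of empty
  histogram bins between two well-separated classes; any tied choice yields
  the identical segmentation.
- All randomness (phantom placement, noise) flows from explicit integer
  seeds through `numpy.random.default_rng`; repeated runs are bitwise
  identical, including under the parallel JIT kernel (per-site reductions
  are sequential).
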