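# Methods

## Image model and geometry

Images are d-dimensional (d ∈ {2, 3}) scalar arrays with physical geometry:
origin (mm), strictly positive spacing (mm), and an orthonormal direction
matrix.  Indices are 0-based; a voxel's physical position is its center, and
the image domain is the closed box of voxel centers — interpolation outside
it returns a configurable outside value (default 0), and metric sampling
instead *drops* samples whose mapped point leaves the moving domain (see
below).  Compute precision is 64-bit float throughout; a 32-bit "accelerated"
storage path exists for the pyramid and resampler to mirror single-precision
device execution, and its agreement with the double path is part of the test
surface.  NIfTI-1 and MetaImage I/O go through SimpleITK; NIfTI orientation
follows the sform with qform fallback, MetaImage's TransformMatrix maps
directly onto the direction matrix.

## Transforms

Parameter layouts are documented in `voxelreg.transforms`.  Choices that were
genuinely open:

* **Rigid parameterization** — Euler angles, R = R_z R_y R_x in 3-d, one
  angle in 2-d, rotation about a configurable center (image center during
  registration).  Similarity adds one isotropic scale as the last parameter.
* **B-spline grid placement** — the control lattice covers the fixed-image
  physical extent with a two-spacing margin per side, so every point of the
  domain keeps its full (O+1)^d support.  Points outside the support move
  identically (zero displacement).
* **Composite semantics** — members apply innermost-first,
  T(x) = T_n(…T_1(x)); only the last (outermost) member is optimized, earlier
  stages are frozen, matching the similarity → affine → B-spline staging.
* **Transformation averaging** returns a dense displacement field sampled on
  a caller-supplied lattice with linear inter-voxel interpolation, since the
  average of arbitrary nonrigid members is not parametric.  This
  representation is closed under averaging and numerically invertible.
* **Inversion** is damped fixed-point iteration v ← v − λ(U(x+v) − x) with
  λ = 1 and a fallback to λ = 0.5 when the worst residual increases;
  tolerance 0.01 mm, 50 iterations by default.  The template-construction
  wrapper samples the average on a lattice padded by the observed peak
  displacement so the inverse is well-defined at the domain edge.
* **Grid refinement** uses the exact cubic subdivision weights
  (1, 4, 6, 4, 1)/8 for dyadic spacing halving — the refined transform
  reproduces the displacement field to rounding — and falls back to a
  least-squares coefficient fit with a reported residual for non-dyadic
  targets.

## Interpolation

Nearest-neighbor rounding is half-away-from-zero per component (documented
because single- and double-precision paths can legitimately disagree at
near-half-integer positions; the tests assert such flips are isolated).
Linear and first-order B-spline interpolation produce identical values; the
linear kind carries the fast analytic gradient used in metric assembly.
Cubic B-spline interpolation prefilters the image into spline coefficients
(scipy's recursive filter, mirror boundary), so voxel values are reproduced
at voxel centers to 1e-8.  Gradients are the analytic derivatives of each
interpolant, converted to physical units through spacing and direction.

## Gaussian pyramid

Smoothing is a 4th-order recursive (IIR) approximation of Gaussian
convolution in the Deriche family, applied separably per axis (x, then y,
then z); all scan lines within an axis are independent, so any processing
order gives the identical result.  The filter is realized as two *parallel
second-order sections* — the approximating impulse response is a sum of two
damped cosinusoids, each with an exact 2nd-order recursion — rather than one
direct 4th-order recursion: the parallel form is markedly better conditioned
in single precision.  Numerators are normalized to unit DC gain, and the
image is filtered as deviation-from-mean, which together preserve constants
and keep the float32 path's nRMSE against the float64 path near 1e-7 (the
contract is < 1e-6 per level).  Boundaries are handled by edge-value
extension with a pad long enough for the transient to die out (10σ + 8
samples).  Accuracy of the approximation itself is pinned by a dense-FIR
oracle: relative L2 error ≤ 1e-3 on impulses for σ ∈ {1, 2, 4}.

σ is interpreted in voxel units.  The standard 4-level schedule pairs
downsampling factors (8, 4, 2, 1) with σ (4, 2, 1, 0); downsampling modes
are `off`, `shrinker` (every factor-th voxel, origin kept at the old
index-0 voxel center), and `resampler` (linear interpolation onto a lattice
with spacing × factor).  `max_local_line_length` is a planning utility for
devices that stage scan lines in small local memories (three float buffers
in 16 kB bound lines to 1365 elements); the implementation itself has no
such limit.

## Metrics and stochastic sampling

Samples are uniform continuous points over the fixed domain (rejection-
sampled against an optional mask), drawn from a counter-keyed generator
(seed, iteration), so iteration-k sample sets are reproducible without
sequential state.  Samples mapping outside the moving domain are excluded
and η recomputed over the remainder — boundary voxels then never contribute
outside-value artifacts to the derivative; fewer than two surviving samples
is an error.

* **MSD** — η Σ (I_F − I_M∘T)², ξ = 2(I_M∘T − I_F).
* **NC** — cost 1 − NC² with NC the Pearson correlation of the sampled
  intensity pairs; analytic ξ from the quotient rule (mean terms cancel).
  Constant images yield a flat cost with zero derivative.
* **MI** — negated Mattes-style mutual information: 32 histogram bins,
  zero-order window on the fixed intensity, cubic B-spline Parzen window on
  the moving intensity.  Bin edges derive from the global image ranges (the
  moving range spread over bins 2..B−3 so the 4-tap window never leaves the
  histogram), making the estimate a smooth function of the moving samples;
  the analytic derivative is the standard Σ β₃′ · log(p/p_M) form.
* **Bending energy** — η-weighted sample sum of the squared Frobenius norm
  of the transform's second spatial derivative, analytic in the B-spline
  coefficients; exactly zero for globally affine displacement.  Exposed as
  an optional regularizer with weight 0 by default (on the synthetic
  recovery problem it reduced accuracy at every weight tried).

All four derivatives are validated against central finite differences to
1e-4 relative (they agree to ~1e-9 in practice).  The fork-join contract
splits the per-sample accumulation into T contiguous partitions whose
partition-mean vectors are joined as η Σ_t n_t g^t; for any T the result
equals the single-partition sum up to floating-point reassociation
(≤ 1e-12 relative per component).

## Optimization

Plain decaying-gain gradient descent a_k = a/(A + k)^α (defaults A = 20,
α = 0.602).  Adaptive step-size estimation is intentionally out of scope;
instead two classical stabilizers make the plain scheme robust across
transform kinds and intensity scales:

* the derivative is normalized by its max-norm before the gain is applied,
  so `a` reads as an initial parameter step in physical units (mm);
* the returned parameters of each resolution are the Polyak–Ruppert average
  of the iterate over a tail fraction of its iterations (default 50 %),
  which suppresses the random-walk noise floor that constant-magnitude
  stochastic steps would otherwise leave.

New samples are drawn every iteration; a non-finite derivative or overlap
failure is retried once with a fresh sample set, then aborted with context.
Stages run coarse-to-fine over the shared pyramid; the B-spline grid spacing
halves per resolution via the exact subdivision, ending at the configured
finest spacing.

The standard recovery protocol used by the acceptance machinery is
3 resolutions × 1000 iterations with 2000 samples per iteration, finest
grid spacing 8 mm on a 64 mm synthetic volume (proportionally matching the
6 mm used on ~200 mm adult-brain volumes), gain a = 3 mm, and tail
averaging over the last 30 %.  On one CPU this runs in about a minute in
2-d and a few minutes in 3-d.

## Resampling

The resampler computes I_M(T(x)) over an output lattice (normally the fixed
geometry) in three stages per chunk — initialize the coordinate buffer,
apply the transform stages innermost-first (a composite is unrolled into its
member list at call time), interpolate — with chunks as contiguous
flat-index ranges (default 2²⁰ voxels).  Chunking bounds the intermediate
coordinate buffer and is semantically invisible: outputs are bit-identical
for any chunk size.  The single-precision path stores the moving image, the
coordinate buffers and the output in float32.

## Cohort operations

Template construction, template-image averaging, majority-vote fusion
(ties break to the smallest label value; the counting is atlas-order
invariant), Jacobian-determinant modulation (negative determinants are
counted and warned about as a folding diagnostic), region-wise volume
features (per-ROI map mass × voxel volume ÷ intracranial volume, with an
exclusion list), and the comparison measures nRMSE, displacement-field RMSE
(optionally masked) and Dice (both-empty defined as 1).  Feature z-scoring
uses the population (divide-by-n) standard deviation, fitted on a designated
subject subset and applied to all rows; constant columns become zero with a
warning.  Classifier training is outside the package boundary — the feature
table is the interface.

## Synthetic data: what it emulates and what it does not

The generator draws an analytic *scene* — a smooth intensity ramp plus
randomly placed anisotropic Gaussian blobs, clipped to [0, 1000] — defined
on all of ℝ^d, samples it on the lattice, and adds white noise.  Blob
density defaults to 20 (2-d) / 80 (3-d) blobs so a realistic fraction of the
field of view carries texture, including its boundary faces; a scene
textured only in the interior would leave the boundary deformation
ill-determined (an aperture problem no registration method can overcome).
Warped pairs plant a random cubic B-spline field (peak displacement bounded
below half the warp grid spacing, guaranteeing invertibility) and build the
moving image by sampling the scene at numerically inverse-warped positions
on a lattice padded by the displacement amplitude — so the true
correspondence of every fixed voxel lies inside the moving field of view,
as it does for a scan that fully contains the matched anatomy.  Label
atlases are Voronoi partitions warped per atlas.

What passing tests on these fixtures show: the machinery recovers known
smooth deformations to well under a voxel, conserves modulated mass, and is
exactly reproducible.  What they do not show: robustness to the intensity
inhomogeneity, partial-volume effects, anatomy-dependent contrast and
pathology of real MRI — the fixtures have stationary noise, globally smooth
truth, and no tissue model.

## Numerical choices and degenerate inputs

Tolerances: geometry round-trip 1e-10; direction orthonormality 1e-6;
inversion 0.01 mm (50 iterations); cubic-coefficient reproduction 1e-8;
FIR-oracle 1e-3; derivative oracles 1e-4 relative.  Degenerate inputs fail
loudly with typed errors: axes shorter than 4 samples under smoothing,
empty masks, all-zero nRMSE references, more partitions than samples,
non-finite gradients.  Determinism: every stochastic component is keyed by
explicit seeds; registrations with one partition are bit-reproducible.

## Known limitations

No adaptive step-size estimation (the classical gain must be chosen per
problem scale, though the max-norm normalization makes the default broadly
usable); no diffeomorphic guarantees (folding is diagnosed, not prevented);
displacement-field transforms are linearly interpolated (their spatial
Jacobian uses central differences); 4-D series, DICOM and GPU execution are
out of scope.
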