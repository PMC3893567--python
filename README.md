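# voxelreg

Parametric intensity-based image registration for 2-d and 3-d medical images,
with the cohort-level machinery of morphometry studies: unbiased template
construction, multi-atlas label fusion, and Jacobian-modulated volume
features.  Everything is exercisable on built-in synthetic data — no external
dataset is needed.

## Who it is for

Researchers who need a transparent, fully-tested reference implementation of
the classical registration stack — the kind of pipeline used to normalize
structural MRI into a common space for group comparison or diagnostic
classification — and who want to inspect or instrument every stage of it
from Python.

## The model

Registration estimates the parameters **μ** of a coordinate transform
**T**_μ : Ω_F → Ω_M that makes a moving image I_M(**T**_μ) match a fixed
image I_F, by minimizing a cost 𝒞(I_F, I_M; μ) with iterative gradient
descent,

    μ_{k+1} = μ_k − a_k g_k,        a_k = a / (A + k)^α,

inside a coarse-to-fine Gaussian-pyramid loop.  The derivative g_k is a
stochastic estimate over a small random subset Ω̃_F of fixed-domain points,
redrawn every iteration:

    g_k = η Σ_{x ∈ Ω̃_F}  ξ(x) · J(x)ᵀ ∂I_M/∂x,      η = 1/|Ω̃_F|,

where J = ∂**T**/∂μ is the transform's parameter Jacobian and ξ the
metric-specific factor (for mean squared difference, the intensity
residual).  For a cubic B-spline free-form deformation J is block-sparse:
only P = (O+1)^d basis products are nonzero out of d·N entries, and the
package computes exactly those, making the per-sample cost O(dP) rather than
O(dN).  Supported metrics are MSD, normalized correlation, and Mattes-style
mutual information, plus a bending-energy penalty; transforms are
translation, rigid, similarity, affine, cubic B-spline, dense displacement
fields, and arbitrary compositions.

Cohort operations follow the unbiased-template recipe: with pairwise
transforms W_{i,j} from subject i to subject j,

    U_i(x) = (1/N) Σ_j W_{i,j}(x)   (identity W_{i,i} included),
    V_i    = U_i⁻¹,
    Ī(x)   = (1/N) Σ_i I_i(V_i(x)),

and warped probabilistic tissue maps are modulated by det(∂**T**/∂x) so that
total tissue volume is preserved by spatial normalization.

## Worked example

`examples/01_register_synthetic_pair.py` plants a known random B-spline warp
(peak displacement 3 voxels) in a 64² synthetic image pair and registers the
pair back with the similarity → affine → B-spline staging over 3 pyramid
levels:

```
initial field RMSE : 1.534 mm (the planted misalignment)
final field RMSE   : 0.188 mm (residual after registration)
improvement        : 8.2x
final metric value : 3.55 (mean squared intensity difference over the last sample set)
```

The initial RMSE is the root-mean-square of the planted displacement field;
the final RMSE compares the recovered field against the ground truth voxel
by voxel — 0.19 mm means the nonrigid stage found the true deformation to a
fifth of a voxel.  The other examples demonstrate the pyramid precision
contract (`02`), template construction and majority-vote fusion (`03`), and
modulated volume features (`04`).

A thin command-line interface mirrors the library for batch use:

```
voxelreg fixtures --kind pair --shape 64,64,64 --seed 7 -o fx/
voxelreg register --fixed fx/fixed.mha --moving fx/moving.mha -p params.txt -o out/
voxelreg resample --moving fx/moving.mha -t out/transform.txt -o warped.mha
voxelreg compare --reference fx/fixed.mha --test warped.mha
```

with `params.txt` holding flat `Key = value` pairs
(`Transform = similarity affine bspline`, `Metric = msd`,
`NumberOfResolutions = 3`, …; every key has a documented default and unknown
keys are rejected).

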