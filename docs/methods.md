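# Methods

This note records the models, numerical choices and limitations behind
`mrepmap`, in the spirit of a methods appendix. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions

World coordinates are millimetres with x = patient lateral,
y = anterior–posterior (+y posterior), z = craniocaudal (+z superior).
Volumes store `data[ix, iy, iz]` with `world = origin + index * spacing`
referring to voxel centers; indices are 0-based. The default imaging
geometry is 1 × 1 mm axial pixels with 3 mm slices.

## The m-rep chain model

A chain of `n_atoms` medial atoms (default 13) spans the organ from the
superior to the inferior pole; each atom carries a hub and `n_spokes`
spokes (default 16; spoke 0 points anterior). Pole atoms sit at the
chain ends with all spokes meeting at the pole, which closes the
interpolated surface without extra cap machinery. The continuous
coordinate map is

    x(i, j, k) = hub(i) + k · r(i, j) · U(i, j),

with the hub curve interpolated by a cubic spline in `i`, spoke length
`r` and direction `U` by bicubic splines (periodic in `j` via generous
periodic padding; directions renormalized after interpolation), and
`k` linear. At integer (i, j) the map reproduces the stored atoms
exactly, so refining the surface sampling never moves existing spoke
tips. A *rind* extends the `k` domain to `1 + t/r(i, j)` so that a
point at `k = 1 + d/r` lies exactly `d` mm beyond the surface along the
spoke; the default thickness is 3 mm (middle of the 2–5 mm band used
for dose mapping).

**Inversion** (`image_to_model`) seeds from a cached coarse (i, j, k)
lattice via nearest neighbour and refines with damped Gauss–Newton on
the squared distance (numerical Jacobians, step clipping, quarter-step
fallback); the convergence tolerance is 0.01 mm and a point is declared
outside the domain when the residual exceeds 0.05 mm. Round-trip errors
on interior points are below 0.01 mm. Ties at the medial curve (where
`j` is unidentifiable at `k = 0`) are resolved by damping; only the
position, not the `j` label, is meaningful there.

**Containment** (`chain_mask`) classifies voxel centers: voxels far
from the boundary by the sign of the offset along the nearest boundary
sample's outward normal, voxels in a thin shell around the boundary
exactly by inversion. The optional occupancy output adds a box-filter
partial-volume fraction along the local normal, used by the phantom
renderer.

## Fitting a chain to planning contours

The fit assumes the organ is star-shaped about its volume centroid —
true for prostate-like bodies. Stages:

1. Center estimation: area-weighted contour centroid, then up to two
   re-centerings on the numeric volume centroid of the fitted surface.
2. A regularized real spherical-harmonic fit (degree 8) of the radial
   surface r(θ, φ) to all contour vertices; the penalty
   `smoothness_weight · n_vertices · (ℓ(ℓ+1))²` enforces the continuous-
   curvature constraint and controls the polar extrapolation beyond the
   last contour slice.
3. A one-shot linear polish of the spoke-tip radii: bicubic cardinal-
   spline design matrix against the vertex radii with a squared
   discrete-Laplacian curvature penalty (`smoothness_weight · n_vertices`)
   and a weak anchor to the harmonic solution for the unconstrained
   polar caps.

The reported residual is the true Euclidean vertex-to-surface distance
(dense sampling plus Gauss–Newton refinement), averaged per contour and
then over contours. `smoothness_weight = 1e-5` by default, set so that
smooth phantom contour stacks fit to well under 0.2 mm with hubs
recovered within 0.5 mm; larger weights trade residual for smoothness.

## Shape space

Atom parameters are stacked as hub (3), log spoke lengths (16), raw
spoke direction components (48) per atom; log lengths keep synthesized
lengths positive and directions are renormalized on synthesis. The
shape space is the SVD of centered training vectors (orthonormal modes,
variances in non-increasing order). Per-patient training sets are
synthesized perturbations of the fitted planning chain (below), not an
inter-patient atlas.

## Rigid registration

Translation-only throughout; rotations are deliberately not modeled
(patient setup corrects translations; residual rotation is absorbed by
the deformable segmentation).

* Step 1 uses a body mask threshold of −200 HU for the skin bounding
  boxes, the bone window [200, 1500] HU for per-slice voxel counts, and
  normalized cross-correlation over integer slice shifts (ties to the
  smallest |shift|). Bright contrast (>1% of in-body voxels above
  2000 HU in the pCT) sets the skip flag and the cascade starts at
  step 2. The window bounds and contrast rule are configurable; no
  canonical published values exist for them.
* MI uses a 64-bin joint histogram with partial-volume (trilinear-
  weight) accumulation and a minimum overlap fraction of 0.25. For the
  optimization samplers the fixed-image sample positions are jittered
  off the voxel grid (seeded, ±0.5 voxel, trilinear fixed intensities):
  with equal slice grids the partial-volume joint histogram sharpens
  artificially whenever a candidate z-shift aligns the two grids,
  producing spurious MI maxima at multiples of the slice thickness;
  jittering removes these. The plain `mutual_information` function
  keeps exact voxel-center sampling, so MI(A, A) equals the histogram
  entropy H(A) exactly. Ascent is gradient ascent with central
  differences (one voxel step) and a backtracking line search, stopping
  when the accepted step falls below 0.1 mm or after 200 iterations.
* Step 2 runs a deterministic star of starts (prior ± 10, 20, 30 mm per
  axis, 7 by default) on a coarse sample grid (stride 6 × 6 × 2), then
  one fine ascent (stride 3 × 3 × 1) from the best start. Whether the
  original multi-start scheme was random or structured is not
  documented; determinism was chosen for reproducibility.
* Step 3 restricts the fixed-image samples to the atlas model placed at
  the prior, dilated by an 8 mm margin.

## Segmentation

The posterior combines geometric typicality
`−½ Σ cᵢ²/σᵢ²` and an image match: boundary-crossing intensity
profiles (±5 mm at 1 mm steps) sampled along spokes of an interpolated
2× spoke grid, z-scored per profile under a Gaussian offset taper
(σ = 2 mm), scored by the tapered negative mean squared difference
summed over spokes. Both images are pre-smoothed with a 1 mm Gaussian
before profile sampling. These likelihood choices were set by probing
the match landscape on phantoms: atom-resolution sampling plus raw
voxel noise leaves the weakest shape mode (craniocaudal elongation,
whose signal lives at the poorly-resolved poles) with a posterior
spread approaching its prior sigma, and an untapered profile lets the
far tail — which can contain structures such as bone that move
relative to the prostate between images — bias the deformation
estimate away from the true boundary by more than a prior sigma. The
taper keeps the ±5 mm reach while making the boundary crossing carry
the likelihood.

Optimization is Polak–Ribière conjugate gradient over translation (3)
plus the mode coefficients covering 95% of training variance, in
preconditioned units (mm, units of σ); gradients by central differences
(step 0.05), normalized search directions with backtracking line
search, restart every dim+1 iterations, stop at objective gain below
1e-6 or 300 iterations. Coefficients are hard-clipped to ±3σ, so the
model never leaves the trained space. Accepted steps are monotone by
construction; the diagnostics record the objective trace and a
convergence flag. Geometry and image terms carry equal unit weights by
default (no relative weighting is prescribed by the underlying
formalism); both are configurable, and the two degenerate limits
(prior-only, data-only) are exercised in the tests.

## Dose mapping and DVHs

Delivered dose is modeled as a rigid translation of the planned dose
grid to each mapped isocenter — the central simplification of this
package; no per-treatment heterogeneity recomputation is performed.
Reverse mapping assigns each planning-grid voxel inside prostate + rind
the trilinear-interpolated treatment dose at its corresponding point;
voxels whose corresponding point leaves the source grid are flagged and
left undefined rather than zero-filled, as is all tissue outside the
modeled region. Accumulation resamples each contribution onto the
planning grid and sums voxelwise; the error dose subtracts the
fraction-scaled plan. DVHs count voxel centers inside the interpolated
surface (sub-voxel partial volumes ignored; conservation is exact by
construction at the voxel level) with 10 cGy default bins aligned to
multiples of the bin width.

## Evaluation statistics

Signed differences are method − reference per axis. Summary rows use
the mean unsigned difference, max, min, and the sample (n−1) standard
deviation. Histogram bins are centered on zero with widths 0.5 mm
(x, y) and 1.0 mm (z). Outliers are |Δ| > 3σ_clinical on any axis, with
σ_clinical computed from the same dataset being flagged. The precision
comparison is a two-sample variance-ratio F test per axis
(two-sided p from the F(n_a−1, n_b−1) distribution); "pooled axes"
variants are not implemented because the per-axis test is what the
summary tables support.

## The phantom

The phantom emulates a pelvic CT pair: soft-tissue body ellipse
(46 × 40 mm semi-axes), a pelvic bone ring with femoral-head spheres
(asymmetric in z so slice profiles are informative), optional bladder
contrast (2500 HU, exercising the step-1 skip) and rectal gas pocket, a
prostate rendered from the chain model, and Gaussian intensity noise
(default σ = 15 HU). Every structure is rendered with partial-volume
(box-filter) edges — binary voxel rendering quantizes all boundaries to
the 3 mm slice grid, which both erases the sub-slice information real
CT carries and (measurably) biases registration and shape estimation.
Levels: air −1000, soft tissue 35, prostate 70, bone 1000 HU — chosen
once as representative of low-contrast prostate CT.

The prostate surface is an ellipsoid (semi-axes 25 / 20 / 30 mm) with
seeded low-order radial harmonics (rms 2%). Three generative
deformation modes act on log spoke lengths — volume scale, anterior–
posterior squash, craniocaudal elongation — each with a 4% (1σ)
physical amplitude; deformations are applied directly in m-rep
parameter space so segmentation ground truth is exact. A linearized
rotation mode was evaluated and rejected: for a near-axisymmetric
smooth organ its radial boundary signal (~0.1 mm per σ) is far below
the noise, making the coefficient unidentifiable; rotation instead
enters as an explicit out-of-space perturbation (`rotation_deg`).

Inter-image motion separates the whole-patient setup translation
(default: uniform ±10 mm per axis from the seed) from internal prostate
motion relative to bone (N(0, 2 mm), clipped ±4 mm). Skin marks are the
body-surface projections of the planned isocenter; imaged BBs follow
the setup translation with 0.3 mm placement noise. The simulated
user-directed comparator adds zero-mean Gaussian error with per-axis
σ = (1.4, 2.3, 3.5) mm around the true isocenter — a stand-in for
intra/inter-user match variability, not a claim about human operators.

The analytic plan is a 200 cGy prescription plateau over prostate plus
a 5 mm margin with a Gaussian falloff (3 mm scale), evaluated at 1 mm
and resampled to the 5 mm planning grid.

**What the phantom does not emulate:** beam hardening, scatter and
CBCT artifacts; realistic bone texture; bladder/rectum deformation
coupled to the prostate; inter-patient anatomy variation; out-of-space
organ deformations beyond rotation. Passing tests therefore demonstrate
the correctness and precision of the algorithms under controlled
conditions, not clinical performance on patient images.

## Problem sizes and determinism

Phantom volumes are 128 × 116 × 36 voxels (1 × 1 × 3 mm). The seeded
study populations are 100 phantoms for rigid-registration recovery
(pure translations uniform over ±20 mm), 50 for segmentation parameter
recovery, and 50 for the end-to-end comparison; shape spaces are
trained on 60 synthesized chains (200 where mode-subspace recovery
itself is under test). All randomness flows through explicit seeds
(numpy Generator substreams), and every stage logs its parameters.

## Known limitations

* The fit requires star-shaped organs and a single contour per slice;
  bilobed cross-sections or branching anatomy are out of scope.
* `image_to_model` is only as exact as the star-shaped spoked volume is
  a bijection; strongly bent or self-overlapping chains would violate
  this silently.
* The image-match likelihood is a fixed profile-MSE surrogate, trained
  per patient on a single planning image; it has no learned covariance.
* The clinical comparator is a parametric error model, so comparisons
  against it quantify the automatic pipeline's precision, not human
  performance.
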