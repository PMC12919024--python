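# Methods

This note records the models implemented in `cellshapes`, the conventions
chosen where the underlying procedures leave freedom, the defaults and why,
and what the synthetic-data generators do and do not emulate.

## 2-D contour model

A cell (or nucleus) outline is an ordered simple polygon in micrometres
(pixel inputs are scaled by a caller-supplied resolution; 0.49 μm/px is the
reference value for the imaging setup the defaults were designed around).
Pose is removed before fitting:

1. the area centroid is translated to the origin;
2. the contour is rotated so the leading eigenvector of the boundary-point
   scatter lies along x;
3. among the four axis-flip choices (±x, ±y) the one placing the largest
   enclosed area in the first quadrant is kept (computed by clipping the
   polygon against the quadrant; ties keep the unflipped orientation).

Rotationally symmetric contours (order ≥ 3 symmetry makes the point scatter
isotropic) have no defined principal axis; alignment then warns and keeps the
incoming orientation rather than picking an arbitrary one.

The aligned contour is resampled at uniform normalized arc length,
θ_k = 2πk/N with N = 360 by default (comfortably above the 4·15+2 = 62
parameters of the body fit and independent of the input vertex density).
Arc-length parameterization needs an origin and a direction that the
procedure itself does not supply; the package fixes **counterclockwise
traversal starting from the vertex of maximal x (ties toward larger y)**.
This is a convention, not a derived fact — but it is applied identically to
every cell, which is what makes coefficients comparable across cells.

x(θ) and y(θ) are fit as two independent linear least-squares systems over
the shared trigonometric design matrix (constant column ½, then cos nθ,
sin nθ). The truncation order is chosen by inspecting RSS/AIC/BIC across
orders; the information criteria use the Gaussian least-squares form
AIC = N ln(RSS/N) + 2p and BIC = N ln(RSS/N) + p ln N with the x and y
residuals pooled (N = 2 × samples, p = 4n + 2). Whether to pool or score
per-axis was an open choice; pooling matches how the fit is actually used
(one order for both coordinates).

A caution for interpreting the order-selection table: radial lobe
modulations do not land on the same contour harmonic. A five-lobed star
r = R + A cos 5t enters x = r cos t at harmonics 4 and 6 (product-to-sum),
so the RSS elbow sits at the sidebands of the lobe frequency, not at the
lobe count itself. The tests pin this behaviour.

## 3-D surface model

Meshes must be watertight and genus 0. Alignment:

1. the volume centroid is recorded (its z, in μm, is the height feature:
   cells with pre-alignment centroid height > 10 μm are labeled *deformed*,
   ≤ 10 μm *non-deformed* — the tie goes to non-deformed so the rule
   partitions heights) and translated to the origin;
2. basal facets are those with face-normal z < −0.8; their area-weighted
   mean normal is rotated onto (0, 0, −1). Because facets cross the −0.8
   threshold as the mesh rotates, this is solved as a fixed-point iteration
   (re-select facets, rotate, repeat until the mean normal is within 10⁻⁹ of
   −z); that is what makes alignment exactly idempotent;
3. the mesh is spun about z so the leading principal axis of the
   xy-projected vertex scatter lies along x (angle normalized to
   (−π/2, π/2] since the axis is directionless), then flipped 180° about z
   if the enclosed volume with x > 0 is less than half the total. The
   half-space volume is computed exactly by clipping triangles against
   x = 0 and applying the divergence (cone) formula with apex at the
   origin, which lies in the cap plane, so the cap contributes nothing.

Spherical parameterization places 64 polar rings at θ_j = (j − ½)·π/64 and
128 azimuthal columns at φ_i = i·π/64, plus the two poles: 8,194 grid
directions with uniform π/64 spacing and no ring/pole collision. ("Resolution
π/64" admits several grids; this is the one whose cardinality is 8,194.)
Each grid direction takes the Cartesian position of the mesh vertex whose
centroid-relative direction is angularly nearest (maximum dot product,
implemented as a Euclidean nearest-neighbour query on unit vectors; ties are
resolved by the k-d tree deterministically). Nearest-vertex lookup assumes
star-convexity about the origin; a fast sufficient check (all face normals
pointing away from the origin) warns when the map may fold. The origin must
be inside the mesh, verified by the surface's winding number about the
origin (van Oosterom–Strackee solid angles), which needs no spatial index.

Each coordinate function over the grid is fit independently against the
complex spherical-harmonic basis Yₗᵐ (m = −l…l; scipy's `sph_harm_y`,
Condon–Shortley phase) by unweighted complex least squares over the 8,194
grid points. A quadrature alternative (inner products with sin θ weights)
would differ only through the grid's nonuniform area sampling; the two agree
on band-limited shapes, and the test suite uses the quadrature form as the
independent oracle for the sphere's degree-1 coefficient
c₁₀ᶻ = √(4π/3) ≈ 2.0467. For real surfaces the fitted coefficients satisfy
the conjugate symmetry c_{l,−m} = (−1)ᵐ c̄_{l,m} to solver tolerance, which
is why (L+1)² complex coefficients per coordinate carry the expected number
of real degrees of freedom. Degree selection mirrors the 2-D elbow
diagnostics with p = 6(L+1)² pooled over the three coordinates.

## Fiber anisotropy

Gradients use the exact 3×3 Sobel-Feldman kernels applied as true
convolutions (the kernel is flipped, as the convolution notation implies);
on a unit ramp the interior response has magnitude 8. Border handling and
kernel truncation are not specified by the construction, so the package uses
reflection padding everywhere (zero padding would manufacture spurious edge
anisotropy) and truncates the Gaussian at 4σ. The smoothing σ defaults to
4 px — about one stress-fiber diameter at the reference resolution — and is
exposed because it should track the structure of interest.

Coherence c = (λ₁−λ₂)/(λ₁+λ₂) with λ₁ ≥ λ₂ from the closed-form symmetric
2×2 eigendecomposition. The 0/0 case (flat regions) is undefined in the
formula; the package defines c = 0 wherever the tensor trace is below
10⁻¹² of the image's maximum trace, reading "no signal" as "no preferred
direction". DOA is the median coherence over the mask (standard
midpoint-of-two rule for even counts). DOA is invariant to affine intensity
rescaling I → αI + β (α > 0) since gradients scale linearly and the
eigenvalue ratio cancels the scale.

## Harmonized records

A record is [flattened shape coefficients | scalar biology (DOA or height) |
one-hot condition]: 84 + 1 + 2 = 87 columns in the 2-D schema, 726 + 1 + 2 =
729 in 3-D. The numeric block — including the scalar, which is normalized
together with the coefficients — is z-scored feature-wise with the
**population** standard deviation (ddof = 0; the convention is recorded in
the stats object). Zero-variance columns would produce NaNs; they are
dropped with a warning and their constants stored so denormalization
restores them exactly. One-hot columns pass through untouched. Exactly two
categories is the validated regime; more are accepted with a warning. CSV
serialization keeps 17 significant digits and the reader parses with
round-trip float precision, so write→read→write is byte-stable.

## β-VAE

Architecture: input n → 8n → ReLU → 4n → ReLU → parallel linear heads for μ
and log σ² (latent dimension 15); reparameterized z = μ + exp(logσ²/2)·ε;
mirrored decoder 15 → 4n → ReLU → 8n → ReLU → n. Loss =
(1−β)·MSE + β·KLD with β = 10⁻⁶, the MSE averaged over samples × features
and the closed-form Gaussian KLD summed over latent dimensions and averaged
over samples. The one-hot columns are part of the reconstructed vector and
therefore of the MSE; argmax snapping happens only at generation time.
Training is full-batch Adam (lr 10⁻³, 500 epochs). Weights initialize
uniformly in ±1/√fan_in (the standard linear-layer default), from the same
seeded generator that drives the reparameterization noise, so training is
bit-reproducible single-threaded. At β = 0 the objective is exactly the
plain autoencoder MSE (property-tested); the backward pass is hand-derived
for this fixed architecture and verified against central finite differences.

The network and optimizer are implemented directly in numpy. The model is
seven dense layers trained full-batch; an explicit implementation keeps the
package light, makes the gradient check meaningful, and removes any
framework nondeterminism from the reproducibility story.

Generation samples z ~ N(0, I), decodes, denormalizes with the training
statistics, clips a DOA scalar to [0, 1] (heights are not clipped), and
snaps the one-hot block by argmax. The naïve baseline draws each feature
independently from its own 1-D Gaussian KDE (Silverman bandwidth — none is
prescribed), which preserves marginals but destroys cross-feature
correlation by construction; the Spearman-matrix Frobenius distance to the
real data is the fidelity summary on which the VAE must beat it. Novelty is
the nearest-real Euclidean distance in normalized numeric space.

## Outliers and eigenshapes

PCA is an eigendecomposition of the covariance of the standardized numeric
block (one-hot columns removed; the standardization statistics are shared
with the harmonization step so both pipelines scale identically). K is the
minimal component count reaching 95 % cumulative variance, capped at the
matrix rank. In PC coordinates the covariance is diagonal(λᵢ), so
D_M² = Σ (xᵢ−μᵢ)²/λᵢ; the package compares **D_M² against χ²₀.₉₅,K**
(equivalently the root distance against the root quantile). Comparing the
root distance directly against the unrooted quantile would misstate the
null level badly (e.g. at K = 66 it would flag essentially nothing); the
squared comparison is the one under which scoring training data against
itself flags ≈ 5 %, which the tests verify at n = 10⁴. Per-PC contributions
(xᵢ−μᵢ)²/λᵢ sum to D_M²; rankings use contributions normalized to 1, ties
toward the lower index. Eigenshapes start from the training-mean score
vector, move one component to mean + sσ for s ∈ {−2, −1, 0, 1, 2}
(σ = √λ), invert the PCA and the standardization, and decode with the
matching geometry module; all other components stay at their training means,
so the s = 0 shape is the mean shape regardless of which PC is swept.

## Augmentation experiment

Classifiers are unregularized logistic regressions (no regularization is
prescribed; L2 remains available through the underlying estimator) on shape
coefficients only — the scalar biology column and one-hot conditions are
excluded, and alignment has already removed pose and position, so the model
can only use morphology. The test split is stratified 70/30, fixed per
seed, drawn from real cells only, and identical across schemes. The VAE
that supplies synthetic cells is trained exclusively on the 50 % real
training subset, so no information from test cells can leak through the
generator. Synthetic labels come from the generated one-hot block. ROC/AUC
is implemented in-package (threshold sweep with tied scores grouped,
trapezoidal area — equal to Mann–Whitney pair counting with ties worth ½)
and cross-checked against both pair counting and scikit-learn in tests.

## Synthetic data: what it does and does not emulate

Boundaries are star-shaped radius functions — a base ellipse of aspect
ratio *e* at constant area (a·b = R², R = 10 μm by default) plus Gaussian
bump protrusions (default 3–6 bumps, 2 μm amplitude) and radial noise
(0.2 μm). Star-shapedness guarantees simple polygons without
self-intersection checks. Two-class populations separate by elongation
(class means at the ends of the elongation range, per-cell spread 15 %) and
by the DOA-like scalar (class means 0.25/0.75, sd 0.1, clipped to [0, 1]);
both separations are constructed ground truth that downstream classifiers
are measured against. Meshes are displaced icospheres (smooth radial bumps)
clamped against a basal plane (flat bottom with exact −z normals), tilted
5–15° for the deformed class, and translated so the volume centroid sits at
a drawn height — 4–8 μm for non-deformed, 12–18 μm for deformed — so the
10 μm labeling rule recovers the class exactly. Fiber images are sinusoidal
stripes (period 12 px) with optional Gaussian background noise and a
central-disk mask.

None of the generators simulate microscope optics, point-spread functions,
segmentation errors, touching cells, or non-star-shaped morphologies.
Passing tests therefore demonstrate the correctness and calibration of the
computations, not robustness to real segmentation artifacts; real inputs
with folds or self-intersections are outside the generators' support and
will trigger the star-convexity warnings rather than silent misfits.

All randomness flows from one integer seed per call through a dedicated
generator; no global random state is touched anywhere in the package.

## Problem sizes used in the test and acceptance runs

Populations of 100–300 cells, Fourier order 15/5, SPHARM degree ≤ 10 on
the full 8,194-vertex grid, VAE training of 30–500 epochs on ≈ 200 × 87
tables, and a 10⁴ × 20 null-calibration sample. These sizes make the whole
suite run in well under a minute of numerical work per stage while keeping
every statistical check (null rate 5 % ± 1 %, AUC comparisons, fidelity
inequalities) adequately powered.

## Known limitations

- Arc-length parameterization origin/direction and the spherical grid
  placement are conventions; coefficients are comparable within this
  package but not numerically identical to other implementations of the
  same models.
- The unweighted SPHARM least squares slightly overweights polar regions
  relative to an area-weighted quadrature; for shapes band-limited well
  below the grid Nyquist the difference is negligible (tested), for sharper
  shapes the fitted coefficients are a least-squares compromise on this
  particular grid.
- The β-VAE is full-batch; very large tables would need minibatching,
  which is deliberately not implemented (batch size was not part of the
  validated regime).
- Eigenshape decoding assumes no numeric column was dropped as
  zero-variance; fixtures guarantee that, degenerate real tables may not.
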