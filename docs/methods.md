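# Methods

This note records the modelling assumptions, numerical conventions, and
design choices behind `earlyfmt`, and what the synthetic studies do and
do not demonstrate.

## Physical model and discretization

Photon densities at the excitation and emission wavelengths obey
coupled time-domain diffusion equations with Robin boundary conditions
(see the README for the equations).  Optical properties are taken as
identical at both wavelengths — the excitation/emission bands of common
NIR fluorophores are close enough that separate property maps would add
parameters without changing the study's conclusions.

Space is discretized with linear (P1) tetrahedral elements and
piecewise-constant coefficients per element; all element integrals use
closed forms (mass `(V/c)(1+δij)/20`, surface `(A/2q)(1+δij)/12`,
constant gradients for the stiffness term).  An independent Gaussian-
quadrature oracle in the test suite confirms the closed forms to 1e−12.
The Robin term `(1/2q)∮ u_i u_j` is folded into K.  Time uses backward
Euler, which is L-stable: fields stay finite for Δt from 1 to 100 ps
(property-tested).  The matrix A = K + C/Δt is symmetric positive
definite; it is factorized exactly once (sparse LU on the SPD system)
and reused by every source, detector, and time step — the "precompute
the inversion" economy, realized as a factorization because it is
mathematically equivalent and better conditioned than forming A⁻¹.

### Time-grid convention

Fields are stored as N×(T+1) arrays over nodes t_k = k·Δt with
G(·,0) ≡ 0; the gate index is `round(gate/Δt)` (snapped with a warning
when off-grid).  The default grid is Δt = 10 ps over 300 ps, so the
300 ps gate is the final stored node.  The excitation impulse is a unit
nodal load applied in the first update; a unit discrete load represents
a source of time-integral Δt, so comparisons against continuous
Green's functions divide the field by Δt.  The impulse magnitude and
its half-step time offset cancel exactly in the normalized Born ratio.

Sources and detector-adjoint anchors are placed by displacing the
surface point one transport mean free path 1/μs′ along the inward
normal and snapping to the nearest node; the detector reading is the
nodal photon density (for an isotropic impulse source the Green's
function equals the density, so no exitance conversion is applied).

### Weight matrix

The Born weight of node n for pair (s,d) at gate index K is evaluated
with the exact discrete adjoint identity of the stepping scheme:

    W[sd, n] = (c/τ) Σ_{j=0..K} (Gs ∗ E)[n, j] · (C · Gd[·, K−j])_n

where ∗ is the causal discrete convolution `out[k] = Δt Σ a[j]b[k−j]`.
The mass matrix C distributes the nodal emission density into
consistent FEM loads — the exact counterpart of a lumped nodal-volume
share.  Because the emission equation is exactly linear in η with
frozen optical properties, W·η reproduces the fully coupled two-stage
simulation to rounding error (verified to ~1e−10 relative per pair);
"first-order Born" is not an approximation inside this model, only with
respect to real physics (no fluorophore absorption feedback).

Rows are independent across nodes and pairs; the `accelerated` backend
evaluates them with vectorized Toeplitz/contraction kernels, while the
`reference` backend loops node-by-node through the scalar convolution.
Both agree to 1e−12 and the scalar convolution matches a brute-force
O(T²) double sum bitwise (the production loop uses the same sequential
accumulation order — vectorized BLAS paths differ in the last ulp,
which the exactness contract forbids).

### Normalized Born and the early-gate validity floor

Each row and its datum are divided by that pair's gated excitation
Φx(gate), cancelling source strength and coupling.  Pairs whose
|Φx(gate)| falls below `1e−9 × max` are flagged unusable and excluded
(listed, never silently dropped).  A caveat specific to early gates: at
the default mesh resolution (~0.18 cm) the true transmitted excitation
at 300 ps across the 2.4 cm phantom (~1e−6 of the source) lies below
the spatial-discretization floor, and computed gate values for some
antipodal pairs are small or even negative.  Because measurements and
weights derive from the same discrete operator, the normalized system
remains exactly consistent and reconstruction is unaffected in these
synthetic studies; with experimental data such pairs must be excluded
by a detector-dynamic-range floor instead.  This is the main feature of
real data the generator does not emulate (along with instrument
response functions, autofluorescence, and model mismatch between the
reconstruction mesh and the animal).

## Acquisition geometry

The specimen's rotation stage is emulated by rotating the
source/detector frame about the fixed z-axis: 6 projections at 60°
(n × increment must equal 360°), one source per projection on the
boundary at height 1.9 cm — the plane through the fluorescent target,
matching the study layout — and detectors on the opposite surface
within a 120° field of view and a ±0.75 cm z-band, uniformly
subsampled over azimuth to 120 per projection (720 pairs).  Detector
density and z-extent are free parameters of the instrument model;
neither is pinned by the study being emulated.

## Synthetic phantom

A 1.2 cm × 3 cm cylinder stands in for the segmented torso: a
structured cylindrical lattice (rings every ~edge length, tiny
deterministic jitter to break Delaunay degeneracies; wall and cap
points jittered only tangentially) is triangulated with scipy's
Delaunay — exact for a convex domain.  Ellipsoidal heart/lung/liver
regions carry the published optical properties (heart 0.156/9.0, lung
0.516/21.2, liver 0.935/6.4, background 0.1/10 cm⁻¹); element regions
are assigned by centroid membership.  Around the fluorescent target a
dedicated point cluster is inserted whose inner points' Voronoi cells
tile the target cylinder, so the discretized yield mass matches
η × volume within a few percent at default resolution (the surrounding
lattice is cleared from that neighbourhood first).  Refractive index
defaults to n = 1.37 (c = 0.0300/n cm/ps, q from the standard
effective-reflection fit); lifetime defaults to τ = 560 ps, a typical
NIR-dye value — the emulated study never states one.

## Reconstruction

Relaxed Kaczmarz over the gated normalized system, η initialized to 0,
λ = 0.1, 100 full sweeps, nonnegativity clamped after every row update
(the stronger, standard variant), fixed source-major row order
(seeded-random optional), rows with squared norm below 1e−30 skipped
and counted.  Updates are invariant to per-row scaling; without the
clamp the iteration converges to the minimum-norm solution (tested
against a pseudoinverse oracle).

Two quality metrics accompany the result: the distance from the
η-weighted centroid of above-half-maximum nodes to the true target
center, and the fraction of recovered yield mass (η × nodal volume)
within a given radius of it.  The cross-precision error metric is
`max |η_ref − η_test|/η_ref × 100%` over nodes where the reference is
at least 1% of its maximum (the formula is undefined on the empty
background, where nonnegative ART reconstructs exact zeros).

A caution established by in-package experiments: the 100-sweep
under-relaxed iterate is a *semi-converged* regularized solution.  On
noiseless data the exact nonnegative least-squares solution recovers
the target perfectly, but fully converged solutions of 10%-noise data
are dominated by noise fitting; the protocol's early stopping is what
makes the noisy reconstruction localize (~0.23 cm).  The price is
spatial spread: only ~30% of the recovered mass lies within 0.5 cm of
the target, for noiseless and noisy data alike, and longer iteration
makes the spread worse, not better.  Users who need compact recoveries
should stack additional gates or use an explicitly sparsity-promoting
solver — both outside this pipeline's default protocol.

## Precision parameterization

The dominant-cost stages — batched detector-adjoint propagation (T4)
and weight construction (T5) — accept single or double precision.  In
single mode the inverse of A is precomputed in double, cast to float32,
and each step becomes one float32 matrix multiplication (the structure
used when offloading these stages to multiply-optimized hardware);
stages T1–T3 and the ART solve remain double.  The measured
cross-precision reconstruction difference on the default phantom is
~0.003% over the support, well below the 0.15% working tolerance.
Casting the *factorization* itself to float32 instead raises the error
to ~0.3% — the precomputed-inverse structure is what keeps single
precision accurate.

## Problem sizes and determinism

Default studies use the ~3100-node phantom, 720 pairs, 31 time nodes —
chosen so a full double-plus-single comparison completes in a couple of
minutes on one CPU while remaining in the regime of the emulated study
(3074–4697 nodes, 710–1409 detectors).  The finer analytic-limit check
uses a 15k-node homogeneous mesh at Δt = 4 ps.  All randomness (mesh
jitter, measurement noise, optional row shuffling) flows from explicit
seeds; a configuration reruns to bit-identical artifacts (HDF5 written
without timestamps).

## Known limitations

- Diffusion approximation only; no radiative-transfer or telegraph
  corrections, so very early gates in low-scatter regions are outside
  the model's validity.
- Linear elements and consistent mass admit small negative field
  undershoots near impulsive sources (no discrete maximum principle).
- Single-gate reconstruction is severely underdetermined; see the
  reconstruction caution above.
- No instrument response function, camera mapping, or free-space
  optics; detector readings are nodal densities.
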