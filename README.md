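# earlyfmt

Time-domain **early-photon fluorescence molecular tomography** (FMT) in
Python: a finite-element time-domain diffusion forward model, Green's-
function-based normalized-Born weight matrices built by temporal
convolution, and nonnegative ART reconstruction of 3-D fluorophore
distributions — with the heavy detector-adjoint and weight-matrix stages
batched and parameterized by floating precision.

It is written for researchers in diffuse optical / fluorescence imaging
who want a transparent, fully scriptable reference pipeline for gated
(early-photon) reconstruction on tetrahedral meshes.

## The model

Photon migration at the excitation (x) and emission (m) wavelengths is
modelled by coupled time-domain diffusion equations on a domain Ω with
Robin boundary conditions:

    (1/c) ∂Φx/∂t + μa Φx − ∇·(D ∇Φx) = δ(r − r_s, t)
    (1/c) ∂Φm/∂t + μa Φm − ∇·(D ∇Φm) = (η(r)/τ) [Φx ∗ E](r, t)
    2qD ∂Φ/∂n + Φ = 0  on ∂Ω,        D = 1 / (3(μa + μs′))

where η is the fluorophore yield, τ its lifetime, E(t) = exp(−t/τ), and
∗ temporal convolution.  Galerkin FEM over linear tetrahedra plus
backward-Euler stepping gives

    (K + C/Δt) G(k+1) = (C/Δt) G(k) + S(k),      G(−1) = G(0) = 0,

with stiffness/boundary matrix K and mass-like matrix C.  To first Born
order the gated fluorescence measurement for a source-detector pair is

    Φm(r_sd, t) = Σ_n W(r_sd, n, t) η_n,
    W = G_s ∗ E ∗ G_d   (normalized per pair by Φx(r_sd, t_gate)),

and η is recovered from the single early gate (300 ps) by relaxed
Kaczmarz (ART) iterations with nonnegativity clamping (λ = 0.1, 100
sweeps).  The matrix A = K + C/Δt is factorized once and reused for
every source, detector, and time step; detector-adjoint fields for all
detectors advance jointly one time node at a time.  In single-precision
mode the inverse of A is precomputed in double and the per-step batched
multiplications run in float32.

The default synthetic phantom is a 3 cm tall, 1.2 cm radius cylinder
with ellipsoidal heart/lung/liver regions carrying published murine
optical properties (background μa = 0.1, μs′ = 10 cm⁻¹) and a small
cylindrical fluorescent target (radius 0.1 cm, height 0.2 cm) at
(−0.31, −0.02, 1.93) cm.  Six sources at 60° increments illuminate the
surface; detectors cover a 120° field of view opposite each source.

## Worked example

```sh
earlyfmt all --out demo
```

runs phantom generation → FEM assembly → excitation Green's functions
and synthetic noisy measurements → batched detector-adjoint fields →
normalized-Born weight matrix → nonnegative ART, and prints:

```
 T1 load data / phantom          0.17s  {}
 T2 assemble K, C                0.15s  {'nodes': 3112}
 T3 form Gs / forward data       0.58s  {'nodes': 3112, 'pairs': 720}
 T4 form Gd                     10.31s  {'nodes': 3112, 'detectors': 364}
 T5 form W                       0.87s  {'pairs': 720, 'nodes': 3112}
 T6 solve eta                    0.67s  {'pairs': 720, 'nodes': 3112}
{
  "localization_error_cm": 0.22899358186160143,
  "mass_fraction_within_0p5cm": 0.27767765623283414,
  "max_eta_hat": 0.0888048178485883,
  "n_nodes": 3112,
  "n_pairs_excluded": 0,
  "n_pairs_usable": 720
}
```

The phantom mesh has 3112 nodes; all 720 source-detector pairs pass the
gated-excitation validity floor.  The reconstructed target centroid
(over nodes above half maximum) lands 0.23 cm from the true target
center — about one mesh edge length — while the recovered yield mass is
spread more broadly, the expected behaviour of 100 under-relaxed
Kaczmarz sweeps on a single-gate system (see `docs/methods.md`).
`demo/` receives the mesh (TetGen `.node`/`.ele`), VTK fields
(`eta`, `eta_hat`, optical properties), the gated system
(`weights.mtx`, `rhs.csv`), measurements (HDF5), the residual log, and
`metrics.json`.  The subcommands `phantom`, `forward`, `weights`, and
`recon` write the same artifacts piecewise.

Everything is equally usable as a library:

```python
from earlyfmt import PipelineConfig, run_pipeline
arts = run_pipeline(PipelineConfig(precision="single"))
print(arts.metrics)
```

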