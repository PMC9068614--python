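# Methods

This note documents the model, the numerical conventions, the synthetic data
conditions, and the design choices made where more than one construction is
self-consistent. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The model

The potential is an E(3)-equivariant message-passing network. A configuration
is a graph whose nodes are atoms and whose directed edges connect atoms
closer than a cutoff radius `r_c` (periodic images included). Node features
are geometric tensors: direct sums of irreducible representations (irreps) of
O(3), labeled by rotation order `l` (dimension `2l+1`) and parity
`p ∈ {+1, -1}`, with a channel multiplicity per `(l, p)`.

A forward pass is:

1. **Embedding.** One-hot species → linear map → even scalars (`0e`).
2. **Interaction blocks** (repeated `num_layers` times):
   self-interaction → convolution → self-interaction → per-species residual
   add → gate nonlinearity. The convolution couples the neighbor's features
   with a filter `S(r⃗) = R(r) Y(r̂)` through Clebsch-Gordan tensor products;
   every output `(l_o, p_o)` obeys the triangle rule
   `|l_i − l_f| ≤ l_o ≤ l_i + l_f`, the parity rule `p_o = p_i p_f`, and the
   truncation `l_o ≤ l_max`. The sum over neighbors is divided by `√N̄`,
   where `N̄` is the average neighbor count of the *training set*, computed
   once and frozen in the model configuration. All learnable filter content
   is in the radial function `R`, an MLP on a trainable Bessel expansion of
   the distance; messages therefore vanish smoothly (value and two
   derivatives) at `r_c`.
3. **Output block.** The even scalars of the final features pass through two
   linear atom-wise layers (feature width 16, then 1), giving a per-atom
   energy. Per-species learnable scale/shift (init 1 and 0) are applied, and
   the per-atom terms are summed into the total energy.

Forces are the exact negative gradient of the total energy with respect to
positions, obtained by reverse-mode differentiation through the entire graph
including the edge vectors. Energy conservation is therefore structural, not
learned. Setting `l_max = 0` collapses the same code to an invariant
(scalar-feature) network — the equivariance ablation is a configuration
switch, not a separate implementation.

### Automatic differentiation

The package carries a small reverse-mode engine (`e3pot.autodiff`) written on
numpy. Every vector-Jacobian product is expressed in engine operations, so
backward passes are themselves differentiable: this second-order capability
is required because the training loss contains the forces, i.e. a gradient.
All computation is float64; the equivariance and gradient-check tolerances
(1e-10 for symmetry contracts, 1e-4 relative for force/finite-difference
agreement at step 1e-3 Å) reflect double-precision accumulation over ~10²
flops per component.

## Conventions (documented, not canonical)

Any self-consistent set of conventions passes the same mathematics; these are
the ones implemented:

* **Real spherical harmonics** as Cartesian polynomials (never spherical
  angles, so there is no pole singularity), component-normalized:
  `Σ_m Y_m^(l)(u)² = 2l+1` on the unit sphere. Ordering `m = −l..l` with the
  standard real combinations; `l=1` is `√3 (y, z, x)`.
* **Wigner matrices** are built from the closed-form factorial sum for the
  small-d matrix and the complex→real basis change; improper elements act by
  the irrep parity `p` (natural parity `(−1)^l` matches the harmonics). They
  serve as the independent rotation oracle in the tests.
* **Clebsch-Gordan tensors** come from the Racah closed form in the complex
  basis, transformed to the real basis; the free overall phase per triple is
  fixed by making the tensor real, unit Frobenius norm, first nonzero entry
  positive. Coefficients depend only on rotation orders, never on parities.
  The `(1,1,0)` coupling is the dot product times `1/√3`; `(1,1,1)` is the
  Levi-Civita tensor times `1/√6`.
* **Path ordering** is lexicographic in (input segment, filter segment,
  `l_o`); downstream self-interaction weights index into this concatenation,
  so the order is part of the model contract.
* **Initialization**: weights are stored standard-normal and rescaled by
  `1/√fan_in` when applied, keeping activations O(1) at init. The radial MLP
  has biases on hidden layers only; the embedding has a bias; output-block
  layers have none.
* **Gate**: even scalars → SiLU, odd scalars → tanh; each `l>0` channel is
  multiplied by SiLU of a dedicated even-scalar gate channel produced by the
  same post-convolution self-interaction. The residual (per-species) branch
  is added *before* the gate. At blocks where the input signature lacks an
  output irrep (e.g. the first block, whose input is scalars only), the
  residual covers the matching segments and the rest pass through the
  convolution path alone.

## Training protocol

Loss: `λ_E‖Ê−E‖² + λ_F (1/3N) Σ_{i,α}(−∂Ê/∂r_{i,α} − F_{i,α})²`, averaged
over the structures of a batch; an optional per-element mode replaces the
uniform force mean by a weighted per-element average (for strongly unbalanced
compositions). Targets are normalized by the training-set mean energy and the
root-mean-square force component; a per-species mode (for mixed-size
datasets) instead initializes the per-species shift/scale to the mean
per-atom energy and the force standard deviation with no global scaling.

Optimization: Adam with the maximum-of-second-moment (AMSGrad) variant,
β = (0.9, 0.999), ε = 1e-8, no weight decay. Defaults: learning rate 0.01
and batch 5 (molecular protocol; a periodic preset uses 0.005 / batch 1),
plateau decay ×0.8 with patience 50 epochs on the validation force loss,
exponential moving average of the weights (decay 0.99) used for validation
and selection, stop on LR < 1e-6 / validation patience 1000 epochs /
epoch or wall-time caps. The returned parameters are the EMA weights of the
best validation-force-loss epoch. Splits are sampled uniformly without
replacement with a recorded seed and written next to the checkpoint. Training
is deterministic given the seed. Trainable Bessel frequencies are per-layer
independent copies (the alternative — shared across layers — is a flag away
in the layer construction but not exposed; per-layer is strictly more
expressive and matches treating each convolution's filters as independent).

## Molecular dynamics and observables

Velocity-Verlet with a single Nosé-Hoover thermostat variable (not a chain);
with the thermostat off the integrator is plain NVE. Units: Å, fs, eV, amu,
K; `1 amu Å²/fs² = 103.642697 eV`, `k_B = 8.617333e-5 eV/K`. Initial
velocities are Maxwell-Boltzmann with the center-of-mass drift removed; the
thermostat mass defaults to `Q = 3 N k_B T τ²` with coupling time τ = 50 fs,
and the thermostat targets all 3N degrees of freedom (no constraint-count
correction — a deliberate simplification for small periodic systems).

*Energy drift* is measured as the difference between the time-averaged total
energy over the last and first 10% of the run, relative to the time-averaged
kinetic energy: a symplectic integrator's energy error is a bounded
oscillation, and the secular trend is the physically meaningful drift.

MSD uses multiple time origins with maximum lag of half the trajectory.
Diffusivity is the MSD slope over a fit window divided by 6, reported in
Å²/fs and cm²/s (1 Å²/fs = 0.1 cm²/s); the default window discards the first
10% of lags, and a log-log slope far from 1 flags non-diffusive (e.g.
ballistic) motion. The RDF is reported as a probability density over pair
distance on [0, r_max] integrating to 1 (a `g(r)` convenience transform
exists but the density is the primary quantity); the ADF is the analogous
density over the angle at a center atom between neighbor pairs within a
cutoff. Both pool periodic images through the same full-image neighbor
search used by the model, which is valid for ranges beyond half the cell.

## Synthetic data conditions

The toy oracle is a Lennard-Jones pair potential, `4ε[(σ/r)¹² − (σ/r)⁶]`,
smoothly truncated by the same `p = 6` polynomial envelope as the model's
radial basis so the target is C² at the model's own cutoff. Defaults:
ε = 0.2 eV, σ = 2.2 Å, cutoff 4.0 Å — a noble-gas-like scale whose dimer
minimum (2.47 Å) sits well inside the cutoff. The sampling template is a
2×2×2 simple-cubic periodic cell (8 atoms, spacing 2.47 Å); training frames
are Gaussian perturbations of it with displacement scale 0.15 Å, roughly a
warm-crystal amplitude that produces force components with RMS of a few
eV/Å. Labels are analytic, so they are exactly energy-conserving and exactly
smooth: failures of the model-side gradient checks isolate model bugs.

The oracle optionally adds a Stillinger-Weber-style three-body term,
`ε₃ (cos θ_jik − cos θ₀)² g(r_ij) g(r_ik)` summed over neighbor pairs of
every center atom (θ₀ the tetrahedral angle, `g` the same smooth envelope),
with hand-derived analytic forces. It is off by default; the
*data-efficiency* experiment uses `ε₃ = 1.0 eV`, calibrated so the angular
term carries about one third of the force RMS under the standard sampling
conditions. The reason is representational: a sum of radial pair terms is
natively expressible by an invariant (`l_max = 0`) message-passing network,
so comparing equivariant against invariant models on a purely pairwise
target tests nothing about equivariance — the invariant model contains the
true function class. The angular target restores the many-body character
that real ab-initio reference data has and that the comparison is about.
Teacher-student recovery, by contrast, runs on the pure pair potential.

What the toy task does *not* emulate: chemical diversity (one species),
long-range electrostatics, label noise, and the conformational diversity of
real trajectories. Passing the recovery tests therefore shows that the
architecture, gradients, optimizer and protocol work — not that the model
generalizes to real ab-initio data.

## Problem sizes used in the checks

The automated checks run the full protocol at deliberately small scale,
chosen as the smallest sizes at which the properties under test are stable:
teacher-student recovery trains the 16-feature, 2-block, `l_max=1` model on
200 labeled frames of the 8-atom cell for 100 epochs; the data-efficiency
comparison trains `l_max=1` (16 features) against a parameter-matched
`l_max=0` network (36 features, weights matched to ~0.7%) on the angular
task at 50 and 200 frames with an equal optimizer-step budget per run
(1440 steps, i.e. more epochs for the smaller set — otherwise data
efficiency would be confounded with training length), 3 seeds each,
comparing median held-out force MAE; MD checks integrate the 8-atom
cluster for a few thousand steps. Larger models, longer
runs and real datasets use exactly the same code paths.

## Known limitations

* `l_max ≤ 3` (hard-coded spherical-harmonic polynomials).
* No stress/virial outputs, no charges or dipoles, no attention or explicit
  three-body terms.
* The numpy engine is single-threaded and keeps the whole backward graph in
  memory; it is sized for desk-scale experiments (10²-10³ atoms ·
  parameters in the 10⁴-10⁵ range), not production GPU training.
* The Nosé-Hoover implementation is a single-variable thermostat; chains
  would sample small stiff systems more ergodically.
* Element coverage of the mass/symbol tables is Z ≤ 30 (extend
  `structures.CHEMICAL_SYMBOLS` / `ATOMIC_MASSES` as needed).
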