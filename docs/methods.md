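# Methods

## Scope and units

`dynpot` trains a graph-neural-network interatomic potential on
subsequences of reference MD trajectories by differentiating through the
velocity-Verlet integrator. All quantities use Å (length), fs (time), eV
(energy) and amu (mass). Newton's second law in these units is
a = c_acc · F/m with c_acc = 9.648533212×10⁻³ Å/fs² per (eV/Å)/amu;
k_B = 8.617333×10⁻⁵ eV/K. Kinetic energy is ½ m v² / c_acc.

## The potential

Given species labels and positions, a radius graph (cutoff R, default 5 Å)
defines the neighborhood N(i). Under periodic boundary conditions the
minimum image is found by searching integer shifts {−1,0,1}³ over the
periodic directions, which is exact while R is below half the smallest
periodic cell height (enforced; a larger cutoff raises a geometry error).

The energy model:

1. node embedding h_i⁰ = φ_n(x_i), x_i the one-hot species vector
   (vocabulary sorted lexicographically and stored in checkpoints);
2. edge embedding φ_e(d_ij) = [sin(b₁d), cos(b₁d), …, sin(b_{d_e}d),
   cos(b_{d_e}d)], b ~ N(0, σ²) sampled once from a recorded seed and
   **frozen** (never touched by the optimizer);
3. K message-passing rounds: m_ij = Φ_l(h_i, h_j, φ_e(d_ij)), aggregated
   m_i = Σ_{j∈N(i)} m_ij, update h_i ← Φ′_l(h_i, m_i);
4. sum pooling over atoms, then a readout MLP ψ gives the scalar energy.

Forces are the exact reverse-mode gradient F_i = −∂E/∂r_i, never finite
differences. Since the network sees only distances, energy invariance and
force covariance under rigid motions and permutations are structural; the
test suite checks them to ≤10⁻⁶ relative.

Architecture defaults mirror the reference configuration of the method:
d_n = 128, edge embedding 2·d_e = 512, σ = 4, K = 3, R = 5 Å. The interior
MLP shapes are a free design choice here: φ_n is a single affine map,
Φ_l, Φ′_l and ψ are two-layer MLPs with hidden width d_n; all shapes are
configurable. The activation must be smooth everywhere because the
training loss is differentiated *through* the forces; the default is SiLU.
There is no smooth cutoff envelope at R: during training the edge sets are
frozen (below), and at inference the discontinuity at R is tolerated.

`count_parameters` counts optimizer-visible scalars only (the frozen RFF
vector is excluded).

## The autodiff core

No installed framework provides what force-dependent losses need —
d/dθ of −∂E/∂r, a mixed second derivative — so the package carries a
small reverse-mode autodiff engine (`dynpot.autodiff`): float64 tensors, a
closed set of primitives (affine, matmul, elementwise, gather/scatter,
concat/narrow, reductions) whose vector-Jacobian products are built from
the same primitives, and a functional `grad(..., create_graph=True)` that
makes gradients themselves differentiable. Second-order correctness is
tested against finite differences on exactly the force-loss pattern.

## Rollouts

A **training-mode** rollout starts from a sample's reference positions and
velocities and integrates S−1 velocity-Verlet steps, querying the model
for forces at every step (step 0 forces are predicted, not copied from the
reference). The radius-graph *membership* for step k — and the
minimum-image shifts — are frozen from reference frame k of the sample
("the neighborhood as a parameter"), while distances are recomputed from
the predicted positions, so each distance is a smooth function of
positions and gradients flow from every step's forces back to the
parameters. An **inference-mode** rollout recomputes the radius graph from
the predicted positions at every step. There is no thermostat anywhere:
all dynamics are microcanonical.

Two identities pin the implementation down: with exact reference forces a
rollout reproduces the reference trajectory to machine precision (same
integrator, same dt), and reversing the final velocities returns to the
initial state to ≤10⁻⁸ Å on an analytic force field.

## Losses and MEPA

* Energy loss: (1/B) Σ_b |ΔE_b|/N_b (eV/atom).
* Force loss: (1/B) Σ_b Σ_{a∈A_b} (1/(3N_{a,b})) Σ_{i,α}|ΔF| — the
  per-species normalization makes the loss invariant to replicating atoms
  of one species with identical residuals; the weighted-MSE baseline
  (λ_E·MSE_E + λ_F·MSE_F, per-configuration normalization) deliberately
  lacks this property and is provided for comparison and for conventional
  single-point training.
* Rollout loss: S = 1 → energy + force loss; S > 1 → Σ_k λ_k L_force^k
  with λ₁ = 50, λ_k>1 = 1 and no energy term (only step 1 starts from
  exact reference positions, hence its dominant weight). An optional
  energy term for S > 1 exists but is off by default.
* MEPA = mean of the per-step force loss over a rollout; validation and
  test metrics are force-only.

Inside batched rollouts the same losses are computed as weighted L1 sums
with per-atom weights 1/(3N_{a,b}B); a test asserts this path equals the
reference per-configuration formulation.

## Curriculum

Training starts at S = 1. After every epoch the model is validated with
fixed-length S_val rollouts (frozen reference edge sets, mirroring how
training subsequences are evaluated; S_val never changes during a run).
A plateau rule with patience p: an epoch without improvement increments a
counter; when the counter exceeds p at lr > min_lr the lr is multiplied by
the plateau factor (floored at min_lr) and the counter resets; when it is
exceeded *at* min_lr the model is converged for the current S. Then S is
incremented, the lr is reset to 10⁻⁴, and per-S bookkeeping is cleared.
The best parameters per S (lowest validation MEPA) are retained
throughout. Learning rates follow the reference setup: initial 10⁻³,
reset 10⁻⁴, minimum 2×10⁻⁶. Patience and factor are not fixed by the
reference description; defaults are 25 and 0.5 (standard plateau
practice), configurable. An optional `max_epochs_per_s` hard cap forces
the advance — an engineering guard for bounded desk-scale runs.

The optimizer is Adam (fresh moments at each curriculum advance; moments
persist across lr decays within an S). Gradients are clipped by global
norm (default 10) to guard against rollout blow-ups early in training.
Batches of subsequences are merged into one block-diagonal graph and
advanced in lockstep, which realizes the batch-averaged per-step losses
directly. Training is deterministic given the config seed, and a training
run can be checkpointed and resumed bit-identically (parameters, Adam
moments, curriculum state and RNG state are all saved).

At S = 1 the curriculum is *operationally identical* to conventional
single-point training with the same loss; the suite asserts equal
per-epoch losses for equal seeds. This is what makes the conventional
baseline comparison exact rather than approximate.

## Synthetic reference data

The generator emulates the statistical shape of the target data — a light
diatomic projectile impinging on a small cluster thermalized at a target
temperature, integrated microcanonically at fixed dt — with *exact*
energies and forces from an analytic potential:

* substrate: 7 heavy atoms ("Pd", 106.42 amu) bound by Lennard-Jones
  ε = 0.3 eV, σ = 2.55 Å, initialized at the pentagonal-bipyramid LJ7
  minimum. ε ≫ k_BT(300 K) ≈ 0.026 eV keeps the cluster solid;
* projectile: an "H₂"-like dimer (1.008 amu each) with a Morse bond
  D = 2.5 eV, a = 1.5 Å⁻¹, r₀ = 0.9 Å — soft enough that dt = 0.5 fs
  resolves the vibration comfortably (period ≈ 13 fs);
* cross interaction: LJ ε = 0.05 eV, σ = 2.0 Å; vacuum cell.

Defaults mirror the reference study conditions: substrate at 300 K,
projectile translational energy 0.125 eV, dt = 0.5 fs. Thermalization
samples Maxwell–Boltzmann velocities at 2T (half the kinetic energy
relaxes into potential energy of the cluster) followed by a 500-step
equilibration of the substrate alone; the projectile is then aimed
downward from 4.5 Å above the cluster with a ±0.5 Å lateral jitter and a
random bond orientation. Trajectories differ only through seed-derived
initial conditions and regenerate byte-identically.

What the toy data does *not* share with ab initio reference data: no
electronic structure (no reactivity, no dissociation chemistry), two
species only, 9 atoms, and an analytic PES that the network can fit far
more tightly than a DFT surface. Passing tests therefore demonstrate the
*mechanics* of the training scheme (gradient flow, curriculum, metric
behavior, the benefit of rollout supervision at this scale), not
production accuracy on real systems.

## The desk-scale efficacy experiment

`dynpot.experiments.run_dt_efficacy` is the package's central experiment:
8 generated trajectories of 101 frames (6 train / 2 held out), training
samples of S_max = 5 sliced with stride 3 (192 samples), 24 validation
samples rolled out for S_val = 20, a small model (d_n = d_e = 16, K = 2),
and a tight curriculum budget (patience 2, factor 0.2, ≤12 epochs per S).
Three independent repeats are trained; each repeat's best-per-S
checkpoints are evaluated by 50-step inference-mode rollouts from 16
samples of the held-out trajectories. These sizes are the package's own
desk-scale choice: large enough for the effect to be unambiguous, small
enough that the whole experiment (three repeats plus the conventional
baseline) runs in about three minutes on one CPU core. The observed
outcome mirrors the full-scale finding: median test MEPA drops
monotonically with S (≈65% lower at S = 5 than at S = 1 for seed 1), and
the conventionally trained model coincides with dynamic training stopped
at S = 1.

## Numerical choices and edge cases

* float64 throughout; energies of identical graphs are bit-identical, and
  JSON checkpoints round-trip exactly (shortest-repr floats).
* Coincident atoms on an edge (d = 0) raise a geometry error; zero-edge
  graphs are legal — the energy is then position-independent and forces
  are exactly zero.
* |x| has subgradient 0 at the origin; the force loss only ever needs
  first derivatives of |·|.
* The extended-XYZ dialect: per-frame comment line with `Lattice`,
  `Properties=species:S:1:pos:R:3:vel:R:3:forces:R:3`, `energy`, `dt`,
  `pbc`; velocities are required input — without them a trajectory can
  only form single-point (S = 1) datasets.
* Masses come from a built-in element table, overridable per species.
* Batches require a common dt/cell/pbc (they always come from one
  dataset); a mixed batch raises.

## Known limitations

* The minimum-image search over {−1,0,1}³ limits cutoffs to half the cell
  height — correct but not general for very skewed or small cells.
* No constraints, thermostats, barostats or cell dynamics.
* No smooth cutoff envelope: inference forces are discontinuous at R.
* The autodiff core is tuned for small graphs (hundreds of atoms per
  batch); it is not a general deep-learning runtime.
* Validation rollouts reuse frozen reference edge sets rather than
  recomputed graphs — consistent with training-time evaluation, and kept
  as the benchmark definition here.
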