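# Methods

This note documents the model implemented by `eqff`, the functional forms
and defaults it adopts, the synthetic-data generator, the numerical
choices, and the desk-scale problem sizes used by the test suite and the
reproduction script. Units throughout: Å, kcal/mol, elementary charge e,
amu, fs; Coulomb constant k_e = 332.0637 kcal Å mol⁻¹ e⁻².

## 1. Species encoding

An element with periodic-table coordinates (row r, column c; 18-column
IUPAC convention, H in group 1, He in group 18) is encoded as the
concatenation of two transformer-style positional encodings:
component 2i of the column block is sin(c / γ_col^(2i/d_col)), component
2i+1 is cos(·); likewise for the row block. Defaults d_row = 5,
d_col = 10, γ_row = 100, γ_col = 1000 (an odd dimension ends with an
unpaired sine). The encoding is a smooth function of (r, c) as real
numbers, which is what enables interpolation between species, perturbing
an element's coordinates, and the "average element" construction
(`encoding.average_element_encoding`, supported for H–Xe). The element
table ships as a plain-text resource so the group convention can be
swapped; encodings are computed once per element and cached read-only.

## 2. Local geometry

Directed neighbor pairs use a strict half-open criterion 0 < R < r_c
(default r_c = 5.2 Å); each pair's reverse is always present, and
ordering is deterministic (sorted by source, destination, lattice image).
Periodic systems enumerate explicit lattice images, which also covers
cells smaller than 2 r_c. Pairs closer than 10⁻⁶ Å are input errors.
Neighbor search is a vectorized all-pairs scan with image enumeration —
exact and fast at the system sizes this implementation targets (up to a
few hundred atoms); a cell-list search would only change the scaling
constant, not any result.

The radial basis is the spherical Bessel basis
B_n(R) = sqrt(2/r_c) · sin(nπR/r_c)/R multiplied by the polynomial
envelope u(d) = 1 − (p+1)(p+2)/2 d^p + p(p+2) d^(p+1) − p(p+1)/2 d^(p+2),
d = R/r_c, whose value and first p−1 derivatives vanish at the cutoff
(defaults N_basis = 10, p = 3). Real spherical harmonics are
component-normalized (|Y_l|² = 2l+1, i.e. √(4π) × orthonormal), ordered
m = −l..l, Condon–Shortley phase, implemented up to l = 2 — the orders
the model family uses.

## 3. Equivariant embedding

The embedding follows the Allegro layer structure. Two-body scalars are
x²ᴮ = MLP_2B[Z_i ‖ Z_j ‖ B(R_ij)] · f_c(R_ij) (hidden 64, 128, SiLU;
output 256 at full size). Initial tensor features multiply per-(channel, l)
linear weights of x²ᴮ (no bias, no activation) into the spherical
harmonics. Each of the N_layers = 3 interaction layers:

1. builds Γ_i^{nlp} = Σ_k w_ik^{nl} Y_ik^{lp} with w = Linear(x_ik) · f_c,
   normalized by 1/sqrt(N̄) with a fixed expected neighbor count N̄ = 20
   (a constant, so strict locality and transferability are preserved);
2. takes the channel-wise tensor product Γ_i ⊗ V_ij over every
   symmetry-allowed path |l₁−l₂| ≤ l ≤ l₁+l₂, p = p₁p₂, capped at l_max,
   tracking multiplicities; coupling tensors are real Clebsch–Gordan
   coefficients obtained by conjugating the complex coefficients with the
   complex→real unitary, each normalized to unit Frobenius norm;
3. updates the scalar track x ← α x + sqrt(1−α²) MLP_latent[x ‖ scalar
   paths] (hidden 256, 256, SiLU). α = sigmoid(a) is one trainable
   parameter per layer, initialized to 1/√2; the sqrt(1−α²) complement
   preserves feature normalization;
4. filters the tensor paths back to N_channels channels with learned
   linear weights per (l, p), divided by sqrt(fan-in).

The feature layout is fixed to all (l, p) with l ≤ l_max and p = ±1;
blocks not produced by the spherical harmonics start at zero, so every
layer sees the same layout. Scalar features feed the scalar track from
the (l = 0, p = +1) paths only (true scalars, not pseudoscalars). With
the full-size hyperparameters this architecture has 1,224,179 trainable
parameters.

Weight initialization is scaled Gaussian (std 1/sqrt(fan-in)) from one
seeded generator; biases start at zero; linear embeddings carry no bias
(a bias would break smoothness at the cutoff).

## 4. Output heads and reference energies

Three independent MLPs (hidden 256, 128, 64, 32, 16, SiLU) read
[x²ᴮ ‖ x^(final)] (512 inputs at full size) and emit per-pair scalars:
e_ij, δq_ij, u_ij. Aggregation: E^NN_i = Σ_j e_ij;
q^NN_i = Σ_j (δq_ij − δq_ji) — the antisymmetrization makes global
neutrality exact by construction, which is why it is preferred over
post-hoc renormalization; v_i/v_i^free = softplus(Σ_j u_ij) > 0. The
softplus is applied after summation (the positivity constraint targets
the atomic quantity, not each pair contribution). An optional shorter
output cutoff exists as a configuration hook and is off by default.

Isolated-atom reference energies are non-trainable constants added to
every total energy; they set the dissociation asymptote. For synthetic
training they are the surrogate oracle's own isolated-atom values.

## 5. Physics module

Charge pipeline (in order): scaling q_i = ε q^NN_i; then the valence
correction. The correction bounds q_i ≤ 0.95 N_i (N_i = valence electron
count): the "valence hole" is h_i = hinge(q_i − 0.95 N_i) with a C¹
quadratically-smoothed hinge of half-width 0.05 e — exactly zero more
than 0.05 e below the bound, so the correction is genuinely inactive for
well-behaved charges. The hole is transferred back from the neighbors
that drained atom i, proportionally to the (smoothly rectified) drained
amounts, in one pass; total charge is conserved exactly. If an atom has a
hole but no draining neighbor (a degenerate input the model never
produces), its charge is left unchanged with a warning. Scaling is
applied before correcting so the bound is enforced on the physical
charges that actually enter the Coulomb term.

Charge-penetration Coulomb between atoms with valence populations
N − q:

    E^C_ij = (k_e / R) [ N_i N_j
                         − N_i (N_j − q_j) f_α(R) − N_j (N_i − q_i) f_α(R)
                         + (N_i − q_i)(N_j − q_j) f_β(R)² ]

with f_k(r) = 1 − e^(−kr) and universal damping rates α, β. The form is
symmetric in (i ↔ j) and reduces exactly to k_e q_i q_j / R as R → ∞.
The scaling factor ε multiplies every occurrence of q.

Dispersion is the pairwise TS model: homonuclear parameters scale with
the predicted volume ratios, C6_ii = (v/v^free)² C6^free and
α_i = (v/v^free) α^free; the heteronuclear coefficient follows the
combination rule C6_ij = 2 C6_ii C6_jj / [(α_j/α_i) C6_ii + (α_i/α_j)
C6_jj] (exact in the homonuclear limit); the damping is the sigmoid
1/(1 + e^(−γ [R/(s(r_i + r_j)) − 1])) with environment-dependent van der
Waals radii r_i = (v_i/v_i^free)^{1/3} r_i^{vdW,free} (the standard TS
cube-root volume scaling).

Universal parameters default to ε = 1, α = β = 4 Å⁻¹ (bond-scale
damping), γ = 20 and s = 0.94 (the constants of the original TS damping
function); all five are stored as log-parameterized trainables (kept
positive by construction) and are optimized only in training stage 3.
The free-atom table (valence counts, Chu–Dalgarno polarizabilities and
C6, TS free vdW radii, free volumes) ships for H, C, N, O, F, S in a
YAML resource with units declared; none of the test results depend on
the exact values.

Range policy. The bare point-charge Coulomb acts between all pairs
(Ewald under periodic boundary conditions); the charge-penetration
correction E^C − E^bare decays like e^(−αR) and is applied within r_c
only (at r_c = 5.2 Å and α = 4 Å⁻¹ the truncated remainder is below
10⁻⁸ of k_e). Dispersion acts within a 12 Å cutoff with a C²
smoothstep switch starting at 10 Å; periodic systems add the analytic
homogeneous tail correction −(2π/V) Σ_ij C6_ij ∫(1−S)/r⁴ dr (the
integral includes the switch region). Two consequences: (i) the
long-range tail of dispersion is retained in periodic systems, where its
neglect visibly distorts liquid structure; (ii) a system whose pairs all
exceed every cutoff has zero charges (empty pair sums), zero switched
dispersion and zero bare Coulomb — the total energy is exactly the
reference sum with exactly zero forces, for any weights.

Ewald summation uses real + reciprocal + self terms. The splitting
parameter and cutoffs derive from a relative accuracy target (default
10⁻⁵): the per-term truncation threshold is set two orders below the
target so the accumulated error stays within it; the result is
independent of the splitting parameter within the target. Non-neutral
cells are rejected (no background correction is implemented). Real-space
image pairs are enumerated explicitly, so small cells work unchanged.

Forces everywhere are exact gradients of the implemented energy, via the
package's reverse-mode autodiff engine (`eqff.autodiff`): a small tape
of numpy primitives whose vector-Jacobian products are themselves built
from primitives, so gradients can be differentiated again (needed when a
loss contains forces). Everything is float64.

## 6. Training procedure

Records are merged into batched graphs (geometries are static, so
neighbor and long-range pair lists are built once per batch). Losses are
mean-squared errors averaged over the batch; the force term is a
per-component mean per record, charge and volume terms per-atom means.

* **Stage 1** (NN only): λ_E = 0.001, λ_F = 1, λ_q = λ_v = 1000, plus a
  covariance regularizer — the sum of squared off-diagonal entries of the
  sample covariance of the scalar embedding features over the batch
  (weight 10⁻³ by default; zero for batches smaller than two). Following
  the same mid-stage rebalancing used at full scale, the desk-scale runs
  execute stage 1 in two phases, switching to λ_E = 0.01, λ_F = 0.1.
* **Stage 2**: embedding and charge/volume heads frozen; the energy head
  retrains so the full physics-augmented energy matches energies/forces,
  with the end-of-stage-1 weights (λ_E = 0.01, λ_F = 0.1).
* **Stage 3**: total energies (λ_E = 0.1) plus dimer interaction
  energies (λ_DES = 5), each interaction energy computed by the model
  itself as E(dimer) − E(monomer A) − E(monomer B) with the monomer
  sub-systems appended to the batch; interaction records weight
  per-record. The physics parameters unfreeze here. Stop threshold
  10⁻⁵.
* **Stage 4** (system-specific refinement) is configured like any other
  stage with extra force-matching records; no special machinery.

Optimizer: AdamW with decoupled weight decay, 0.5 on the output module
and none on the embedding or physics parameters; frozen groups are
excluded from the optimizer entirely (their state is untouched).
Learning-rate schedule: reduce-on-plateau on the training loss, patience
10 epochs, factor 0.8; stages stop when the rate falls below their
threshold (10⁻⁴ for stages 1–2, 10⁻⁵ for stage 3) or at the epoch cap.
Validation is a fixed random 10% split chosen once from the seed. Batch
sizes default to 256 for total-energy records and 64 for interaction
records. One seed controls weight initialization, the split, shuffling
and data generation; runs are bit-reproducible.

## 7. Synthetic data generator

The generator emulates the *structure* of coupled-cluster-style training
records — (species, coordinates, total energy, forces, charges, volume
ratios) for monomers and interaction-energy records for dimers — with an
analytic surrogate oracle:

* energy = isolated-atom reference constants + Morse terms over template
  bonds + damped point-charge Coulomb (f = 1 − e^(−2.5r)) + softened
  dispersion −C6/(r⁶ + d⁶), d = 2.5 Å;
* forces: exact analytic gradients (via the autodiff engine);
* charges: fixed per-bond charge transfers modulated by a smooth envelope
  of the bond length vanishing at 6 Å — neutral per molecule, zero at
  dissociation, so labels and the model's built-in asymptote agree;
* volume ratios: a smooth decreasing function of a Gaussian coordination
  number, in (0.5, 1].

Templates: H₂, OH, HF, O₂, H₂O (equilibrium geometries, Morse well
depths 109.5–136 kcal/mol at spectroscopic bond lengths). Diatomic
geometries mix vibrational-scale deformations (σ = 0.08 Å, 60% of
records) with dissociative stretches (half-Gaussian, σ = 1.2 Å) so the
curve is sampled from repulsion to dissociation; polyatomics get
Cartesian jitter; everything is randomly rotated and, for dimers, placed
at 2.5–6.5 Å center separation. Defaults: 2,000 records over the H₂/OH
templates for the recovery experiment.

What passing desk-scale tests shows — and what it does not: the
surrogate is smooth, low-dimensional and noise-free, so recovery
demonstrates that the architecture, losses, freezing schedule and
optimizer are implemented consistently (the model can fit the surrogate
through the exact training path), not that the model reaches
coupled-cluster accuracy on real chemistry; real records are far more
diverse, carry correlated labels, and their energies are not a sum of
closed-form pair terms.

## 8. Molecular dynamics and analyses

BAOAB Langevin splitting with exact Ornstein–Uhlenbeck coefficients
(c₁ = e^(−γΔt), c₂ = sqrt((1−c₁²) k_B T/m)); default timestep 0.5 fs.
The thermostat interface is pluggable (a colored-noise thermostat could
be slotted in); the default is classical Langevin. Positions are kept
unwrapped internally (dipoles and transport need continuous
coordinates); structural analyses wrap on demand. Non-finite forces
abort with the offending atom index.

Partial RDFs histogram minimum-image distances normalized by ideal-gas
shell counts (exact shell volumes, so the counting identity
∫ρg4πr²dr = mean neighbor count holds by construction); r_max must not
exceed half the smallest cell height. Dipole spectra Fourier-transform
the Hann-windowed autocorrelation of M(t) = Σ q_i(t) r_i(t); the
frequency axis is cm⁻¹.

## 9. Desk-scale problem sizes

The verification suite and `scripts/acceptance.py` use: the full-size
architecture for the parameter count; a mid-size model (32 scalar
features, 4 channels, l_max = 2, 2 layers) for the equivariance, force
and charge benchmarks — it exercises every tensor path at a fraction of
the cost, and the checked properties are exact by construction, not
approached with size; 10 clusters × 20 transforms for equivariance; 10
five-atom clusters (all 150 force components) for force consistency
against central differences with h = 10⁻⁴ Å, deviations measured
relative to the cluster's largest force component — at fixed step the
finite-difference oracle carries an absolute O(h²E''') truncation error,
so a componentwise ratio on near-zero components would measure the
oracle's noise rather than the gradient; 1,000 systems (200 full-pipeline, half with the
charge scaling inflated to force valence holes, plus 800 direct
stress cases) for charge conservation; an 8-atom rock-salt cell against
a 15³-cell direct sum for Ewald; 2,000 diatomic records, a two-phase
stage 1 (30 + 60 epoch caps), for training recovery (energy RMSE
measured on the validation split, compared to the 109.5 kcal/mol well
depth); 10⁶ BAOAB steps at friction 0.1 fs⁻¹ for equipartition; a
300-step water-pair run with the untrained model as the MD stability
smoke test.

## 10. Known limitations

* Spherical harmonics (hence l_max) are implemented up to l = 2.
* No tensorial outputs from the equivariant features (the hook exists;
  the heads used here are scalar).
* Charged total systems are out of scope (the Ewald term requires
  neutrality; the charge heads are built around neutral exchange).
* No cell-list neighbor search or parallelism: the implementation
  targets correctness and desk-scale sizes, not production throughput.
* The Coulomb bare term in isolated systems is an O(N²) all-pairs sum.
* Trained full-scale weights are not shipped; the training machinery is
  exercised on synthetic data only.
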