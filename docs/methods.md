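# Methods

`ampmm` implements a machine-learned potential for the high-accuracy
("QM") zone of a multiresolution simulation, electrostatically embedded
in a classical point-charge ("MM") environment, together with the
surrounding machinery needed to turn labeled snapshots into free-energy
estimates: a training loop, a stochastic-dynamics engine with harmonic
umbrella restraints, and WHAM reweighting with bootstrap errors.

Units everywhere: kJ/mol, Angstrom, elementary charges, fs, K, g/mol;
the Coulomb constant is k_e = 138.935458 kJ mol^-1 A e^-2.

## The potential

The total energy splits as

    V = V_QM + V_QM-MM + V_MM

with `V_QM` the learned part plus a switched intra-solute Coulomb term,
`V_QM-MM = V_ES + V_LJ + V_pol` the embedding terms, and `V_MM` a
classical solvent force field (Lennard-Jones plus reaction-field
Coulomb).

**Message passing with multipole channels.** Each atom i carries a
hidden vector h_i (initialized from a learned embedding of the element
one-hot) and a set of C multipole channels, each holding a scalar,
a vector and a rank-2 tensor.  Edges within the graph cutoff
r_graph carry radial features: a zeroth-order spherical Bessel basis
sin(n pi r / r_c)/r scaled by sqrt(2/r_c) and multiplied by a quintic
envelope (value 1 and zero first/second derivative at r = 0; 0, 0, 0 at
r = r_c), so every edge quantity vanishes smoothly at the cutoff.  Per
step, channel and order k, multipoles are expanded as

    M_i^(k,c) = sum_{j in N(i)} c_ij^(k,c) * basis(u_ij, k),

with basis tensors 1, u, u (x) u and scalar coefficients predicted per
edge from the radial features and the endpoint embeddings.  Orientation
information enters the (scalar) messages through rotation-invariant
interaction coefficients g_ij: for every composition
d_i + d_j + d_c = k (one triple for k = 0, three for k = 1, six for
k = 2) the order-(d_i + d_c) multipole of atom i is contracted d_i
times with the edge direction and d_c times against atom j's factor.
Combinatorial prefactors are omitted; any fixed positive prefactor is
absorbed by the downstream network weights.  Because everything that
reaches the scalar networks is built from full contractions, the
predicted energy is exactly invariant and the multipoles exactly
equivariant under rigid motions, up to floating-point error; the test
suite checks both to 1e-4/1e-5 in double precision.

The hidden-state update additionally receives each node's *own*
multipole invariants (M0, |M1|^2, M2:M2, tr M2 per channel).  Edge
coefficients couple only different nodes' moments, so without this
pathway the squared magnitude of a node's induced dipole — which is
exactly where the polarization energy of the embedding lives — could
never reach the scalar energy head; with it, the MM-induced response
becomes expressible, and the surrogate-recovery experiment confirms
the polarization term is then learned.

All network blocks are fully connected with two hidden layers, Swish
activations (implemented in the overflow-free two-branch form) and He
initialization.

**Readout.** Per-atom heads produce: energies (summed to V_AMP),
partial charges (projected by subtracting the mean excess so that
sum q_i equals the total charge exactly), a per-atom polarizability
coupling, and a *separate* set of electrostatic multipoles — channel
gates contract the multipole channels into one charge/dipole/quadrupole
set per atom; the quadrupole is detraced before use (the trace produces
no field at a monopole).

**Switched intra-solute Coulomb.**

    V_ES,QM = k_e sum_{i<j} q_i q_j (1 - f_switch(r_ij)) / r_ij

with f_switch the unique quintic with value/1st/2nd derivative
(1, 0, 0) at r = 0 and (0, 0, 0) at r_graph.  The term is therefore
fully suppressed where the learned part operates and exactly Coulombic
beyond the graph cutoff; (1 - f)/r stays bounded at contact.

**QM-MM electrostatics.** Multipole-monopole interactions up to
quadrupole with radial functions T^(l) = (2l-1)!!/r^(l+1):

    V_ES,QMMM = k_e sum_ij [ q_i Q_j / r + Q_j (mu_i . u_ij) / r^2
                             + 3 Q_j (u^T Theta_i u) / r^3 ]

over pairs gathered group-wise within r_es = 14 A (a charge group
enters whole if any member is inside the cutoff; no switching at r_es).
Lennard-Jones coupling uses Lorentz-Berthelot combination (geometric
epsilon, arithmetic sigma), the common default when per-atom parameters
are taken from an existing force field without a stated rule.

**Polarization.** For QM-MM pairs within r_pol, induced multipoles

    dM_i = alpha_i * sum_j Q_j * b_ij * basis(u_ij, k)

are added to the channels before the final message-passing step, so the
learned energy absorbs the MM-induced response; b_ij is a network of
the QM/MM Bessel features and the coefficients between the QM
multipoles and the MM monopole, and the explicit Q_j factor makes the
response exactly linear in the MM charges when the network inputs are
held fixed.

**Forces** are exact negative gradients of the assembled energy,
obtained by reverse-mode differentiation of the full computational
graph.  The autodiff engine (`ampmm.autodiff`) is a small tape whose
backward pass is itself built from differentiable primitives; this is
what makes the training loss — which contains forces — differentiable
with respect to the parameters.  Newton's third law and
finite-difference consistency (relative 1e-4 at h = 1e-4 A) are tested
for every term.

## Training

Loss:  L = 0.99 MSE(V) + 100 MSE(gradients, QM and MM atoms alike)
+ 100 MSE(molecular dipole and quadrupole components).  MM force
components enter on the same footing as QM ones — both are genuine
model outputs.  Optimization: Adam (beta1 0.9, beta2 0.999,
eps 1e-7), global-norm clipping at 1, exponential decay
lr(t) = lr0 * 0.02^(t/T) interpreted over the whole run, so the rate
ends at 2% of its initial value.  Energy labels are median-shifted over
the training set (the same shift is applied to validation/test labels);
a per-batch-relative mode for multi-system datasets is available and
enforces single-topology batches.  The checkpoint kept is the epoch
with the lowest validation loss.  Runs are bit-reproducible for a fixed
seed.

Training runs in float32 (the numpy graph is roughly 1.6x faster and
half the memory); model evaluation, invariant tests and dynamics use
float64.  MM arrays are zero-padded per batch with zero charge, zero LJ
epsilon and positions 50 A outside every cutoff — far enough to be
inert, close enough that high powers of r in nested derivatives stay in
float32 range.

## Dynamics

BAOAB-splitting Langevin dynamics (dt default 0.5 fs, T 298 K, friction
1 ps^-1); zero friction reduces exactly to velocity Verlet, and an NVE
test at dt = 0.1 fs holds total-energy drift below 0.1 kJ/mol over 1e4
steps.  Velocities start Maxwell-Boltzmann; center-of-mass motion is
removed every 1,000 steps.  Harmonic restraints on distances and
dihedrals (differences wrapped to (-180, 180]) have analytic forces,
checked against finite differences.  The MM internal force field is
Lennard-Jones plus Barker-Watts reaction-field Coulomb with a single
cutoff (default 14 A) and configurable dielectric; intra-group pairs
are excluded.  Umbrella schedules: n equidistant distance windows
inclusive of both ends (2-20 A by default) or an n x n equidistant
dihedral grid covering (-180, 180] per angle.  Replicates differ only
in velocity seeds derived deterministically from the master seed; a
window whose forces blow up is marked failed and the rest continue.

## Free-energy analysis

WHAM iterates the window free energies on pooled replicate histograms
until the largest change is below 1e-7 kJ/mol (defaults: 100 bins in
1-D, 72 x 72 periodic bins in 2-D).  In 1-D the biased Boltzmann
factors are averaged over each bin rather than evaluated at its center
— the bias can vary by several kT across a bin in a window's far
wings, and bin averaging is the discretization consistent with binned
counts.  Unsampled bins are masked with a warning, as are
non-overlapping adjacent windows.  Errors come from a
Monte Carlo block bootstrap over whole replicate trajectories.  Two
registration conventions are provided: min-shift (the convention
profiles are reported in) and mean-alignment, which avoids the pinned
zero-variance bin at the profile minimum and is the right choice when a
whole profile is compared bin by bin against a reference.

The 4 pi r^2 Jacobian correction *adds* kT ln(4 pi r^2) to a raw
radial profile: a free particle's raw radial histogram is
-kT ln(4 pi r^2) + C, so this sign is the one that renders the ideal
gas flat.  Dissociation free energies integrate the radial density
p(r) proportional to 4 pi r^2 exp(-G/kT) by the trapezoidal rule up to
the first barrier (bound) and from the barrier to r_max (unbound):

    dG_diss = -RT ln(p_unbound / p_bound),

positive when the bound state is favored; no standard-state volume
correction is applied.

When a WHAM histogram is compared against an analytic potential, the
reference must be bin-averaged (-kT ln of the mean Boltzmann weight
over the bin): comparing bin centers against a steeply varying wall
would attribute discretization bias to the estimator.

## Synthetic ground truth

The surrogate stands in for the expensive reference calculations that
label snapshots in production use.  It is analytic: harmonic bonds and
angles, cosine torsions, intra-solute Coulomb between fixed reference
charges, direct Coulomb between those charges and the MM sites, an
induced-dipole polarization energy -1/2 k_e alpha_i |E_i|^2 in the MM
field, and Lennard-Jones coupling.  The polarization and direct-Coulomb
terms make the labels genuinely MM-field-dependent, so training
exercises the embedding pathway and the MM-gradient head, not just the
vacuum network.  Labels (energy, QM and MM gradients, molecular dipole
and quadrupole about the solute centroid) are generated on the autodiff
graph, so gradients are exact derivatives of the label energy by
construction (finite-difference checked to 1e-8).

The default solute is a five-atom bent O=C-N(H2) fragment with one soft
torsion; configurations are drawn by stochastic dynamics at an elevated
sampling temperature (350 K) with a fresh random shell of 16 balanced
+/-0.4 e charges at 4.5-7 A per frame, and split 80/10/10 after
shuffling.  Sampled energies then span a few tens of kJ/mol.  What this
does *not* emulate: real electronic structure (no charge transfer, no
anisotropic atomic densities, no many-body dispersion), conformational
diversity beyond one small fragment, and solvent structure (the shell
is uncorrelated noise, not a liquid).  Passing the recovery experiment
therefore demonstrates that the architecture, embedding, loss and
optimizer can fit labels *of the right mathematical structure* to below
1 kJ/mol — not that DFT-quality accuracy transfers to real chemistry.

The toy dimer used for end-to-end free-energy validation is two
particles (mass 14) bound by an analytic radial double well: an r^-12
core, a Gaussian well (depth 15 kJ/mol at 3.0 A) and a Gaussian barrier
(2 kJ/mol at 4.6 A).  Its standard PMF is the pair potential itself,
and its dissociation free energy follows from dense quadrature of the
same radial-density expression the estimator uses, making analytic
truth available for every step of the umbrella -> WHAM -> dG chain.

## Problem sizes and experiment design

The validation experiments are sized for a desk-scale single-CPU run:

- Surrogate recovery: 2,000 labeled frames, model scaled down from the
  small published configuration to node size 64 with 2 message-passing
  steps; 8 multipole channels, 8 Bessel features and edge size 32 (the
  natural scale-down of the remaining rows); batch size 192, initial
  learning rate 2e-3, 110 epochs.
- Umbrella + WHAM end-to-end: 12 windows over 2-20 A, force constant
  10 kJ/mol/A^2 (chosen so neighbouring-window histograms overlap:
  sigma ~ sqrt(kT/k) ~ 0.5 A against 1.64 A spacing), 3 replicates,
  dt 2 fs, friction 5 ps^-1, 120 ps production per replicate.
- WHAM self-test: 16 windows over the well region 2.2-6.2 A, force
  constant 20 kJ/mol/A^2, 6 replicates of 50 ps production.  The
  "everywhere within bootstrap bands" statement is a family of ~64
  correlated per-bin comparisons, so the band is simultaneous,
  calibrated from the bootstrap's own max-deviation statistic; the
  analytic reference is bin-averaged (see above).

## Known limitations

- Neighbor search is brute-force all-pairs (with minimum image); exact
  and adequate for solute-sized QM zones, not for thousands of atoms.
- The MM solvent model is monatomic sites with a reaction field; no
  constraint dynamics (SHAKE), no barostat, NVT/NVE only.
- One estimator (WHAM) serves both 1-D and periodic 2-D reweighting.
- Self-consistent mutual polarization is out of scope: MM charges are
  fixed; only the QM zone responds.
- The spin multiplicity of a system is stored but does not enter the
  model.
- Training of the numpy graph is single-threaded; wall-clock budgets
  are what limit dataset and model size in the validation experiments.
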