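# Methods

## Physical model

Particles are monodisperse spheres of core radius r = 1.985 nm (the
best-fit gold-core diameter 3.97 nm) in water at T = 297 K.  The pair
energy is DLVO: the non-retarded Hamaker two-sphere attraction and the
screened-Coulomb (Yukawa) repulsion with the (e^{κr}/(1+κr))² surface
correction, both in units of k_BT, with domain d > 2r.  Parameters and
units:

| parameter | meaning | default | unit |
|---|---|---|---|
| Z_eff | effective macroion valency | sampled in [10, 70] | — |
| κ⁻¹ | Debye screening length | sampled in [3, 7] | nm |
| r | core radius | 1.985 | nm |
| H_A | Hamaker constant | 2.5×10⁻¹⁹ | J |
| L_B | Bjerrum length | from T, ε_r = 78.5 → 0.717 | nm |
| t | steric shell thickness | 0 (potentials) / 1.2 (curve generator) | nm |
| n_p | number density | 6.32×10⁻⁵ (40 mg/mL Au) | nm⁻³ |

H_A and L_B are not measurable from a scattering curve alone and are
fixed constants of the generator, exposed in configuration.  All q
values are inverse Angstroms (the .dat file convention); all real-space
lengths are nm.  The single conversion (1 Å⁻¹ = 10 nm⁻¹) lives in
`sasmc.constants.q_in_nm_inv`.

### The steric shell

The Hamaker attraction diverges at contact, so a bare hard core at 2r
makes the primary minimum an infinitely deep energy sink.  Short
simulations at weak charge never find it, but any run long enough to
equilibrate a small system nucleates irreversible aggregates and the
total energy falls without bound (we measured −2×10⁸ k_BT before
aborting).  Ligand-capped metal nanoparticles do not do this: the
grafted monolayer keeps cores apart.  The engine therefore places its
hard core at d = 2(r + t) with an impenetrable shell t; at the default
t = 1.2 nm (a compressed undecyl-sulfonate monolayer) the core–core
attraction at steric contact is ≈ −0.2 k_BT and the sampled parameter
box is repulsion-dominated throughout, consistent with the observed
phenomenology (low-q intensity suppression deepening with Z_eff and
κ⁻¹).  The closed-form potentials keep their full domain d > 2r; t = 0
reproduces the bare hard-sphere limits used in the validation suite.

## Monte Carlo engine

Single-particle Metropolis moves: uniform displacement within
±max_displacement per axis, periodic wrapping, minimum-image
convention, acceptance min(1, e^{−ΔE}); overlap moves are rejected
outright.  The pair potential is truncated at min(L/2, 2r + 8κ⁻¹)
without tail corrections (energies only drive acceptance).  Energy
bookkeeping is incremental; a test pins it to a full recomputation at
10⁻⁶ k_BT after 10⁵ steps.

Equilibration follows the checkpoint rule: compare total energies every
`equil_block` steps and declare equilibrium when the relative change
drops below `equil_rel_tol` (defaults 100 000 steps and 1%).  Two
variants exist:

* **instantaneous** checkpoints (default) — the literal rule;
* **block-averaged** checkpoints (`block_average=True`) — at a few
  hundred particles the instantaneous total energy fluctuates by
  several percent at equilibrium, so the literal rule terminates only
  by luck; block averages restore a usable signal.  Desk-scale configs
  enable this variant with a 5% tolerance.

The zero-energy case (ideal gas) is guarded by an energy floor in the
relative-change denominator.  The trial amplitude adapts toward 30–50%
acceptance between equilibration blocks only and is frozen for
production (adaptation during sampling would violate detailed balance).

Production runs `post_equil_steps` further steps; `n_snapshots`
configurations are recorded at step indices drawn uniformly without
replacement.  g(r) is a histogram of minimum-image pair distances over
all snapshots, normalized per snapshot by the ideal shell count
(N/2)·(N−1)/V·(4π/3)(r³_{k+1}−r³_k).  The (N−1)/V pair density (rather
than N/V) makes ĝ ≡ 1 exactly for an uncorrelated fixed-N system;
with N/V the fixed-N constraint biases the transform of [g−1] by
−V_sphere/V (≈ −0.5 at r_max = L/2) even for an ideal gas.  The N/V
density is still what enters the structure-factor transform.

### Finite-size behaviour of S(0)

In the canonical ensemble ∫_box(ĝ−1)dV = 0 exactly, while the
grand-canonical g satisfies n∫(g−1)dV = S(0)−1.  The difference appears
as a small positive offset in the tail of ĝ, so integrating to
r_max = L/2 inflates S(0) by ≈ (1−S(0))·V_sphere/V.  Where a
quantitative S(0) matters (the hard-sphere validation), g(r) is
truncated at ~2.5 diameters — beyond the decay of dilute-fluid
correlations but small against the box.  Curve generation keeps the
literal r_max = L/2; the resulting low-q compression is a smooth,
deterministic function of (Z_eff, κ⁻¹), identical in training corpus,
surrogate and pseudo-measurements, so the learning and inference
pipeline is self-consistent; absolute S(q→0) values at desk scale carry
this finite-size imprint.

## Scattering

S(q) by trapezoidal quadrature of the sine transform over the RDF bins
(the q = 0 point uses the sinc limit); P(q) is the normalized
homogeneous-sphere form factor with a series branch below x = 10⁻⁴;
I(q) = scale·P·S + background with defaults 1 and 0.  The default grid
is 225 linearly spaced points on 0.012–0.501 Å⁻¹ (log spacing
available).  Structure factors from noisy counting can graze zero;
intensities are floored at 10⁻⁶·P before composition.

## Training corpora and networks

Parameters are drawn uniformly over [10, 70] × [3, 7] nm — matching the
prior support used in inference — with per-curve seeds spawned from the
master seed, 8:1:1 train/validation/test split by seeded shuffle, and
no noise augmentation by default.  Features are log₁₀ intensities
standardized per grid point with training-split statistics only;
targets are standardized internally and predictions always return in
physical units.

Both networks follow one recipe: ReLU, Adam at 0.001, MSE, early
stopping when the validation loss has not decreased for 10 consecutive
epochs, best-validation weights restored.  The forward net funnels
512 → 4 over 8 hidden layers onto 2 outputs; the surrogate stacks
(128, 512, 512, 512) onto one output per grid point.  Unstated
hyperparameters are fixed as: batch size 128 (full scale; desk runs use
16 so that a few-hundred-sample epoch still provides tens of gradient
updates), max 500 epochs, sklearn's default fan-in initialization and
small L2 (10⁻⁴).  Training is seed-reproducible; the `select_q_cutoff`
sweep retrains the forward net per candidate cutoff with shared seeds
and picks the minimum validation loss.

### Surrogate error propagation

After training, the surrogate's RMS relative residual per grid point is
measured on the validation split and stored with the model.  This
number is the honest distance between an emulated curve and a freshly
simulated one (network error plus simulator sampling noise, 1–8% at the
lowest q, ~0.2% at mid-q at desk scale).  The χ² likelihood adds it to
the measurement uncertainty in quadrature.  Without this term the
posterior treats the emulator as exact and is overconfident exactly
where the data are informative: measured 90%-interval coverage rose
from 75–80% to 90–95% across synthetic replicates once the emulator
uncertainty was propagated.

## Inference

Uniform priors over the training box (closed boundaries); χ² likelihood
on the surrogate grid with σ from the data's third column, or 2% of the
intensity when absent; affine-invariant ensemble sampling with 32
walkers × 5000 steps by default, first 20% discarded, optional step
thinning.  Convergence is reported (split-chain R̂ < 1.05 over
half-chains), never silently enforced.  The MAP is the retained sample
with maximal log posterior, optionally polished by Nelder–Mead on the
smooth surrogate posterior; credible intervals are central 68%/95%
sample quantiles.  Posterior summaries (marginal histograms, 2-D
histogram, Pearson correlation) provide corner-plot data; the
Z_eff–κ⁻¹ posterior is a strongly anti-correlated ridge because both
parameters raise repulsion, which is also why single-point estimates
of Z_eff carry much wider intervals than κ⁻¹.

## Desk-scale study conditions

Full-scale conditions (5000 particles, 10⁵-step blocks, 250 000
curves) are the configuration defaults but are not what the test bench
runs.  The desk scale used by the test suite and `scripts/acceptance.py`:

* curve generation: 128 particles at n_p = 6.32×10⁻⁵ nm⁻³
  (L ≈ 127 nm), 20 000-step blocks, block-averaged 5% equilibration
  tolerance, 75 000 production steps, 500 snapshots, 256 RDF bins to
  L/2 — ≈ 0.5 s per curve;
* corpora: 600 curves (test suite) / 800 curves (acceptance script);
  at this size the forward net reaches r² ≈ 0.95 for both parameters —
  the paper-scale protocol at 200× the data is not attempted on one CPU;
* ideal-gas check: box-scale trial moves (exact decorrelation for a
  non-interacting system), 4000 snapshots over 600 000 steps,
  r_max = 32 nm;
* hard-sphere check (φ = 0.05): 256 particles, near-teleport moves
  (≈ 2/3 acceptance at this density), 2000 snapshots over 500 000
  steps, r_max = 10 nm;
* two-body Boltzmann check: 3×10⁶ steps, 600 000 recorded distances;
* MCMC: 32 × 2000 (headline fit), 16 × 1000 across the calibration
  replicates.

## What the synthetic data does and does not show

The generator emulates the full forward physics the method targets —
DLVO-correlated particle configurations, their structure factors, and
measurement-like multiplicative noise — so passing tests demonstrate
the complete loop: simulate → learn → invert → recover with calibrated
uncertainty.  It does not emulate instrument resolution smearing,
polydispersity, incoherent background, absolute calibration, or a
measured (rather than analytic-sphere) form factor; real-data use
enters through the user-supplied P(q) and σ columns, and accuracy there
inherits whatever mismatch exists between the DLVO model and the true
interactions.  Desk-scale structure factors also carry the finite-size
imprint described above, so learned mappings are internally consistent
but not interchangeable with full-scale (5000-particle) ones.

## Numerical choices and degenerate inputs

Energies are compared in k_BT throughout; pair distances at or below
the hard core raise domain errors in the closed forms and reject moves
in the engine.  The q = 0 structure-factor point uses the analytic sinc
limit; form-factor evaluation switches to its series below
x = 10⁻⁴.  Insertion of an overpacked box (steric φ ≥ 0.3) and
RDF ranges beyond L/2 are rejected with diagnostics.  Equilibration
budget exhaustion raises an error carrying the full energy trace.
Random draws everywhere derive from explicit seeds via
`numpy.random.SeedSequence`; compiled-kernel streams use numba's
generator seeded per block, reproducible within a numba version.

## Known limitations

* Monodisperse spheres only; no polydispersity, anisotropy, cluster
  moves or NPT ensemble.
* The q_cutoff value 0.00183 Å⁻¹ quoted alongside the grid minimum
  0.012 Å⁻¹ in the source material cannot exist on that grid; cutoffs
  are validated against the grid and such values rejected.
* The surrogate extrapolates silently outside the training box — the
  uniform prior confines inference to the box, but direct
  `predict_curve` calls are not range-checked.
* Model checkpoints are joblib pickles (sklearn convention): portable
  across sessions, not across major sklearn versions.
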