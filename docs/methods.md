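# Methods

## The kinetic model

Photoactivated cryptochrome 4 relays an electron to its FAD chromophore
through a conserved tetrad of tryptophan residues; equivalently, an electron
hole hops outward along the chain Trp_A → Trp_B → Trp_C → Trp_D (residues
396, 373, 319 and 370 in the Atlantic herring orthologue, ChCry4).  The
occupation of the hole on site X corresponds to the radical-pair state
[FAD·⁻ TrpX·⁺].  We model the hole dynamics as a reversible linear chain of
first-order transfer reactions,

    A ⇄ B ⇄ C ⇄ D

with six rate constants k_f/k_b per neighbouring pair (units 1/ps).  The
occupations p(t) = (A, B, C, D)(t) obey the master equation dp/dt = M p with
the tridiagonal generator

    M = [ -kfAB      kbAB            0          0    ]
        [  kfAB   -(kbAB+kfBC)     kbBC         0    ]
        [   0        kfBC       -(kbBC+kfCD)   kbCD  ]
        [   0         0             kfCD      -kbCD  ]

whose columns sum to zero (probability conservation).  The default initial
condition is p(0) = (1, 0, 0, 0): the first electron transfer from Trp_A to
FAD is taken as already completed, so the hole starts on Trp_A.  This is
overridable.

Assumptions: the hole is always localized on exactly one site (a kinetic,
not a coherent-quantum description), rates are time-independent (no
conformational gating, no temperature dependence), and only
nearest-neighbour transfer occurs.  Rates are fit parameters of this model;
the package makes no attempt to predict them from structure (no
Marcus/Moser–Dutton analysis).

### Propagation

`propagate` solves the master equation exactly through the
eigendecomposition of M, p(t) = V exp(Λt) V⁻¹ p(0).  If the eigenvector
matrix is ill-conditioned (condition number above 1e8, i.e. a
near-degenerate spectrum) or conservation degrades beyond 1e-8, the solver
falls back to stepwise dense matrix exponentials expm(M Δt), which are exact
for the linear system at any stiffness.  Output occupations are clipped to
[0, 1] and renormalized per time point; conservation holds to 1e-9 on every
grid point (tested to 1e-6 against an independent fixed-step RK4 integration
at dt = 0.01 ps).

For a reversible chain (all six rates positive) the equilibrium is the
detailed-balance closed form π ∝ (1, K₁, K₁K₂, K₁K₂K₃) with
K₁ = kfAB/kbAB, K₂ = kfBC/kbBC, K₃ = kfCD/kbCD.  `steady_state` refuses
irreversible chains and directs the caller to long-time propagation.

### Rate fitting

`fit_rates` recovers the six rates from an occupation trace by minimizing
the equally weighted sum of squared residuals over all four site curves and
all time points, using Levenberg–Marquardt on the *logarithms of the time
constants*.  The log parameterization enforces positivity without bounds and
puts rates spanning an order of magnitude on a common scale.  Because the
problem is nonconvex, 16 seeded log-uniform initializations with time
constants in [1, 1000] ps are tried by default; ties are broken by residual
norm and then by the lexicographically smallest rate vector, so results are
deterministic given the seed.  Internally the time constants are clamped to
[1e-8, 1e12] ps so stray optimizer steps cannot overflow the rate matrix.
The reported `per_parameter_spread` (population sd of each rate across
successful starts) is a cheap identifiability diagnostic, not a confidence
interval.  Non-convergence of every start returns a flagged result, never an
exception.

Reference parameter set: the package ships the ChCry4 transfer time
constants (forward 23, 149, 57 ps; backward 141, 82, 240 ps) as
`CHCRY4_TIME_CONSTANTS_PS`/`chcry4_rates()`.  On noiseless model output the
fit recovers all six to machine precision; 1 % relative is the tested
contract on 1000-point grids.

## The synthetic ensemble generator

No trajectory data ship with the package, so every downstream stage is
validated against generated ensembles with known ground truth.  The
generator's defaults are the study conditions: 51 trajectories (23
"completed" + 28 "stuck") of 1 ns sampled on a 1 ps grid, hole starting on
Trp_A.

`simulate_kmc` realizes the chain as a continuous-time Markov jump process
(Gillespie/kinetic Monte Carlo), sampled on the grid as indicator
occupations — exactly one site occupied per time point.  The ensemble mean
of indicators is an unbiased estimate of the master-equation solution and
plays the role of ensemble-averaged quantum populations.  What this does
*not* emulate: true per-trace QM/MM populations are continuous partial
charges, not indicators; an optional sliding-window mean (default window
25 ps) provides fractional per-trace occupations, but neither mode models
coherence, vibronic effects or rate heterogeneity between trajectories.
Random streams are split per trajectory from the master seed
(`SeedSequence.spawn`), so enlarging the ensemble never reshuffles earlier
trajectories.

`make_heterogeneous_ensemble` models the stuck subpopulation by setting
kfBC = 0 — confining the hole to {A, B} — which is the simplest mechanism
reproducing the stuck phenotype, a modelling choice rather than a mechanism
claim (site-energy shifts would be an alternative).  Completed-slot
trajectories are redrawn deterministically (per-slot child streams) until
the hole actually visits Trp_C/Trp_D, so the attached ground-truth labels
are correct by construction on noiseless output; without this, about 1 % of
trajectories at the reference rates never leave {A, B} within 1 ns.

`add_observation_noise` adds i.i.d. Gaussian noise per site and time point,
clips to [0, 1] and renormalizes each time point.  Clipping biases the noise
near the boundaries; the tests compare against a direct Monte-Carlo oracle
with the same rule rather than pretending the noise stays zero-mean.  The
noise magnitude (default 0 in the config; 0.05 is the tested upper band for
reliable classification) is a free parameter — per-trace occupation
variability of the emulated data is not known.

Site energies and electronic couplings are emulated as stationary
Ornstein–Uhlenbeck series (exact discretization, stationary start) around
user-specified means in eV; couplings exist only for the neighbouring pairs
AB/BC/CD, and requesting a non-neighbour pair is an error while looking one
up returns an identically zero series.

## Trajectory reduction

A trajectory is "completed" when the occupation of Trp_C or Trp_D reaches
at least 0.3 at *any* sampled time point, else "stuck".  The boundary is
closed (≥) and the threshold applies to instantaneous occupations; both are
parameters.  Classification is invariant under the permitted per-time-point
renormalization band (sums within 0.05 of 1).  Ensemble summaries report
pointwise means with *population* standard deviations — the bands describe
the ensemble itself, not an estimator; this too is exposed as a choice.
`compare_subsets` returns (all, completed, stuck) summaries, flagging empty
subsets or missing series as absent rather than failing.

## Structural descriptors

`count_waters_near` counts distinct water molecules (residue names
HOH/WAT/SOL/TIP3, configurable) with ANY atom within a closed cutoff
(default 5 Å, with a 1e-9 Å floating-point guard) of ANY heavy atom of the
residue.  `edge_to_edge` is the minimum distance between *side-chain* heavy
atoms of two residues (backbone N/CA/C/O/OXT excluded), the standard
convention for electron-transfer edge distances; an all-heavy-atom mode is
available.  No periodic-image handling: frames are assumed whole and
centered, a documented limitation.  Both descriptors agree exactly with
brute-force all-pairs oracles on every fixture, and are invariant under
rigid motions.

Distance samples are histogrammed (Freedman–Diaconis bin count by default,
minimum 5 bins) into a density and fit with a single Gaussian by unweighted
least squares on the bin centers, initialized at the sample moments; the
fitted mean is reported as the distribution maximum.  Degenerate samples
(zero variance) flag `fit_ok = False`.  Whether the emulated analysis fit a
histogram or matched moments is unknown; for unimodal distributions at
these sample sizes the difference is far below the 0.01 Å tested tolerance.

### Toy structure fixtures

`make_toy_frames` builds four planar TRP side chains in parallel planes so
that neighbouring minimum heavy-atom separations equal the requested values
exactly, and places waters on circles around CB at exact requested minimum
distances.  Frames differ by rigid translations snapped to the 0.001 Å PDB
coordinate grid, so all constructed distances survive PDB round-tripping
bit-for-bit (rotations would destroy the 3-decimal exactness; rotation
invariance is therefore tested on in-memory frames).  A per-frame Gaussian
jitter on the separations produces distance-distribution fixtures.  The
water fan geometry realizes exact distances only for moderate counts
(≈3 per residue); the generator verifies realized distances to 5e-3 Å and
rejects otherwise.  Waters are single-oxygen residues; the any-atom rule
for hydrogens is covered by hand-built frames in the tests.

## Problem sizes and determinism

Default problem sizes are those of the emulated study (51 × 1001-point
trajectories; 500-trajectory ensembles for stochastic rate recovery; 1e5
samples for distribution-fit checks; 100 random rate sets for propagator
validation).  Every stochastic component takes an explicit integer seed and
is reproducible bit-for-bit; the CLI records seeds and subset sizes in its
logs and JSON outputs.  At 500 trajectories the recovered slow backward C–D
time constant scatters by roughly ±20 % across seeds — the ensemble mean's
binomial noise propagates most strongly into the weakly identified backward
rates, which is why the stochastic-recovery contract is 25 % while the
noiseless contract is 1 %.

## Known limitations

- The KMC generator cannot reproduce coherent or vibronic effects, nor any
  correlation between hole dynamics and the structural/energetic series
  (site energies, couplings, water counts are generated independently).
- Rates are constant; gating by conformational change is out of scope.
- Only PDB input is supported for structure frames (no XTC/DCD), and no
  solvent-accessible-surface-area analysis is provided.
- The stuck/completed mixture is phenomenological (kfBC = 0); fitted rates
  from a completed-only subset are conditioned on completion and will not
  equal the generating rates of the full mixture.
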