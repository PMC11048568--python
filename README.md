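# trpchain

Electron-hole hopping kinetics along the cryptochrome-4 tryptophan tetrad:
reversible four-state kinetic modelling, stochastic trajectory ensembles
with known ground truth, completed/stuck trajectory classification, and
structural descriptors of the tetrad environment.

## The problem

Cryptochrome 4 (Cry4) is the leading candidate protein for radical-pair
magnetoreception in migratory animals.  After blue-light excitation of its
FAD chromophore, an electron is relayed to the flavin through a conserved
chain of four tryptophan residues — equivalently, an electron hole hops
outward, Trp_A → Trp_B → Trp_C → Trp_D (residues 396, 373, 319, 370 in the
Atlantic herring orthologue, ChCry4).  The hole occupation on site X defines
the radical-pair state [FAD·⁻ TrpX·⁺]; whether the hole reaches the surface
residue Trp_D decides whether a magnetically sensitive radical pair can
form.

This package is for computational biophysicists who have (or want to
emulate) ensembles of such hole-transfer trajectories and need to

- extract the six forward/backward transfer rate constants of the chain

      Trp_A ⇄ Trp_B ⇄ Trp_C ⇄ Trp_D,      dp/dt = M p,

  by fitting the four-state master equation to ensemble-averaged
  occupations A(t), B(t), C(t), D(t);
- classify trajectories as *completed* (occupation ≥ 0.3 on Trp_C or Trp_D
  at some time) versus *stuck* on Trp_B, and summarize site-energy ε_i and
  electronic-coupling T_ij series per class;
- compute water counts within 5 Å of each tryptophan and Trp_B–Trp_C
  edge-to-edge (side-chain heavy-atom minimum) distance distributions with
  Gaussian fits from PDB frames;
- generate all of the above synthetically — kinetic-Monte-Carlo hole
  hopping, Ornstein–Uhlenbeck energy/coupling series, toy PDB frames with
  exactly constructed geometry — so every stage is testable without the
  original trajectory data.

The package ships the ChCry4 reference time constants (forward 23, 149,
57 ps and backward 141, 82, 240 ps for A–B, B–C, C–D) as its default
parameter set.

## Worked example

```python
import numpy as np
import trpchain as tc

rates = tc.chcry4_rates()                  # reference ChCry4 rate constants
grid = np.arange(0.0, 1001.0)              # 0..1000 ps at 1 ps

# exact master-equation solution, hole starting on Trp_A
trace = tc.propagate(rates, grid)
print(np.round(trace.occ[100], 3))         # [0.114 0.609 0.144 0.132]
print(np.round(trace.occ[1000], 3))        # [0.041 0.252 0.137 0.57 ]

# recover the rate constants back from the curves (multi-start least squares)
fit = tc.fit_rates(trace, n_starts=16, seed=1)
print({k: round(v, 1) for k, v in fit.time_constants().items()})
# {'tau_fAB': 23.0, 'tau_bAB': 141.0, 'tau_fBC': 149.0,
#  'tau_bBC': 82.0, 'tau_fCD': 57.0, 'tau_bCD': 240.0}

# labeled synthetic ensemble: 23 completed + 28 stuck 1 ns trajectories
ens = tc.make_heterogeneous_ensemble(seed=1)
res = tc.classify_ensemble(ens)
print(res.n_completed, res.n_stuck, res.agreement)   # 23 28 1.0

print(np.round(tc.steady_state(rates), 4))
# [0.0405 0.2481 0.1365 0.5749]
```

The numbers mean: within 100 ps the hole has mostly left Trp_A (occupation
0.114) and accumulated on Trp_B (0.609); by 1 ns the chain approaches its
equilibrium, with Trp_D the most occupied site (0.57) — the configuration
relevant for magnetosensing.  The refit recovers every generating time
constant, and the classifier reproduces the generator's 23/28
completed/stuck split with 100 % label agreement.

## Command line

```sh
trpchain simulate --seed 11 --out run             # occupations.csv + labels + meta
trpchain classify --occupations run/occupations.csv --labels run/labels.json --out run/classification
trpchain fit --occupations run/occupations.csv --subset completed \
             --labels run/labels.json --out run/fit.json
trpchain structure --pdb frames.pdb --out run/structure_completed
trpchain report --run-dir run                     # one machine-readable summary
```

Every command takes explicit seeds and is reproducible byte-for-byte; exit
codes are 0 (success), 2 (validation error), 3 (fit non-convergence).

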