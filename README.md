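# agegrn

Attractor, bifurcation, and quasi-potential landscape analysis of a
p53-centred gene-regulatory-network model of cellular ageing.

## The model

Thirteen species — p53, Mdm2, Wip1, ATM, p21, PTEN, AKT, Myc, E2F, RB,
CycE, CycD, ARF — couple the DNA-damage response circuit around p53 to the
Rb–E2F cell-cycle entry switch.  Each concentration `x_i` obeys a
Hill-kinetics ODE

    dx_i/dt = a · Σ_act  x_s^n / (S^n + x_s^n)
            + b · Σ_inh  S^n / (S^n + x_s^n)
            − k · x_i

with activation rate `a` (interpreted as accumulated DNA damage),
inhibition rate `b`, Hill threshold `S = 0.5`, coefficient `n = 4`, and
degradation `k = 1 /h`.  Two constant inputs drive the network: `Stress =
0.3` (→ ATM) and the growth signal `GS = 0.2` (→ Myc, CycD).  The built-in
network has 13 nodes and 32 signed interactions.

On top of the ODE core the package provides:

- **attractors** — seeded multistart relaxation, Newton polishing, analytic
  Jacobian stability, basin fractions, and phenotype labels (homeostasis,
  cell-cycle arrest, senescence/apoptosis, cancer) from the (p53, ATM)
  markers;
- **bifurcation** — natural-parameter continuation with saddle-node
  bracketing, quasi-static hysteresis sweeps, two-parameter (a, b)
  stability maps, and the growth-signal-gated Rb–E2F restriction point;
- **landscape** — Monte Carlo quantification of the Waddington
  quasi-potential `U = −ln P(x)` over a 2-D projection from many random
  initial conditions, persistent-basin detection, depth ranking, and
  heteroclinic saddle paths;
- **perturbation** — edge deletion (e.g. removing the activation of p53 by
  ATM and by ARF, which creates a low-p53/high-ATM "cancer" basin in the
  aged landscape).

## Worked example

```python
import numpy as np
from agegrn import (ParameterSet, build_ageing_network, find_attractors,
                    converge_to_steady_state, continue_branch)

net = build_ageing_network()
p = ParameterSet()                       # S=0.5, n=4, k=1, a=1, b=0.05

att = find_attractors(net, p.with_(a=1.0), n_starts=1000, seed=1,
                      distinct_by=("p53", "ATM"))
for s in att:
    if s.stable:
        print(f"{s.phenotype:24s} p53={s.state[0]:.3f} "
              f"ATM={s.state[3]:.3f} basin={s.basin_fraction:.3f}")

x0, _, _ = converge_to_steady_state(net, p.with_(a=0.3), np.zeros(13))
br = continue_branch(net, p, "a", 0.3, x0, +1, step=0.01)
print("low-branch fold at a =", round(br.folds[0], 3))
```

prints

```
senescence_or_apoptosis  p53=1.954 ATM=1.073 basin=0.883
cell_cycle_arrest        p53=0.931 ATM=0.122 basin=0.116
homeostasis              p53=0.121 ATM=0.182 basin=0.001
low-branch fold at a = 1.152
```

At the default damage level the cell can rest in three fates distinguished
by its p53 and ATM levels — the tri-stable switch — and the low-p53
homeostasis branch is lost in a saddle-node at `a ≈ 1.15`: past that
damage threshold p53 turns on.  `distinct_by=("p53", "ATM")` counts cell
fates on the marker plane; without it the search also distinguishes the
E2F-low/high variants of each fate produced by the self-sustaining Rb–E2F
switch, which the p53 module does not feed back on (see
`docs/methods.md`).

The same analyses are available from the shell:

```sh
agegrn attractors --out runs/tri --param a=1.0 --seed 1
agegrn landscape  --out runs/aged --param a=1.5 --n-traj 10000 --seed 1
agegrn landscape  --out runs/cancer --param a=1.5 --seed 1 \
    --delete ATM:p53:activation --delete ARF:p53:activation
```

Every run directory receives a `provenance.json` (resolved configuration,
seed, versions, wall time) sufficient to reproduce it.

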