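# Methods

## Model

The network state is a vector of 13 non-negative, dimensionless
concentrations in fixed order: p53, Mdm2, Wip1, ATM, p21, PTEN, AKT, Myc,
E2F, RB, CycE, CycD, ARF.  Every regulatory interaction contributes one
additive Hill production term to its target's ODE — `a·x^n/(S^n+x^n)` for
an activation by species (or input) `x`, `b·S^n/(S^n+x^n)` for an
inhibition — and every species decays linearly at rate `k`.  Inhibition is
therefore modelled as basal production that the inhibitor shuts off, not
as enhanced degradation; production is always non-negative and the
non-negative orthant is forward-invariant.  Every steady state is bounded
by `(a·#activators + b·#inhibitors)/k` per node.

The two external inputs, `Stress` (oxidative/DNA-damage stress, driving
ATM) and `GS` (growth signal, driving Myc and CycD), are constant
pseudo-nodes: they may source edges but are never integrated.

| parameter | meaning | default | units |
|---|---|---|---|
| `S` | Hill threshold of every regulatory term | 0.5 | conc. |
| `n` | Hill coefficient (binding cooperativity) | 4 | — |
| `k` | degradation rate, scalar or per node | 1 | 1/h |
| `a` | activation rate; proxy for accumulated DNA damage | 1 | conc./h |
| `b` | inhibition (basal) rate | 0.05 | conc./h |
| `Stress` | constant stress input level | 0.3 | conc. |
| `GS` | constant growth-signal level | 0.2 | conc. |

Networks are compiled to edge-grouped index arrays, so the right-hand side
evaluates vectorised over whole ensembles of states and perturbed variants
(edge deletions) need no hand-written equations; a transcription test pins
the built-in network to the written-out 13 equations.  The Jacobian is
analytic: each node-sourced edge contributes
`±(a|b)·n·S^n·x^{n−1}/(S^n+x^n)^2` off the diagonal and the diagonal
carries `−k`.

## One-way module coupling and what "an attractor" means

The p53 module (p53, Mdm2, Wip1, ATM, p21, PTEN, AKT) receives its only
cell-cycle input through ARF ← Myc ← GS, a feed-forward chain that does
not depend on E2F.  The Rb–E2F switch (E2F, RB, CycE; CycD and Myc are
monotone slaves) is therefore driven by, but never feeds back on, the
DNA-damage side.  Fixed points consequently come in products: whenever the
E2F self-activation is strong enough to be bistable (roughly `a ≳ 0.55`,
self-sustaining at zero growth signal for `a ≳ 0.88`), every p53-module
state exists in an E2F-low and an E2F-high variant with *identical* p53,
ATM, and all other damage-module coordinates.

Cell fates, as read out on the (p53, ATM) marker plane or in the
landscape projection, collapse these variants.  `find_attractors` hence
supports two counting modes: full-state clustering (default; max-coordinate
metric, tolerance 1e-3) and `distinct_by=("p53","ATM")`, which clusters on
the marker coordinates and is the mode in which the model is tri-stable at
`a = 1` and mono-stable at `a = 0.3` and `a = 2`.

## Integration and steady states

Single trajectories: `solve_ivp`/LSODA with the analytic Jacobian,
rtol 1e-8 / atol 1e-10; negative excursions beyond −1e-9 raise, smaller
ones are clipped to zero.  Ensembles (multistart, landscapes): all `m`
trajectories are stacked into one flat state and integrated with RK45 at
rtol 1e-6 (1e-8 for convergence blocks) — the error norm couples the
ensemble, which is appropriate for Monte Carlo statistics and amortises
the per-step Python cost; a consistency test checks ensemble endpoints
against single-trajectory integration.

Convergence is declared on the derivative norm (`max |dx/dt| < 1e-8`,
step-size independent), probed after 50 h blocks up to 2000 h.  Endpoints
are polished with a Newton solve (`scipy.optimize.root`, hybr, analytic
Jacobian) and accepted at residual < 1e-8; stability is the sign of the
spectral abscissa.  Initial conditions are sampled coordinate-wise uniform
on `[0, x_max]` with `x_max = 3` by default — the attractors of all
studied regimes lie inside `[0, 3]` for 12 of 13 coordinates (p53 reaches
4.0 only at `a = 2`), and widening the box only dilutes sampling density
without changing which basins exist.  The range is recorded in every
output's metadata.

## Continuation and folds

Branches are traced by natural-parameter predictor–corrector: step the
free parameter (`a`, `b`, `S`, or an input level), Newton-correct from the
previous fixed point, and accept if the corrected point moved less than
0.25 in any coordinate.  Corrector failure or a jump beyond that
continuity tolerance marks the loss of the branch; the fold is then
bracketed by bisection in the parameter to a width of 1e-5 — narrow
enough that the leading eigenvalue (which vanishes like the square root of
the distance to a saddle-node) is below 1e-2 at the last accepted point —
and reported as the bracket midpoint to three decimals.  Pseudo-arclength
is deliberately not used: the model exhibits folds only (no Hopf points),
and branch segments past a fold are reached by restarting from the other
attractor.

Protocol matters because of the product structure above.  The high-p53
branch obtained by relaxing an all-high state carries the E2F-high
variant, whose own E2F fold (at `a ≈ 0.865`) terminates the downward
continuation early.  The physical "coming down after going up" protocol —
relax the origin at `a = 2`, which yields the E2F-low variant — continues
down to the p53-module fold at `a = 0.747`.  The acceptance computation
uses the up-sweep protocol.  The three thresholds of the tri-stable p53
switch at `b = 0.05` are then 1.152 (low branch lost), 1.455
(intermediate branch lost), 0.747 (high branch lost).

Quasi-static hysteresis sweeps relax to rest at each parameter value from
the previous endpoint.  Tracking the intermediate branch requires steps
small enough (≈0.02 near the folds) that the jump off the vanished low
branch lands on the nearest attractor; with coarse steps the sweep jumps
straight to the high state, which is a property of the flow, not of the
sweep machinery.

### Restriction point

The Rb–E2F analysis treats `GS` as the free parameter.  At the default
`a = 1` the E2F self-activation is self-sustaining even at `GS = 0`, so
the committed branch never folds and the switch is one-way.  The
growth-signal-gated regime — an activation fold SN4 and a lower
commitment-locking fold SN5, both at positive GS, with the p53 module
quiescent throughout — exists for `a ≈ 0.6–0.7`; the package's
recapitulation uses `a = 0.7` (SN4 ≈ 0.491, SN5 ≈ 0.415) and continues
the committed branch from the state the up-sweep jumps to just past SN4.
CycD increases monotonically along the off branch.

## Quasi-potential landscape

`U = −ln P(x)` with `P` estimated from `n_traj` trajectories started
uniform in `[0, x_max]^13`, each sampled at 500 evenly spaced times over
50 h and binned by its (p53, ATM) — alternatively (p21, ATM) — values on
a 100×100 grid over `[0, 3]²`.  Transients and equilibrium dwell both
count; the long residence at attractors relative to transit regions is
what carves the valleys.  Probabilities sum to one exactly; empty boxes
carry a capped potential (max finite U + 1) and are flagged.  Trajectories
run in batches of 2000 with per-batch seeds spawned by counter from the
run seed, so results are independent of the batch size.  The default
budget is 100,000 trajectories; basin counts saturate far earlier, and the
test suite and acceptance use 10,000 (2,000 for smoke-level tests).

### Basin detection

Raw local minima of U include Monte Carlo speckle wherever a few counts
land in thinly visited regions.  `locate_basins` therefore (i) smooths the
histogram with a 3×3 box mean, (ii) floods the smoothed potential in
sublevel order with a union-find, pruning any minimum whose separating
ridge stands less than 1 (in −ln P units, i.e. an e-fold of probability)
above its floor — never-visited boxes flood at the cap level so no region
is walled off, (iii) snaps survivors to the raw-potential floor box inside
the smoothing window and requires a raw visit probability of at least
2e-5 there, and (iv) merges survivors closer than 5 boxes.  The
probability floor is scale-free (the binned *density* converges as
`n_traj` grows, so the threshold does not depend on the budget); genuine
valleys in this model hold ≥ 6e-5 of the visit mass per floor box while
speckle stays below ~1e-5.  All four knobs are exposed.

### Ghost basins

A `−ln P` landscape is a statement about *dwell*, not about fixed points.
Just past a saddle-node, the flow through the region where the fixed point
annihilated is algebraically slow, and that slow transit shows up as a
genuine, reproducible valley.  Two of the model's headline landscapes rely
on this: at `a = 1.5` the intermediate-p53 branch is already gone (fold at
1.455), and the second, shallower basin of the aged landscape is the slow
remnant of the cell-cycle-arrest state; in the p53-inactivated network at
`a = 1.5` the ATM-low fixed points do not exist at all (the ATM drive has
no low root), and the homeostasis and arrest valleys of its four-basin
landscape are likewise near-fold transit regions.  Multistart counts
therefore differ from basin counts in exactly these regimes — the
landscape sees four basins where Newton finds two fixed points — and the
package reports both honestly rather than forcing agreement.  U-minima are
expected to co-locate with stable fixed points (within one grid box; this
is tested) only in regimes whose basins all hold attractors, e.g.
`a = 0.5` and `a = 1.0`, and never with saddles.

### Saddle paths

For an index-1 saddle (exactly one eigenvalue with positive real part),
integrating from `saddle ± 1e-4·v` along the unstable eigenvector yields
the two heteroclinic halves of its unstable manifold, each terminating at
an attractor; they are returned projected on the landscape coordinates.
Saddles are sought by Newton solves seeded along segments between
attractor pairs.  In the tri-stable window (e.g. `a = 1.3`) the path
connects cell-cycle arrest to senescence; in the perturbed network at
`a = 1.5` the one index-1 saddle connects cancer to senescence.  No
heteroclinic path can terminate in a ghost basin, since there is no fixed
point there.

## Phenotype labels

Labels depend only on (p53, ATM) and three cut points, derived from the
computed attractor structure: the p53 low/intermediate and
intermediate/high cuts are midpoints of the branch levels in the
tri-stable regime (defaults 0.5 and 1.4), and the ATM cut is the midpoint
of the largest gap in the pooled attractor ATM levels of the `a = 1` and
`a = 1.5` regimes (default 0.65).  `derive_thresholds` recomputes all
three for any network; classification reports `unclassified` for
combinations outside the four named fates (e.g. high p53 with low ATM).  A
known limitation: in the p53-inactivated network the arrest-like and
senescence-like states share the same p53 level, so no monotone threshold
scheme can name both; no analysis here depends on those two labels.

## What the random-initial-condition ensemble does and does not emulate

The Monte Carlo ensemble is the model's own definition of the landscape:
uniform random starts stand in for a population of cells in scattered
initial expression states, and all stochasticity lives in the initial
condition — the dynamics are deterministic, with no intrinsic
(Langevin/chemical-master-equation) noise, no cell division, and no
parameter heterogeneity between trajectories.  Passing the landscape
checks therefore shows that the deterministic flow, projected and weighted
by dwell time, reproduces the published basin structure; it does not show
how molecular noise would reshape barrier crossings in a real cell.

## Problem sizes and runtime choices

Default test-suite and acceptance sizes: 2,000 multistart samples for the
fate counts, 10,000 trajectories per acceptance landscape (1,000–2,000 in
unit tests), 500 trajectories (300 in tests) for the commitment-time
median, continuation step 0.01 with 1e-5 fold brackets.  These sizes are
saturated: doubling the multistart or trajectory budget changes no
reported count, and halving solver tolerances or continuation steps moves
endpoints by < 1e-6 and folds by < 1e-3 (both tested).

## Known limitations

- Global `a` and `b`: one activation and one inhibition rate for the whole
  network; per-edge kinetics are out of scope.  Per-node degradation maps
  are supported but no alternative rate set ships.
- Multistart cannot find repellors and finds saddles only via the seeded
  between-attractor search; exhaustive fixed-point enumeration (homotopy)
  is out of scope.
- Basin-detection defaults are tuned to the 100×100 / `[0,3]²` grid; very
  coarse grids or tiny trajectory budgets may need a lower probability
  floor.
- No stochastic dynamics, no delays, no Hopf/limit-cycle continuation (the
  model exhibits folds only in the studied ranges).
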