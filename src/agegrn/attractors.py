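"""Attractor identification by seeded multistart, stability, and phenotypes.

Random initial states are relaxed to rest, endpoints are polished by a Newton
root solve on the right-hand side, near-identical fixed points are clustered,
and stability is read off the analytic Jacobian.  Phenotype labels follow the
(p53, ATM) coordinates: homeostasis (both low), cell-cycle arrest
(intermediate p53, low ATM), senescence/apoptosis (both high), and the
cancer state (low p53, high ATM) that appears only after p53-inactivating
network perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import root

from .model import CompiledNetwork, ParameterSet, RegulatoryNetwork, compile_network
from .integrate import converge_ensemble, sample_initial_conditions

RESIDUAL_TOL = 1e-8


def jacobian(state, network: RegulatoryNetwork, params: ParameterSet,
             compiled: CompiledNetwork | None = None) -> np.ndarray:
    """Analytic Jacobian of the model right-hand side at ``state`` (per hour)."""
    cn = compiled or compile_network(network, params)
    return cn.jac(np.asarray(state, dtype=float))


@dataclass
class SteadyState:
    """A polished fixed point with its spectrum and multistart statistics."""

    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    basin_fraction: float = 0.0
    phenotype: str = "unclassified"
    residual: float = np.nan

    @property
    def spectral_abscissa(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Cut points on (p53, ATM) separating the phenotype labels.

    ``p53_low`` splits low from intermediate p53, ``p53_high`` intermediate
    from high; ``atm`` splits low from high ATM.  Defaults are midpoints
    between the attractor levels of the unperturbed network at its default
    parameters (the three p53 branch levels in the tri-stable regime at
    a = 1; the gap in the pooled bimodal ATM levels); see
    :func:`derive_thresholds`, which recomputes them from the network at
    hand.
    """

    p53_low: float = 0.5
    p53_high: float = 1.4
    atm: float = 0.65

    def __post_init__(self):
        if not (0 < self.p53_low < self.p53_high):
            raise ValueError("need 0 < p53_low < p53_high")
        if self.atm <= 0:
            raise ValueError("atm cut must be > 0")


def classify_phenotype(state, thresholds: PhenotypeThresholds | None = None,
                       network: RegulatoryNetwork | None = None,
                       p53: float | None = None, atm: float | None = None) -> str:
    """Label a steady state from its (p53, ATM) coordinates.

    Either pass the full ``state`` with its ``network`` (to locate the two
    coordinates), or pass ``p53`` and ``atm`` directly.
    """
    th = thresholds or PhenotypeThresholds()
    if p53 is None or atm is None:
        if network is None:
            raise ValueError("need a network to locate p53/ATM in the state vector")
        state = np.asarray(state, dtype=float)
        p53 = float(state[network.node_index("p53")])
        atm = float(state[network.node_index("ATM")])
    if atm < th.atm:
        if p53 < th.p53_low:
            return "homeostasis"
        if p53 < th.p53_high:
            return "cell_cycle_arrest"
        return "unclassified"
    if p53 < th.p53_low:
        return "cancer"
    if p53 >= th.p53_high:
        return "senescence_or_apoptosis"
    return "unclassified"


def polish_fixed_point(cn: CompiledNetwork, x_guess: np.ndarray) -> np.ndarray | None:
    """Newton-polish a candidate fixed point; None when the solve fails."""
    sol = root(cn.rhs, np.asarray(x_guess, dtype=float), jac=cn.jac, method="hybr",
               options={"xtol": 1e-12})
    if not sol.success or np.max(np.abs(cn.rhs(sol.x))) > RESIDUAL_TOL:
        return None
    return np.clip(sol.x, 0.0, None)


def _cluster(points: np.ndarray, tol: float) -> list[list[int]]:
    """Greedy max-coordinate clustering; returns member index lists."""
    clusters: list[list[int]] = []
    reps: list[np.ndarray] = []
    for i, p in enumerate(points):
        for c, r in zip(clusters, reps):
            if np.max(np.abs(p - r)) < tol:
                c.append(i)
                members = points[c]
                r[:] = members.mean(axis=0)
                break
        else:
            clusters.append([i])
            reps.append(p.copy())
    return clusters


def find_attractors(network: RegulatoryNetwork, params: ParameterSet,
                    n_starts: int = 1000, x_max: float = 3.0, seed: int = 0,
                    cluster_tol: float = 1e-3,
                    thresholds: PhenotypeThresholds | None = None,
                    t_max: float = 2000.0,
                    distinct_by: Sequence[str] | None = None,
                    compiled: CompiledNetwork | None = None) -> list[SteadyState]:
    """Multistart attractor search; deterministic under a fixed seed.

    Each uniform random start in [0, x_max]^N is relaxed until its derivative
    norm falls below 1e-8, the endpoint is Newton-polished, and fixed points
    closer than ``cluster_tol`` (max-coordinate metric) are merged.  Stable
    fixed points are returned sorted by descending basin fraction; any
    unstable ones stumbled upon are appended with zero basin weight.
    Unconverged starts are excluded from the basin denominator.

    ``distinct_by`` restricts the clustering metric to the named coordinates.
    The p53 module drives the cell-cycle module without feedback, so full-
    state attractors come in pairs that differ only in the self-sustaining
    Rb-E2F switch while sharing identical DNA-damage-marker coordinates;
    counting cell fates the way the landscape projection does means
    clustering on ``("p53", "ATM")``.  The default (None) distinguishes every
    full-state fixed point.
    """
    cn = compiled or compile_network(network, params)
    X0 = sample_initial_conditions(network, n_starts, x_max=x_max, seed=seed)
    endpoints, converged = converge_ensemble(cn, X0, t_max=t_max)
    idx = np.nonzero(converged)[0]
    if idx.size == 0:
        return []
    pts = endpoints[idx]
    polished = np.empty_like(pts)
    ok = np.zeros(len(pts), dtype=bool)
    # polish one representative per coarse cluster, then re-assign members
    coarse = _cluster(pts, tol=max(cluster_tol, 1e-4))
    for members in coarse:
        fp = polish_fixed_point(cn, pts[members[0]])
        if fp is None:
            continue
        polished[members] = fp
        ok[members] = True
    pts = polished[ok]
    if pts.size == 0:
        return []
    if distinct_by is not None:
        cols = [network.node_index(c) for c in distinct_by]
        clusters = _cluster(pts[:, cols], cluster_tol)
    else:
        clusters = _cluster(pts, cluster_tol)
    out: list[SteadyState] = []
    n_eff = len(pts)
    for members in clusters:
        rep = pts[members[0]]
        eig = np.linalg.eigvals(cn.jac(rep))
        stable = bool(np.max(eig.real) < 0)
        ss = SteadyState(
            state=rep,
            eigenvalues=eig,
            stable=stable,
            basin_fraction=float(len(members) / n_eff) if stable else 0.0,
            phenotype=classify_phenotype(rep, thresholds, network=network),
            residual=float(np.max(np.abs(cn.rhs(rep)))),
        )
        out.append(ss)
    out.sort(key=lambda s: (not s.stable, -s.basin_fraction))
    return out


def find_saddles(network: RegulatoryNetwork, params: ParameterSet,
                 attractors: Sequence[SteadyState], n_line: int = 21,
                 cluster_tol: float = 1e-3,
                 compiled: CompiledNetwork | None = None) -> list[SteadyState]:
    """Search for unstable fixed points between attractor pairs.

    Newton solves are seeded along the straight segments joining each pair of
    attractor states; converged fixed points with at least one unstable
    direction are clustered and returned sorted by their number of unstable
    eigenvalues (index-1 saddles first).
    """
    cn = compiled or compile_network(network, params)
    seeds = []
    stable = [a for a in attractors if a.stable]
    for i in range(len(stable)):
        for j in range(i + 1, len(stable)):
            for lam in np.linspace(0.15, 0.85, n_line):
                seeds.append((1 - lam) * stable[i].state + lam * stable[j].state)
    found = []
    for s in seeds:
        fp = polish_fixed_point(cn, s)
        if fp is None:
            continue
        if any(np.max(np.abs(fp - a.state)) < cluster_tol for a in stable):
            continue
        found.append(fp)
    if not found:
        return []
    found = np.array(found)
    out = []
    for members in _cluster(found, cluster_tol):
        rep = found[members[0]]
        eig = np.linalg.eigvals(cn.jac(rep))
        if np.max(eig.real) <= 0:
            continue
        out.append(SteadyState(rep, eig, stable=False,
                               phenotype=classify_phenotype(rep, network=network),
                               residual=float(np.max(np.abs(cn.rhs(rep))))))
    out.sort(key=lambda s: int(np.sum(s.eigenvalues.real > 0)))
    return out


def derive_thresholds(network: RegulatoryNetwork, params: ParameterSet,
                      seed: int = 0, n_starts: int = 400) -> PhenotypeThresholds:
    """Derive phenotype cut points from the network's own attractor structure.

    p53 cuts: midpoints between the low/intermediate and intermediate/high
    attractor p53 levels in the tri-stable regime (a = 1).  ATM cut: the
    attractor ATM levels pooled over the tri-stable (a = 1) and aged
    (a = 1.5) regimes are bimodal; the cut sits at the midpoint of the
    largest gap.
    """
    marker = ("p53", "ATM")
    tri = find_attractors(network, params.with_(a=1.0), n_starts=n_starts,
                          seed=seed, distinct_by=marker)
    p53s = sorted(a.state[network.node_index("p53")] for a in tri if a.stable)
    if len(p53s) < 3:
        raise RuntimeError("expected a tri-stable regime at a=1 to derive p53 cuts")
    aged = find_attractors(network, params.with_(a=1.5), n_starts=n_starts,
                           seed=seed, distinct_by=marker)
    atms = np.sort([a.state[network.node_index("ATM")]
                    for a in tri + aged if a.stable])
    if atms.size < 2:
        raise RuntimeError("need at least two attractor ATM levels for the cut")
    gaps = np.diff(atms)
    g = int(np.argmax(gaps))
    return PhenotypeThresholds(
        p53_low=(p53s[0] + p53s[1]) / 2,
        p53_high=(p53s[1] + p53s[2]) / 2,
        atm=float((atms[g] + atms[g + 1]) / 2),
    )


def attractor_table(attractors: Sequence[SteadyState],
                    network: RegulatoryNetwork):
    """Tidy per-fixed-point summary (one row each) as a DataFrame."""
    import pandas as pd
    rows = []
    for a in attractors:
        row = {n: a.state[i] for i, n in enumerate(network.nodes)}
        row.update(stable=a.stable, spectral_abscissa=a.spectral_abscissa,
                   basin_fraction=a.basin_fraction, phenotype=a.phenotype,
                   residual=a.residual)
        rows.append(row)
    return pd.DataFrame(rows)
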