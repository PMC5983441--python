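"""Steady-state continuation, fold (saddle-node) detection, hysteresis, 2-D scans.

Branches are traced by natural-parameter predictor-corrector: step the free
parameter, Newton-correct the fixed point from the previous solution, and
treat corrector failure (or a jump to a distant solution) as the signature of
a fold, which is then bracketed by bisection in the parameter.  The free
parameter may be a kinetic constant (``a``, ``b``, ``S``) or a constant input
level (``GS``, ``Stress``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ParameterSet, RegulatoryNetwork, compile_network
from .attractors import polish_fixed_point, RESIDUAL_TOL
from .integrate import converge_to_steady_state

#: max-coordinate jump allowed between consecutive branch points before the
#: corrector is deemed to have left the branch
CONTINUITY_TOL = 0.25
#: width to which a fold bracket is bisected in the parameter; narrow enough
#: that the leading eigenvalue (~ sqrt of the distance to the fold) has
#: decayed below 1e-2 at the last accepted point
FOLD_BRACKET = 1e-5


def set_parameter(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a parameter set with the named kinetic constant or input set."""
    if name in ("a", "b", "S", "k"):
        return params.with_(**{name: value})
    if name in params.input_levels:
        return params.with_(input_levels={name: value})
    raise KeyError(f"unknown continuation parameter {name!r}")


@dataclass
class Branch:
    """An ordered steady-state branch in one parameter.

    ``folds`` lists the parameter values where the branch terminates in a
    saddle-node (bracketed to ~1e-4, reported at that midpoint).
    """

    param_name: str
    values: np.ndarray
    states: np.ndarray          # (len(values), n_nodes)
    stable: np.ndarray          # bool per point
    folds: list[float] = field(default_factory=list)
    nodes: tuple[str, ...] = ()

    def node(self, name: str) -> np.ndarray:
        return self.states[:, self.nodes.index(name)]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(self.nodes))
        df.insert(0, self.param_name, self.values)
        df["stable"] = self.stable
        return df


def _correct(network, params, param_name, value, x_from):
    cn = compile_network(network, set_parameter(params, param_name, value))
    fp = polish_fixed_point(cn, x_from)
    if fp is None or np.max(np.abs(fp - x_from)) > CONTINUITY_TOL:
        return None, cn
    return fp, cn


def continue_branch(network: RegulatoryNetwork, params: ParameterSet,
                    param_name: str, start_value: float, start_state,
                    direction: int, step: float = 0.01,
                    bounds: tuple[float, float] = (0.0, 3.0)) -> Branch:
    """Trace one branch from a fixed point until a fold or a parameter bound.

    Parameters
    ----------
    direction : +1 or -1
        Sense in which the parameter is stepped.
    step : float
        Natural-parameter step; on corrector failure the fold is bracketed by
        bisection to ~1e-4 regardless of ``step``.
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    x = np.asarray(start_state, dtype=float)
    cn0 = compile_network(network, set_parameter(params, param_name, start_value))
    x0 = polish_fixed_point(cn0, x)
    if x0 is None or np.max(np.abs(x0 - x)) > CONTINUITY_TOL:
        raise ValueError("start_state is not a fixed point at start_value")
    x = x0

    values, states, stables = [start_value], [x], [_is_stable(cn0, x)]
    p = start_value
    folds: list[float] = []
    while True:
        p_next = float(np.clip(p + direction * step, *bounds))
        if abs(p_next - p) < 1e-12:
            break
        fp, cn = _correct(network, params, param_name, p_next, x)
        if fp is not None:
            p, x = p_next, fp
            values.append(p)
            states.append(x)
            stables.append(_is_stable(cn, x))
            if abs(p - bounds[0]) < 1e-12 or abs(p - bounds[1]) < 1e-12:
                break
            continue
        # corrector lost the branch: bisect [p, p_next] for the fold
        lo, hi = p, p_next           # lo: branch exists, hi: it does not
        while abs(hi - lo) > FOLD_BRACKET:
            mid = 0.5 * (lo + hi)
            fp, cn = _correct(network, params, param_name, mid, x)
            if fp is not None:
                lo, x = mid, fp
                values.append(mid)
                states.append(x)
                stables.append(_is_stable(cn, x))
            else:
                hi = mid
        folds.append(0.5 * (lo + hi))
        break
    return Branch(param_name, np.array(values), np.array(states),
                  np.array(stables), folds, network.nodes)


def _is_stable(cn, x) -> bool:
    return bool(np.max(np.linalg.eigvals(cn.jac(x)).real) < 0)


def hysteresis_sweep(network: RegulatoryNetwork, params: ParameterSet,
                     param_name: str, values_up, values_down,
                     x0=None) -> tuple[Branch, Branch]:
    """Quasi-static up and down sweeps of one parameter.

    At each parameter value the system is relaxed to rest starting from the
    previous value's endpoint, so the attained state exhibits the hysteresis
    of the underlying fold structure.  The up sweep starts from ``x0``
    (default: the all-zero state) relaxed at the first up value; the down
    sweep starts from the up sweep's final state.
    """
    values_up = np.asarray(values_up, dtype=float)
    values_down = np.asarray(values_down, dtype=float)
    if np.any(np.diff(values_up) <= 0) or np.any(np.diff(values_down) >= 0):
        raise ValueError("values_up must increase and values_down decrease")

    def sweep(values, x_start):
        x = np.asarray(x_start, dtype=float)
        states, stables = [], []
        for v in values:
            pset = set_parameter(params, param_name, v)
            x, _, _ = converge_to_steady_state(network, pset, x)
            states.append(x)
            stables.append(True)
        return Branch(param_name, values.copy(), np.array(states),
                      np.array(stables), [], network.nodes)

    if x0 is None:
        x0 = np.zeros(network.n_nodes)
    up = sweep(values_up, x0)
    down = sweep(values_down, up.states[-1])
    return up, down


@dataclass
class RegionMap:
    """Stable-steady-state counts over an (a, b) parameter grid."""

    a_values: np.ndarray
    b_values: np.ndarray
    counts: np.ndarray          # (len(a_values), len(b_values))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.counts, index=self.a_values, columns=self.b_values)


def scan_two_parameters(network: RegulatoryNetwork, params: ParameterSet,
                        a_values, b_values, n_starts: int = 200,
                        seed: int = 0,
                        distinct_by: tuple[str, ...] | None = ("p53", "ATM")
                        ) -> RegionMap:
    """Count stable cell fates on each cell of an (a, b) grid by multistart.

    All cells share the same seed schedule so the map is reproducible and
    differences between cells reflect the dynamics, not the sampling.  By
    default states are counted as distinct fates on the (p53, ATM) marker
    plane — the projection in which the stability regions are drawn; pass
    ``distinct_by=None`` to count full-state fixed points instead.
    """
    from .attractors import find_attractors
    a_values = np.asarray(a_values, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if a_values.size == 0 or b_values.size == 0:
        raise ValueError("parameter grids must be non-empty")
    counts = np.zeros((a_values.size, b_values.size), dtype=int)
    for i, av in enumerate(a_values):
        for j, bv in enumerate(b_values):
            att = find_attractors(network, params.with_(a=float(av), b=float(bv)),
                                  n_starts=n_starts, seed=seed,
                                  distinct_by=distinct_by)
            counts[i, j] = sum(1 for s in att if s.stable)
    return RegionMap(a_values, b_values, counts)


def cell_cycle_bifurcation(network: RegulatoryNetwork, params: ParameterSet,
                           readout: str = "E2F",
                           gs_range: tuple[float, float] = (0.0, 1.0),
                           step: float = 0.005) -> dict[str, Branch]:
    """Continuation in the growth-signal input; the Rb-E2F restriction point.

    Mirrors the physical hysteresis protocol: the off branch is continued
    upward from ``gs_range[0]`` until it folds (the activation threshold);
    the system is then allowed to jump just past the fold, and the resulting
    committed branch is continued back downward until its own fold (the
    lower, commitment-locking threshold) or the range boundary.  When the up
    branch never folds the down branch starts from the upper range end.
    ``readout`` must name a network node (callers extract e.g. the E2F or
    CycD coordinate from the returned branches).
    """
    if readout not in network.nodes:
        raise KeyError(f"{readout!r} is not a node of this network")
    if "GS" not in params.input_levels:
        raise KeyError("network has no GS input level configured")
    lo, hi = gs_range

    x_lo, conv, _ = converge_to_steady_state(
        network, set_parameter(params, "GS", lo), np.zeros(network.n_nodes))
    if not conv:
        raise RuntimeError("no steady state found at the low end of the GS range")
    up = continue_branch(network, params, "GS", lo, x_lo, +1, step=step,
                         bounds=gs_range)

    gs_restart = min(up.folds[0] + 2 * step, hi) if up.folds else hi
    x_hi, conv, _ = converge_to_steady_state(
        network, set_parameter(params, "GS", gs_restart), up.states[-1])
    if not conv:
        raise RuntimeError("no steady state past the activation fold")
    down = continue_branch(network, params, "GS", gs_restart, x_hi, -1,
                           step=step, bounds=gs_range)
    return {"up": up, "down": down}
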