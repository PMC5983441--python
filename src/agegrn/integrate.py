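"""Deterministic ODE integration, convergence detection, initial-condition sampling.

Single trajectories use a stiff-capable `scipy.integrate.solve_ivp` call at
tight tolerances.  Monte Carlo work (attractor multistart, landscape
estimation) integrates whole ensembles at once: m trajectories are stacked
into one flat state vector so the vectorised right-hand side amortises the
Python overhead across the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp

from .model import CompiledNetwork, ParameterSet, RegulatoryNetwork, compile_network

RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10
#: negative excursions smaller than this are solver round-off and clipped
NEG_CLIP = 1e-9


@dataclass
class Trajectory:
    """One time course: times (hours), states matrix, run metadata."""

    times: np.ndarray
    states: np.ndarray          # (len(times), n_nodes)
    nodes: tuple[str, ...]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states rows must align with times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def node(self, name: str) -> np.ndarray:
        return self.states[:, self.nodes.index(name)]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(self.nodes))
        df.insert(0, "time", self.times)
        return df


def _clip_states(y: np.ndarray) -> np.ndarray:
    low = y.min()
    if low < -NEG_CLIP:
        raise RuntimeError(f"state went negative ({low:.3g}); solver tolerance too loose")
    return np.clip(y, 0.0, None)


def simulate(network: RegulatoryNetwork, params: ParameterSet, x0,
             t_end: float, n_out: int = 201,
             rtol: float = RTOL_DEFAULT, atol: float = ATOL_DEFAULT,
             compiled: CompiledNetwork | None = None) -> Trajectory:
    """Integrate one initial condition over [0, t_end], sampled at n_out times."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    cn = compiled or compile_network(network, params)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (network.n_nodes,):
        raise ValueError(f"x0 must have shape ({network.n_nodes},)")
    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(lambda t, y: cn.rhs(y), (0.0, t_end), x0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol,
                    jac=lambda t, y: cn.jac(y))
    if not sol.success:
        raise RuntimeError(f"ODE solver failed at t={sol.t[-1]:.4g}: {sol.message}")
    states = _clip_states(sol.y.T)
    meta = {"params": params.to_dict(), "x0": x0.tolist(), "t_end": t_end,
            "rtol": rtol, "atol": atol}
    return Trajectory(sol.t, states, network.nodes, meta)


def simulate_ensemble(network: RegulatoryNetwork, params: ParameterSet,
                      X0: np.ndarray, t_end: float, n_out: int,
                      rtol: float = 1e-6, atol: float = 1e-9,
                      compiled: CompiledNetwork | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Integrate m initial conditions jointly; returns (times, states).

    ``states`` has shape (m, n_out, n_nodes).  All trajectories share the
    adaptive step of one explicit Runge-Kutta solve, with the error measured
    over the whole stacked state; tolerances default looser than
    :func:`simulate` because the ensemble feeds Monte Carlo statistics, not
    pointwise results.
    """
    cn = compiled or compile_network(network, params)
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    m, N = X0.shape
    if N != network.n_nodes:
        raise ValueError("ensemble width must equal node count")

    def flat_rhs(t, y):
        return cn.rhs(y.reshape(m, N)).ravel()

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(flat_rhs, (0.0, t_end), X0.ravel(), method="RK45",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ensemble solver failed at t={sol.t[-1]:.4g}: {sol.message}")
    states = _clip_states(sol.y.T.reshape(n_out, m, N).transpose(1, 0, 2))
    return t_eval, states


def sample_initial_conditions(network: RegulatoryNetwork, n_samples: int,
                              x_max: float = 3.0, seed: int | None = None) -> np.ndarray:
    """Draw n_samples states, each coordinate uniform on [0, x_max]."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if x_max <= 0:
        raise ValueError("x_max must be > 0")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, x_max, size=(n_samples, network.n_nodes))


def converge_to_steady_state(network: RegulatoryNetwork, params: ParameterSet, x0,
                             t_block: float = 50.0, tol: float = 1e-8,
                             t_max: float = 2000.0,
                             compiled: CompiledNetwork | None = None
                             ) -> tuple[np.ndarray, bool, float]:
    """Integrate in blocks until max |dx/dt| < tol; never raises on slow runs.

    Returns (endpoint, converged flag, elapsed simulated hours).  Convergence
    is measured on the derivative norm, which is independent of the solver's
    internal step size.
    """
    if t_block <= 0 or tol <= 0 or t_max < t_block:
        raise ValueError("need t_block > 0, tol > 0, t_max >= t_block")
    cn = compiled or compile_network(network, params)
    x = np.asarray(x0, dtype=float).copy()
    elapsed = 0.0
    if np.max(np.abs(cn.rhs(x))) < tol:
        return x, True, 0.0
    while elapsed < t_max:
        sol = solve_ivp(lambda t, y: cn.rhs(y), (0.0, t_block), x, method="LSODA",
                        rtol=RTOL_DEFAULT, atol=ATOL_DEFAULT,
                        jac=lambda t, y: cn.jac(y))
        if not sol.success:
            raise RuntimeError(f"solver failed at t={elapsed + sol.t[-1]:.4g}")
        x = _clip_states(sol.y[:, -1])
        elapsed += t_block
        if np.max(np.abs(cn.rhs(x))) < tol:
            return x, True, elapsed
    return x, False, elapsed


def time_to_attractor(times: np.ndarray, states: np.ndarray, target,
                      rtol: float = 0.01) -> np.ndarray:
    """First sampled time each trajectory enters (and stays in) a target ball.

    The ball is ``||x - target||_inf <= rtol * ||target||_inf``: "within 1%"
    is measured against the attractor's overall scale, so near-zero
    coordinates do not demand absolute accuracies far below the landscape of
    interest.  ``states`` has shape (m, n_times, n_nodes).  Returns one time
    per trajectory, NaN where the trajectory never settles into the ball by
    the final sample.
    """
    target = np.asarray(target, dtype=float)
    radius = rtol * np.max(np.abs(target))
    inside = np.max(np.abs(states - target), axis=2) <= radius   # (m, n_times)
    # last exit: first index after which the trajectory stays inside
    outside_rev = ~inside[:, ::-1]
    n_t = times.size
    stays_from = n_t - np.argmax(outside_rev, axis=1)  # index of first always-in
    stays_from = np.where(outside_rev.any(axis=1), stays_from, 0)
    out = np.full(states.shape[0], np.nan)
    ok = (stays_from < n_t) & inside[:, -1]
    out[ok] = times[stays_from[ok]]
    return out


def converge_ensemble(cn: CompiledNetwork, X0: np.ndarray,
                      t_block: float = 50.0, tol: float = 1e-8,
                      t_max: float = 2000.0) -> tuple[np.ndarray, np.ndarray]:
    """Block-integrate an ensemble until each trajectory's |dx/dt| drops below tol.

    Returns (endpoints, converged mask).  Trajectories already at rest keep
    being integrated with the rest of the ensemble — they no longer move, so
    this costs little and keeps the implementation branch-free.
    """
    X = np.atleast_2d(np.asarray(X0, dtype=float)).copy()
    m, N = X.shape
    elapsed = 0.0
    done = np.max(np.abs(cn.rhs(X)), axis=1) < tol
    while elapsed < t_max and not done.all():
        def flat_rhs(t, y):
            return cn.rhs(y.reshape(m, N)).ravel()
        sol = solve_ivp(flat_rhs, (0.0, t_block), X.ravel(), method="RK45",
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError("ensemble solver failed during convergence blocks")
        X = _clip_states(sol.y[:, -1].reshape(m, N))
        elapsed += t_block
        done = np.max(np.abs(cn.rhs(X)), axis=1) < tol
    return X, done
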