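"""Signed regulatory networks and their Hill-kinetics ODE right-hand sides.

Every species obeys

    dx_i/dt = a * sum_act x_s^n/(S^n + x_s^n)
            + b * sum_inh S^n/(S^n + x_s^n)
            - k_i * x_i

where the first sum runs over the activators of node i, the second over its
inhibitors, and sources may be network nodes or constant external inputs.
``a`` scales all activation terms (interpreted as accumulated DNA damage in
the ageing model), ``b`` all inhibition terms, and ``k`` is the linear
degradation rate.  A :class:`RegulatoryNetwork` is purely structural;
:func:`compile_network` turns it into fast vectorised callables for the
right-hand side and its analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

ACTIVATION = "activation"
INHIBITION = "inhibition"

#: canonical node order of the ageing network (equation order)
AGEING_NODES = (
    "p53", "Mdm2", "Wip1", "ATM", "p21", "PTEN", "AKT",
    "Myc", "E2F", "RB", "CycE", "CycD", "ARF",
)

#: the p53-inactivating perturbation: remove activation of p53 by ATM and ARF
P53_INACTIVATION_EDGES = (("ATM", "p53", ACTIVATION), ("ARF", "p53", ACTIVATION))


class Edge(NamedTuple):
    """A signed directed interaction. ``source`` may be a node or an input."""

    source: str
    target: str
    sign: str


def hill_activation(x, S: float, n: float):
    """Sigmoidal activation fraction x^n / (S^n + x^n), in [0, 1).

    Parameters
    ----------
    x : float or ndarray
        Non-negative concentration of the activating species.
    S : float
        Half-saturation threshold (> 0).
    n : int
        Hill coefficient (>= 1); cooperativity of the binding.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    if S <= 0:
        raise ValueError("Hill threshold S must be positive")
    if n < 1:
        raise ValueError("Hill coefficient n must be >= 1")
    xn = x ** n
    return xn / (S ** n + xn)


def hill_inhibition(x, S: float, n: float):
    """Sigmoidal inhibition fraction S^n / (S^n + x^n), in (0, 1].

    Complement of :func:`hill_activation`: the two sum to one for the same
    (x, S, n).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    if S <= 0:
        raise ValueError("Hill threshold S must be positive")
    if n < 1:
        raise ValueError("Hill coefficient n must be >= 1")
    Sn = S ** n
    return Sn / (Sn + x ** n)


@dataclass(frozen=True)
class ParameterSet:
    """Global kinetic constants of the Hill-kinetics model.

    Attributes
    ----------
    S : float
        Hill threshold, shared by all regulatory terms (default 0.5).
    n : int
        Hill coefficient (default 4, tetramer-binding cooperativity).
    k : float or mapping
        Linear degradation rate per hour; a scalar applied to every node
        (default 1) or a per-node mapping.
    a : float
        Activation rate scaling every activation term (default 1).
    b : float
        Inhibition rate scaling every inhibition term (default 0.05).
    input_levels : mapping
        Constant levels of the external inputs; defaults Stress = 0.3,
        GS (growth signal) = 0.2.
    """

    S: float = 0.5
    n: int = 4
    k: float | Mapping[str, float] = 1.0
    a: float = 1.0
    b: float = 0.05
    input_levels: Mapping[str, float] = field(
        default_factory=lambda: {"Stress": 0.3, "GS": 0.2}
    )

    def __post_init__(self):
        if self.S <= 0:
            raise ValueError("S must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.a < 0 or self.b < 0:
            raise ValueError("a and b must be >= 0")
        ks = self.k.values() if isinstance(self.k, Mapping) else [self.k]
        if any(k <= 0 for k in ks):
            raise ValueError("all degradation rates k must be > 0")
        if any(v < 0 for v in self.input_levels.values()):
            raise ValueError("input levels must be >= 0")

    def with_(self, **kwargs) -> "ParameterSet":
        """Copy with selected fields replaced (``input_levels`` merged)."""
        if "input_levels" in kwargs:
            merged = dict(self.input_levels)
            merged.update(kwargs["input_levels"])
            kwargs["input_levels"] = merged
        return replace(self, **kwargs)

    def k_vector(self, nodes: Sequence[str]) -> np.ndarray:
        if isinstance(self.k, Mapping):
            missing = [nd for nd in nodes if nd not in self.k]
            if missing:
                raise KeyError(f"no degradation rate for node(s) {missing}")
            return np.array([float(self.k[nd]) for nd in nodes])
        return np.full(len(nodes), float(self.k))

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "n": self.n,
            "k": dict(self.k) if isinstance(self.k, Mapping) else self.k,
            "a": self.a,
            "b": self.b,
            "input_levels": dict(self.input_levels),
        }


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Nodes, signed edges, and constant-input names of a regulatory network.

    Inputs are pseudo-nodes with externally fixed levels: they may appear as
    edge sources but are never integrated and never targeted.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    inputs: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(Edge(*e) for e in self.edges))
        object.__setattr__(self, "inputs", tuple(self.inputs))
        node_set, input_set = set(self.nodes), set(self.inputs)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        if node_set & input_set:
            raise ValueError("a name cannot be both node and input")
        seen = set()
        for e in self.edges:
            if e.sign not in (ACTIVATION, INHIBITION):
                raise ValueError(f"bad edge sign {e.sign!r}")
            if e.source not in node_set and e.source not in input_set:
                raise ValueError(f"unknown edge source {e.source!r}")
            if e.target not in node_set:
                raise ValueError(f"edge target {e.target!r} is not a node")
            if e in seen:
                raise ValueError(f"duplicate edge {e}")
            seen.add(e)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, name: str) -> int:
        try:
            return self.nodes.index(name)
        except ValueError:
            raise KeyError(f"{name!r} is not a node of this network") from None

    def regulators(self, target: str, sign: str) -> list[str]:
        return [e.source for e in self.edges if e.target == target and e.sign == sign]


def build_ageing_network() -> RegulatoryNetwork:
    """The canonical 13-node / 32-edge ageing network.

    Couples the p53 DNA-damage response module (Stress -> ATM -> p53 with the
    Mdm2 and Wip1 negative feedbacks, PTEN/AKT/p21 effectors) to the Rb-E2F
    cell-cycle entry switch (GS -> Myc/CycD, E2F self-activation), linked
    through ARF and p21.  Input edges Stress->ATM, GS->Myc and GS->CycD count
    toward the 32 interactions.
    """
    A, I = ACTIVATION, INHIBITION
    edges = [
        # p53: activated by ARF, itself, ATM; inhibited by Mdm2, Wip1
        ("ARF", "p53", A), ("p53", "p53", A), ("ATM", "p53", A),
        ("Mdm2", "p53", I), ("Wip1", "p53", I),
        # Mdm2: activated by p53, AKT, Wip1; inhibited by ATM, ARF
        ("p53", "Mdm2", A), ("AKT", "Mdm2", A), ("Wip1", "Mdm2", A),
        ("ATM", "Mdm2", I), ("ARF", "Mdm2", I),
        ("p53", "Wip1", A),
        # ATM: self-activating, driven by Stress, dephosphorylated by Wip1
        ("ATM", "ATM", A), ("Stress", "ATM", A), ("Wip1", "ATM", I),
        ("p53", "p21", A), ("AKT", "p21", I),
        ("p53", "PTEN", A),
        ("PTEN", "AKT", I),
        ("GS", "Myc", A),
        # E2F: self-activation and Myc drive; p21 and RB repress
        ("E2F", "E2F", A), ("Myc", "E2F", A), ("p21", "E2F", I), ("RB", "E2F", I),
        ("p21", "RB", A), ("CycD", "RB", I), ("CycE", "RB", I),
        ("E2F", "CycE", A), ("p21", "CycE", I),
        ("Myc", "CycD", A), ("GS", "CycD", A), ("p21", "CycD", I),
        ("Myc", "ARF", A),
    ]
    return RegulatoryNetwork(nodes=AGEING_NODES, edges=tuple(Edge(*e) for e in edges),
                             inputs=("Stress", "GS"))


def delete_edges(network: RegulatoryNetwork,
                 edges: Iterable[tuple[str, str, str]]) -> RegulatoryNetwork:
    """Return a copy of ``network`` without the listed edges.

    Raises ``KeyError`` naming the first listed edge that is not present.
    """
    remaining = list(network.edges)
    for e in edges:
        e = Edge(*e)
        if e not in remaining:
            raise KeyError(f"edge {e.source}->{e.target} ({e.sign}) not in network")
        remaining.remove(e)
    return RegulatoryNetwork(network.nodes, tuple(remaining), network.inputs)


@dataclass(frozen=True)
class CompiledNetwork:
    """Index arrays turning a network + parameters into vectorised kinetics.

    ``rhs(x)`` accepts a state of shape (n_nodes,) or an ensemble of shape
    (m, n_nodes) and returns derivatives of the same shape; ``jac(x)`` returns
    the analytic (n_nodes, n_nodes) Jacobian of a single state.
    """

    network: RegulatoryNetwork
    params: ParameterSet
    act_src: np.ndarray      # source index into extended state, per activation edge
    act_mat: np.ndarray      # (n_act_edges, n_nodes) incidence
    inh_src: np.ndarray
    inh_mat: np.ndarray
    input_vec: np.ndarray    # constant input levels, extended-state tail
    k_vec: np.ndarray

    def extended(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return np.concatenate([x, self.input_vec])
        tail = np.broadcast_to(self.input_vec, (x.shape[0], self.input_vec.size))
        return np.hstack([x, tail])

    def rhs(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        ext = self.extended(x)
        Sn = p.S ** p.n
        prod = np.zeros(np.shape(x), dtype=float)
        if self.act_src.size:
            xs = ext[..., self.act_src]
            xn = xs ** p.n
            prod += p.a * ((xn / (Sn + xn)) @ self.act_mat)
        if self.inh_src.size:
            xn = ext[..., self.inh_src] ** p.n
            prod += p.b * ((Sn / (Sn + xn)) @ self.inh_mat)
        return prod - self.k_vec * np.asarray(x, dtype=float)

    def jac(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        x = np.asarray(x, dtype=float)
        N = self.network.n_nodes
        Sn = p.S ** p.n
        J = np.zeros((N, N))
        # d/dx [x^n/(S^n+x^n)] = -d/dx [S^n/(S^n+x^n)] = n S^n x^(n-1)/(S^n+x^n)^2
        def dhill(xs):
            return p.n * Sn * xs ** (p.n - 1) / (Sn + xs ** p.n) ** 2

        for src, mat, coeff in ((self.act_src, self.act_mat, p.a),
                                (self.inh_src, self.inh_mat, -p.b)):
            for e, s in enumerate(src):
                if s >= N:      # constant input: no state dependence
                    continue
                tgt = np.nonzero(mat[e])[0][0]
                J[tgt, s] += coeff * dhill(x[s])
        J[np.diag_indices(N)] -= self.k_vec
        return J


def compile_network(network: RegulatoryNetwork, params: ParameterSet) -> CompiledNetwork:
    """Build the edge-grouped vectorised evaluator for ``network``."""
    missing = [i for i in network.inputs if i not in params.input_levels]
    if missing:
        raise KeyError(f"no level configured for input(s) {missing}")
    N = network.n_nodes
    ext_index = {name: i for i, name in enumerate(network.nodes)}
    ext_index.update({name: N + j for j, name in enumerate(network.inputs)})

    def arrays(sign):
        sel = [e for e in network.edges if e.sign == sign]
        src = np.array([ext_index[e.source] for e in sel], dtype=int)
        mat = np.zeros((len(sel), N))
        for row, e in enumerate(sel):
            mat[row, ext_index[e.target]] = 1.0
        return src, mat

    act_src, act_mat = arrays(ACTIVATION)
    inh_src, inh_mat = arrays(INHIBITION)
    input_vec = np.array([float(params.input_levels[i]) for i in network.inputs])
    return CompiledNetwork(network, params, act_src, act_mat, inh_src, inh_mat,
                           input_vec, params.k_vector(network.nodes))


# ---------------------------------------------------------------------------
# file formats

def write_network(network: RegulatoryNetwork, path: str | Path) -> None:
    """Write the edge list as a 3-column TSV (source, target, sign)."""
    lines = ["source\ttarget\tsign"]
    lines += [f"{e.source}\t{e.target}\t{e.sign}" for e in network.edges]
    lines.append(f"# inputs: {','.join(network.inputs)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read a network written by :func:`write_network` (lossless round-trip)."""
    edges, inputs = [], ()
    lines = Path(path).read_text().splitlines()
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("# inputs:"):
            declared = line.split(":", 1)[1].strip()
            inputs = tuple(s.strip() for s in declared.split(",") if s.strip())
            continue
        if line.startswith("source"):
            continue
        src, tgt, sign = line.split("\t")
        edges.append(Edge(src, tgt, sign))
    targets = [e.target for e in edges]
    node_names = list(dict.fromkeys(
        targets + [e.source for e in edges if e.source not in inputs]))
    # preserve canonical order when the file is the built-in network
    if set(node_names) == set(AGEING_NODES):
        node_names = list(AGEING_NODES)
    return RegulatoryNetwork(tuple(node_names), tuple(edges), inputs)
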