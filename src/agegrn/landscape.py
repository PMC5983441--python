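"""Monte Carlo quasi-potential landscapes U = -ln P over a 2-D projection.

Many trajectories from uniform random initial states are projected onto two
chosen species (default p53 and ATM) and binned on a regular grid; the visit
probability P per box — transients and equilibrium dwell alike — defines the
quasi-potential U = -ln P.  Attractors appear as deep valleys because
trajectories spend most of their time at rest; saddle corridors appear as
shallow ridges traced by the connecting unstable manifolds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .model import ParameterSet, RegulatoryNetwork, compile_network
from .integrate import sample_initial_conditions, simulate_ensemble, simulate
from .attractors import SteadyState, PhenotypeThresholds, classify_phenotype

#: trajectories integrated per ensemble batch (bounds peak memory)
BATCH_SIZE = 2000


@dataclass
class LandscapeGrid:
    """2-D visit histogram with probability P and potential U per box.

    Boxes never visited carry the capped potential ``u_cap`` (one above the
    largest finite U) and are flagged in ``empty``.
    """

    coords: tuple[str, str]
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)
    P: np.ndarray = field(init=False)
    U: np.ndarray = field(init=False)
    empty: np.ndarray = field(init=False)
    u_cap: float = field(init=False)

    def __post_init__(self):
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("landscape grid has no samples")
        self.P = self.counts / total
        self.empty = self.counts == 0
        with np.errstate(divide="ignore"):
            U = -np.log(self.P)
        self.u_cap = float(U[~self.empty].max()) + 1.0
        U[self.empty] = self.u_cap
        self.U = U

    def box_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
                0.5 * (self.y_edges[:-1] + self.y_edges[1:]))

    def box_width(self) -> tuple[float, float]:
        return (float(self.x_edges[1] - self.x_edges[0]),
                float(self.y_edges[1] - self.y_edges[0]))


def estimate_landscape(network: RegulatoryNetwork, params: ParameterSet,
                       coords: tuple[str, str] = ("p53", "ATM"),
                       n_traj: int = 100_000, t_end: float = 50.0,
                       n_samples_per_traj: int = 500,
                       grid_boxes: int = 100, x_max: float = 3.0,
                       axis_max: float | None = None,
                       seed: int = 0) -> LandscapeGrid:
    """Estimate the quasi-potential over ``coords`` from seeded Monte Carlo runs.

    Every sampled time point of every trajectory (``n_samples_per_traj``
    evenly spaced points over ``[0, t_end]``) contributes one count; the long
    dwell at attractors relative to transients is what carves the valleys.
    Trajectories are integrated in fixed-size batches with a per-batch seed
    derived by counter from ``seed``, so results are reproducible and
    independent of the batch size.
    """
    ci, cj = (network.node_index(c) for c in coords)
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    axis_max = x_max if axis_max is None else axis_max
    edges = np.linspace(0.0, axis_max, grid_boxes + 1)
    counts = np.zeros((grid_boxes, grid_boxes))
    cn = compile_network(network, params)
    seed_seq = np.random.SeedSequence(seed)
    done = 0
    batch_id = 0
    while done < n_traj:
        m = min(BATCH_SIZE, n_traj - done)
        batch_seed = np.random.SeedSequence(entropy=seed_seq.entropy,
                                            spawn_key=(batch_id,))
        rng = np.random.default_rng(batch_seed)
        X0 = rng.uniform(0.0, x_max, size=(m, network.n_nodes))
        _, states = simulate_ensemble(network, params, X0, t_end,
                                      n_samples_per_traj, compiled=cn)
        h, _, _ = np.histogram2d(states[:, :, ci].ravel(),
                                 states[:, :, cj].ravel(),
                                 bins=(edges, edges))
        counts += h
        done += m
        batch_id += 1
    meta = {"coords": list(coords), "n_traj": n_traj, "t_end": t_end,
            "n_samples_per_traj": n_samples_per_traj, "grid_boxes": grid_boxes,
            "x_max": x_max, "axis_max": axis_max, "seed": seed,
            "params": params.to_dict()}
    return LandscapeGrid(tuple(coords), edges, edges, counts, meta)


def locate_basins(grid: LandscapeGrid, min_separation: int = 5,
                  min_persistence: float = 1.0,
                  smooth: int = 1,
                  min_prob: float = 2e-5) -> list[tuple[float, float, float]]:
    """Basin bottoms of U: persistent local minima, merged and sorted by depth.

    The raw histogram is first smoothed with a (2*smooth+1)-box mean filter:
    a genuine valley — an attractor, or the slow remnant of a just-vanished
    fixed point — concentrates orders of magnitude more visit probability
    than its surroundings and survives smoothing, whereas one-count Monte
    Carlo speckle in thinly visited transient regions is flattened away.
    Minima of the smoothed potential are then pruned by topological
    persistence (sublevel-set flooding with a union-find): when the rising
    flood joins a shallower minimum to a deeper one, the shallower survives
    only if the ridge between them stands at least ``min_persistence`` above
    its floor.  In -ln P units a persistence of 1 means the basin floor is
    e-fold more probable than its escape ridge.  Never-visited boxes flood at
    a common cap level so no region is artificially walled off.  Each
    surviving minimum is snapped to the raw-potential floor box inside its
    smoothing window and must hold a raw visit probability of at least
    ``min_prob`` there — a floor that is independent of the trajectory count,
    since the binned density, not the counts, is what converges.  Surviving
    minima closer than ``min_separation`` boxes (Chebyshev) are merged,
    keeping the deeper.  Returns (coord1, coord2, U) per basin with the raw
    (unsmoothed) potential at the floor box, deepest first.
    """
    from scipy.ndimage import uniform_filter

    nx, ny = grid.counts.shape
    if smooth > 0:
        csm = uniform_filter(grid.counts.astype(float),
                             size=2 * smooth + 1, mode="constant")
        csm = np.clip(csm, 0.0, None)
    else:
        csm = grid.counts.astype(float)
    psm = csm / csm.sum()
    visited = psm > 0
    with np.errstate(divide="ignore"):
        U = -np.log(psm)
    u_cap = float(U[visited].max()) + 1.0 if visited.any() else 1.0
    U[~visited] = u_cap

    order = np.argsort(U, axis=None, kind="stable")
    label = np.full(nx * ny, -1, dtype=int)       # minimum id per flooded box
    parent: list[int] = []                        # union-find over minima
    min_u: list[float] = []                       # birth level per minimum
    min_box: list[tuple[int, int]] = []
    alive: list[bool] = []

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for flat in order:
        i, j = divmod(int(flat), ny)
        u = U[i, j]
        neighbour_roots = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ii, jj = i + di, j + dj
                if 0 <= ii < nx and 0 <= jj < ny and label[ii * ny + jj] >= 0:
                    neighbour_roots.add(find(label[ii * ny + jj]))
        if not neighbour_roots:
            label[flat] = len(parent)
            parent.append(len(parent))
            min_u.append(float(u))
            min_box.append((i, j))
            alive.append(True)
            continue
        deepest = min(neighbour_roots, key=lambda r: min_u[r])
        label[flat] = deepest
        for r in neighbour_roots - {deepest}:
            # ridge at level u joins minimum r into the deeper basin
            if u - min_u[r] < min_persistence:
                alive[r] = False
            parent[r] = deepest

    kept_idx = [r for r in range(len(parent))
                if alive[r] and min_u[r] <= u_cap - min_persistence]
    kept_idx.sort(key=lambda r: min_u[r])
    kept: list[tuple[int, int]] = []
    w = max(smooth, 1)
    for r in kept_idx:
        i, j = min_box[r]
        # snap to the raw floor inside the smoothing window
        i0, i1 = max(i - w, 0), min(i + w + 1, nx)
        j0, j1 = max(j - w, 0), min(j + w + 1, ny)
        sub = grid.U[i0:i1, j0:j1]
        di, dj = np.unravel_index(np.argmin(sub), sub.shape)
        i, j = i0 + int(di), j0 + int(dj)
        if grid.P[i, j] < min_prob:
            continue
        if all(max(abs(i - ii), abs(j - jj)) >= min_separation for ii, jj in kept):
            kept.append((i, j))
    kept.sort(key=lambda b: grid.U[b[0], b[1]])
    cx, cy = grid.box_centers()
    return [(float(cx[i]), float(cy[j]), float(grid.U[i, j])) for i, j in kept]


def basin_depth_rank(grid: LandscapeGrid,
                     minima: Sequence[tuple[float, float, float]],
                     thresholds: PhenotypeThresholds | None = None,
                     attractors: Sequence[SteadyState] | None = None,
                     network: RegulatoryNetwork | None = None
                     ) -> list[tuple[str, float, float, float]]:
    """Order basins by depth and attach phenotype labels.

    When ``attractors`` (with ``network``) are given, each minimum inherits
    the phenotype of the nearest attractor in the projected plane; otherwise
    the grid coordinates must be (p53, ATM) and the box-centre values are
    classified directly.  Returns (phenotype, coord1, coord2, U), deepest
    first.
    """
    if not minima:
        raise ValueError("need at least one basin minimum")
    out = []
    for (c1, c2, u) in sorted(minima, key=lambda t: t[2]):
        if attractors is not None and network is not None:
            ii, jj = network.node_index(grid.coords[0]), network.node_index(grid.coords[1])
            stable = [a for a in attractors if a.stable]
            d = [np.hypot(a.state[ii] - c1, a.state[jj] - c2) for a in stable]
            label = stable[int(np.argmin(d))].phenotype
        else:
            if tuple(grid.coords) != ("p53", "ATM"):
                raise ValueError("direct classification needs (p53, ATM) coordinates")
            label = classify_phenotype(None, thresholds, p53=c1, atm=c2)
        out.append((label, c1, c2, u))
    return out


def saddle_path(network: RegulatoryNetwork, params: ParameterSet,
                saddle: SteadyState | np.ndarray,
                coords: tuple[str, str] = ("p53", "ATM"),
                eps: float = 1e-4, t_end: float = 200.0,
                n_out: int = 2001) -> tuple[np.ndarray, np.ndarray]:
    """The two unstable-manifold halves of an index-1 saddle, projected.

    Integrates forward from ``saddle ± eps * v`` where v is the unstable
    eigenvector; each half is a heteroclinic curve terminating at an
    attractor.  Returns two (n_out, 2) arrays of projected points.
    Raises when the fixed point does not have exactly one unstable direction.
    """
    cn = compile_network(network, params)
    x_s = saddle.state if isinstance(saddle, SteadyState) else np.asarray(saddle, float)
    eigval, eigvec = np.linalg.eig(cn.jac(x_s))
    unstable = np.nonzero(eigval.real > 0)[0]
    if unstable.size != 1:
        raise ValueError(
            f"saddle has {unstable.size} unstable directions; need exactly 1")
    v = eigvec[:, unstable[0]].real
    v = v / np.linalg.norm(v)
    ci, cj = (network.node_index(c) for c in coords)
    curves = []
    for sgn in (+1.0, -1.0):
        x0 = np.clip(x_s + sgn * eps * v, 0.0, None)
        traj = simulate(network, params, x0, t_end, n_out=n_out, compiled=cn)
        curves.append(np.column_stack([traj.states[:, ci], traj.states[:, cj]]))
    return curves[0], curves[1]


# ---------------------------------------------------------------------------
# output

def write_landscape(grid: LandscapeGrid, outdir) -> None:
    """Plain-text matrices (counts, P, U) plus a JSON metadata sidecar."""
    import json
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "counts.txt", grid.counts, fmt="%d")
    np.savetxt(outdir / "P.txt", grid.P)
    np.savetxt(outdir / "U.txt", grid.U)
    meta = dict(grid.metadata)
    meta["u_cap"] = grid.u_cap
    (outdir / "landscape.json").write_text(json.dumps(meta, indent=2))


def plot_landscape(grid: LandscapeGrid, path, view: str = "surface") -> None:
    """3-D surface or top view of U with attractor valleys in blue."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    cx, cy = grid.box_centers()
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    if view == "surface":
        fig = plt.figure(figsize=(7, 5))
        ax = fig.add_subplot(projection="3d")
        ax.plot_surface(X, Y, grid.U, cmap="jet_r", linewidth=0)
        ax.set_zlabel("U")
    else:
        fig, ax = plt.subplots(figsize=(6, 5))
        pc = ax.pcolormesh(grid.x_edges, grid.y_edges, grid.U.T, cmap="jet_r")
        fig.colorbar(pc, ax=ax, label="U")
    ax.set_xlabel(grid.coords[0])
    ax.set_ylabel(grid.coords[1])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
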