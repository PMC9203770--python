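"""The Landscape-Transport-Population (LTP) reinforcement core.

Two coupled discrete-time maps on a transport graph with fixed effective
distances r_ij.  Connectivity w_ij (symmetric, per edge) evolves by
mass-action reinforcement offset by a distance-deterrence decay,

    w_ij(t+1) - w_ij(t) = eps * [ x_i(t) x_j(t) - f(r_ij) w_ij(t) ],

with deterrence f(r) = (r/R) exp(r/R); R is the characteristic transport
length scale of the epoch.  Holding x fixed, w relaxes geometrically to the
equilibrium w* = x_i x_j / f(r_ij).  Popularity x_i (normalised population,
sum 1) evolves by a PageRank-style diffusion on the current weights,

    x_i(t+1) - x_i(t) = d * sum_j [ T_ij x_j - T_ji x_i ] + (1-d)(1/N - x_i),

where T_ij = w_ij / sum_k w_kj is the transition probability from j to i and
d in [0, 1] balances network flow against uniform dispersion (the
agricultural-hinterland term).  Because T is column-stochastic the map
collapses to x(t+1) = d T x(t) + (1-d)/N, which conserves sum(x) = 1
analytically.  The model has only three parameters: R, eps, d.

Within one simulation step the connectivity map is applied first (using
x(t)) and the popularity map second (using w(t+1)); fixed points are
insensitive to this ordering.

A "geographical determinism" counterfactual freezes w at the uniform-
population equilibrium w_ij = (1/N^2)/f(r_ij) — connectivity set by distance
alone — and iterates only the popularity map, isolating what the landscape
produces without reinforcement.  An optional capacity vector C_i replaces
the uniform dispersion target 1/N by C_i / sum(C) (spatially-varying
population capacity hook; off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landscape import LandscapeGrid
from .mobility import TransportGraph

__all__ = [
    "ModelParams",
    "ModelState",
    "SimulationResult",
    "TrafficField",
    "deterrence",
    "equilibrium_connectivity",
    "update_connectivity",
    "transition_matrix",
    "update_popularity",
    "init_state",
    "simulate",
    "run_geographical_determinism",
    "scale_population",
    "net_traffic",
]


@dataclass
class ModelParams:
    """The three model parameters plus the optional capacity hook.

    R_km: characteristic transport distance of the epoch (km).
    epsilon: connectivity relaxation rate (per step, dimensionless).
    d: network-flow vs uniform-dispersion balance, in [0, 1].
    capacity: optional per-node C_i >= 0 replacing the uniform dispersion
        target by C_i / sum(C).
    """

    R_km: float = 40.0
    epsilon: float = 0.1
    d: float = 0.9
    capacity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.R_km <= 0:
            raise ValueError("R must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0.0 <= self.d <= 1.0):
            raise ValueError("d must lie in [0, 1]")
        if self.capacity is not None:
            self.capacity = np.asarray(self.capacity, dtype=float)
            if np.any(self.capacity < 0) or self.capacity.sum() <= 0:
                raise ValueError("capacity must be non-negative with positive total")

    def dispersion_target(self, n: int) -> np.ndarray:
        if self.capacity is None:
            return np.full(n, 1.0 / n)
        if self.capacity.size != n:
            raise ValueError("capacity length does not match node count")
        return self.capacity / self.capacity.sum()


@dataclass
class ModelState:
    """Popularity vector x (sum 1) and per-edge connectivity w at step t."""

    x: np.ndarray
    w: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.x < 0) or abs(self.x.sum() - 1.0) > 1e-9:
            raise ValueError("x must be non-negative and sum to 1")
        if np.any(self.w < 0):
            raise ValueError("w must be non-negative")

    def copy(self) -> "ModelState":
        return ModelState(self.x.copy(), self.w.copy(), self.t)


@dataclass
class SimulationResult:
    """Final state plus convergence info and any requested checkpoints."""

    state: ModelState
    converged: bool
    n_steps: int
    final_residual: float
    checkpoints: dict[int, ModelState] = field(default_factory=dict)
    warning: str | None = None


@dataclass
class TrafficField:
    """Per-cell accumulated net traffic deposited by edge flows."""

    values: np.ndarray  # (nrows, ncols), >= 0


def deterrence(r_km: np.ndarray | float, R_km: float) -> np.ndarray | float:
    """Distance deterrence f(r) = (r/R) exp(r/R); f(0)=0, strictly increasing."""
    if R_km <= 0:
        raise ValueError("R must be positive")
    r = np.asarray(r_km, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    out = (r / R_km) * np.exp(r / R_km)
    return float(out) if np.isscalar(r_km) else out


def equilibrium_connectivity(x: np.ndarray, edges: np.ndarray, f: np.ndarray) -> np.ndarray:
    """w*_ij = x_i x_j / f(r_ij), the fixed point of the connectivity map at fixed x."""
    return x[edges[:, 0]] * x[edges[:, 1]] / f


def _check_w_stability(params: ModelParams, f: np.ndarray) -> None:
    m = params.epsilon * f.max(initial=0.0)
    if m >= 2.0:
        warnings.warn(
            f"epsilon * f(r) reaches {m:.3g} >= 2 on some edge: the connectivity "
            "map is overstable and will oscillate/diverge; reduce epsilon or r_max.",
            RuntimeWarning,
            stacklevel=3,
        )


def update_connectivity(
    state: ModelState, graph: TransportGraph, params: ModelParams, f: np.ndarray | None = None
) -> np.ndarray:
    """One application of the mass-action reinforcement map; returns new w."""
    if f is None:
        f = deterrence(graph.r_km, params.R_km)
        _check_w_stability(params, f)
    x = state.x
    e = graph.edges
    return state.w + params.epsilon * (x[e[:, 0]] * x[e[:, 1]] - f * state.w)


def _column_sums(w: np.ndarray, edges: np.ndarray, n: int) -> np.ndarray:
    s = np.bincount(edges[:, 0], weights=w, minlength=n)
    s += np.bincount(edges[:, 1], weights=w, minlength=n)
    return s


def transition_matrix(state: ModelState, graph: TransportGraph):
    """Column-stochastic T with T[i, j] = w_ij / sum_k w_kj (scipy CSC).

    Nodes with no incident weight (isolated, or all-zero w) fall back to
    self-retention T[j, j] = 1, so the column sums stay 1; such nodes are
    reported via a warning.
    """
    from scipy import sparse

    n = graph.n_nodes
    e = graph.edges
    s = _column_sums(state.w, e, n)
    dead = s <= 0.0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} node(s) have zero incident connectivity; "
            "using self-retention for their columns.",
            RuntimeWarning,
            stacklevel=2,
        )
    s_safe = np.where(dead, 1.0, s)
    rows = np.concatenate([e[:, 0], e[:, 1], np.nonzero(dead)[0]])
    cols = np.concatenate([e[:, 1], e[:, 0], np.nonzero(dead)[0]])
    vals = np.concatenate(
        [state.w / s_safe[e[:, 1]], state.w / s_safe[e[:, 0]], np.ones(int(dead.sum()))]
    )
    return sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))


def _popularity_step(
    x: np.ndarray,
    w: np.ndarray,
    edges: np.ndarray,
    d: float,
    target: np.ndarray,
) -> np.ndarray:
    """x(t+1) = d T x + (1-d) target, without materialising T."""
    n = x.size
    s = _column_sums(w, edges, n)
    dead = s <= 0.0
    y = x / np.where(dead, 1.0, s)
    i, j = edges[:, 0], edges[:, 1]
    flow = np.bincount(i, weights=w * y[j], minlength=n)
    flow += np.bincount(j, weights=w * y[i], minlength=n)
    flow[dead] += x[dead]  # self-retention fallback
    return d * flow + (1.0 - d) * target


def update_popularity(state: ModelState, T, params: ModelParams) -> np.ndarray:
    """One application of the popularity map given a transition matrix T."""
    n = state.x.size
    target = params.dispersion_target(n)
    return params.d * (T @ state.x) + (1.0 - params.d) * target


def init_state(
    graph: TransportGraph,
    params: ModelParams,
    mode: str = "near_homogeneous",
    seed: int | None = 0,
    sigma: float = 0.01,
    population: np.ndarray | None = None,
) -> ModelState:
    """Initial state: x by mode, w at the connectivity equilibrium for that x.

    near_homogeneous: x_i proportional to 1 + sigma*u_i, u_i ~ Uniform(-1, 1)
    (seeded); from_population: x_i proportional to the supplied totals.
    """
    n = graph.n_nodes
    if mode == "near_homogeneous":
        rng = np.random.default_rng(seed)
        x = 1.0 + sigma * rng.uniform(-1.0, 1.0, size=n)
    elif mode == "from_population":
        if population is None:
            raise ValueError("from_population mode needs a population vector")
        x = np.asarray(population, dtype=float)
        if np.any(x < 0) or x.sum() <= 0:
            raise ValueError("population must be non-negative with positive total")
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    x = x / x.sum()
    f = deterrence(graph.r_km, params.R_km)
    w = equilibrium_connectivity(x, graph.edges, f)
    return ModelState(x=x, w=w, t=0)


def step(state: ModelState, graph: TransportGraph, params: ModelParams,
         f: np.ndarray | None = None) -> ModelState:
    """One coupled step: connectivity update, then popularity update."""
    if f is None:
        f = deterrence(graph.r_km, params.R_km)
    w_new = state.w + params.epsilon * (
        state.x[graph.edges[:, 0]] * state.x[graph.edges[:, 1]] - f * state.w
    )
    target = params.dispersion_target(state.x.size)
    x_new = _popularity_step(state.x, w_new, graph.edges, params.d, target)
    return ModelState(x=x_new, w=w_new, t=state.t + 1)


def simulate(
    graph: TransportGraph,
    params: "ModelParams | object",
    init: ModelState,
    max_steps: int = 20000,
    tol: float = 1e-8,
    checkpoint_steps: tuple[int, ...] = (),
    grid: LandscapeGrid | None = None,
) -> SimulationResult:
    """Iterate the coupled maps to stationarity.

    Stops when max_i |x_i(t+1) - x_i(t)| * N < tol or after ``max_steps``
    (then the result carries a non-convergence warning flag rather than
    raising).  ``params`` may also be a :class:`~ltpsim.history.RampSchedule`
    — then ``grid`` is required and the run is delegated to
    :func:`ltpsim.history.run_ramp`, recomputing distances at each epoch
    boundary.
    """
    from .history import RampSchedule, run_ramp

    if isinstance(params, RampSchedule):
        if grid is None:
            raise ValueError("a RampSchedule run needs the landscape grid")
        return run_ramp(grid, graph.locations, params, init, tol=tol)

    f = deterrence(graph.r_km, params.R_km)
    _check_w_stability(params, f)
    n = graph.n_nodes
    state = init.copy()
    checkpoints: dict[int, ModelState] = {}
    residual = np.inf
    for k in range(max_steps):
        new = step(state, graph, params, f=f)
        residual = float(np.max(np.abs(new.x - state.x)) * n)
        state = new
        if state.t in checkpoint_steps:
            checkpoints[state.t] = state.copy()
        if residual < tol:
            return SimulationResult(state, True, state.t, residual, checkpoints)
    return SimulationResult(
        state,
        False,
        state.t,
        residual,
        checkpoints,
        warning=f"not converged after {max_steps} steps (residual {residual:.3g})",
    )


def run_geographical_determinism(
    graph: TransportGraph,
    params: ModelParams,
    init: ModelState | None = None,
    max_steps: int = 20000,
    tol: float = 1e-8,
) -> SimulationResult:
    """Counterfactual: same landscape, no reinforcement.

    Connectivity is frozen at the uniform-population equilibrium
    w_ij = (1/N^2) / f(r_ij) — pure distance decay — and only the popularity
    map is iterated to stationarity.  On a homogeneous landscape this returns
    the uniform distribution; heterogeneity can only enter through r_ij.
    """
    n = graph.n_nodes
    f = deterrence(graph.r_km, params.R_km)
    w_frozen = np.full(graph.n_edges, 1.0) / (n * n) / f
    if init is None:
        x = np.full(n, 1.0 / n)
    else:
        x = init.x.copy()
    target = params.dispersion_target(n)
    residual = np.inf
    for t in range(1, max_steps + 1):
        x_new = _popularity_step(x, w_frozen, graph.edges, params.d, target)
        residual = float(np.max(np.abs(x_new - x)) * n)
        x = x_new
        if residual < tol:
            return SimulationResult(ModelState(x, w_frozen, t), True, t, residual)
    return SimulationResult(
        ModelState(x, w_frozen, max_steps),
        False,
        max_steps,
        residual,
        warning=f"not converged after {max_steps} steps (residual {residual:.3g})",
    )


def scale_population(x: np.ndarray, total_population: float) -> np.ndarray:
    """X_i = x_i * total; converts normalised popularity to head counts."""
    if total_population <= 0:
        raise ValueError("total population must be positive")
    x = np.asarray(x, dtype=float)
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("x must sum to 1")
    return x * total_population


def net_traffic(
    state: ModelState, graph: TransportGraph, grid: LandscapeGrid
) -> TrafficField:
    """Accumulate per-edge probability flux onto least-cost path cells.

    The flow on edge (i, j) is phi_ij = T_ij x_j + T_ji x_i (total per-step
    flux in both directions); it is deposited on every cell of the edge's
    stored least-cost path.  Requires :func:`ltpsim.mobility.attach_paths`
    to have been run on the graph.
    """
    n = graph.n_nodes
    s = _column_sums(state.w, graph.edges, n)
    s = np.where(s <= 0, 1.0, s)
    field = np.zeros(grid.nrows * grid.ncols)
    for e, (i, j) in enumerate(graph.edges):
        w = state.w[e]
        if w == 0.0:
            continue
        key = (int(i), int(j))
        if key not in graph.paths:
            raise KeyError(f"no stored path for positive-weight edge {key}")
        phi = w / s[j] * state.x[j] + w / s[i] * state.x[i]
        field[graph.paths[key]] += phi
    return TrafficField(values=field.reshape(grid.shape))
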