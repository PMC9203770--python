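"""Historical initial conditions and epoch ramps of the transport scale.

Two ingredients let a run start from a reconstructed historical state
rather than near-homogeneous noise.  First, a city table (name, lon, lat,
population) is snapped onto the location nodes and the known rural total is
spread around the cities with a distance-discounted score per location i,

    s(i) = sum_u (r_{i,j_u} / R)^(-1) * Population(u),

where j_u is the node of city u and r the least-cost distance for the
epoch's movement mode (walking, R = 8 km, in the historical use).  Rural
population is allocated proportionally to s(i); city populations sit
directly on their own nodes (whose own-city term is excluded from the sum).

Second, a ramp schedule steps the characteristic transport distance R (and
the movement-cost surface) through epochs — e.g. 8 km for pre-modern
walking up to 40 km for a motorised society — re-deriving the effective
distances at each epoch boundary while carrying the connectivity state
across, and snapshotting the model state at requested checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mobility
from .landscape import LandscapeGrid
from .mobility import CostParams, LocationSet, TransportGraph

__all__ = [
    "CityTable",
    "Epoch",
    "RampSchedule",
    "rural_spread_score",
    "build_historical_population",
    "build_ramp_schedule",
    "run_ramp",
]


@dataclass
class CityTable:
    """City point populations for one epoch."""

    table: pd.DataFrame
    epoch_label: str = ""

    def __post_init__(self) -> None:
        required = {"name", "lon", "lat", "population"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"city table missing columns: {sorted(missing)}")
        if (self.table["population"] < 0).any():
            raise ValueError("city populations must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path, epoch_label: str = "") -> "CityTable":
        return cls(pd.read_csv(path), epoch_label)

    def __len__(self) -> int:
        return len(self.table)


def _snap_cities_to_nodes(
    grid: LandscapeGrid,
    cost_params: CostParams,
    locations: LocationSet,
    cities: CityTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Map each city to its nearest location node and return
    (node index per city, least-cost distance matrix city-node x location).

    Nearness is least-cost distance from the city's cell; cities whose cell
    is unreachable from every node fall back to Euclidean-nearest.
    """
    city_cells = []
    for _, row in cities.table.iterrows():
        r, c = grid.lonlat_to_cell(row["lon"], row["lat"])
        city_cells.append(r * grid.ncols + c)
    city_cells = np.asarray(city_cells, dtype=int)
    node_cells = locations.flat_cells(grid.ncols)
    dist = mobility.distance_matrix_from_cells(grid, cost_params, city_cells, node_cells)
    nodes = np.empty(len(cities), dtype=int)
    for u in range(len(cities)):
        du = dist[u]
        if np.isfinite(du).any():
            nodes[u] = int(np.argmin(du))
        else:  # Euclidean fallback
            cr, cc = divmod(city_cells[u], grid.ncols)
            d2 = (locations.rows - cr) ** 2 + (locations.cols - cc) ** 2
            nodes[u] = int(np.argmin(d2))
    # distances measured from each city's own node cell (not the raw city cell)
    dist_from_nodes = mobility.distance_matrix_from_cells(
        grid, cost_params, node_cells[nodes], node_cells
    )
    return nodes, dist_from_nodes


def rural_spread_score(
    dist_city_to_location: np.ndarray,
    city_populations: np.ndarray,
    R_km: float,
    city_nodes: np.ndarray | None = None,
) -> np.ndarray:
    """Distance-discounted score s(i) = sum_u (r/R)^-1 * Pop(u) per location.

    Zero-distance terms (a city's own node) are excluded — the city
    population is placed there directly instead — and unreachable cities
    (infinite r) contribute nothing to that location.
    """
    if R_km <= 0:
        raise ValueError("R must be positive")
    dist = np.asarray(dist_city_to_location, dtype=float)
    pops = np.asarray(city_populations, dtype=float)
    if dist.shape[0] != pops.size:
        raise ValueError("one distance row per city required")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), R_km / dist, 0.0)
    return inv.T @ pops


def build_historical_population(
    grid: LandscapeGrid,
    cost_params: CostParams,
    locations: LocationSet,
    cities: CityTable,
    rural_total: float,
    R_km: float = 8.0,
) -> np.ndarray:
    """Per-location population: cities at their nearest nodes plus the rural
    total spread proportionally to the distance-discounted score.

    The output sums exactly to (city total + rural total) and, normalised,
    feeds :func:`ltpsim.dynamics.init_state` with mode ``from_population``.
    """
    import warnings

    if rural_total < 0:
        raise ValueError("rural total must be non-negative")
    n = len(locations)
    pop = np.zeros(n)
    if len(cities) == 0:
        if rural_total > 0:
            warnings.warn(
                "empty city table: spreading the rural population uniformly",
                RuntimeWarning,
                stacklevel=2,
            )
            pop += rural_total / n
        return pop
    nodes, dist = _snap_cities_to_nodes(grid, cost_params, locations, cities)
    city_pops = cities.table["population"].to_numpy(dtype=float)
    np.add.at(pop, nodes, city_pops)
    if rural_total > 0:
        s = rural_spread_score(dist, city_pops, R_km, city_nodes=nodes)
        if s.sum() > 0:
            pop += rural_total * s / s.sum()
        else:
            pop += rural_total / n
    return pop


@dataclass
class Epoch:
    """One ramp stage: label, transport scale, cost surface, step budget."""

    label: str
    R_km: float
    cost_params: CostParams
    steps: int

    def __post_init__(self) -> None:
        if self.R_km <= 0 or self.steps <= 0:
            raise ValueError("epoch needs positive R and step budget")


@dataclass
class RampSchedule:
    """Ordered epochs with non-decreasing R plus checkpoint R values."""

    epochs: list[Epoch]
    checkpoints_km: list[float] = field(default_factory=list)
    epsilon: float = 0.1
    d: float = 0.9
    r_max_factor: float = 2.0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "epsilon": self.epsilon,
            "d": self.d,
            "r_max_factor": self.r_max_factor,
            "checkpoints_km": list(self.checkpoints_km),
            "epochs": [
                {
                    "label": e.label,
                    "R_km": e.R_km,
                    "steps": e.steps,
                    "cost_params": {
                        "slope_coefficient": e.cost_params.slope_coefficient,
                        "embark_surcharge_km": e.cost_params.embark_surcharge_km,
                        "epoch_label": e.cost_params.epoch_label,
                        "type_multiplier": {
                            f"{a},{b}": (m if np.isfinite(m) else "inf")
                            for (a, b), m in e.cost_params.type_multiplier.items()
                        },
                    },
                }
                for e in self.epochs
            ],
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RampSchedule":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        epochs = []
        for e in doc["epochs"]:
            cp = e["cost_params"]
            mult = {}
            for key, m in cp["type_multiplier"].items():
                a, b = (int(v) for v in key.split(","))
                mult[(a, b)] = float("inf") if m == "inf" else float(m)
            epochs.append(
                Epoch(
                    label=e["label"],
                    R_km=float(e["R_km"]),
                    steps=int(e["steps"]),
                    cost_params=CostParams(
                        slope_coefficient=float(cp["slope_coefficient"]),
                        type_multiplier=mult,
                        embark_surcharge_km=float(cp["embark_surcharge_km"]),
                        epoch_label=cp["epoch_label"],
                    ),
                )
            )
        return cls(
            epochs=epochs,
            checkpoints_km=[float(v) for v in doc.get("checkpoints_km", [])],
            epsilon=float(doc.get("epsilon", 0.1)),
            d=float(doc.get("d", 0.9)),
            r_max_factor=float(doc.get("r_max_factor", 2.0)),
        )


def build_ramp_schedule(
    epoch_configs: list[dict],
    checkpoints_km: list[float] | None = None,
    allow_decreasing: bool = False,
    epsilon: float = 0.1,
    d: float = 0.9,
    r_max_factor: float = 2.0,
) -> RampSchedule:
    """Assemble a ramp from epoch config dicts.

    Each config needs ``label``, ``R_km``, ``steps`` and either a ready
    ``cost_params`` or a ``scenario`` name (+ optional overrides).  R must be
    non-decreasing across epochs unless ``allow_decreasing`` is set.
    """
    epochs: list[Epoch] = []
    for cfg in epoch_configs:
        cfg = dict(cfg)
        label = cfg.pop("label")
        R = float(cfg.pop("R_km"))
        steps = int(cfg.pop("steps"))
        if "cost_params" in cfg:
            cp = cfg.pop("cost_params")
        else:
            cp = mobility.scenario_cost_params(cfg.pop("scenario"), **cfg.pop("overrides", {}))
        if cfg:
            raise ValueError(f"unknown epoch config keys: {sorted(cfg)}")
        epochs.append(Epoch(label, R, cp, steps))
    Rs = [e.R_km for e in epochs]
    if not allow_decreasing and any(b < a for a, b in zip(Rs, Rs[1:])):
        raise ValueError("R must be non-decreasing across epochs (override to allow)")
    return RampSchedule(
        epochs=epochs,
        checkpoints_km=list(checkpoints_km or []),
        epsilon=epsilon,
        d=d,
        r_max_factor=r_max_factor,
    )


def paper_style_ramp(
    scenario: str = "water_bodies",
    steps_per_epoch: int = 2000,
    R_values: tuple[float, ...] = (8.0, 12.0, 16.0, 20.0, 22.0, 24.0, 30.0, 40.0),
    checkpoints_km: tuple[float, ...] = (8.0, 22.0, 24.0, 40.0),
) -> RampSchedule:
    """Stepwise ramp of R from 8 to 40 km with quasi-equilibration per epoch.

    The first epoch uses the Roman-era cost surface (cheaper sailing); later
    epochs use the plain scenario surface.  Checkpoint states are snapshotted
    at the listed R values.
    """
    configs = []
    for k, R in enumerate(R_values):
        if k == 0:
            cp = mobility.roman_cost_params()
        else:
            cp = mobility.scenario_cost_params(scenario)
        configs.append({"label": f"R{R:g}", "R_km": R, "steps": steps_per_epoch, "cost_params": cp})
    return build_ramp_schedule(configs, checkpoints_km=list(checkpoints_km))


def run_ramp(
    grid: LandscapeGrid,
    locations: LocationSet,
    schedule: RampSchedule,
    init: "object",
    tol: float = 1e-8,
):
    """Run the coupled dynamics through a ramp schedule.

    At each epoch boundary the effective distances are recomputed for the
    epoch's cost surface and R (edge cutoff ``r_max_factor * R``);
    connectivity w is carried across on edges common to both graphs, while
    newly appearing edges start at the connectivity equilibrium for the
    current x and vanished edges are dropped.  States are snapshotted the
    first time each checkpoint R value is reached.
    """
    from .dynamics import (
        ModelParams,
        ModelState,
        SimulationResult,
        deterrence,
        equilibrium_connectivity,
        simulate,
    )

    state: ModelState = init.copy() if hasattr(init, "copy") else init
    checkpoints: dict[float, ModelState] = {}
    prev_edges: dict[tuple[int, int], float] = {}
    graph: TransportGraph | None = None
    total_steps = 0
    converged = True
    residual = float("nan")
    for epoch in schedule.epochs:
        params = ModelParams(R_km=epoch.R_km, epsilon=schedule.epsilon, d=schedule.d)
        graph = mobility.least_cost_distances(
            grid, epoch.cost_params, locations, r_max=schedule.r_max_factor * epoch.R_km
        )
        f = deterrence(graph.r_km, epoch.R_km)
        w = equilibrium_connectivity(state.x, graph.edges, f)
        for e, (i, j) in enumerate(graph.edges):
            key = (int(i), int(j))
            if key in prev_edges:
                w[e] = prev_edges[key]
        state = ModelState(x=state.x, w=w, t=state.t)
        res = simulate(graph, params, state, max_steps=epoch.steps, tol=tol)
        state = res.state
        total_steps += res.n_steps
        converged = converged and res.converged
        residual = res.final_residual
        prev_edges = {
            (int(i), int(j)): state.w[e] for e, (i, j) in enumerate(graph.edges)
        }
        for ck in schedule.checkpoints_km:
            if ck not in checkpoints and abs(ck - epoch.R_km) < 1e-9:
                checkpoints[ck] = state.copy()
    result = SimulationResult(
        state=state,
        converged=converged,
        n_steps=total_steps,
        final_residual=residual,
        checkpoints={int(k): v for k, v in enumerate(checkpoints.values())},
    )
    result.checkpoint_states_by_R = checkpoints  # type: ignore[attr-defined]
    result.final_graph = graph  # type: ignore[attr-defined]
    return result
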