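"""Movement costs and least-cost effective distances on a landscape.

A movement step goes from a cell to one of its eight adjacent neighbours
(with wrap-around on periodic grids).  Its cost in *effective kilometres* is

    cost = horizontal_km * type_multiplier * slope_penalty (+ embark surcharge)

where ``horizontal_km`` is the true centre-to-centre horizontal distance
(diagonals are longer; east-west spacing may vary by row on geographic
grids), ``type_multiplier`` depends on the origin/destination cell types
(impassable pairs have multiplier +inf), ``slope_penalty = exp(k * |slope|)``
with slope = rise over run, and a fixed surcharge applies whenever a step
crosses between land and water (embarking or landing).

The effective transport distance r_ij between two sampled locations is the
minimum accumulated step cost over 8-connected cell paths, computed with
Dijkstra on the sparse cell graph.  All landscape influence on the
population/transport dynamics enters through these r_ij.

Scenario presets mirror the progressive build-up from an idealised flatland
to a full landscape: flatland and coastline ignore slope and treat all water
as a hard barrier; elevation adds the slope penalty; water_bodies makes
ocean, lakes and rivers navigable at a reduced multiplier (marine and river
transport) at the price of an embarkation surcharge.  The numeric
coefficients are documented, overridable defaults — stand-ins calibrated to
the qualitative regime (water transport cheaper than land, steep slopes
strongly penalised), not externally derived constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .landscape import LAND, OCEAN, LAKE, RIVER, LandscapeGrid

__all__ = [
    "BlockedMoveError",
    "CostParams",
    "LocationSet",
    "TransportGraph",
    "scenario_cost_params",
    "step_cost",
    "sample_locations",
    "least_cost_distances",
    "least_cost_path",
    "attach_paths",
    "distance_matrix_from_cells",
    "SCENARIOS",
]

SCENARIOS = ("flatland", "coastline", "elevation", "water_bodies")

INF = math.inf


class BlockedMoveError(ValueError):
    """The requested step crosses an impassable cell-type pair."""


@dataclass
class CostParams:
    """Movement-cost coefficients for one scenario/epoch.

    ``type_multiplier`` maps unordered cell-type pairs (stored on ordered
    keys, symmetric) to a multiplicative cost factor; +inf blocks the step.
    ``slope_coefficient`` is k in the penalty exp(k |slope|), dimensionless
    (slope is rise/run).  ``embark_surcharge_km`` is a fixed effective-km
    cost added on every land<->water transition.
    """

    slope_coefficient: float = 0.0
    type_multiplier: dict[tuple[int, int], float] = field(default_factory=dict)
    embark_surcharge_km: float = 0.0
    epoch_label: str = ""

    def __post_init__(self) -> None:
        if self.embark_surcharge_km < 0:
            raise ValueError("embark surcharge must be non-negative")
        for pair, m in self.type_multiplier.items():
            if not (m > 0):  # catches <=0 and nan; inf passes
                raise ValueError(f"multiplier for {pair} must be > 0 or +inf")

    def multiplier_table(self) -> np.ndarray:
        """Dense 4x4 symmetric lookup table of pair multipliers."""
        tab = np.full((4, 4), INF)
        for (a, b), m in self.type_multiplier.items():
            tab[a, b] = m
            tab[b, a] = m
        return tab


#: Documented default coefficients (config values, not constants).
DEFAULT_SLOPE_COEFFICIENT = 3.5
DEFAULT_WATER_MULTIPLIER = 0.5
DEFAULT_EMBARK_SURCHARGE_KM = 2.0
ROMAN_WATER_MULTIPLIER = 0.25


def _pair_table_from_type_costs(per_type: dict[int, float]) -> dict[tuple[int, int], float]:
    """Symmetric pair multipliers as the mean of per-type factors (inf wins)."""
    out: dict[tuple[int, int], float] = {}
    types = (LAND, OCEAN, LAKE, RIVER)
    for a in types:
        for b in types:
            if a <= b:
                ma, mb = per_type[a], per_type[b]
                out[(a, b)] = INF if math.isinf(ma) or math.isinf(mb) else 0.5 * (ma + mb)
    return out


def scenario_cost_params(scenario: str, **overrides) -> CostParams:
    """Cost parameters for one of the four landscape scenarios.

    flatland / coastline: flat cost surface, all water impassable.
    elevation: adds the slope penalty, water still impassable.
    water_bodies: water navigable at ``water_multiplier`` (default 0.5x land)
    with an embarkation surcharge; slope penalty on land.

    Keyword overrides: ``slope_coefficient``, ``water_multiplier``,
    ``embark_surcharge_km``, ``epoch_label`` (e.g. the Roman epoch uses
    ``water_multiplier=0.25`` — sailing comparably cheaper than land travel).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    water_mult = overrides.pop("water_multiplier", DEFAULT_WATER_MULTIPLIER)
    label = overrides.pop("epoch_label", scenario)
    if scenario in ("flatland", "coastline"):
        slope_k = overrides.pop("slope_coefficient", 0.0)
        per_type = {LAND: 1.0, OCEAN: INF, LAKE: INF, RIVER: INF}
        surcharge = overrides.pop("embark_surcharge_km", 0.0)
    elif scenario == "elevation":
        slope_k = overrides.pop("slope_coefficient", DEFAULT_SLOPE_COEFFICIENT)
        per_type = {LAND: 1.0, OCEAN: INF, LAKE: INF, RIVER: INF}
        surcharge = overrides.pop("embark_surcharge_km", 0.0)
    else:  # water_bodies
        slope_k = overrides.pop("slope_coefficient", DEFAULT_SLOPE_COEFFICIENT)
        per_type = {LAND: 1.0, OCEAN: water_mult, LAKE: water_mult, RIVER: water_mult}
        surcharge = overrides.pop("embark_surcharge_km", DEFAULT_EMBARK_SURCHARGE_KM)
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")
    return CostParams(
        slope_coefficient=slope_k,
        type_multiplier=_pair_table_from_type_costs(per_type),
        embark_surcharge_km=surcharge,
        epoch_label=label,
    )


def roman_cost_params() -> CostParams:
    """Water-bodies cost surface for the Roman epoch (cheaper sailing)."""
    return scenario_cost_params(
        "water_bodies", water_multiplier=ROMAN_WATER_MULTIPLIER, epoch_label="roman"
    )


# ---------------------------------------------------------------------------
# Step costs and the cell graph
# ---------------------------------------------------------------------------

def _horizontal_km(grid: LandscapeGrid, ra: int, rb: int, dc: int) -> float:
    ew = np.asarray(grid.cell_size_ew_km)
    ew_step = 0.5 * (ew[ra] + ew[rb]) * abs(dc)
    ns_step = grid.cell_size_ns_km * (0 if ra == rb else 1)
    return math.hypot(ew_step, ns_step)


def step_cost(
    grid: LandscapeGrid,
    params: CostParams,
    cell_a: tuple[int, int],
    cell_b: tuple[int, int],
) -> float:
    """Effective-km cost of one 8-adjacent step; raises on blocked moves."""
    ra, ca = cell_a
    rb, cb = cell_b
    dr = rb - ra
    dc = cb - ca
    if grid.periodic:
        half_r, half_c = grid.nrows // 2, grid.ncols // 2
        dr = (dr + half_r) % grid.nrows - half_r
        dc = (dc + half_c) % grid.ncols - half_c
    if max(abs(dr), abs(dc)) != 1:
        raise ValueError(f"cells {cell_a} and {cell_b} are not 8-adjacent")
    ta = int(grid.cell_type[ra, ca])
    tb = int(grid.cell_type[rb, cb])
    mult = params.multiplier_table()[ta, tb]
    if math.isinf(mult):
        raise BlockedMoveError(f"move {cell_a}->{cell_b} blocked (types {ta}->{tb})")
    hdist = _horizontal_km(grid, ra, rb, dc)
    slope = abs(grid.elevation_m[ra, ca] - grid.elevation_m[rb, cb]) / (hdist * 1000.0)
    cost = hdist * mult * math.exp(params.slope_coefficient * slope)
    if (ta == LAND) != (tb == LAND):
        cost += params.embark_surcharge_km
    return cost


def _cell_graph(grid: LandscapeGrid, params: CostParams) -> sparse.csr_matrix:
    """Sparse symmetric graph over all cells with finite step costs."""
    nr, nc = grid.shape
    n = nr * nc
    tab = params.multiplier_table()
    ew = np.asarray(grid.cell_size_ew_km)
    ns = grid.cell_size_ns_km
    ctype = grid.cell_type
    elev = grid.elevation_m
    land = ctype == LAND

    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    # four forward offsets; symmetry supplies the reverse directions
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        if grid.periodic:
            r0 = np.arange(nr)[:, None]
            c0 = np.arange(nc)[None, :]
            r1 = (r0 + dr) % nr
            c1 = (c0 + dc) % nc
            r0, c0, r1, c1 = np.broadcast_arrays(r0, c0, r1, c1)
        else:
            rlo, rhi = max(0, -dr), nr - max(0, dr)
            clo, chi = max(0, -dc), nc - max(0, dc)
            r0, c0 = np.mgrid[rlo:rhi, clo:chi]
            r1, c1 = r0 + dr, c0 + dc
        r0, c0, r1, c1 = (a.ravel() for a in (r0, c0, r1, c1))
        mult = tab[ctype[r0, c0], ctype[r1, c1]]
        ok = np.isfinite(mult)
        if not ok.any():
            continue
        r0, c0, r1, c1, mult = r0[ok], c0[ok], r1[ok], c1[ok], mult[ok]
        ew_step = 0.5 * (ew[r0] + ew[r1]) * abs(dc)
        ns_step = ns * abs(dr)
        hdist = np.hypot(ew_step, ns_step)
        slope = np.abs(elev[r0, c0] - elev[r1, c1]) / (hdist * 1000.0)
        cost = hdist * mult * np.exp(params.slope_coefficient * slope)
        cost = cost + np.where(land[r0, c0] != land[r1, c1], params.embark_surcharge_km, 0.0)
        a = r0 * nc + c0
        b = r1 * nc + c1
        rows_out += [a, b]
        cols_out += [b, a]
        vals_out += [cost, cost]
    if not rows_out:
        return sparse.csr_matrix((n, n))
    return sparse.csr_matrix(
        (np.concatenate(vals_out), (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(n, n),
    )


# ---------------------------------------------------------------------------
# Locations and transport graphs
# ---------------------------------------------------------------------------

@dataclass
class LocationSet:
    """Sampled location nodes: id -> land cell (row, col)."""

    rows: np.ndarray
    cols: np.ndarray
    spacing_km: float

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if self.rows.shape != self.cols.shape:
            raise ValueError("rows/cols length mismatch")

    def __len__(self) -> int:
        return self.rows.size

    def flat_cells(self, ncols: int) -> np.ndarray:
        return self.rows * ncols + self.cols


def sample_locations(grid: LandscapeGrid, spacing_km: float) -> LocationSet:
    """One location per spacing x spacing block, at the land cell nearest the
    block centre (ties broken lexicographically by (row, col)); blocks with no
    land cell get no node.  Deterministic; node ids run in block raster order.
    """
    if spacing_km <= 0:
        raise ValueError("spacing must be positive")
    if not grid.is_land.any():
        raise ValueError("grid has no land cells to place locations on")
    ew_mean = float(np.mean(np.asarray(grid.cell_size_ew_km)))
    bs_r = max(1, int(round(spacing_km / grid.cell_size_ns_km)))
    bs_c = max(1, int(round(spacing_km / ew_mean)))
    rows: list[int] = []
    cols: list[int] = []
    for br in range(0, grid.nrows, bs_r):
        for bc in range(0, grid.ncols, bs_c):
            block = grid.is_land[br : br + bs_r, bc : bc + bs_c]
            if not block.any():
                continue
            rr, cc = np.nonzero(block)
            ctr_r = (min(bs_r, grid.nrows - br) - 1) / 2.0
            ctr_c = (min(bs_c, grid.ncols - bc) - 1) / 2.0
            d2 = (rr - ctr_r) ** 2 + (cc - ctr_c) ** 2
            best = np.lexsort((cc, rr, d2))[0]
            rows.append(br + int(rr[best]))
            cols.append(bc + int(cc[best]))
    return LocationSet(np.array(rows), np.array(cols), spacing_km)


@dataclass
class TransportGraph:
    """Locations plus pairwise effective distances r_ij on retained edges.

    ``edges`` is an (E, 2) array of node-id pairs with i < j; ``r_km`` the
    matching effective distances.  ``paths`` (optional, via
    :func:`attach_paths`) stores the least-cost cell path per edge as an
    array of flat cell indices.  ``component_report`` lists the connected
    components of the retained edge set (singleton when connected).
    """

    locations: LocationSet
    edges: np.ndarray
    r_km: np.ndarray
    r_max: float
    component_report: list[list[int]] = field(default_factory=list)
    paths: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.r_km = np.asarray(self.r_km, dtype=float)
        if np.any(self.r_km <= 0):
            raise ValueError("effective distances must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.locations)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def is_connected(self) -> bool:
        return len(self.component_report) == 1

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for (i, j) in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"i": self.edges[:, 0], "j": self.edges[:, 1], "r_km": self.r_km})


def least_cost_distances(
    grid: LandscapeGrid,
    params: CostParams,
    locations: LocationSet,
    r_max: float = INF,
) -> TransportGraph:
    """Effective distances between all location pairs within ``r_max``.

    Runs Dijkstra on the 8-connected cell graph from every location cell and
    keeps node pairs whose least accumulated cost is <= r_max.  Locations
    unreachable from every other location are reported in
    ``component_report`` rather than silently dropped.
    """
    n = len(locations)
    cells = locations.flat_cells(grid.ncols)
    graph = _cell_graph(grid, params)
    limit = r_max if math.isfinite(r_max) else np.inf
    dist = csgraph.dijkstra(graph, directed=False, indices=cells, limit=limit)
    d_nodes = dist[:, cells]
    iu, ju = np.triu_indices(n, k=1)
    r = 0.5 * (d_nodes[iu, ju] + d_nodes[ju, iu])  # symmetrise float noise
    keep = np.isfinite(r) & (r <= r_max)
    edges = np.column_stack([iu[keep], ju[keep]])
    adj = sparse.csr_matrix(
        (np.ones(edges.shape[0]), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    ncomp, labels = csgraph.connected_components(adj, directed=False)
    report = [sorted(np.nonzero(labels == c)[0].tolist()) for c in range(ncomp)]
    report.sort(key=lambda comp: (-len(comp), comp[0]))
    return TransportGraph(locations, edges, r[keep], r_max, component_report=report)


def _backtrack_path(
    grid: LandscapeGrid,
    params: CostParams,
    dist_field: np.ndarray,
    source_cell: int,
    target_cell: int,
    rtol: float = 1e-9,
) -> np.ndarray:
    """Walk back from target to source along the distance field.

    At each cell the predecessor is the 8-neighbour p minimising
    dist[p] + step_cost(p, cell); among equal-cost predecessors the
    lexicographically smallest (row, col) is taken, which makes stored paths
    deterministic.
    """
    nc = grid.ncols
    path = [target_cell]
    cur = target_cell
    guard = grid.nrows * grid.ncols + 1
    while cur != source_cell and guard > 0:
        guard -= 1
        r, c = divmod(cur, nc)
        best: tuple[float, int, int] | None = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                pr, pc = r + dr, c + dc
                if grid.periodic:
                    pr %= grid.nrows
                    pc %= grid.ncols
                elif not (0 <= pr < grid.nrows and 0 <= pc < grid.ncols):
                    continue
                p = pr * nc + pc
                if not np.isfinite(dist_field[p]):
                    continue
                try:
                    sc = step_cost(grid, params, (pr, pc), (r, c))
                except BlockedMoveError:
                    continue
                total = dist_field[p] + sc
                cand = (total, pr, pc)
                if best is None or cand < best:
                    best = cand
        if best is None:
            raise RuntimeError("backtrack failed: no finite predecessor")
        total, pr, pc = best
        if not math.isclose(total, dist_field[cur], rel_tol=rtol, abs_tol=1e-12):
            raise RuntimeError("backtrack failed: distance field inconsistent")
        cur = pr * nc + pc
        path.append(cur)
    if cur != source_cell:
        raise RuntimeError("backtrack did not reach the source cell")
    return np.array(path[::-1], dtype=int)


def least_cost_path(
    grid: LandscapeGrid,
    params: CostParams,
    locations: LocationSet,
    node_i: int,
    node_j: int,
) -> np.ndarray:
    """Least-cost cell path between two locations as (row, col) pairs.

    The accumulated step cost along the returned path equals r_ij.  Ties
    among equal-cost paths are broken lexicographically (deterministic).
    """
    cells = locations.flat_cells(grid.ncols)
    graph = _cell_graph(grid, params)
    dist = csgraph.dijkstra(graph, directed=False, indices=cells[node_i])
    if not np.isfinite(dist[cells[node_j]]):
        raise BlockedMoveError(f"nodes {node_i} and {node_j} are mutually unreachable")
    flat = _backtrack_path(grid, params, dist, int(cells[node_i]), int(cells[node_j]))
    return np.column_stack(divmod(flat, grid.ncols))


def attach_paths(graph: TransportGraph, grid: LandscapeGrid, params: CostParams) -> TransportGraph:
    """Store the least-cost cell path (flat indices) for every edge in-place.

    One Dijkstra per location; each incident edge's path is recovered by
    deterministic backtracking on that node's distance field.
    """
    cells = graph.locations.flat_cells(grid.ncols)
    cgraph = _cell_graph(grid, params)
    by_source: dict[int, list[int]] = {}
    for e, (i, j) in enumerate(graph.edges):
        by_source.setdefault(int(i), []).append(e)
    for i, edge_ids in by_source.items():
        dist = csgraph.dijkstra(cgraph, directed=False, indices=cells[i])
        for e in edge_ids:
            j = int(graph.edges[e, 1])
            graph.paths[(i, j)] = _backtrack_path(
                grid, params, dist, int(cells[i]), int(cells[j])
            )
    return graph


def distance_matrix_from_cells(
    grid: LandscapeGrid,
    params: CostParams,
    source_cells: np.ndarray,
    target_cells: np.ndarray,
) -> np.ndarray:
    """Least-cost distances from each source cell to each target cell
    (shape: n_sources x n_targets; +inf where unreachable)."""
    graph = _cell_graph(grid, params)
    src = np.asarray(source_cells, dtype=int)
    dist = csgraph.dijkstra(graph, directed=False, indices=src)
    return dist[:, np.asarray(target_cells, dtype=int)]
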