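import numpy as np
import pytest

from ltpsim import dynamics, landscape, mobility, stability


@pytest.fixture(scope="session")
def flat10():
    """10x10 periodic flatland, 2 km cells."""
    return landscape.generate_flatland(10, 10, 2.0, periodic=True)


@pytest.fixture(scope="session")
def wall_gap_grid():
    """7x7 flat grid split by a full-height ocean wall with a single gap.

    The wall occupies column 3; the gap is at row 5, so any land route
    between the halves must detour through (5, 3).
    """
    ctype = np.full((7, 7), landscape.LAND, dtype=np.int8)
    ctype[:, 3] = landscape.OCEAN
    ctype[5, 3] = landscape.LAND
    return landscape.LandscapeGrid(
        cell_type=ctype,
        elevation_m=np.zeros((7, 7)),
        cell_size_ew_km=2.0,
        cell_size_ns_km=2.0,
        periodic=False,
    )


@pytest.fixture(scope="session")
def hetero_grid():
    """Small heterogeneous synthetic landscape: coast + relief + one river."""
    spec = landscape.SyntheticLandscapeSpec(
        nrows=36,
        ncols=30,
        cell_size_km=2.0,
        land_fraction=0.65,
        roughness=2.2,
        amplitude_m=1500.0,
        rivers=[[(4, 4), (14, 10), (26, 12)]],
        seed=7,
    )
    return landscape.generate_synthetic_landscape(spec)


@pytest.fixture(scope="session")
def hetero_graph(hetero_grid):
    cost = mobility.scenario_cost_params("water_bodies")
    locs = mobility.sample_locations(hetero_grid, 4.0)
    return mobility.least_cost_distances(hetero_grid, cost, locs, r_max=12.0)


@pytest.fixture(scope="session")
def ring5_graph():
    """5-node ring with unit distances (hand-checkable transition matrix)."""
    edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [0, 4]])
    locs = mobility.LocationSet(np.zeros(5, dtype=int), np.arange(5), 1.0)
    return mobility.TransportGraph(
        locs, edges, np.ones(5), r_max=np.inf, component_report=[[0, 1, 2, 3, 4]]
    )


@pytest.fixture(scope="session")
def baseline_lattice16():
    return stability.baseline_lattice()


def bellman_ford_distance(grid, params, source_cell, target_cell):
    """Independent exhaustive-relaxation oracle for least-cost distances.

    Relaxes every adjacent cell pair |cells| times using step_cost only; no
    priority queue, no shortest-path library.
    """
    n = grid.nrows * grid.ncols
    dist = np.full(n, np.inf)
    dist[source_cell] = 0.0
    pairs = []
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if grid.periodic:
                        r2 %= grid.nrows
                        c2 %= grid.ncols
                    elif not (0 <= r2 < grid.nrows and 0 <= c2 < grid.ncols):
                        continue
                    try:
                        cost = mobility.step_cost(grid, params, (r, c), (r2, c2))
                    except mobility.BlockedMoveError:
                        continue
                    pairs.append((r * grid.ncols + c, r2 * grid.ncols + c2, cost))
    for _ in range(n):
        changed = False
        for a, b, cost in pairs:
            if dist[a] + cost < dist[b] - 1e-15:
                dist[b] = dist[a] + cost
                changed = True
        if not changed:
            break
    return dist[target_cell]


@pytest.fixture(scope="session")
def bf_oracle():
    return bellman_ford_distance


def make_state(x, w):
    return dynamics.ModelState(x=np.asarray(x, float), w=np.asarray(w, float))


@pytest.fixture(scope="session")
def state_factory():
    return make_state
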