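import math

import numpy as np
import pytest

from ltpsim import mobility, stability
from ltpsim.dynamics import (
    ModelParams,
    ModelState,
    deterrence,
    equilibrium_connectivity,
    init_state,
    net_traffic,
    run_geographical_determinism,
    scale_population,
    simulate,
    transition_matrix,
    update_connectivity,
    update_popularity,
)


class TestDeterrence:
    @pytest.mark.parametrize(
        "r,R,expected",
        [
            (1.0, 1.0, math.e),
            (0.0, 1.0, 0.0),
            (2.0, 1.0, 2 * math.e**2),
            (8.0, 8.0, math.e),
        ],
    )
    def test_closed_form(self, r, R, expected):
        assert deterrence(r, R) == pytest.approx(expected, rel=1e-15)

    def test_strictly_increasing(self):
        r = np.linspace(0.01, 10, 200)
        f = deterrence(r, 2.5)
        assert (np.diff(f) > 0).all()

    def test_depends_on_r_only_through_ratio(self):
        # scaling all distances and R together leaves f unchanged
        r = np.array([1.0, 3.0, 7.0])
        assert np.allclose(deterrence(r, 2.0), deterrence(5 * r, 10.0))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            deterrence(-1.0, 1.0)


class TestConnectivityUpdate:
    def test_explicit_arithmetic(self, ring5_graph):
        # one edge with eps=0.5, x_i=x_j=0.1, f=1, w=0.005 -> 0.0075
        params = ModelParams(R_km=1.0, epsilon=0.5, d=0.5)
        state = ModelState(
            x=np.array([0.1, 0.1, 0.4, 0.2, 0.2]), w=np.full(5, 0.005)
        )
        f = np.ones(5)
        w_new = update_connectivity(state, ring5_graph, params, f=f)
        assert w_new[0] == pytest.approx(0.5 * 0.005 + 0.5 * 0.1 * 0.1)
        assert w_new[0] == pytest.approx(0.0075)

    def test_equilibrium_is_fixed_point(self, ring5_graph):
        params = ModelParams(R_km=1.0, epsilon=0.3, d=0.5)
        x = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        f = deterrence(ring5_graph.r_km, params.R_km)
        w_star = equilibrium_connectivity(x, ring5_graph.edges, f)
        state = ModelState(x=x, w=w_star)
        assert np.allclose(update_connectivity(state, ring5_graph, params, f=f), w_star)

    def test_geometric_convergence_rate(self, ring5_graph):
        # with x frozen, deviation from w* contracts by (1 - eps f) per step
        params = ModelParams(R_km=1.0, epsilon=0.2, d=0.5)
        x = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        f = deterrence(ring5_graph.r_km, params.R_km)
        w_star = equilibrium_connectivity(x, ring5_graph.edges, f)
        w = np.full(5, 0.05)
        dev0 = w - w_star
        n = 25
        for _ in range(n):
            state = ModelState(x=x, w=w)
            w = update_connectivity(state, ring5_graph, params, f=f)
        expected = dev0 * (1.0 - params.epsilon * f) ** n
        assert np.allclose(w - w_star, expected, atol=1e-14)

    def test_overstable_configuration_warns(self, ring5_graph):
        params = ModelParams(R_km=0.1, epsilon=0.5, d=0.5)  # eps*f huge
        state = ModelState(x=np.full(5, 0.2), w=np.full(5, 0.01))
        with pytest.warns(RuntimeWarning, match="overstable"):
            update_connectivity(state, ring5_graph, params)


class TestTransitionMatrix:
    def test_uniform_ring_matches_hand_matrix(self, ring5_graph):
        state = ModelState(x=np.full(5, 0.2), w=np.ones(5))
        T = transition_matrix(state, ring5_graph).toarray()
        expected = np.zeros((5, 5))
        for i in range(5):
            expected[(i + 1) % 5, i] = 0.5
            expected[(i - 1) % 5, i] = 0.5
        assert np.allclose(T, expected)

    def test_columns_sum_to_one_for_random_weights(self, ring5_graph):
        rng = np.random.default_rng(42)
        state = ModelState(x=np.full(5, 0.2), w=rng.uniform(0.1, 2.0, size=5))
        T = transition_matrix(state, ring5_graph)
        assert np.allclose(np.asarray(T.sum(axis=0)).ravel(), 1.0)

    def test_equal_weights_split_half_half(self):
        edges = np.array([[0, 1], [1, 2]])
        locs = mobility.LocationSet(np.zeros(3, dtype=int), np.arange(3), 1.0)
        graph = mobility.TransportGraph(locs, edges, np.ones(2), np.inf)
        state = ModelState(x=np.full(3, 1 / 3), w=np.array([0.7, 0.7]))
        T = transition_matrix(state, graph).toarray()
        assert T[0, 1] == pytest.approx(0.5)
        assert T[2, 1] == pytest.approx(0.5)

    def test_zero_weight_node_falls_back_to_self_retention(self, ring5_graph):
        state = ModelState(x=np.full(5, 0.2), w=np.zeros(5))
        with pytest.warns(RuntimeWarning, match="zero incident"):
            T = transition_matrix(state, ring5_graph).toarray()
        assert np.allclose(np.diag(T), 1.0)


class TestPopularityUpdate:
    def test_d_zero_resets_to_uniform(self, ring5_graph):
        params = ModelParams(R_km=1.0, epsilon=0.1, d=0.0)
        state = ModelState(x=np.array([0.5, 0.2, 0.1, 0.1, 0.1]), w=np.ones(5))
        T = transition_matrix(state, ring5_graph)
        x_new = update_popularity(state, T, params)
        assert np.allclose(x_new, 0.2)

    def test_homogeneous_ring_fixed_point(self, ring5_graph):
        params = ModelParams(R_km=1.0, epsilon=0.1, d=0.8)
        state = ModelState(x=np.full(5, 0.2), w=np.ones(5))
        T = transition_matrix(state, ring5_graph)
        assert np.allclose(update_popularity(state, T, params), 0.2)

    def test_mass_conservation_on_random_graph(self):
        rng = np.random.default_rng(7)
        edges = np.array([[0, 1], [0, 2], [1, 3], [2, 4], [3, 5], [4, 5], [1, 2]])
        locs = mobility.LocationSet(np.zeros(6, dtype=int), np.arange(6), 1.0)
        graph = mobility.TransportGraph(locs, edges, np.ones(7), np.inf)
        x = rng.dirichlet(np.ones(6))
        state = ModelState(x=x, w=rng.uniform(0.1, 1.0, size=7))
        T = transition_matrix(state, graph)
        x_new = update_popularity(state, T, ModelParams(d=0.85))
        assert x_new.sum() == pytest.approx(1.0, abs=1e-14)
        assert (x_new >= 0).all()

    def test_capacity_variant_conserves_and_biases(self, ring5_graph):
        cap = np.array([4.0, 1.0, 1.0, 1.0, 1.0])
        params = ModelParams(R_km=1.0, epsilon=0.1, d=0.5, capacity=cap)
        state = ModelState(x=np.full(5, 0.2), w=np.ones(5))
        T = transition_matrix(state, ring5_graph)
        x_new = update_popularity(state, T, params)
        assert x_new.sum() == pytest.approx(1.0, abs=1e-14)
        assert x_new[0] > x_new[1]


class TestInitState:
    def test_zero_sigma_exactly_uniform(self, ring5_graph):
        st = init_state(ring5_graph, ModelParams(), sigma=0.0, seed=0)
        assert np.allclose(st.x, 0.2)

    def test_same_seed_identical_states(self, hetero_graph):
        params = ModelParams(R_km=6.0)
        a = init_state(hetero_graph, params, seed=5)
        b = init_state(hetero_graph, params, seed=5)
        assert (a.x == b.x).all() and (a.w == b.w).all()

    def test_from_population_indicator(self, ring5_graph):
        pop = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        st = init_state(ring5_graph, ModelParams(), mode="from_population", population=pop)
        assert st.x[2] == 1.0 and st.x.sum() == 1.0

    def test_w_initialised_at_equilibrium(self, ring5_graph):
        params = ModelParams(R_km=1.0)
        st = init_state(ring5_graph, params, seed=3)
        f = deterrence(ring5_graph.r_km, params.R_km)
        assert np.allclose(st.w, equilibrium_connectivity(st.x, ring5_graph.edges, f))

    def test_zero_total_population_rejected(self, ring5_graph):
        with pytest.raises(ValueError):
            init_state(
                ring5_graph, ModelParams(), mode="from_population", population=np.zeros(5)
            )


class TestSimulate:
    def test_subcritical_flatland_returns_to_uniform(self, baseline_lattice16):
        params = stability.baseline_params(d=0.7)
        init = init_state(baseline_lattice16.graph, params, seed=2, sigma=0.01)
        res = simulate(baseline_lattice16.graph, params, init, max_steps=5000, tol=1e-10)
        assert res.converged
        assert np.allclose(res.state.x, 1.0 / 256, atol=1e-9)

    def test_supercritical_flatland_forms_pattern(self, baseline_lattice16):
        params = stability.baseline_params(d=0.9)
        init = init_state(baseline_lattice16.graph, params, seed=2, sigma=0.01)
        res = simulate(baseline_lattice16.graph, params, init, max_steps=6000)
        x_field = res.state.x.reshape(16, 16)
        kmag, mode = stability.dominant_wavenumber(x_field, 2.0)
        assert kmag > 0
        assert res.state.x.max() > 3.0 / 256  # strong peaks, not uniform

    def test_epsilon_frozen_equilibrium_keeps_uniform(self, ring5_graph):
        # with w at the uniform equilibrium and x uniform, nothing moves
        params = ModelParams(R_km=1.0, epsilon=0.1, d=0.9)
        st = init_state(ring5_graph, params, sigma=0.0)
        res = simulate(ring5_graph, params, st, max_steps=50, tol=0.0)
        assert np.allclose(res.state.x, 0.2, atol=1e-15)

    def test_determinism_bit_identical(self, hetero_graph):
        params = ModelParams(R_km=6.0, epsilon=0.1, d=0.9)
        runs = []
        for _ in range(2):
            init = init_state(hetero_graph, params, seed=11)
            res = simulate(hetero_graph, params, init, max_steps=500, tol=0.0)
            runs.append(res.state)
        assert (runs[0].x == runs[1].x).all()
        assert (runs[0].w == runs[1].w).all()

    def test_nonconvergence_flags_warning_not_exception(self, baseline_lattice16):
        params = stability.baseline_params(d=0.9)
        init = init_state(baseline_lattice16.graph, params, seed=0)
        res = simulate(baseline_lattice16.graph, params, init, max_steps=10, tol=1e-14)
        assert not res.converged
        assert res.warning is not None

    def test_mass_conserved_over_long_run(self, baseline_lattice16):
        params = stability.baseline_params(d=0.9)
        init = init_state(baseline_lattice16.graph, params, seed=4)
        res = simulate(baseline_lattice16.graph, params, init, max_steps=2000, tol=0.0)
        assert abs(res.state.x.sum() - 1.0) < 1e-12


class TestGeographicalDeterminism:
    def test_flatland_stays_uniform(self, baseline_lattice16):
        params = stability.baseline_params(d=0.9)
        res = run_geographical_determinism(baseline_lattice16.graph, params)
        assert np.allclose(res.state.x, 1.0 / 256, atol=1e-12)

    def test_d_zero_uniform_regardless_of_landscape(self, hetero_graph):
        params = ModelParams(R_km=6.0, d=0.0)
        res = run_geographical_determinism(hetero_graph, params)
        assert np.allclose(res.state.x, 1.0 / hetero_graph.n_nodes)

    def test_narrow_range_compared_to_full_model(self, hetero_graph):
        params = ModelParams(R_km=6.0, epsilon=0.1, d=0.9)
        det = run_geographical_determinism(hetero_graph, params)
        init = init_state(hetero_graph, params, seed=0)
        full = simulate(hetero_graph, params, init, max_steps=8000)
        var_det = np.var(np.log(det.state.x))
        var_full = np.var(np.log(full.state.x))
        assert var_full > var_det


class TestScalePopulation:
    def test_uniform_scaling(self):
        assert np.allclose(scale_population(np.full(4, 0.25), 100.0), 25.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            scale_population(np.full(4, 0.25), 0.0)

    def test_total_preserved_for_random_x(self):
        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(50))
        assert scale_population(x, 12345.6).sum() == pytest.approx(12345.6, rel=1e-15)


class TestNetTraffic:
    def _two_node_setup(self):
        from ltpsim.landscape import generate_flatland

        grid = generate_flatland(1, 5, 2.0, periodic=False)
        locs = mobility.LocationSet(np.array([0, 0]), np.array([0, 4]), 2.0)
        cost = mobility.scenario_cost_params("flatland")
        graph = mobility.least_cost_distances(grid, cost, locs)
        mobility.attach_paths(graph, grid, cost)
        return grid, graph

    def test_two_node_flow_on_every_path_cell(self):
        grid, graph = self._two_node_setup()
        state = ModelState(x=np.array([0.6, 0.4]), w=np.array([1.0]))
        traffic = net_traffic(state, graph, grid)
        # single edge: T_ij = T_ji = 1, phi = x_i + x_j = 1
        assert np.allclose(traffic.values[0, :], 1.0)

    def test_total_deposit_equals_flow_times_path_length(self):
        grid, graph = self._two_node_setup()
        state = ModelState(x=np.array([0.6, 0.4]), w=np.array([1.0]))
        traffic = net_traffic(state, graph, grid)
        path_len = len(graph.paths[(0, 1)])
        assert traffic.values.sum() == pytest.approx(1.0 * path_len)

    def test_collinear_overlap_adds_flows(self):
        from ltpsim.landscape import generate_flatland

        grid = generate_flatland(1, 9, 2.0, periodic=False)
        locs = mobility.LocationSet(np.array([0, 0, 0]), np.array([0, 4, 8]), 2.0)
        cost = mobility.scenario_cost_params("flatland")
        graph = mobility.least_cost_distances(grid, cost, locs, r_max=20.0)
        mobility.attach_paths(graph, grid, cost)
        x = np.array([0.3, 0.4, 0.3])
        f = deterrence(graph.r_km, 8.0)
        w = equilibrium_connectivity(x, graph.edges, f)
        state = ModelState(x=x, w=w)
        traffic = net_traffic(state, graph, grid)
        # enumerate expected flows explicitly over the three edges
        n = 3
        s = np.zeros(n)
        for e, (i, j) in enumerate(graph.edges):
            s[i] += w[e]
            s[j] += w[e]
        expected = np.zeros(9)
        for e, (i, j) in enumerate(graph.edges):
            phi = w[e] / s[j] * x[j] + w[e] / s[i] * x[i]
            for cell in graph.paths[(int(i), int(j))]:
                expected[cell] += phi
        assert np.allclose(traffic.values[0, :], expected)
        # the middle node's cell carries both hops plus the long edge
        assert traffic.values[0, 4] > traffic.values[0, 2]

    def test_missing_path_raises(self):
        grid, graph = self._two_node_setup()
        graph.paths.clear()
        state = ModelState(x=np.array([0.5, 0.5]), w=np.array([1.0]))
        with pytest.raises(KeyError):
            net_traffic(state, graph, grid)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"R_km": 0.0},
            {"epsilon": 0.0},
            {"d": 1.5},
            {"d": -0.1},
            {"capacity": np.zeros(3)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
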