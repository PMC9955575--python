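"""Coupled tissue dynamics, attractor detection and cellular attractors."""

import numpy as np
import pytest

from bntissue.field import (
    FieldParams,
    LatticeSpec,
    SteadyStateSolver,
    extreme_config_concentrations,
    gamma_from_lambda,
)
from bntissue.network import (
    BooleanNetwork,
    critical_bias,
    generate_rbn,
    is_receptor_disconnected,
    update_internal,
)
from bntissue.regions import six_region_samples, two_node_network
from bntissue.tissue import (
    Tissue,
    cell_state_codes,
    make_tissue,
    run_asocial_reference,
    run_to_attractor,
    step,
    unique_cellular_attractors,
)


def _regulatory_only_network(n_reg, k, p, rng):
    """A network whose wiring never touches the receptor (severed wire)."""
    net = generate_rbn(n_reg, k, p, rng)
    wiring = net.wiring.copy()
    wiring[wiring == net.receptor_index] = rng.integers(0, n_reg)
    # re-draw rows that lost distinctness
    for j in range(wiring.shape[0]):
        while len(set(wiring[j].tolist())) < k:
            wiring[j] = rng.choice(np.arange(n_reg), size=k, replace=False)
    return BooleanNetwork(n_reg, k, wiring, net.truth_tables)


def _global_step_oracle(network, lattice, params, lam, theta, states):
    """Independent one-step evaluator: explicit field solve + per-cell
    threshold + per-cell lookup, no shared code path beyond the solver."""
    gamma = gamma_from_lambda(lam, params.D, params.R)
    eta = params.secretion_rates(states[:, network.signal_index])
    conc = SteadyStateSolver(lattice, params.D, gamma).solve(
        eta.reshape(lattice.dims)
    )
    flat = conc.reshape(-1)
    out = np.empty_like(states)
    for i in range(states.shape[0]):
        out[i] = update_internal(network, states[i], int(flat[i] > theta))
    return out


class TestStep:
    def test_threshold_unreachable_turns_receptors_off(self, params, rng):
        lattice = LatticeSpec((4, 4, 4), 20.0)
        net = two_node_network()
        states = np.ones((lattice.n_cells, 2), dtype=np.uint8)
        t = Tissue(net, lattice, params, lam=1.0, theta=1e9, states=states)
        nxt = step(t)
        assert not nxt.states[:, net.receptor_index].any()
        assert nxt.t == 1

    def test_basal_secretion_activates_below_c00(self, params):
        # theta below C00: basal secretion alone turns every receptor ON
        lattice = LatticeSpec((4, 4, 4), 20.0)
        c00, *_ = extreme_config_concentrations(1.0, params, lattice)
        net = two_node_network()
        states = np.zeros((lattice.n_cells, 2), dtype=np.uint8)
        t = Tissue(net, lattice, params, lam=1.0, theta=0.5 * c00, states=states)
        assert step(t).states[:, net.receptor_index].all()

    def test_matches_independent_one_step_oracle(self, params, rng):
        lattice = LatticeSpec((3, 3, 3), 20.0)
        net = generate_rbn(10, 3, critical_bias(3), rng)
        states = net.random_state(rng, lattice.n_cells)
        t = Tissue(net, lattice, params, lam=1.5, theta=3.0, states=states)
        expected = _global_step_oracle(net, lattice, params, 1.5, 3.0, states)
        np.testing.assert_array_equal(step(t).states, expected)

    def test_severed_receptor_equals_independent_cells(self, params, rng):
        # a network that ignores its receptor evolves as N closed cells
        lattice = LatticeSpec((3, 3, 3), 20.0)
        net = _regulatory_only_network(6, 2, 0.35, rng)
        assert is_receptor_disconnected(net)
        states = net.random_state(rng, lattice.n_cells)
        t = Tissue(net, lattice, params, lam=1.0, theta=2.0, states=states)
        cur = t
        per_cell = states.copy()
        for _ in range(10):
            cur = step(cur)
            # closed-system oracle: update each cell alone; receptor value
            # is irrelevant to the updatable nodes, pin it to the coupled
            # run's value for bitwise comparison
            rec = cur.states[:, net.receptor_index]
            nxt = np.empty_like(per_cell)
            for i in range(per_cell.shape[0]):
                nxt[i] = update_internal(net, per_cell[i], int(rec[i]))
            per_cell = nxt
            np.testing.assert_array_equal(cur.states, per_cell)


class TestRunToAttractor:
    def test_constant_zero_network_fixed_point(self, params, rng):
        lattice = LatticeSpec((3, 3, 3), 20.0)
        net = generate_rbn(4, 2, 0.4, rng)
        net = BooleanNetwork(4, 2, net.wiring, np.zeros_like(net.truth_tables))
        t = make_tissue(net, lattice, params, lam=1.0, theta=1e9, rng=rng)
        res = run_to_attractor(t, max_steps=50)
        assert res.found and res.period == 1 and res.transient <= 2
        assert not res.cycle[0][:, : net.n_updatable].any()

    def test_single_cell_two_cycle(self, params):
        # 3-node toy (NOT self-loop) on a 1-cell lattice, receptor OFF
        from bntissue.experiments import three_node_toy_network

        lattice = LatticeSpec((1, 1, 1), 20.0)
        net = three_node_toy_network()
        states = np.array([[1, 1, 0]], dtype=np.uint8)
        t = Tissue(net, lattice, params, lam=1.0, theta=1e9, states=states)
        res = run_to_attractor(t, max_steps=20)
        assert res.found and res.period == 2
        ca = res.cell_attractors()[0]
        # exhaustive oracle over the 2^3 state graph with receptor pinned 0
        oracle_states = set()
        cur = states[0]
        seen = {}
        hist = []
        for k in range(9):
            key = tuple(cur)
            if key in seen:
                cycle = hist[seen[key]:]
                oracle_states = {
                    int(cell_state_codes(np.array([s]))[0]) for s in cycle
                }
                break
            seen[key] = k
            hist.append(tuple(cur))
            cur = update_internal(net, cur, 0)
        assert ca == frozenset(oracle_states)

    def test_replaying_cycle_returns_identical_state(self, params, rng):
        lattice = LatticeSpec((3, 3, 3), 20.0)
        net = generate_rbn(10, 3, critical_bias(3), rng)
        t = make_tissue(net, lattice, params, lam=1.5, theta=3.0, rng=rng)
        res = run_to_attractor(t, max_steps=2000)
        assert res.found
        cur = Tissue(net, lattice, params, 1.5, 3.0, res.cycle[-1])
        nxt = step(cur)
        np.testing.assert_array_equal(nxt.states, res.cycle[0])

    def test_tiny_tissue_matches_exhaustive_oracle(self, params, rng, tiny_lattice):
        # 2 cells x 3 nodes: walk the trajectory with the independent
        # one-step oracle and find the first recurrence by brute force
        net = generate_rbn(1, 1, 0.5, rng)
        states = net.random_state(rng, tiny_lattice.n_cells)
        lam, theta = 1.0, 1.5
        t = Tissue(net, tiny_lattice, params, lam, theta, states)
        res = run_to_attractor(t, max_steps=2 ** (2 * 3) + 1)
        assert res.found
        seen, cur, k = {}, states, 0
        while True:
            key = cur.tobytes()
            if key in seen:
                oracle_transient, oracle_period = seen[key], k - seen[key]
                break
            seen[key] = k
            cur = _global_step_oracle(net, tiny_lattice, params, lam, theta, cur)
            k += 1
        assert (res.transient, res.period) == (oracle_transient, oracle_period)

    def test_timeout_is_result_not_exception(self, params, rng):
        lattice = LatticeSpec((3, 3, 3), 20.0)
        net = generate_rbn(10, 3, critical_bias(3), rng)
        t = make_tissue(net, lattice, params, lam=1.5, theta=3.0, rng=rng)
        res = run_to_attractor(t, max_steps=1)
        if not res.found:
            assert res.period == 0 and res.cycle == ()
            with pytest.raises(ValueError):
                res.cell_attractors()

    def test_severed_receptor_invariant_to_lambda_theta(self, params, rng):
        lattice = LatticeSpec((3, 3, 3), 20.0)
        net = _regulatory_only_network(6, 2, 0.35, rng)
        states = net.random_state(rng, lattice.n_cells)
        # the receptor bit still tracks the field, but with the wire severed
        # it cannot influence the updatable nodes: their trajectory is
        # identical for any (lambda, theta)
        trajectories = []
        for lam, theta in [(0.5, 0.1), (2.0, 5.0), (4.0, 100.0)]:
            cur = Tissue(net, lattice, params, lam, theta, states)
            traj = []
            for _ in range(30):
                cur = step(cur)
                traj.append(cur.states[:, : net.n_updatable].copy())
            trajectories.append(traj)
        for traj in trajectories[1:]:
            for a, b in zip(traj, trajectories[0]):
                np.testing.assert_array_equal(a, b)


class TestAsocialReferences:
    @pytest.mark.parametrize("mode,label", [("on", "A1"), ("self", "A2"), ("off", "A3")])
    def test_reference_equals_in_region_grid_point(self, params, rng, mode, label):
        # the closed-mode reference must reproduce the full coupled run at
        # any (lambda, theta) inside the corresponding asocial region
        lattice = LatticeSpec((3, 3, 3), 20.0)
        points = {lab: (lam, theta) for lab, lam, theta in
                  six_region_samples(params, lattice)}
        net = generate_rbn(10, 3, critical_bias(3), rng)
        states = net.random_state(rng, lattice.n_cells)
        lam, theta = points[label]
        coupled = run_to_attractor(
            Tissue(net, lattice, params, lam, theta, states), 2000
        )
        ref = run_asocial_reference(net, lattice, params, states, mode, 2000)
        assert coupled.found and ref.found
        assert (coupled.transient, coupled.period) == (ref.transient, ref.period)
        for a, b in zip(coupled.cycle, ref.cycle):
            np.testing.assert_array_equal(a, b)


class TestUniqueCellularAttractors:
    def test_homogeneous_fixed_point(self, params, rng):
        lattice = LatticeSpec((3, 3, 3), 20.0)
        net = generate_rbn(4, 2, 0.4, rng)
        net = BooleanNetwork(4, 2, net.wiring, np.zeros_like(net.truth_tables))
        t = make_tissue(net, lattice, params, lam=1.0, theta=1e9, rng=rng)
        res = run_to_attractor(t, 50)
        cas, assignment = unique_cellular_attractors(res)
        assert len(cas) == 1 and (assignment == 0).all()

    def test_matches_quadratic_comparison_oracle(self, params, rng):
        lattice = LatticeSpec((4, 4, 4), 20.0)
        net = generate_rbn(10, 3, critical_bias(3), rng)
        t = make_tissue(net, lattice, params, lam=1.5, theta=3.0, rng=rng)
        res = run_to_attractor(t, 2000)
        assert res.found
        cas, assignment = unique_cellular_attractors(res)
        per_cell = res.cell_attractors()
        # quadratic oracle: explicit pairwise set-equality grouping
        reps: list[frozenset] = []
        oracle_assign = []
        for ca in per_cell:
            for idx, rep in enumerate(reps):
                if ca == rep:
                    oracle_assign.append(idx)
                    break
            else:
                reps.append(ca)
                oracle_assign.append(len(reps) - 1)
        assert len(cas) == len(reps)
        np.testing.assert_array_equal(assignment, oracle_assign)

    def test_two_decoupled_groups_two_cas(self, params):
        # 2-cell lattice, severed receptor, cells started in different
        # fixed points of a 2-fixed-point network (identity regulatory node)
        lattice = LatticeSpec((2, 1, 1), 20.0)
        wiring = np.array([[0], [0]])
        tables = np.array([[0, 1], [0, 0]], dtype=np.uint8)  # copy; signal 0
        net = BooleanNetwork(1, 1, wiring, tables)
        states = np.array([[0, 0, 0], [1, 0, 0]], dtype=np.uint8)
        t = Tissue(net, lattice, params, lam=1.0, theta=1e9, states=states)
        res = run_to_attractor(t, 20)
        cas, assignment = unique_cellular_attractors(res)
        assert len(cas) == 2 and set(assignment.tolist()) == {0, 1}


def test_cell_state_codes_big_endian():
    states = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.uint8)
    np.testing.assert_array_equal(cell_state_codes(states), [5, 3])
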