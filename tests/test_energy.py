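import numpy as np
import pytest

from nnct import validate_connectome
from nnct.controllability import NormalizedSystem, normalize_adjacency
from nnct.energy import (
    ControlTask,
    build_target_state,
    network_energy_table,
    nodal_energy,
    solve_optimal_control,
)
from nnct.errors import DegenerateInputError, SolvabilityError, ValidationError
from nnct.io import Atlas

from _oracles import collocation_energy, minimum_energy_closed_form
from conftest import random_symmetric_normalized


def cont_system(A):
    return NormalizedSystem(A_norm=np.asarray(A, float), scale=1.0, mode="continuous")


def random_cont_system(n, seed):
    rng = np.random.default_rng(seed)
    return cont_system(random_symmetric_normalized(n, rng) - np.eye(n))


class TestTargetState:
    def test_membership_vector(self, small_atlas):
        assert np.array_equal(build_target_state(small_atlas, "visual"), [1, 1, 0])
        assert build_target_state(small_atlas, "somatomotor").sum() == 1

    def test_empty_network_rejected(self, small_atlas):
        with pytest.raises(DegenerateInputError):
            build_target_state(small_atlas, "frontoparietal")

    def test_unknown_network_rejected(self, small_atlas):
        with pytest.raises(ValidationError):
            build_target_state(small_atlas, "salience")


class TestSolveOptimalControl:
    def test_null_transition_is_free(self):
        S = random_cont_system(4, 0)
        traj = solve_optimal_control(
            S, ControlTask(x0=np.zeros(4), xT=np.zeros(4)), n_grid=201
        )
        assert np.allclose(traj.u, 0) and np.allclose(traj.x, 0)
        assert nodal_energy(traj).total == 0.0

    def test_permutation_symmetry_swaps_energies(self):
        # nodes 1<->2 symmetric; swapping the target swaps per-node energies
        A = np.array([[-1.0, 0.3, 0.1], [0.3, -1.0, 0.2], [0.1, 0.2, -1.0]])
        P = np.array([0, 2, 1])
        Ap = A[np.ix_(P, P)]
        xT = np.array([0.0, 1.0, 0.4])
        e1 = nodal_energy(
            solve_optimal_control(cont_system(A), ControlTask(x0=np.zeros(3), xT=xT))
        ).per_node
        e2 = nodal_energy(
            solve_optimal_control(cont_system(Ap), ControlTask(x0=np.zeros(3), xT=xT[P]))
        ).per_node
        assert np.allclose(e2, e1[P], rtol=1e-9)

    def test_scalar_closed_form_minimum_energy(self):
        # xdot = -x + u, 0 -> 1 over T=1: E = 1 / W_c(1), W_c = (1 - e^-2)/2
        S = cont_system([[-1.0]])
        task = ControlTask(x0=np.zeros(1), xT=np.ones(1), T=1.0, state_cost_on=False)
        E = nodal_energy(solve_optimal_control(S, task, n_grid=2001)).total
        Wc = (1 - np.exp(-2.0)) / 2.0
        assert np.isclose(E, 1.0 / Wc, rtol=1e-6)
        assert np.isclose(E, 2.3130, atol=5e-5)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_collocation_qp_oracle(self, seed):
        n = 3
        S = random_cont_system(n, seed)
        rng = np.random.default_rng(100 + seed)
        xT = rng.random(n)
        task = ControlTask(x0=np.zeros(n), xT=xT, T=1.0, state_cost_on=True)
        E = nodal_energy(solve_optimal_control(S, task, n_grid=2001)).total
        E_qp, _ = collocation_energy(S.A_norm, np.eye(n), np.zeros(n), xT, 1.0, True)
        assert abs(E - E_qp) / E_qp < 1e-3

    @pytest.mark.parametrize("seed", range(3))
    def test_state_cost_energy_dominates_minimum_energy(self, seed):
        n = 4
        S = random_cont_system(n, 10 + seed)
        xT = np.random.default_rng(seed).random(n)
        E_min = minimum_energy_closed_form(S.A_norm, np.eye(n), np.zeros(n), xT, 1.0)
        for state_cost in (False, True):
            task = ControlTask(x0=np.zeros(n), xT=xT, state_cost_on=state_cost)
            E = nodal_energy(solve_optimal_control(S, task, n_grid=1001)).total
            if state_cost:
                assert E >= E_min * (1 - 1e-9)
            else:
                # trapezoid quadrature on 1001 points: O(dt^2) error
                assert np.isclose(E, E_min, rtol=1e-5)

    def test_doubling_target_quadruples_minimum_energy(self):
        S = random_cont_system(3, 5)
        xT = np.array([1.0, 0.0, 0.5])
        def energy(scale):
            task = ControlTask(x0=np.zeros(3), xT=scale * xT, state_cost_on=False)
            return nodal_energy(solve_optimal_control(S, task)).total
        assert np.isclose(energy(2.0), 4.0 * energy(1.0), rtol=1e-9)

    def test_unreachable_target_raises(self):
        # decoupled nodes, control only node 0, target on node 1
        S = cont_system(-np.eye(2))
        task = ControlTask(
            x0=np.zeros(2), xT=np.array([0.0, 1.0]), control_set=(0,),
            state_cost_on=False,
        )
        with pytest.raises(SolvabilityError):
            solve_optimal_control(S, task)

    def test_endpoint_error_small(self):
        S = random_cont_system(8, 2)
        xT = np.random.default_rng(3).random(8)
        traj = solve_optimal_control(S, ControlTask(x0=np.zeros(8), xT=xT))
        assert traj.endpoint_error <= 1e-6


class TestNodalEnergy:
    def test_constant_control_integrates_to_square(self):
        times = np.linspace(0, 1, 101)
        traj_like = type("T", (), {})()
        from nnct.energy import OptimalTrajectory

        traj = OptimalTrajectory(
            times=times,
            x=np.zeros((2, 101)),
            p=np.zeros((2, 101)),
            u=np.vstack([np.full(101, 3.0), np.zeros(101)]),
            control_set=(0, 1),
            endpoint_error=0.0,
        )
        ep = nodal_energy(traj)
        assert np.isclose(ep.per_node[0], 9.0) and ep.per_node[1] == 0.0
        assert ep.total == pytest.approx(9.0)

    def test_grid_refinement_stability(self):
        S = random_cont_system(4, 9)
        xT = np.random.default_rng(9).random(4)
        task = ControlTask(x0=np.zeros(4), xT=xT)
        E1 = nodal_energy(solve_optimal_control(S, task, n_grid=101)).total
        E2 = nodal_energy(solve_optimal_control(S, task, n_grid=1001)).total
        assert abs(E1 - E2) / E2 < 1e-4


class TestNetworkEnergyTable:
    def test_eight_networks_for_canonical_atlas(self, params):
        from nnct.synth import default_atlas, generate_connectome

        C = generate_connectome(params, 40.0, "term", seed=0)
        table = network_energy_table(C, default_atlas(params), n_grid=201)
        assert len(table) == 8
        for ep in table.values():
            assert np.all(ep.per_node >= -1e-12)
            assert np.isclose(ep.total, ep.per_node.sum())

    def test_isolated_block_concentrates_energy(self):
        # visual nodes form an isolated block; activating visual must load
        # the block's own nodes more than any off-block node
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 0.5
        A[2, 3] = A[3, 2] = 0.5
        C = validate_connectome(["a", "b", "c", "d"], A)
        atlas = Atlas(
            node_ids=("a", "b", "c", "d"),
            labels=("A", "B", "C", "D"),
            lobes=("o",) * 4,
            networks=("visual", "visual", "somatomotor", "somatomotor"),
        )
        table = network_energy_table(C, atlas, n_grid=501)
        e = table["visual"].per_node
        assert min(e[0], e[1]) > max(e[2], e[3])

    def test_atlas_permutation_permutes_energies(self, params):
        from nnct.synth import default_atlas, generate_connectome

        C = generate_connectome(GeneratorParamsSmall(), 40.0, "term", seed=1)
        atlas = default_atlas(GeneratorParamsSmall())
        perm = np.random.default_rng(0).permutation(C.n_nodes)
        Cp = validate_connectome(
            [C.node_ids[i] for i in perm], C.A[np.ix_(perm, perm)]
        )
        atlas_p = Atlas(
            node_ids=tuple(atlas.node_ids[i] for i in perm),
            labels=tuple(atlas.labels[i] for i in perm),
            lobes=tuple(atlas.lobes[i] for i in perm),
            networks=tuple(atlas.networks[i] for i in perm),
        )
        t1 = network_energy_table(C, atlas, n_grid=201)
        t2 = network_energy_table(Cp, atlas_p, n_grid=201)
        for nw in t1:
            assert np.allclose(t2[nw].per_node, t1[nw].per_node[perm], rtol=1e-8)


def GeneratorParamsSmall():
    from nnct import GeneratorParams

    return GeneratorParams(n_nodes=16, n_modules=8)
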