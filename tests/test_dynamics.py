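import numpy as np
import pytest

import networkx as nx

from tfa_cycle.core_io import ActivityMatrix, DataValidationError, TimeGrid
from tfa_cycle.dynamics import (
    Edge,
    TransitionModel,
    asymptotic_modes,
    estimate_transition_nonneg,
    estimate_transition_unconstrained,
    export_network,
    extract_network,
    model_residuals,
    network_to_graph,
    normalize_oxygen,
    read_network_edgelist,
    simulate,
)
from tfa_cycle.synthetic_data import generate_linear_system


def activity_from_trajectory(traj, period_minutes=300.0):
    n_f, n_t = traj.shape
    times = tuple(25.0 * np.arange(n_t))
    grid = TimeGrid(times=times, period_minutes=period_minutes)
    ids = tuple(f"F{i}" for i in range(n_f))
    return ActivityMatrix(tf_ids=ids, grid=grid, alpha=traj)


def rotation_trajectory(angle_deg, n_steps=35, radius=1.0):
    a = np.deg2rad(angle_deg)
    T = radius * np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    traj = np.empty((2, n_steps + 1))
    traj[:, 0] = (1.0, 0.2)
    for s in range(1, n_steps + 1):
        traj[:, s] = T @ traj[:, s - 1]
    return T, traj


class TestNormalizeOxygen:
    def test_trace_matching_alpha_row_gets_that_scale(self, grid36):
        rng = np.random.default_rng(0)
        alpha = rng.normal(scale=0.3, size=(3, 36))
        act = ActivityMatrix(tf_ids=("A", "B", "C"), grid=grid36, alpha=alpha)
        row = normalize_oxygen(alpha[1], act)
        target = np.median(np.std(alpha, axis=1))
        assert np.std(row) == pytest.approx(target, abs=1e-9)

    def test_affine_invariance(self, grid36):
        rng = np.random.default_rng(1)
        alpha = rng.normal(size=(3, 36))
        act = ActivityMatrix(tf_ids=("A", "B", "C"), grid=grid36, alpha=alpha)
        trace = rng.normal(size=36)
        assert np.allclose(normalize_oxygen(trace, act),
                           normalize_oxygen(4.2 * trace - 7.0, act),
                           atol=1e-10)

    def test_constant_trace_rejected(self, grid36):
        act = ActivityMatrix(tf_ids=("A",), grid=grid36,
                             alpha=np.random.default_rng(2).normal(size=(1, 36)))
        with pytest.raises(DataValidationError, match="zero-variance"):
            normalize_oxygen(np.full(36, 3.0), act)


class TestUnconstrainedEstimation:
    def test_scalar_decay_recovered_exactly(self):
        traj = 0.9 ** np.arange(10)[None, :]
        times = tuple(25.0 * np.arange(10))
        act = ActivityMatrix(tf_ids=("F0",),
                             grid=TimeGrid(times=times, period_minutes=100.0),
                             alpha=traj)
        model = estimate_transition_unconstrained(act)
        assert model.T[0, 0] == pytest.approx(0.9, abs=1e-12)

    def test_recovers_random_stable_system(self):
        T_true, traj = generate_linear_system(5, 0.95, 35, 0.0, seed=3)
        model = estimate_transition_unconstrained(activity_from_trajectory(traj))
        assert np.linalg.norm(model.T - T_true) <= 1e-8
        # independent oracle: explicit normal-equations solve of B ~ T A
        A, B = traj[:, :-1], traj[:, 1:]
        T_oracle = np.linalg.solve(A @ A.T, A @ B.T).T
        assert np.allclose(model.T, T_oracle, atol=1e-8)

    def test_rotation_eigenvalue_angle_recovered(self):
        T_true, traj = rotation_trajectory(30.0)
        model = estimate_transition_unconstrained(activity_from_trajectory(traj))
        assert np.allclose(model.T, T_true, atol=1e-9)
        angles = np.abs(np.angle(np.linalg.eigvals(model.T)))
        assert np.rad2deg(angles.max()) == pytest.approx(30.0, abs=1e-9)

    def test_orientation_contract(self):
        # T applied to the activity at time t approximates time t+1
        T_true, traj = generate_linear_system(4, 0.9, 30, 0.0, seed=9)
        model = estimate_transition_unconstrained(activity_from_trajectory(traj))
        assert np.allclose(model.T @ model.A, model.B, atol=1e-8)

    def test_too_few_timepoints_rejected(self):
        traj = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(DataValidationError, match="identify"):
            estimate_transition_unconstrained(activity_from_trajectory(traj))


class TestNonnegEstimation:
    def test_equals_unconstrained_when_truth_nonneg(self):
        rng = np.random.default_rng(12)
        T_true = rng.uniform(0.0, 1.0, size=(4, 4))
        T_true *= 0.95 / max(abs(np.linalg.eigvals(T_true)))
        traj = np.empty((4, 31))
        traj[:, 0] = rng.uniform(0.5, 1.5, size=4)
        for s in range(1, 31):
            traj[:, s] = T_true @ traj[:, s - 1]
        act = activity_from_trajectory(traj)
        nn = estimate_transition_nonneg(act)
        un = estimate_transition_unconstrained(act)
        assert np.allclose(nn.T, un.T, atol=1e-8)
        assert np.allclose(nn.T, T_true, atol=1e-8)
        # KKT check of the active-set solution: feasible and stationary
        grad = (nn.T @ nn.A - nn.B) @ nn.A.T
        assert nn.T.min() >= 0
        assert np.all(grad[nn.T > 1e-10] < 1e-6)

    def test_negative_truth_entries_clamped_to_zero(self):
        T_true, traj = rotation_trajectory(30.0, radius=0.97)
        act = activity_from_trajectory(traj)
        nn = estimate_transition_nonneg(act)
        un = estimate_transition_unconstrained(act)
        assert nn.T.min() >= 0.0
        assert nn.T[0, 1] == pytest.approx(0.0, abs=1e-10)  # true entry < 0
        assert nn.frobenius_fit_residual > un.frobenius_fit_residual

    def test_zero_activity_gives_zero_matrix(self, grid36):
        act = ActivityMatrix(tf_ids=tuple("abc"), grid=grid36,
                             alpha=np.zeros((3, 36)))
        assert np.all(estimate_transition_nonneg(act).T == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_unconstrained_fit_never_worse(self, seed):
        _, traj = generate_linear_system(4, 0.9, 30, noise_sd=0.1, seed=seed)
        act = activity_from_trajectory(traj)
        un = estimate_transition_unconstrained(act)
        nn = estimate_transition_nonneg(act)
        assert un.frobenius_fit_residual <= nn.frobenius_fit_residual + 1e-12


class TestSimulateAndResiduals:
    def test_identity_keeps_trajectory_constant(self):
        model = TransitionModel(factor_ids=("a", "b"), T=np.eye(2),
                                constrained=False, A=np.zeros((2, 1)),
                                B=np.zeros((2, 1)))
        traj = simulate(model, np.array([1.0, -2.0]), 4)
        assert np.allclose(traj, np.array([[1.0], [-2.0]]) @ np.ones((1, 5)))

    def test_zero_matrix_dies_after_first_step(self):
        model = TransitionModel(factor_ids=("a",), T=np.zeros((1, 1)),
                                constrained=False, A=np.zeros((1, 1)),
                                B=np.zeros((1, 1)))
        traj = simulate(model, np.array([3.0]), 3)
        assert np.allclose(traj, [[3.0, 0.0, 0.0, 0.0]])

    def test_scalar_halving(self):
        model = TransitionModel(factor_ids=("a",), T=np.array([[0.5]]),
                                constrained=False, A=np.zeros((1, 1)),
                                B=np.zeros((1, 1)))
        traj = simulate(model, np.array([8.0]), 3)
        assert np.allclose(traj, [[8.0, 4.0, 2.0, 1.0]])

    def test_dimension_mismatch_rejected(self):
        model = TransitionModel(factor_ids=("a", "b"), T=np.eye(2),
                                constrained=False, A=np.zeros((2, 1)),
                                B=np.zeros((2, 1)))
        with pytest.raises(DataValidationError):
            simulate(model, np.ones(3), 2)

    def test_noiseless_self_fit_has_zero_residuals(self):
        _, traj = generate_linear_system(5, 0.95, 35, 0.0, seed=4)
        act = activity_from_trajectory(traj)
        model = estimate_transition_unconstrained(act)
        res = model_residuals(model, act)
        assert np.abs(res["mean_residual"]).max() <= 1e-8
        assert np.abs(res["rmse"]).max() <= 1e-8


class TestAsymptoticModes:
    def test_rotation_mode_period_and_modulus(self):
        T, _ = rotation_trajectory(30.0)
        model = TransitionModel(factor_ids=("a", "b"), T=T, constrained=False,
                                A=np.zeros((2, 1)), B=np.zeros((2, 1)))
        modes = asymptotic_modes(model)
        assert modes.iloc[0]["period_samples"] == pytest.approx(12.0)
        assert modes.iloc[0]["modulus"] == pytest.approx(1.0)

    def test_pure_decay_has_no_oscillatory_mode(self):
        model = TransitionModel(factor_ids=("a", "b"), T=0.9 * np.eye(2),
                                constrained=False, A=np.zeros((2, 1)),
                                B=np.zeros((2, 1)))
        modes = asymptotic_modes(model)
        assert not modes["oscillatory"].any()
        assert np.allclose(modes["modulus"], 0.9)

    def test_damped_rotation(self):
        T, _ = rotation_trajectory(30.0, radius=0.95)
        model = TransitionModel(factor_ids=("a", "b"), T=T, constrained=False,
                                A=np.zeros((2, 1)), B=np.zeros((2, 1)))
        modes = asymptotic_modes(model)
        assert modes.iloc[0]["period_samples"] == pytest.approx(12.0)
        assert modes.iloc[0]["modulus"] == pytest.approx(0.95)


def make_model(T, ids=None):
    k = T.shape[0]
    ids = ids or tuple(f"F{i + 1}" for i in range(k))
    return TransitionModel(factor_ids=ids, T=T, constrained=False,
                           A=np.zeros((k, 1)), B=np.zeros((k, 1)))


class TestExtractNetwork:
    def test_direct_application_with_self_loop(self):
        T = np.array([[0.6, -0.2], [-0.7, 0.1]])
        net = extract_network(make_model(T), 0.5)
        assert [(e.source, e.target, e.weight) for e in net.edges] == \
            [("F1", "F2", -0.7)]
        assert [(e.source, e.target) for e in net.self_loops] == [("F1", "F1")]

    def test_zero_matrix_gives_empty_network(self):
        net = extract_network(make_model(np.zeros((3, 3))), 0.5)
        assert net.edges == [] and net.self_loops == []

    def test_bidirectional_pair_keeps_larger_magnitude(self):
        # T[0,1] = -0.9: factor 2 -> factor 1; T[1,0] = 0.8: 1 -> 2
        T = np.array([[0.0, -0.9], [0.8, 0.0]])
        net = extract_network(make_model(T), 0.5)
        assert [(e.source, e.target, e.weight) for e in net.edges] == \
            [("F2", "F1", -0.9)]

    def test_exact_tie_keeps_both_flagged(self):
        T = np.array([[0.0, 0.8], [-0.8, 0.0]])
        net = extract_network(make_model(T), 0.5)
        assert len(net.edges) == 2
        assert all(e.tie for e in net.edges)

    def test_threshold_is_inclusive(self):
        T = np.array([[0.0, 0.5], [0.0, 0.0]])
        net = extract_network(make_model(T), 0.5)
        assert len(net.edges) == 1

    def test_invariant_to_factor_reordering(self):
        rng = np.random.default_rng(5)
        T = rng.normal(size=(4, 4))
        ids = ("w", "x", "y", "z")
        net = extract_network(make_model(T, ids), 0.5)
        perm = [2, 0, 3, 1]
        T_p = T[np.ix_(perm, perm)]
        ids_p = tuple(ids[i] for i in perm)
        net_p = extract_network(make_model(T_p, ids_p), 0.5)
        as_set = lambda n: {(e.source, e.target, round(e.weight, 12))
                            for e in n.edges}
        assert as_set(net) == as_set(net_p)


class TestExportNetwork:
    def _network(self):
        T = np.array([[0.0, -0.9], [0.8, 0.0]])
        T2 = np.array([[0.0, -0.9, 0.6], [0.0, 0.0, 0.0], [0.0, 0.7, 0.0]])
        return extract_network(make_model(T2), 0.5)

    def test_dot_export_lists_directed_edges(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.dot"
        export_network(net, path, fmt="dot")
        text = path.read_text()
        assert text.count("->") == len(net.edges) == 3

    def test_empty_network_exports_valid_graph(self, tmp_path):
        net = extract_network(make_model(np.zeros((2, 2))), 0.5)
        path = tmp_path / "net.graphml"
        export_network(net, path, fmt="graphml")
        g = nx.read_graphml(path)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 2

    def test_edge_list_round_trip(self, tmp_path):
        net = self._network()
        path = tmp_path / "edges.tsv"
        export_network(net, path, fmt="edgelist")
        back = read_network_edgelist(path, threshold=0.5)
        assert {(e.source, e.target, e.weight) for e in back.edges} == \
            {(e.source, e.target, e.weight) for e in net.edges}

    def test_graphml_preserves_weight_and_sign(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.graphml"
        export_network(net, path, fmt="graphml")
        g = nx.read_graphml(path)
        assert g.number_of_edges() == 3
        weights = {(u, v): d["weight"] for u, v, d in g.edges(data=True)}
        assert weights[("F2", "F1")] == pytest.approx(-0.9)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(DataValidationError, match="format"):
            export_network(self._network(), tmp_path / "x", fmt="json")

    def test_self_loops_excluded_from_graph_by_default(self):
        T = np.array([[0.9, 0.0], [0.8, 0.0]])
        net = extract_network(make_model(T), 0.5)
        g = network_to_graph(net)
        assert ("F1", "F1") not in g.edges
        net_incl = extract_network(make_model(T), 0.5, include_self_loops=True)
        assert ("F1", "F1") in network_to_graph(net_incl).edges
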