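"""Waypoints, pseudotime refinement, the absorbing chain and its fates."""

import numpy as np
import pandas as pd
import pytest

from vdjtraj.markov import (
    MarkovTrajectory,
    TrajectoryError,
    TrajectoryParams,
    absorption_probabilities,
    build_markov_chain,
    compute_pseudotime,
    identify_terminal_states,
    markov_probability,
    monte_carlo_absorption,
    rescue_dead_ends,
    select_waypoints,
)


def brute_force_waypoints(coords, n_waypoints, root):
    """Independent re-enumeration of the per-dimension max-min rule."""
    coords = np.atleast_2d(coords)
    n, d = coords.shape
    chosen = [root]
    dim = 0
    while len(chosen) < min(n_waypoints, n):
        best, best_score = None, -1.0
        for s in range(n):
            if s in chosen:
                continue
            score = min(abs(coords[s, dim] - coords[c, dim]) for c in chosen)
            if score > best_score:
                best, best_score = s, score
        chosen.append(best)
        dim = (dim + 1) % d
    return chosen


def y_coords():
    """Symmetric Y: a trunk along x then two mirror-image arms."""
    trunk = np.column_stack([np.linspace(0, 1, 12), np.zeros(12)])
    s = np.linspace(0.1, 1, 10)
    arm_a = np.column_stack([1 + s, s])
    arm_b = np.column_stack([1 + s, -s])
    return np.vstack([trunk, arm_a, arm_b])


class TestSelectWaypoints:
    def test_line_picks_extreme_then_middle(self):
        coords = np.arange(11.0)[:, None]
        assert select_waypoints(coords, 3, root=0).tolist() == [0, 10, 5]

    def test_matches_brute_force_on_random_coords(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(20, 3))
        got = select_waypoints(coords, 9, root=4)
        assert got.tolist() == brute_force_waypoints(coords, 9, 4)

    def test_saturation_returns_every_state(self):
        coords = np.random.default_rng(1).normal(size=(7, 2))
        assert sorted(select_waypoints(coords, 7, root=2).tolist()) == list(range(7))

    def test_duplicated_coordinates_never_selected_twice(self):
        coords = np.array([[0.0], [0.0], [0.0], [1.0]])
        wp = select_waypoints(coords, 4, root=0)
        assert len(set(wp.tolist())) == 4

    def test_fewer_than_two_waypoints_raises(self):
        with pytest.raises(ValueError):
            select_waypoints(np.zeros((3, 1)), 1, root=0)


class TestComputePseudotime:
    def test_unit_path_graph_is_exact_fixed_point(self):
        coords = np.arange(4.0)[:, None]
        pt, _ = compute_pseudotime(coords, 0, np.arange(4), k_traj=1, tol=1e-10, max_iter=200)
        assert np.allclose(pt, [0, 1, 2, 3], atol=1e-9)

    def test_nonnegative_with_root_at_zero(self):
        rng = np.random.default_rng(2)
        coords = np.sort(rng.random(30))[:, None]
        wp = select_waypoints(coords, 10, root=0)
        pt, _ = compute_pseudotime(coords, 0, wp, k_traj=4)
        assert pt.min() == 0.0
        assert pt[0] < 1e-6
        assert (pt >= 0).all()

    def test_symmetric_y_gives_equal_tip_pseudotimes(self):
        """Mirror-image branch tips end at matching pseudotime.

        Exact equality is unattainable: the before/after perspective rule
        is discontinuous at pseudotime ties, which makes the perfectly
        symmetric fixed point exponentially unstable, so the two tips
        agree to a small fraction of the pseudotime range rather than to
        machine precision.
        """
        coords = y_coords()
        wp = select_waypoints(coords, len(coords), root=0)
        pt, _ = compute_pseudotime(coords, 0, wp, k_traj=3, tol=1e-8, max_iter=200)
        tip_a, tip_b = 12 + 9, 22 + 9  # arm endpoints
        assert abs(pt[tip_a] - pt[tip_b]) < 0.03 * pt.max()

    def test_disconnected_graph_reports_component_sizes(self):
        coords = np.array([[0.0], [0.1], [100.0], [100.1]])
        with pytest.raises(TrajectoryError, match=r"\[2, 2\]"):
            compute_pseudotime(coords, 0, np.array([0, 2]), k_traj=1)


class TestBuildMarkovChain:
    def test_increasing_line_keeps_only_forward_edges(self):
        coords = np.arange(10.0)[:, None]
        pt = np.arange(10.0)
        T = build_markov_chain(coords, pt, k_mc=2)
        # upper-triangular under pseudotime order, apart from the final state
        lower = np.tril(T, k=-1)
        assert lower[:-1].max() == 0.0
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)

    def test_constant_pseudotime_prunes_nothing(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(12, 2))
        T = build_markov_chain(coords, np.zeros(12), k_mc=4)
        assert (T > 0).sum() == 12 * 4  # every directed KNN edge survives
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)

    def test_rows_sum_to_one_on_random_input(self):
        rng = np.random.default_rng(4)
        T = build_markov_chain(rng.normal(size=(30, 3)), rng.random(30), k_mc=6)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)


class TestTerminalStates:
    def test_linear_chain_ends_at_last_state(self):
        coords = np.arange(15.0)[:, None]
        pt = np.arange(15.0)
        T = build_markov_chain(coords, pt, k_mc=2)
        term = identify_terminal_states(T, pt)
        assert term.tolist() == [14]

    def test_symmetric_y_finds_both_tips(self):
        coords = y_coords()
        wp = select_waypoints(coords, len(coords), root=0)
        pt, _ = compute_pseudotime(coords, 0, wp, k_traj=3, tol=1e-8, max_iter=200)
        T = build_markov_chain(coords, pt, k_mc=3)
        term = set(identify_terminal_states(T, pt).tolist())
        assert term == {21, 31}  # the two arm endpoints

    def test_no_candidates_is_impossible_by_construction_but_errors(self):
        # a doubly-stochastic cyclic chain has uniform stationary mass and
        # no self-loops: nothing stands out as terminal
        T = np.roll(np.eye(6), 1, axis=1)
        with pytest.raises(TrajectoryError, match="terminal"):
            identify_terminal_states(T, np.arange(6.0))


class TestAbsorption:
    def test_one_step_chain(self):
        T = np.array([[0.0, 0.3, 0.7], [0, 1, 0], [0, 0, 1]])
        B = absorption_probabilities(T, np.array([1, 2]))
        assert np.allclose(B.iloc[0], [0.3, 0.7])

    def test_two_step_composition(self):
        T = np.array(
            [[0, 1, 0, 0], [0, 0, 0.5, 0.5], [0, 0, 1, 0], [0, 0, 0, 1.0]]
        )
        B = absorption_probabilities(T, np.array([2, 3]))
        assert np.allclose(B.iloc[0], [0.5, 0.5])

    def test_shared_labels_merge_into_one_fate(self):
        T = np.array([[0.0, 0.4, 0.6], [0, 1, 0], [0, 0, 1]])
        B = absorption_probabilities(
            T, np.array([1, 2]), labels=np.array(["X", "fate", "fate"])
        )
        assert list(B.columns) == ["fate"]
        assert B.iloc[0, 0] == pytest.approx(1.0)

    def test_unreachable_state_raises_naming_it(self):
        T = np.eye(3)
        T[0, 0] = 0.0
        T[0, 1] = 1.0
        # state 2 is absorbing but not in the terminal set -> state 2 and
        # nothing else can reach terminal 1? state 2 self-loops forever
        with pytest.raises(TrajectoryError, match=r"\[2\]"):
            absorption_probabilities(T, np.array([1]))

    def test_matches_linear_solve_and_monte_carlo_on_random_chains(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(4, 11))
            T = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
            for i in range(n):
                if T[i].sum() == 0:
                    T[i, rng.integers(n)] = 1.0
                T[i, rng.integers(n - 2, n)] += 0.3
            T = T / T.sum(axis=1, keepdims=True)
            term = np.array([n - 2, n - 1])
            B = absorption_probabilities(T, term).to_numpy()
            # independent oracle 1: direct linear solve
            Tc = T.copy()
            Tc[term, :] = 0.0
            Tc[term, term] = 1.0
            trans = np.arange(n - 2)
            X = np.linalg.solve(
                np.eye(n - 2) - Tc[np.ix_(trans, trans)], Tc[np.ix_(trans, term)]
            )
            assert np.abs(B[trans] - X).max() < 1e-10
            # independent oracle 2: Monte-Carlo walks
            F = monte_carlo_absorption(T, term, n_walks=20000, seed=trial)
            p = B[trans]
            se = np.sqrt(np.clip(p * (1 - p), 1e-12, None) / 20000)
            z = np.abs(F[trans] - p) / np.maximum(se, 1e-9)
            assert (z <= 3).mean() > 0.99
            assert z.max() < 6


class TestRescueDeadEnds:
    def test_closed_non_terminal_class_gets_escape_edge(self):
        # states 0,1 form a closed 2-cycle; 2 is the genuine terminal
        T = np.array([[0.0, 1, 0], [1, 0, 0], [0, 0, 1.0]])
        coords = np.array([[0.0], [0.1], [1.0]])
        pt = np.array([0.0, 0.1, 1.0])
        fixed = rescue_dead_ends(T, coords, pt, np.array([2]))
        B = absorption_probabilities(fixed, np.array([2]))
        assert np.allclose(B.to_numpy(), 1.0)

    def test_chain_already_absorbing_is_untouched(self):
        T = np.array([[0.0, 0.5, 0.5], [0, 1, 0], [0, 0, 1.0]])
        fixed = rescue_dead_ends(T, np.arange(3.0)[:, None], np.arange(3.0), np.array([1, 2]))
        assert np.allclose(fixed, T)


@pytest.fixture(scope="module")
def y_feature_frame():
    rng = np.random.default_rng(11)
    coords = np.repeat(y_coords(), 3, axis=0)
    coords = coords + rng.normal(scale=0.01, size=coords.shape)
    labels = (["trunk"] * 36) + (["tipA"] * 30) + (["tipB"] * 30)
    df = pd.DataFrame(coords, index=[f"s{i}" for i in range(len(coords))])
    return df, pd.Series(labels, index=df.index)


class TestMarkovTrajectoryModel:
    def test_bifurcation_conserves_probability(self, y_feature_frame):
        df, labels = y_feature_frame
        model = MarkovTrajectory(
            df, root="s0", labels=labels, params=TrajectoryParams(k_dm=10, ka=4)
        )
        res = model.fit()
        assert np.allclose(res.branch_probs.sum(axis=1), 1.0, atol=1e-6)
        assert len(res.fates) == 2

    def test_results_summary_mentions_fates(self, y_feature_frame):
        df, labels = y_feature_frame
        res = MarkovTrajectory(
            df, root="s0", labels=labels, params=TrajectoryParams(k_dm=10, ka=4)
        ).fit()
        text = res.summary()
        for fate in res.fates:
            assert fate in text

    def test_user_supplied_terminals_bypass_detection(self, y_feature_frame):
        df, labels = y_feature_frame
        res = MarkovTrajectory(
            df,
            root="s0",
            terminal_states=["s64", "s94"],
            labels=labels,
            params=TrajectoryParams(k_dm=10, ka=4),
        ).fit()
        assert set(res.terminal_states) == {"s64", "s94"}

    def test_state_permutation_invariance(self, y_feature_frame):
        df, labels = y_feature_frame
        params = TrajectoryParams(k_dm=10, ka=4)
        res1 = MarkovTrajectory(df, root="s0", labels=labels, params=params).fit()
        perm = np.random.default_rng(0).permutation(len(df))
        res2 = MarkovTrajectory(
            df.iloc[perm], root="s0", labels=labels.iloc[perm], params=params
        ).fit()
        pd.testing.assert_series_equal(
            res1.pseudotime.sort_index(),
            res2.pseudotime.sort_index(),
            atol=1e-6,
            check_exact=False,
        )

    def test_error_carries_stage_name(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 3)))
        with pytest.raises((TrajectoryError, ValueError)):
            MarkovTrajectory(df, root=999).fit()
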