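import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqmeg.task import (ACTIONS, TrialSpec, best_plan, build_task_graph,
                         choice_model_probs, drift_rewards, enumerate_plans,
                         evaluate_plan, fit_and_compare, fit_model,
                         generate_session, greedy_plan, plan_values,
                         session_to_frame, frame_to_session, simulate_choices)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

class TestBuildTaskGraph:
    def test_default_successors_of_s1(self, graph):
        assert {graph.successor(1, a) for a in ACTIONS} == {2, 5}

    def test_default_contains_required_edges(self, graph):
        edges = set(graph.edges())
        assert (1, 2) in edges and (1, 5) in edges
        assert (4, 5) in edges and (5, 6) in edges

    def test_rows_sum_to_one(self, T):
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_rows_have_two_half_entries(self, T):
        for row in T:
            nz = row[row != 0]
            assert len(nz) == 2 and np.all(nz == 0.5)

    def test_no_self_loops(self, T):
        assert np.all(np.diag(T) == 0)

    def test_rejects_self_loop(self):
        spec = {s: {"up": s % 6 + 1, "down": (s + 3) % 6 + 1} for s in range(1, 7)}
        spec[3] = {"up": 3, "down": 1}
        with pytest.raises(ValueError, match="self-loop"):
            build_task_graph(spec)

    def test_rejects_duplicate_successor(self):
        spec = {s: {"up": s % 6 + 1, "down": (s + 3) % 6 + 1} for s in range(1, 7)}
        spec[2] = {"up": 4, "down": 4}
        with pytest.raises(ValueError, match="differ"):
            build_task_graph(spec)

    def test_rejects_out_of_range(self):
        spec = {s: {"up": s % 6 + 1, "down": (s + 3) % 6 + 1} for s in range(1, 7)}
        spec[1] = {"up": 7, "down": 5}
        with pytest.raises(ValueError, match="out of range"):
            build_task_graph(spec)

    def test_custom_edge_spec(self):
        spec = {1: {"up": 2, "down": 3}, 2: {"up": 3, "down": 1},
                3: {"up": 1, "down": 2}}
        g = build_task_graph(spec, n_states=3)
        assert g.transition_matrix.shape == (3, 3)
        np.testing.assert_allclose(g.transition_matrix.sum(axis=1), 1.0)

    def test_q_table_size(self, graph):
        assert graph.q_table_size() == 12


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

class TestEnumeratePlans:
    def test_depth4_gives_16(self):
        assert len(enumerate_plans(4)) == 16

    def test_depth1_gives_2(self):
        assert enumerate_plans(1) == [("down",), ("up",)]

    def test_depth3_gives_8_of_length_3(self):
        plans = enumerate_plans(3)
        assert len(plans) == 8
        assert all(len(p) == 3 for p in plans)

    def test_unique_and_sorted(self):
        plans = enumerate_plans(4)
        assert len(set(plans)) == 16
        assert plans == sorted(plans)

    def test_rejects_depth_zero(self):
        with pytest.raises(ValueError):
            enumerate_plans(0)


def _trial(start=1, negs=(3, 6), rewards=(0, 0, 0, 0, 0, 0)):
    return TrialSpec(start_state=start, neg_states=frozenset(negs),
                     rewards=tuple(rewards))


class TestEvaluatePlan:
    def test_neg_flip_minus9_to_plus9(self, graph):
        # walk S1 -up-> S2 -up-> S3; rewards put the total at -9 entering S3,
        # which is neg, so the running total flips to +9
        trial = _trial(start=1, negs=(3, 6), rewards=(0, -4, -5, 0, 0, 0))
        out = evaluate_plan(graph, trial, ("up", "up", "up", "up"))
        assert out.running_totals[1] == 9

    def test_zero_rewards_zero_earnings(self, graph):
        trial = _trial()
        for plan in enumerate_plans():
            assert evaluate_plan(graph, trial, plan).earnings == 0

    def test_hand_stepped_example(self, graph):
        # up = +1 edge: path S2,S3,S4,S5 collecting 1+2+3+4 = 10
        trial = _trial(start=1, negs=(6, 5), rewards=(0, 1, 2, 3, 4, 5))
        trial = TrialSpec(1, frozenset({6, 2}), (0, 1, 2, 3, 4, 5))
        out = evaluate_plan(graph, trial, ("up", "up", "up", "up"))
        assert out.path == (2, 3, 4, 5)
        # S2 is neg here: 1 -> -1, then +2 -> 1, +3 -> 4, +4 -> 8
        assert out.earnings == 8
        trial = TrialSpec(1, frozenset({6, 1}), (0, 1, 2, 3, 4, 5))
        assert evaluate_plan(graph, trial, ("up",) * 4).earnings == 10

    def test_start_state_reward_not_collected(self, graph):
        trial = TrialSpec(1, frozenset({3, 6}), (5, 0, 0, 0, 0, 0))
        out = evaluate_plan(graph, trial, ("up", "up", "up", "up"))
        assert out.path == (2, 3, 4, 5)  # start S1 never re-entered
        assert out.earnings == 0

    def test_invalid_action(self, graph):
        with pytest.raises(ValueError):
            evaluate_plan(graph, _trial(), ("up", "left", "up", "up"))

    @given(v=st.integers(min_value=-40, max_value=40))
    @settings(max_examples=25, deadline=None)
    def test_sign_flip_property(self, v):
        """Entering a neg state with pre-flip total v leaves total -v."""
        g = build_task_graph()
        # state 2 neg with reward 0; reach pre-flip total v at S2 via S1 reward? S1
        # is the start (not collected) so set S2's reward to v directly.
        vv = max(min(v, 5), -5)
        trial = TrialSpec(1, frozenset({2, 4}), (0, vv, 0, 0, 0, 0))
        out = evaluate_plan(g, trial, ("up", "up", "up", "up"))
        assert out.running_totals[0] == -vv


class TestTrialSpec:
    def test_rejects_single_neg(self):
        with pytest.raises(ValueError):
            TrialSpec(1, frozenset({2}), (0,) * 6)

    def test_rejects_out_of_bound_rewards(self):
        with pytest.raises(ValueError):
            TrialSpec(1, frozenset({2, 3}), (6, 0, 0, 0, 0, 0))


# ---------------------------------------------------------------------------
# Reward drift and sessions
# ---------------------------------------------------------------------------

class TestDriftRewards:
    def test_stays_in_bounds_and_integer(self, rng):
        r = (5, -5, 0, 3, -2, 1)
        for _ in range(1000):
            r = drift_rewards(r, rng)
            assert all(isinstance(v, int) for v in r)
            assert all(-5 <= v <= 5 for v in r)

    def test_boundary_never_increases(self, rng):
        for _ in range(200):
            r = drift_rewards((5,) * 6, rng)
            assert all(v <= 5 for v in r)

    def test_step_frequencies(self):
        rng = np.random.default_rng(0)
        steps = np.array([drift_rewards((0,) * 6, rng) for _ in range(10_000)])
        for delta in (-1, 0, 1):
            freq = np.mean(steps == delta)
            assert abs(freq - 1 / 3) < 0.02


class TestGenerateSession:
    def test_deterministic_under_seed(self, graph):
        s1 = generate_session(graph, 20, np.random.default_rng(5))
        s2 = generate_session(graph, 20, np.random.default_rng(5))
        assert s1 == s2

    def test_neg_states_distinct(self, graph, rng):
        for t in generate_session(graph, 50, rng):
            assert len(t.neg_states) == 2

    def test_adversarial_filter_margin(self, graph, rng):
        trials = generate_session(graph, 10, rng, adversarial_filter=True,
                                  margin=2)
        for t in trials:
            _, vb = best_plan(graph, t)
            _, vg = greedy_plan(graph, t)
            assert vb - vg >= 2

    def test_rewards_drift_between_trials(self, graph, rng):
        trials = generate_session(graph, 30, rng)
        assert len({t.rewards for t in trials}) > 1


# ---------------------------------------------------------------------------
# Choice models
# ---------------------------------------------------------------------------

class TestChoiceModelProbs:
    def test_zero_temperature_uniform(self, graph, rng):
        trial = generate_session(graph, 1, rng)[0]
        p = choice_model_probs("Plan", {"beta": 0.0}, graph, trial)
        np.testing.assert_allclose(p, 1 / 16)

    def test_probabilities_normalized(self, graph, rng):
        trial = generate_session(graph, 1, rng)[0]
        p = choice_model_probs("Plan", {"beta": 1.3}, graph, trial)
        assert np.all(p >= 0) and abs(p.sum() - 1) < 1e-12

    def test_large_beta_argmax(self, graph, rng):
        trial = generate_session(graph, 1, rng)[0]
        p = choice_model_probs("Plan", {"beta": 1e6}, graph, trial)
        values = plan_values(graph, trial)
        winners = values == values.max()
        np.testing.assert_allclose(p[winners], 1 / winners.sum(), atol=1e-9)
        np.testing.assert_allclose(p[~winners], 0, atol=1e-9)

    def test_nonfinite_params_rejected(self, graph, rng):
        trial = generate_session(graph, 1, rng)[0]
        with pytest.raises(ValueError):
            choice_model_probs("Plan", {"beta": np.nan}, graph, trial)

    def test_greedy_rows_normalized(self, graph, rng):
        trial = generate_session(graph, 1, rng)[0]
        p = choice_model_probs("Greedy", {"beta": 0.7}, graph, trial,
                               chosen_plan=("up", "down", "up", "up"))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


class TestFitting:
    def test_plan_temperature_recovery(self, graph):
        rng = np.random.default_rng(11)
        trials = generate_session(graph, 200, rng)
        plans = simulate_choices(graph, trials, "Plan", {"beta": 1.0}, rng)
        fit = fit_model("Plan", graph, trials, plans)
        assert abs(fit.params["beta"] - 1.0) / 1.0 < 0.2

    def test_best_plan_consistent_with_plan_model(self, graph, rng):
        trial = generate_session(graph, 1, rng)[0]
        plan, value = best_plan(graph, trial)
        p = choice_model_probs("Plan", {"beta": 50.0}, graph, trial)
        assert enumerate_plans()[int(np.argmax(p))] in [
            pl for pl, v in zip(enumerate_plans(), plan_values(graph, trial))
            if v == value]

    def test_random_choices_favor_uniform_baseline(self, graph):
        rng = np.random.default_rng(3)
        trials = generate_session(graph, 80, rng)
        plans = simulate_choices(graph, trials, "Uniform", {"beta": 0.0}, rng)
        fits = fit_and_compare(plans, graph, trials)
        assert fits[0].model_name == "Uniform"

    def test_degenerate_choices_warn(self, graph, rng):
        trials = generate_session(graph, 5, rng)
        plans = [("up", "up", "up", "up")] * 5
        with pytest.warns(UserWarning, match="degenerate"):
            fit_and_compare(plans, graph, trials, model_names=("Uniform",))

    def test_fit_reports_are_valid(self, graph):
        rng = np.random.default_rng(4)
        trials = generate_session(graph, 30, rng)
        plans = simulate_choices(graph, trials, "Plan", {"beta": 2.0}, rng)
        for fit in fit_and_compare(plans, graph, trials):
            assert fit.log_likelihood <= 0
            assert np.isfinite(fit.bic)


class TestCsvRoundTrip:
    def test_session_frame_round_trip(self, graph, rng):
        trials = generate_session(graph, 12, rng)
        plans = simulate_choices(graph, trials, "Plan", {"beta": 1.0}, rng)
        frame = session_to_frame(graph, trials, plans)
        t2, p2 = frame_to_session(frame, graph)
        assert t2 == trials and p2 == plans
        assert list(frame["earnings"]) == [
            evaluate_plan(graph, t, p).earnings for t, p in zip(trials, plans)]
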