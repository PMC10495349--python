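"""Simulator: class assignment, feeder state machine, generative properties."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_events, null_overrides, small_config
from premnet import analytics as an
from premnet import sim
from premnet.sim import FeederState, REWARD_ACCESS, TaskState, step_task_state


# ---------------------------------------------------------------------------
# treatment-class assignment
# ---------------------------------------------------------------------------


class TestAssignClasses:
    def test_four_pairs_split_equally(self, rng):
        ids = [f"x{i}" for i in range(8)]
        pairs = [(ids[0], ids[1]), (ids[2], ids[3]), (ids[4], ids[5]), (ids[6], ids[7])]
        classes = sim.assign_classes(ids, pairs, [], rng)
        combos = sorted("".join(sorted((classes[a], classes[b]))) for a, b in pairs)
        assert combos == ["AA", "AB", "AB", "BB"]

    def test_regulars_split_equally(self, rng):
        regs = [f"r{i}" for i in range(10)]
        classes = sim.assign_classes(regs, [], regs, rng)
        counts = pd.Series(list(classes.values())).value_counts()
        assert counts["A"] == counts["B"] == 5

    def test_duplicate_pair_member_rejected(self, rng):
        with pytest.raises(ValueError):
            sim.assign_classes(["a", "b", "c"], [("a", "b"), ("b", "c")], [], rng)

    def test_regular_overlapping_pair_rejected(self, rng):
        with pytest.raises(ValueError):
            sim.assign_classes(["a", "b"], [("a", "b")], ["a"], rng)

    def test_unsupervised_coin_is_fair(self):
        rng = np.random.default_rng(1234)
        ids = [f"u{i}" for i in range(10_000)]
        classes = sim.assign_classes(ids, [], [], rng)
        frac_a = np.mean([classes[i] == "A" for i in ids])
        se = np.sqrt(0.25 / len(ids))
        assert abs(frac_a - 0.5) < 3 * se

    def test_odd_pair_count_rounds_down(self, rng):
        ids = [f"x{i}" for i in range(10)]
        pairs = [(ids[2 * k], ids[2 * k + 1]) for k in range(5)]
        classes = sim.assign_classes(ids, pairs, [], rng)
        same = sum(classes[a] == classes[b] for a, b in pairs)
        assert same == 2  # floor(5 / 2)


# ---------------------------------------------------------------------------
# feeder state machine
# ---------------------------------------------------------------------------


class TestTaskStateMachine:
    def test_reward_access_is_function_of_state(self):
        assert REWARD_ACCESS[FeederState.DEFAULT] == (True, False)
        assert REWARD_ACCESS[FeederState.LOCKOUT] == (False, False)
        assert REWARD_ACCESS[FeederState.SUCCESS] == (True, True)
        assert REWARD_ACCESS[FeederState.SUCCESS_OVERRIDE] == (False, True)

    def test_successful_dyad_opens_high_reward(self):
        new = step_task_state(TaskState(), "dyad", True, 1.0)
        assert new.state is FeederState.SUCCESS
        assert new.high_reward_accessible
        # the reward stays open for at least 15 s from onset even if the
        # dyad leaves immediately
        after_leave = step_task_state(new, "empty", False, 5.0)
        assert after_leave.state is FeederState.SUCCESS
        later = step_task_state(after_leave, "empty", False, 20.0)
        assert later.state is FeederState.DEFAULT

    def test_unsuccessful_dyad_triggers_full_lockout(self):
        new = step_task_state(TaskState(), "dyad", False, 1.0)
        assert new.state is FeederState.LOCKOUT
        assert new.lockout_remaining == 120.0

    def test_lockout_override_gives_high_quality_only(self):
        locked = TaskState(FeederState.LOCKOUT, lockout_remaining=60.0)
        new = step_task_state(locked, "dyad", True, 1.0)
        assert new.state is FeederState.SUCCESS_OVERRIDE
        assert new.high_reward_accessible and not new.low_reward_accessible

    def test_lockout_expiry_returns_to_default(self):
        locked = TaskState(FeederState.LOCKOUT, lockout_remaining=30.0)
        assert step_task_state(locked, "empty", False, 31.0).state is FeederState.DEFAULT
        still = step_task_state(locked, "solo", False, 10.0)
        assert still.state is FeederState.LOCKOUT
        assert still.lockout_remaining == 20.0

    def test_lockout_restarts_on_further_failure(self):
        locked = TaskState(FeederState.LOCKOUT, lockout_remaining=5.0)
        new = step_task_state(locked, "dyad", False, 1.0)
        assert new.state is FeederState.LOCKOUT
        assert new.lockout_remaining == 120.0

    def test_override_ending_early_reverts_to_lockout(self):
        over = TaskState(
            FeederState.SUCCESS_OVERRIDE, lockout_remaining=100.0, success_elapsed=20.0
        )
        new = step_task_state(over, "solo", False, 1.0)
        assert new.state is FeederState.LOCKOUT
        assert new.lockout_remaining > 0

    def test_lockout_expiry_during_success_grants_both(self):
        over = TaskState(
            FeederState.SUCCESS_OVERRIDE, lockout_remaining=10.0, success_elapsed=5.0
        )
        new = step_task_state(over, "dyad", True, 15.0)
        assert new.state is FeederState.SUCCESS
        assert new.low_reward_accessible and new.high_reward_accessible

    def test_failure_straight_after_success_bypasses_default(self):
        succ = TaskState(FeederState.SUCCESS, success_elapsed=30.0)
        new = step_task_state(succ, "dyad", False, 1.0)
        assert new.state is FeederState.LOCKOUT
        assert new.lockout_remaining == 120.0

    def test_invalid_inputs_fail_loudly(self):
        with pytest.raises(ValueError):
            step_task_state(TaskState(), "crowd", True, 1.0)
        with pytest.raises(ValueError):
            step_task_state(TaskState(), "dyad", True, 0.0)

    def test_exhaustive_transitions_stay_in_state_space(self):
        """From every reachable cell the successor is a defined state."""
        states = [
            TaskState(),
            TaskState(FeederState.LOCKOUT, lockout_remaining=120.0),
            TaskState(FeederState.LOCKOUT, lockout_remaining=1.0),
            TaskState(FeederState.SUCCESS, success_elapsed=1.0),
            TaskState(FeederState.SUCCESS, success_elapsed=40.0),
            TaskState(
                FeederState.SUCCESS_OVERRIDE,
                lockout_remaining=60.0,
                success_elapsed=5.0,
            ),
            TaskState(
                FeederState.SUCCESS_OVERRIDE,
                lockout_remaining=2.0,
                success_elapsed=30.0,
            ),
        ]
        seen = set()
        for task, occ, match, dt in itertools.product(
            states, ("empty", "solo", "dyad"), (True, False), (0.5, 1.0, 10.0, 200.0)
        ):
            new = step_task_state(task, occ, match, dt)
            seen.add(new.state)
            assert new.state in FeederState
            assert new.lockout_remaining >= 0
            # timer invariant holds after every step
            if new.lockout_remaining > 0:
                assert new.state in (
                    FeederState.LOCKOUT,
                    FeederState.SUCCESS_OVERRIDE,
                )
        assert seen == set(FeederState)


# ---------------------------------------------------------------------------
# generative model
# ---------------------------------------------------------------------------


class TestSimulateExperiment:
    def test_reproducible_given_seed(self):
        a = sim.simulate_experiment(small_config(7))
        b = sim.simulate_experiment(small_config(7))
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.visits, b.visits)
        pd.testing.assert_frame_equal(a.individuals, b.individuals)

    def test_juveniles_absent_before_entry_day(self, null_result):
        entry = dict(
            zip(null_result.individuals["id"], null_result.individuals["entry_day"])
        )
        v = null_result.visits
        first_seen = v.groupby("tag_id")["day"].min()
        for tag, day in first_seen.items():
            assert day >= entry[tag]

    def test_no_self_events_and_positive_durations(self, null_result):
        e = null_result.events
        assert (e["source"] != e["target"]).all()
        assert (e["duration"] > 0).all()
        assert (e["latency"] >= 0).all()
        assert e["index"].tolist() == list(range(1, len(e) + 1))

    def test_outcome_matches_class_combination(self, null_result):
        cm = null_result.class_map()
        e = null_result.events
        expected = np.array([cm[s] == cm[t] for s, t in zip(e["source"], e["target"])])
        assert (e["is_same_class"].to_numpy() == expected).all()
        assert (e["outcome"].to_numpy() == np.where(expected, "success", "fail")).all()

    def test_null_stream_matches_random_mixing(self):
        """Uniform partner choice reproduces the analytic same-class fraction."""
        cfg = small_config(
            11,
            n_mate_pairs=0,
            n_sibling_groups=0,
            n_parent_offspring_links=0,
            rate_heterogeneity=50.0,
            site_fidelity=0.5,
            **null_overrides(),
        )
        res = sim.simulate_experiment(cfg)
        ind = res.individuals
        n_a = int((ind["treatment_class"] == "A").sum())
        expected = an.expected_same_class_fraction(
            an.ClassTally(n_a, len(ind) - n_a)
        )
        frac = res.events["is_same_class"].mean()
        se = np.sqrt(expected * (1 - expected) / len(res.events))
        assert abs(frac - expected) < 4 * se

    def test_learning_raises_same_class_fraction(self, null_result, learning_result):
        null_frac = null_result.events["is_same_class"].mean()
        e = learning_result.events
        late = e[e["index"] > len(e) // 2]["is_same_class"].mean()
        assert late > null_frac + 0.05

    def test_affiliate_preference_overrepresents_affiliates(self):
        """With a large affiliate bonus, affiliate dyads join more often.

        The bonus acts on the join decision, whose baseline probability is
        1/2, so its effect on the affiliate event share is bounded; compare
        against the same experiment with the bonus switched off.
        """
        shares = {}
        for theta in (0.0, 4.0):
            pooled = []
            for seed in (13, 14, 15):
                cfg = small_config(
                    seed,
                    learning_rate=0.0,
                    affiliate_weight=theta,
                    affiliate_co_arrival=0.0,
                )
                res = sim.simulate_experiment(cfg)
                pooled.append(res.events["is_affiliate"].mean())
            shares[theta] = np.mean(pooled)
        assert shares[4.0] > 1.3 * shares[0.0]

    def test_replay_task_states_is_consistent(self, null_result):
        states = sim.replay_task_states(
            null_result.events.head(200), null_result.config
        )
        assert len(states) == 200
        for st in states:
            assert st.state in FeederState
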