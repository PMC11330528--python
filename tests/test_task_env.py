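"""Tests for the block-switching task environment."""

import random

import pytest

from taskswitch.task_env import (ActionType, BlockType, EnvConfig, SessionLog,
                                 TaskCue, TaskEnv, TransitionVariant,
                                 _finalise_trial_record, check_block_switch,
                                 schedule_transition_cue)

LICK, NO_LICK = ActionType.LICK, ActionType.NO_LICK


def perfect_action(env: TaskEnv) -> int:
    """Lick exactly when the current cue is the rewarded final-step cue."""
    cue = env.current_cue
    final = env.step_index_in_trial == len(env._cues) - 1
    return LICK if final and cue in (TaskCue.VISUAL_1, TaskCue.ODOUR_1) \
        else NO_LICK


def run_perfect(env: TaskEnv, n_trials: int) -> SessionLog:
    done = 0
    while done < n_trials:
        out = env.step(perfect_action(env))
        if out.trial_ended:
            done += 1
    return env.drain_log()


class TestReset:
    def test_seeded_determinism_of_cue_sequence(self):
        seqs = []
        for _ in range(2):
            env = TaskEnv(EnvConfig(seed=7))
            cues = []
            for _ in range(100):
                cues.append(env.current_cue)
                env.step(perfect_action(env))
            seqs.append(cues)
        assert seqs[0] == seqs[1]

    def test_initial_state_is_visual_block_trial_zero(self):
        env = TaskEnv(EnvConfig(seed=0))
        assert env.block_type == BlockType.VISUAL
        assert env.trial_index == 0 and env.step_index_in_trial == 0
        assert env.current_cue == TaskCue.END_OF_TRIAL

    @pytest.mark.parametrize("p, expected_steps", [(1.0, {3}), (0.0, {2})])
    def test_irrelevant_cue_forcing_controls_odour_trial_length(self, p, expected_steps):
        env = TaskEnv(EnvConfig(seed=3, p_irrelevant_visual=p))
        log = run_perfect(env, 100)
        odour_trials = [t for t in log.trials
                        if t.block_type == BlockType.ODOUR]
        assert len(odour_trials) > 20
        assert {len(t.steps) for t in odour_trials} == expected_steps

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TaskEnv(EnvConfig(p_irrelevant_visual=1.5))
        with pytest.raises(ValueError):
            TaskEnv(EnvConfig(block_accuracy_window=0))
        with pytest.raises(ValueError):
            TaskEnv(EnvConfig(max_block_trials=10, block_accuracy_window=30))


class TestStepRewards:
    def collect(self, env, n_steps, policy):
        rows = []
        for _ in range(n_steps):
            cue = env.current_cue
            final = env.step_index_in_trial == len(env._cues) - 1
            a = policy(env)
            out = env.step(a)
            rows.append((env.block_type, cue, final, a, out.reward))
        return rows

    def test_reward_table(self):
        """Lick at the final step pays +1 for cue 1, -1 for cue 2; needless
        licks cost -1; withholding is always 0."""
        env = TaskEnv(EnvConfig(seed=5))
        always_lick = self.collect(env, 3000, lambda e: LICK)
        for block, cue, final, _a, r in always_lick:
            if final:
                assert r == (1.0 if cue in (TaskCue.VISUAL_1, TaskCue.ODOUR_1)
                             else -1.0)
            else:
                assert r == -1.0
        env = TaskEnv(EnvConfig(seed=5))
        never_lick = self.collect(env, 3000, lambda e: NO_LICK)
        assert all(r == 0.0 for *_, r in never_lick)

    def test_rewards_bounded_and_one_per_step(self, fresh_env, rng):
        for _ in range(2000):
            out = fresh_env.step(rng.choice([LICK, NO_LICK]))
            assert out.reward in (-1.0, 0.0, 1.0)

    def test_invalid_action_rejected(self, fresh_env):
        with pytest.raises(ValueError):
            fresh_env.step(7)


def _mk_trial(block_type, relevant_correct, irrelevant=None):
    """Fabricate a minimal TrialRecord with given correctness flags."""
    if block_type == BlockType.VISUAL:
        cue = TaskCue.VISUAL_1
        action = LICK if relevant_correct else NO_LICK
        steps = [(int(TaskCue.END_OF_TRIAL), 0, 0.0, False),
                 (int(cue), int(action), 0.0, False)]
    else:
        steps = [(int(TaskCue.END_OF_TRIAL), 0, 0.0, False)]
        if irrelevant is not None:
            steps.append((int(TaskCue.VISUAL_1),
                          int(NO_LICK if irrelevant else LICK), 0.0, False))
        steps.append((int(TaskCue.ODOUR_1),
                      int(LICK if relevant_correct else NO_LICK), 0.0, False))
    return _finalise_trial_record(block_type, 0, 0, 0, steps, False)


class TestBlockSwitchCriterion:
    cfg = EnvConfig()

    def test_odour_block_full_criterion(self):
        tail = [_mk_trial(BlockType.ODOUR, True, irrelevant=True)
                for _ in range(30)]
        assert check_block_switch(tail, self.cfg) is True

    def test_window_not_filled(self):
        tail = [_mk_trial(BlockType.VISUAL, True) for _ in range(29)]
        assert check_block_switch(tail, self.cfg) is False

    @pytest.mark.parametrize("n_correct", range(0, 31))
    def test_strict_inequality_against_threshold(self, n_correct):
        # exhaustively: exactly 24/30 (80%) must NOT trigger, 25/30 must
        tail = [_mk_trial(BlockType.VISUAL, i < n_correct) for i in range(30)]
        assert check_block_switch(tail, self.cfg) is (n_correct > 24)

    def test_recent_irrelevant_lick_blocks_switch(self):
        tail = [_mk_trial(BlockType.ODOUR, True, irrelevant=True)
                for _ in range(29)]
        tail.append(_mk_trial(BlockType.ODOUR, True, irrelevant=False))
        assert check_block_switch(tail, self.cfg) is False
        # the same lapse more than 10 trials back is forgiven
        tail = ([_mk_trial(BlockType.ODOUR, True, irrelevant=False)]
                + [_mk_trial(BlockType.ODOUR, True, irrelevant=True)] * 30)
        assert check_block_switch(tail, self.cfg) is True


class TestTransitionPeriod:
    def test_forced_cue_outside_transition_is_error(self, fresh_env):
        with pytest.raises(RuntimeError):
            schedule_transition_cue(fresh_env, fresh_env.config)

    def _reach_transition(self, variant, into):
        env = TaskEnv(EnvConfig(seed=2, transition_variant=variant))
        # drive perfectly until we are in a transition into `into`
        for _ in range(40_000):
            out = env.step(perfect_action(env))
            if out.block_switched and env.block_type == into:
                return env
        raise AssertionError("never reached the requested transition")

    def test_odour_to_visual_forces_rewarded_grating(self):
        env = self._reach_transition(TransitionVariant.V1, BlockType.VISUAL)
        cue, forced = schedule_transition_cue(env, env.config)
        assert cue == TaskCue.VISUAL_1 and forced

    def test_visual_to_odour_variant1_first_cue_is_unrewarded_grating(self):
        env = self._reach_transition(TransitionVariant.V1, BlockType.ODOUR)
        cue, forced = schedule_transition_cue(env, env.config)
        assert cue == TaskCue.VISUAL_2 and forced
        env.transition_irrelevant_count = 1
        cue, _ = schedule_transition_cue(env, env.config)
        assert cue == TaskCue.VISUAL_1

    def test_visual_to_odour_variant2_forces_rewarded_grating(self):
        env = self._reach_transition(TransitionVariant.V2, BlockType.ODOUR)
        cue, forced = schedule_transition_cue(env, env.config)
        assert cue == TaskCue.VISUAL_1 and forced

    def test_free_sampling_resumes_at_half_probability(self):
        # after 3 consecutive correct responses the forcing stops and
        # VISUAL_1 is drawn 50/50
        env = TaskEnv(EnvConfig(seed=4))
        log = run_perfect(env, 12_000)
        free_visual = [t for t in log.trials
                       if t.block_type == BlockType.VISUAL
                       and not t.transition_phase]
        frac_v1 = sum(t.steps[-1][0] == TaskCue.VISUAL_1
                      for t in free_visual) / len(free_visual)
        assert len(free_visual) > 5000
        assert abs(frac_v1 - 0.5) < 0.02


class TestSessionInvariants:
    def test_perfect_policy_blocks_have_minimal_length(self):
        # a perfect agent satisfies the 30-trial criterion immediately, so
        # every block lasts exactly 30 trials
        env = TaskEnv(EnvConfig(seed=9))
        log = run_perfect(env, 190)
        assert log.block_boundaries[:6] == [30, 60, 90, 120, 150, 180]

    def test_block_types_alternate(self):
        env = TaskEnv(EnvConfig(seed=10))
        log = run_perfect(env, 400)
        types = [log.trials[0].block_type] + log.transition_directions()
        assert all(a != b for a, b in zip(types, types[1:]))

    def test_long_run_irrelevant_fraction(self):
        # odour-block trials carry an irrelevant grating at the configured
        # 70% rate
        env = TaskEnv(EnvConfig(seed=12))
        log = run_perfect(env, 11_000)
        odour = [t for t in log.trials if t.block_type == BlockType.ODOUR]
        frac3 = sum(t.irrelevant_shown for t in odour) / len(odour)
        assert len(odour) >= 5000
        assert abs(frac3 - 0.70) < 0.02

    def test_random_agent_blocks_are_capped(self):
        env = TaskEnv(EnvConfig(seed=13, max_block_trials=60))
        r = random.Random(0)
        for _ in range(20_000):
            env.step(r.choice([LICK, NO_LICK]))
        log = env.drain_log()
        assert log.capped_blocks  # a random agent never meets the criterion
        assert all(b - a <= 60 for a, b in
                   zip([0] + log.block_boundaries, log.block_boundaries))


class TestSessionLogIO:
    def test_csv_round_trip(self, tmp_path):
        env = TaskEnv(EnvConfig(seed=14))
        log = run_perfect(env, 120)
        path = tmp_path / "session.csv"
        log.to_csv(path)
        back = SessionLog.read_csv(path)
        assert len(back.trials) == len(log.trials)
        assert back.block_boundaries == log.block_boundaries
        assert back.to_frame().equals(log.to_frame())
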