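"""Discrete step-based simulator of the cross-modal block-switching task.

Mice (or agents) alternate between *visual* blocks, in which two drifting
gratings must be discriminated, and *odour* blocks, in which two odours must
be discriminated while the same gratings, now task-irrelevant, precede 70% of
the odours.  The task is discretised into steps: every trial starts with an
end-of-trial cue (a lick here is a needless lick and is punished), odour-block
trials may contain an irrelevant visual cue (a lick there is also punished),
and the final step presents the reward-relevant cue, where licking to
stimulus 1 is rewarded (+1), licking to stimulus 2 punished (-1) and
withholding always yields 0.

Blocks switch automatically once performance on the relevant stimuli exceeds
80% over the last 30 trials (strictly) and, in odour blocks, all irrelevant
gratings over the last 10 trials were ignored.  Immediately after a switch a
*transition period* forces the stimulus sequence (see
:func:`schedule_transition_cue`) until three consecutive correct responses.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import IntEnum
from typing import NamedTuple, Optional

__all__ = [
    "TaskCue",
    "ActionType",
    "BlockType",
    "TransitionVariant",
    "EnvConfig",
    "StepOutcome",
    "TrialRecord",
    "SessionLog",
    "TaskEnv",
    "reset",
    "check_block_switch",
    "schedule_transition_cue",
]


class TaskCue(IntEnum):
    """The five task states: two gratings, two odours, and the end-of-trial cue."""

    VISUAL_1 = 0  # rewarded grating (in visual blocks)
    VISUAL_2 = 1  # unrewarded grating
    ODOUR_1 = 2   # rewarded odour
    ODOUR_2 = 3   # unrewarded odour
    END_OF_TRIAL = 4


class ActionType(IntEnum):
    NO_LICK = 0
    LICK = 1


class BlockType(IntEnum):
    VISUAL = 0
    ODOUR = 1


class TransitionVariant(IntEnum):
    """Stimulus-forcing variants for the visual-to-odour transition period.

    V1: the first forced irrelevant grating is the unrewarded VISUAL_2 (so the
    block change is signalled by the unexpected odour, not a reward omission),
    subsequent forced irrelevant gratings are VISUAL_1.
    V2: every forced irrelevant grating is VISUAL_1.
    """

    V1 = 1
    V2 = 2


@dataclass
class EnvConfig:
    p_irrelevant_visual: float = 0.70
    block_accuracy_threshold: float = 0.80  # strict >
    block_accuracy_window: int = 30
    ignore_window: int = 10
    transition_variant: TransitionVariant = TransitionVariant.V1
    reward_correct: float = 1.0
    punish: float = -1.0
    max_block_trials: int = 500
    first_block: BlockType = BlockType.VISUAL
    # If set, transition periods last exactly this many trials instead of
    # running until three consecutive correct responses.
    fixed_transition_trials: Optional[int] = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_irrelevant_visual <= 1.0:
            raise ValueError("p_irrelevant_visual must be in [0, 1]")
        if not 0.0 <= self.block_accuracy_threshold <= 1.0:
            raise ValueError("block_accuracy_threshold must be in [0, 1]")
        if self.block_accuracy_window <= 0 or self.ignore_window <= 0:
            raise ValueError("criterion windows must be positive")
        if self.max_block_trials < self.block_accuracy_window:
            raise ValueError("max_block_trials must be >= block_accuracy_window")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


class StepOutcome(NamedTuple):
    reward: float
    trial_ended: bool
    block_switched: bool
    cue_presented: TaskCue
    forced_cue: bool


@dataclass
class TrialRecord:
    """One trial: 2 steps, or 3 in odour-block trials with an irrelevant grating."""

    __slots__ = (
        "block_type", "block_index", "trial_index", "trial_index_in_block",
        "steps", "correct", "relevant_correct", "irrelevant_shown",
        "irrelevant_ignored", "transition_phase",
    )

    block_type: BlockType
    block_index: int
    trial_index: int
    trial_index_in_block: int
    steps: list  # of (cue:int, action:int, reward:float, forced:bool)
    correct: bool            # relevant response correct AND no needless licks
    relevant_correct: bool   # correct response at the final (reward) step
    irrelevant_shown: bool
    irrelevant_ignored: Optional[bool]  # None when no irrelevant cue was shown
    transition_phase: bool


@dataclass
class SessionLog:
    """Ordered record of trials; the common currency of behavioural analysis."""

    trials: list = field(default_factory=list)
    block_boundaries: list = field(default_factory=list)  # global index of first trial of each new block
    capped_blocks: list = field(default_factory=list)     # block indices force-ended by max_block_trials
    config: Optional[EnvConfig] = None
    seed: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_transitions(self) -> int:
        return len(self.block_boundaries)

    def transition_directions(self) -> list:
        """Per transition, the BlockType of the *new* block."""
        return [self.trials[i].block_type for i in self.block_boundaries]

    def to_frame(self):
        """One row per step: the CSV serialisation layout."""
        import pandas as pd

        rows = []
        for t in self.trials:
            for step_index, (cue, action, reward, forced) in enumerate(t.steps):
                rows.append((
                    t.block_index, BlockType(t.block_type).name, t.trial_index,
                    step_index, TaskCue(cue).name, ActionType(action).name,
                    reward, forced, t.transition_phase,
                ))
        return pd.DataFrame(rows, columns=[
            "block_index", "block_type", "trial_index", "step_index",
            "cue", "action", "reward", "forced", "transition_phase",
        ])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df) -> "SessionLog":
        log = cls()
        prev_block = None
        for (block_index, block_type, trial_index), g in df.groupby(
            ["block_index", "block_type", "trial_index"], sort=True
        ):
            g = g.sort_values("step_index")
            steps = [
                (int(TaskCue[c]), int(ActionType[a]), float(r), bool(f))
                for c, a, r, f in zip(g["cue"], g["action"], g["reward"], g["forced"])
            ]
            bt = BlockType[block_type]
            rec = _finalise_trial_record(
                bt, int(block_index), int(trial_index),
                trial_index_in_block=0, steps=steps,
                transition_phase=bool(g["transition_phase"].iloc[0]),
            )
            if prev_block is not None and block_index != prev_block:
                log.block_boundaries.append(len(log.trials))
            prev_block = block_index
            log.trials.append(rec)
        # recover within-block indices
        start = 0
        for b in log.block_boundaries + [len(log.trials)]:
            for j, t in enumerate(log.trials[start:b]):
                t.trial_index_in_block = j
            start = b
        return log

    @classmethod
    def read_csv(cls, path) -> "SessionLog":
        import pandas as pd

        return cls.from_frame(pd.read_csv(path))


_FINAL_REWARDED = (TaskCue.VISUAL_1, TaskCue.ODOUR_1)


def _finalise_trial_record(block_type, block_index, trial_index,
                           trial_index_in_block, steps, transition_phase):
    """Derive the correctness flags from a trial's raw step tuples."""
    cue_f, act_f, _, _ = steps[-1]
    if cue_f in _FINAL_REWARDED:
        relevant_correct = act_f == ActionType.LICK
    else:
        relevant_correct = act_f == ActionType.NO_LICK
    needless = any(a == ActionType.LICK for _, a, _, _ in steps[:-1])
    irrelevant_shown = False
    irrelevant_ignored = None
    if block_type == BlockType.ODOUR and len(steps) == 3:
        irrelevant_shown = True
        irrelevant_ignored = steps[1][1] == ActionType.NO_LICK
    return TrialRecord(
        block_type=block_type, block_index=block_index,
        trial_index=trial_index, trial_index_in_block=trial_index_in_block,
        steps=steps, correct=relevant_correct and not needless,
        relevant_correct=relevant_correct, irrelevant_shown=irrelevant_shown,
        irrelevant_ignored=irrelevant_ignored, transition_phase=transition_phase,
    )


def check_block_switch(log_tail, config: EnvConfig) -> bool:
    """Has the current block's switch criterion been met?

    ``log_tail`` holds the trials of the current block only.  The criterion is
    strictly >80% (by default) correct responses to the relevant stimuli over
    the last 30 trials, plus, in odour blocks, every irrelevant grating over
    the last 10 trials ignored.  Returns False while fewer than 30 trials
    exist.
    """
    w = config.block_accuracy_window
    if len(log_tail) < w:
        return False
    recent = log_tail[-w:]
    n_correct = sum(1 for t in recent if t.relevant_correct)
    if n_correct <= config.block_accuracy_threshold * w:
        return False
    if recent[-1].block_type == BlockType.ODOUR:
        for t in log_tail[-config.ignore_window:]:
            if t.irrelevant_shown and not t.irrelevant_ignored:
                return False
    return True


def schedule_transition_cue(state: "TaskEnv", config: EnvConfig) -> tuple:
    """The forced visual cue for the next trial of a transition period.

    Odour-to-visual: the rewarded grating VISUAL_1 is forced until three
    consecutive correct licks.  Visual-to-odour: the *irrelevant* grating is
    forced -- variant V1 makes the first one VISUAL_2 and the rest VISUAL_1,
    variant V2 forces VISUAL_1 throughout; odour identity stays random.

    Returns ``(cue, forced_flag=True)``.
    """
    if not state.in_transition_period:
        raise RuntimeError("schedule_transition_cue called outside a transition period")
    if state.block_type == BlockType.VISUAL:
        return TaskCue.VISUAL_1, True
    if (config.transition_variant == TransitionVariant.V1
            and state.transition_irrelevant_count == 0):
        return TaskCue.VISUAL_2, True
    return TaskCue.VISUAL_1, True


class TaskEnv:
    """Mutable environment state; also serves as the ``EnvState`` record.

    The generator is seeded from ``config.seed``, so a given seed and action
    sequence reproduce the session bit-for-bit.
    """

    def __init__(self, config: Optional[EnvConfig] = None):
        self.config = config or EnvConfig()
        self.config.validate()
        self.reset()

    # -- state ------------------------------------------------------------
    def reset(self) -> "TaskEnv":
        cfg = self.config
        self.rng = random.Random(cfg.seed)
        self.block_type = cfg.first_block
        self.block_index = 0
        self.trial_index = 0
        self.trial_index_in_block = 0
        self.in_transition_period = False
        self.consecutive_correct_in_transition = 0
        self.transition_irrelevant_count = 0
        self.transition_trial_count = 0
        self._block_trials = []  # TrialRecords of the current block
        self._log = SessionLog(config=cfg, seed=cfg.seed)
        self._begin_trial()
        return self

    @property
    def current_cue(self) -> int:
        return self._cues[self._step_index]

    @property
    def step_index_in_trial(self) -> int:
        return self._step_index

    # -- trial construction ----------------------------------------------
    def _begin_trial(self) -> None:
        cfg = self.config
        rng = self.rng
        forced_mid = False
        forced_final = False
        if self.block_type == BlockType.VISUAL:
            if self.in_transition_period:
                final, forced_final = schedule_transition_cue(self, cfg)
            else:
                final = TaskCue.VISUAL_1 if rng.random() < 0.5 else TaskCue.VISUAL_2
            cues = [TaskCue.END_OF_TRIAL, final]
            forced = [False, forced_final]
        else:
            has_irrelevant = rng.random() < cfg.p_irrelevant_visual
            odour = TaskCue.ODOUR_1 if rng.random() < 0.5 else TaskCue.ODOUR_2
            if has_irrelevant:
                if self.in_transition_period:
                    vis, forced_mid = schedule_transition_cue(self, cfg)
                else:
                    vis = TaskCue.VISUAL_1 if rng.random() < 0.5 else TaskCue.VISUAL_2
                cues = [TaskCue.END_OF_TRIAL, vis, odour]
                forced = [False, forced_mid, False]
            else:
                cues = [TaskCue.END_OF_TRIAL, odour]
                forced = [False, False]
        self._cues = cues
        self._forced = forced
        self._step_index = 0
        self._steps = []

    # -- stepping ---------------------------------------------------------
    def step(self, action) -> StepOutcome:
        action = int(action)
        if action not in (0, 1):
            raise ValueError(f"invalid action {action!r}")
        cfg = self.config
        cue = self._cues[self._step_index]
        forced = self._forced[self._step_index]
        final = self._step_index == len(self._cues) - 1
        if final:
            if action == ActionType.LICK:
                reward = cfg.reward_correct if cue in _FINAL_REWARDED else cfg.punish
            else:
                reward = 0.0
        else:
            reward = cfg.punish if action == ActionType.LICK else 0.0
        self._steps.append((int(cue), action, reward, forced))
        if not final:
            self._step_index += 1
            return StepOutcome(reward, False, False, cue, forced)
        switched = self._end_trial()
        self._begin_trial()
        return StepOutcome(reward, True, switched, cue, forced)

    def _end_trial(self) -> bool:
        cfg = self.config
        rec = _finalise_trial_record(
            self.block_type, self.block_index, self.trial_index,
            self.trial_index_in_block, self._steps, self.in_transition_period,
        )
        self._log.trials.append(rec)
        self._block_trials.append(rec)
        self.trial_index += 1
        self.trial_index_in_block += 1

        # transition-period bookkeeping
        if self.in_transition_period:
            self.transition_trial_count += 1
            if rec.irrelevant_shown:
                self.transition_irrelevant_count += 1
            if cfg.fixed_transition_trials is not None:
                if self.transition_trial_count >= cfg.fixed_transition_trials:
                    self.in_transition_period = False
            else:
                if self.block_type == BlockType.VISUAL:
                    # three consecutive correct licks to the forced grating
                    if rec.relevant_correct:
                        self.consecutive_correct_in_transition += 1
                    else:
                        self.consecutive_correct_in_transition = 0
                else:
                    # three consecutive correctly ignored irrelevant gratings
                    if rec.irrelevant_shown:
                        if rec.irrelevant_ignored:
                            self.consecutive_correct_in_transition += 1
                        else:
                            self.consecutive_correct_in_transition = 0
                if self.consecutive_correct_in_transition >= 3:
                    self.in_transition_period = False

        switched = check_block_switch(self._block_trials, cfg)
        capped = not switched and len(self._block_trials) >= cfg.max_block_trials
        if capped:
            self._log.capped_blocks.append(self.block_index)
        if switched or capped:
            self.block_index += 1
            self.block_type = (BlockType.ODOUR if self.block_type == BlockType.VISUAL
                               else BlockType.VISUAL)
            self.trial_index_in_block = 0
            self._block_trials = []
            self.in_transition_period = True
            self.consecutive_correct_in_transition = 0
            self.transition_irrelevant_count = 0
            self.transition_trial_count = 0
            # boundary index is relative to the current log segment
            self._log.block_boundaries.append(len(self._log.trials))
            return True
        return False

    # -- log access -------------------------------------------------------
    def drain_log(self) -> SessionLog:
        """Return completed trials accumulated since the last drain.

        The environment keeps running (current block state is preserved), so
        a training segment can be drained away and a test segment collected
        afterwards from the same session.
        """
        out = self._log
        # a boundary recorded after the last completed trial belongs to the
        # next segment
        out.block_boundaries = [b for b in out.block_boundaries if b < len(out.trials)]
        self._log = SessionLog(config=self.config, seed=self.config.seed)
        return out


def reset(config: Optional[EnvConfig] = None) -> TaskEnv:
    """Create a fresh environment in a visual block at trial 0, step 0."""
    return TaskEnv(config)
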