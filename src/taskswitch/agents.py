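"""Behavioural models: tabular SARSA and belief-state reinforcement learning.

Two agents act on the task of :mod:`taskswitch.task_env`:

* ``BasicSarsaAgent`` -- a single Q-table over the four stimulus cues and two
  actions, updated on-policy with the TD error delta = r + Q(s', a') - Q(s, a)
  scaled by a learning rate alpha, and an epsilon-greedy policy.

* ``BeliefStateAgent`` -- two Q-tables (one per block context) gated by a
  belief b = (p_visual, p_odour) over the current context.  At each trial end
  the context detected from the final cue, d (one-hot), is compared to the
  belief to give a mismatch signal chi = d - b.  A noise-corrupted version
  chi' = chi * (1 + beta * xi), with a single standard-normal xi per trial,
  drives the belief update b' = b + zeta * chi' (clipped positive and
  renormalised).  Optional silencing factors scale chi before the noise,
  emulating partial suppression of the neural prediction-error signal.

The end-of-trial cue has its Q-values pinned at zero in both agents, so the
policy at that cue is an (epsilon-greedy) coin flip and licks there are pure
internal-cost noise; they never enter the per-stimulus lick probabilities
used for fitting.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

from .task_env import (ActionType, BlockType, SessionLog, TaskCue, TaskEnv)

__all__ = [
    "QTable",
    "TDError",
    "BasicAgentParams",
    "BeliefAgentParams",
    "BeliefState",
    "MismatchRecord",
    "select_action",
    "sarsa_update",
    "compute_mismatch",
    "corrupt_mismatch",
    "update_belief",
    "assumed_block",
    "BasicSarsaAgent",
    "BeliefStateAgent",
    "run_agent",
]

_END = int(TaskCue.END_OF_TRIAL)
_BELIEF_FLOOR = 1e-9


class QTable:
    """Q(s, a) over the 4 stimulus cues x 2 actions; Q(end-of-trial, .) = 0."""

    __slots__ = ("values",)

    def __init__(self, values=None):
        self.values = [list(row) for row in values] if values is not None \
            else [[0.0, 0.0] for _ in range(4)]

    def row(self, cue: int):
        return (0.0, 0.0) if cue == _END else self.values[cue]

    def copy(self) -> "QTable":
        return QTable(self.values)

    def __eq__(self, other) -> bool:
        return isinstance(other, QTable) and self.values == other.values


class TDError(NamedTuple):
    delta: float
    r: float
    q_next: float
    q_cur: float


@dataclass
class BasicAgentParams:
    epsilon: float = 0.236
    alpha: float = 0.9

    def validate(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class BeliefAgentParams:
    zeta: float = 0.6858
    beta: float = 1.997
    epsilon: float = 0.049
    epsilon_prime: float = 0.280
    alpha_train: float = 0.1
    # Q-learning is normally frozen after training; a non-zero value keeps
    # it on in the test phase (a control the original analysis also ran)
    alpha_test: float = 0.0
    silencing_factor_visual: float = 1.0
    silencing_factor_odour: float = 1.0
    # whether epsilon_prime applies to VISUAL_2 in visual blocks as well
    epsilon_prime_both_blocks: bool = True

    def validate(self) -> None:
        if self.zeta < 0 or self.beta < 0:
            raise ValueError("zeta and beta must be non-negative")
        for p in (self.epsilon, self.epsilon_prime, self.alpha_train,
                  self.alpha_test,
                  self.silencing_factor_visual, self.silencing_factor_odour):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/factors must be in [0, 1]")


@dataclass
class BeliefState:
    p_visual: float = 0.5
    p_odour: float = 0.5

    def validate(self) -> None:
        if self.p_visual < 0 or self.p_odour < 0:
            raise ValueError("belief components must be non-negative")
        if abs(self.p_visual + self.p_odour - 1.0) > 1e-12:
            raise ValueError("belief must sum to 1")

    def as_tuple(self):
        return (self.p_visual, self.p_odour)


@dataclass(frozen=True)
class MismatchRecord:
    trial_index: int
    d: tuple            # detected block, one-hot (visual, odour)
    b: tuple            # belief before the update
    chi: tuple
    xi: float
    chi_noisy: tuple
    assumed_after: BlockType


def select_action(q_row, epsilon: float, rng: random.Random) -> int:
    """Epsilon-greedy over two actions, ties broken uniformly at random."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    if epsilon > 0.0 and rng.random() < epsilon:
        return ActionType.LICK if rng.random() < 0.5 else ActionType.NO_LICK
    q_nl, q_l = q_row
    if q_l > q_nl:
        return ActionType.LICK
    if q_nl > q_l:
        return ActionType.NO_LICK
    return ActionType.LICK if rng.random() < 0.5 else ActionType.NO_LICK


def sarsa_update(q: QTable, s: int, a: int, r: float, s_next: int,
                 a_next: int, alpha: float) -> TDError:
    """In-place SARSA update Q(s,a) += alpha * delta with delta = r + Q(s',a') - Q(s,a).

    The end-of-trial cue's Q-values are fixed at zero: they bootstrap as 0 and
    are never written.
    """
    q_next = 0.0 if s_next == _END else q.values[s_next][a_next]
    q_cur = 0.0 if s == _END else q.values[s][a]
    delta = r + q_next - q_cur
    if s != _END:
        q.values[s][a] = q_cur + alpha * delta
    return TDError(delta=delta, r=r, q_next=q_next, q_cur=q_cur)


def compute_mismatch(belief: BeliefState, detected: tuple) -> tuple:
    """chi = d - b componentwise; components sum to zero by construction."""
    if tuple(detected) not in ((1, 0), (0, 1)):
        raise ValueError("detected block must be one-hot (1,0) or (0,1)")
    return (detected[0] - belief.p_visual, detected[1] - belief.p_odour)


def corrupt_mismatch(chi: tuple, beta: float, silencing_factor: float,
                     rng: random.Random, xi: Optional[float] = None) -> tuple:
    """chi' = factor * chi * (1 + beta*xi), one scalar xi ~ N(0,1) per trial end."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if not 0.0 <= silencing_factor <= 1.0:
        raise ValueError("silencing_factor must be in [0, 1]")
    if xi is None:
        xi = rng.gauss(0.0, 1.0)
    g = silencing_factor * (1.0 + beta * xi)
    return (chi[0] * g, chi[1] * g), xi


def update_belief(belief: BeliefState, chi_noisy: tuple, zeta: float,
                  floor: float = _BELIEF_FLOOR) -> BeliefState:
    """b' = b + zeta * chi', clipped to a small positive floor and renormalised."""
    if zeta < 0:
        raise ValueError("zeta must be non-negative")
    bv = belief.p_visual + zeta * chi_noisy[0]
    bo = belief.p_odour + zeta * chi_noisy[1]
    if bv < floor:
        bv = floor
    if bo < floor:
        bo = floor
    if bv <= floor and bo <= floor:
        return BeliefState(0.5, 0.5)
    z = bv + bo
    return BeliefState(bv / z, bo / z)


def assumed_block(belief: BeliefState, previous: BlockType) -> BlockType:
    """The context the agent acts under; an exact tie keeps the previous one."""
    if belief.p_visual > belief.p_odour:
        return BlockType.VISUAL
    if belief.p_odour > belief.p_visual:
        return BlockType.ODOUR
    return previous


class BasicSarsaAgent:
    """Tabular SARSA with a single Q-table and epsilon-greedy policy."""

    kind = "basic"

    def __init__(self, params: BasicAgentParams, rng: random.Random):
        params.validate()
        self.params = params
        self.rng = rng
        self.q = QTable()
        self.learning = True

    def act(self, cue: int) -> int:
        return select_action(self.q.row(cue), self.params.epsilon, self.rng)

    def update(self, s, a, r, s_next, a_next) -> None:
        if self.learning:
            sarsa_update(self.q, s, a, r, s_next, a_next, self.params.alpha)

    def end_trial(self, final_cue: int) -> None:
        pass

    def set_phase(self, phase: str) -> None:
        # the basic agent keeps exploring and learning in the test phase,
        # exactly as during training
        self.learning = True


class BeliefStateAgent:
    """Belief-state RL: two context Q-tables gated by a belief over blocks."""

    kind = "belief"

    def __init__(self, params: BeliefAgentParams, rng: random.Random):
        params.validate()
        self.params = params
        self.rng = rng
        self.q_tables = (QTable(), QTable())  # (visual, odour)
        self.belief = BeliefState(0.5, 0.5)
        self.prev_assumed = BlockType.VISUAL
        self.alpha = params.alpha_train
        self.silencing_active = False
        self.trace: list = []
        self._trial_counter = 0
        self._assumed_s = BlockType.VISUAL
        self._assumed_s2 = BlockType.VISUAL

    def act(self, cue: int) -> int:
        assumed = assumed_block(self.belief, self.prev_assumed)
        self.prev_assumed = assumed
        self._assumed_s = self._assumed_s2
        self._assumed_s2 = assumed
        p = self.params
        if cue == TaskCue.VISUAL_2 and (p.epsilon_prime_both_blocks
                                        or assumed == BlockType.ODOUR):
            eps = p.epsilon_prime
        else:
            eps = p.epsilon
        return select_action(self.q_tables[assumed].row(cue), eps, self.rng)

    def update(self, s, a, r, s_next, a_next) -> None:
        if self.alpha > 0.0:
            sarsa_update(self.q_tables[self._assumed_s], s, a, r,
                         s_next, a_next, self.alpha)

    def end_trial(self, final_cue: int) -> None:
        p = self.params
        d = (1, 0) if final_cue in (TaskCue.VISUAL_1, TaskCue.VISUAL_2) else (0, 1)
        chi = compute_mismatch(self.belief, d)
        if self.silencing_active:
            factor = (p.silencing_factor_visual if d[0] == 1
                      else p.silencing_factor_odour)
        else:
            factor = 1.0
        chi_noisy, xi = corrupt_mismatch(chi, p.beta, factor, self.rng)
        b_before = self.belief.as_tuple()
        self.belief = update_belief(self.belief, chi_noisy, p.zeta)
        new_assumed = assumed_block(self.belief, self.prev_assumed)
        if self.trace is not None:
            self.trace.append(MismatchRecord(
                trial_index=self._trial_counter, d=d, b=b_before, chi=chi,
                xi=xi, chi_noisy=chi_noisy, assumed_after=new_assumed,
            ))
        self._trial_counter += 1

    def set_phase(self, phase: str) -> None:
        if phase == "train":
            self.alpha = self.params.alpha_train
            self.silencing_active = False
        else:
            self.alpha = self.params.alpha_test
            self.silencing_active = True

    def pop_trace(self):
        out = self.trace if self.trace is not None else []
        self.trace = []
        self._trial_counter = 0
        return out


def trace_frame(trace):
    """Belief/mismatch trace as a DataFrame (one row per trial end)."""
    import pandas as pd

    return pd.DataFrame(
        [(m.trial_index, m.b[0], m.chi[0], m.chi[1], m.chi_noisy[0],
          m.chi_noisy[1], m.xi, BlockType(m.assumed_after).name)
         for m in trace],
        columns=["trial_index", "p_visual", "chi_1", "chi_2",
                 "chi_noisy_1", "chi_noisy_2", "xi", "assumed_block"],
    )


def run_agent(env: TaskEnv, agent, n_steps: int, phase: str = "test",
              collect_trace: bool = True):
    """Run ``agent`` in ``env`` for ``n_steps`` steps.

    ``phase='train'`` updates Q-values (the belief agent updates only the
    table of the currently assumed block); ``phase='test'`` freezes Q-value
    learning for the belief agent (belief updates continue) while the basic
    agent keeps learning, and activates any configured silencing factors.
    Returns ``(SessionLog, trace)`` for the segment; the trace is empty for
    the basic agent.
    """
    if phase not in ("train", "test"):
        raise ValueError("phase must be 'train' or 'test'")
    agent.set_phase(phase)
    if phase == "test" and isinstance(agent, BeliefStateAgent) \
            and agent.alpha > 0.0:
        warnings.warn("belief agent learning with alpha > 0 in test phase")
    if isinstance(agent, BeliefStateAgent) and not collect_trace:
        agent.trace = None
    train = (phase == "train" or agent.kind == "basic"
             or getattr(agent, "alpha", 0.0) > 0.0)
    step = env.step
    act = agent.act
    update = agent.update
    end_trial = agent.end_trial
    s = env.current_cue
    a = act(s)
    for _ in range(n_steps):
        out = step(a)
        s2 = env.current_cue
        a2 = act(s2)
        if train:
            update(s, a, out.reward, s2, a2)
        if out.trial_ended:
            end_trial(out.cue_presented)
        s, a = s2, a2
    log = env.drain_log()
    trace = agent.pop_trace() if isinstance(agent, BeliefStateAgent) else []
    return log, trace
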