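"""Synthetic behavioural sessions and calcium recordings with ground truth.

Every pipeline stage is testable without any experimental download:

* ``generate_behaviour`` produces a :class:`~taskswitch.task_env.SessionLog`
  either by running the belief-state agent in the task environment
  (``agent_driven``) or from a scripted per-cue lick-probability table with a
  deterministic rule switch a fixed number of trials after each block
  transition (``scripted_policy``).
* ``generate_calcium`` lays the session out on a timeline and synthesises a
  ΔF/F matrix in which known fractions of neurons are planted as
  prediction-error positive/negative, Type A or Type B responders:
  event-locked single-exponential transients (GCaMP7f-like decay) plus
  i.i.d. Gaussian noise.  Planted prediction-error responses appear only on
  the first post-transition trial by default, mirroring the rapid decay of
  the neural signal across trials.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .agents import BeliefAgentParams, BeliefStateAgent, run_agent
from .neural_analysis import CalciumRecording, EpochSpec, transition_epoch_times
from .task_env import (ActionType, BlockType, EnvConfig, SessionLog, TaskCue,
                       TaskEnv, _finalise_trial_record)

__all__ = [
    "SyntheticBehaviourConfig",
    "SyntheticNeuralConfig",
    "GroundTruth",
    "TrialTiming",
    "DEFAULT_LICK_TABLE",
    "generate_behaviour",
    "generate_calcium",
    "session_timeline",
]

# lick probabilities per (rule block, cue) for the scripted policy: accurate
# discrimination under the current rule, irrelevant gratings ignored
DEFAULT_LICK_TABLE = {
    (BlockType.VISUAL, TaskCue.VISUAL_1): 0.95,
    (BlockType.VISUAL, TaskCue.VISUAL_2): 0.05,
    (BlockType.VISUAL, TaskCue.ODOUR_1): 0.95,
    (BlockType.VISUAL, TaskCue.ODOUR_2): 0.05,
    (BlockType.ODOUR, TaskCue.VISUAL_1): 0.05,
    (BlockType.ODOUR, TaskCue.VISUAL_2): 0.05,
    (BlockType.ODOUR, TaskCue.ODOUR_1): 0.95,
    (BlockType.ODOUR, TaskCue.ODOUR_2): 0.05,
}


@dataclass
class SyntheticBehaviourConfig:
    mode: str = "agent_driven"            # or "scripted_policy"
    agent_params: Optional[BeliefAgentParams] = None
    env_config: Optional[EnvConfig] = None
    n_train_steps: int = 50_000
    n_test_steps: int = 20_000
    # scripted policy
    lick_table: Optional[dict] = None
    n_blocks: int = 41
    trials_per_block: int = 16
    switch_delay: int = 1                 # trials before the rule updates
    p_irrelevant_visual: float = 0.70
    seed: int = 0


@dataclass
class SyntheticNeuralConfig:
    n_neurons: int = 1000
    fraction_pe_positive: float = 0.09    # fraction of recorded neurons
    fraction_pe_negative: float = 0.0
    fraction_type_a: float = 0.0
    fraction_type_b: float = 0.0
    response_amplitude: float = 0.3       # ΔF/F units
    noise_sd: float = 0.1                 # ΔF/F units per frame
    kernel_tau_s: float = 0.7             # GCaMP7f-like decay constant
    frame_rate: float = 4.8
    pe_first_trial_only: bool = True
    seed: int = 0

    def validate(self) -> None:
        total = (self.fraction_pe_positive + self.fraction_pe_negative
                 + self.fraction_type_a + self.fraction_type_b)
        if total > 1.0 + 1e-12:
            raise ValueError("class fractions must sum to at most 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    mode: str
    params: dict = field(default_factory=dict)
    neuron_labels: Optional[np.ndarray] = None
    trace: Optional[list] = None


@dataclass
class TrialTiming:
    """Within-trial stimulus timing on the synthetic timeline (seconds)."""

    trial_period: float = 8.0
    visual_onset: float = 0.5
    visual_duration: float = 1.8
    odour_delay: float = 2.0   # visual offset to odour onset; also the
                               # expected-odour delay used for epoching

    @property
    def visual_offset(self) -> float:
        return self.visual_onset + self.visual_duration

    @property
    def odour_onset(self) -> float:
        return self.visual_offset + self.odour_delay


def generate_behaviour(cfg: SyntheticBehaviourConfig):
    """Return ``(SessionLog, GroundTruth)``; agent mode also yields a trace."""
    if cfg.mode == "agent_driven":
        params = cfg.agent_params or BeliefAgentParams()
        env_cfg = cfg.env_config or EnvConfig()
        from dataclasses import replace

        env = TaskEnv(replace(env_cfg, seed=cfg.seed))
        agent = BeliefStateAgent(params, random.Random(cfg.seed * 7919 + 13))
        run_agent(env, agent, cfg.n_train_steps, "train", collect_trace=False)
        log, trace = run_agent(env, agent, cfg.n_test_steps, "test")
        truth = GroundTruth(mode=cfg.mode, params=params.__dict__.copy(),
                            trace=trace)
        return log, truth
    if cfg.mode == "scripted_policy":
        return _scripted_session(cfg)
    raise ValueError(f"unknown mode {cfg.mode!r}")


def generate_study_dataset(agent_params: Optional[BeliefAgentParams] = None,
                           n_test_steps: int = 100_000,
                           n_train_steps: int = 50_000, seed: int = 0):
    """Agent-driven sessions split across the two transition-period variants.

    Emulates the experimental dataset's composition: sessions are pooled
    over both variants in a 2:3 ratio, and a fit to these data should use
    the same seed composition.  ``n_test_steps`` is the total across the
    five sessions.  Returns ``(logs, truths)`` lists.
    """
    from .task_env import TransitionVariant

    variants = [TransitionVariant.V1, TransitionVariant.V1,
                TransitionVariant.V2, TransitionVariant.V2,
                TransitionVariant.V2]
    per = n_test_steps // len(variants)
    logs, truths = [], []
    for i, v in enumerate(variants):
        cfg = SyntheticBehaviourConfig(
            mode="agent_driven", agent_params=agent_params,
            env_config=EnvConfig(transition_variant=v),
            n_train_steps=n_train_steps, n_test_steps=per,
            seed=seed * 31 + i)
        log, truth = generate_behaviour(cfg)
        logs.append(log)
        truths.append(truth)
    return logs, truths


def _scripted_session(cfg: SyntheticBehaviourConfig):
    table = cfg.lick_table or DEFAULT_LICK_TABLE
    rng = random.Random(cfg.seed)
    log = SessionLog(seed=cfg.seed)
    trial_index = 0
    for b in range(cfg.n_blocks):
        block_type = BlockType.VISUAL if b % 2 == 0 else BlockType.ODOUR
        if b > 0:
            log.block_boundaries.append(len(log.trials))
        for j in range(cfg.trials_per_block):
            rule = block_type
            if b > 0 and j < cfg.switch_delay:
                rule = BlockType.VISUAL if block_type == BlockType.ODOUR \
                    else BlockType.ODOUR
            # the first three gratings of a block are the rewarded one, a
            # fixed-length stand-in for the task's forced transition period
            forced = b > 0 and j < 3
            cues = [TaskCue.END_OF_TRIAL]
            if block_type == BlockType.VISUAL:
                cues.append(TaskCue.VISUAL_1 if forced or rng.random() < 0.5
                            else TaskCue.VISUAL_2)
            else:
                if rng.random() < cfg.p_irrelevant_visual:
                    cues.append(TaskCue.VISUAL_1 if forced
                                or rng.random() < 0.5 else TaskCue.VISUAL_2)
                cues.append(TaskCue.ODOUR_1 if rng.random() < 0.5
                            else TaskCue.ODOUR_2)
            steps = []
            for pos, cue in enumerate(cues):
                if cue == TaskCue.END_OF_TRIAL:
                    action = ActionType.NO_LICK
                else:
                    action = (ActionType.LICK
                              if rng.random() < table[(rule, cue)]
                              else ActionType.NO_LICK)
                final = pos == len(cues) - 1
                if final:
                    r = (1.0 if cue in (TaskCue.VISUAL_1, TaskCue.ODOUR_1)
                         else -1.0) if action == ActionType.LICK else 0.0
                else:
                    r = -1.0 if action == ActionType.LICK else 0.0
                steps.append((int(cue), int(action), r, False))
            rec = _finalise_trial_record(block_type, b, trial_index, j, steps,
                                         transition_phase=False)
            log.trials.append(rec)
            trial_index += 1
    truth = GroundTruth(mode="scripted_policy", params={
        "lick_table": {f"{BlockType(k[0]).name}:{TaskCue(k[1]).name}": v
                       for k, v in table.items()},
        "switch_delay": cfg.switch_delay,
        "trials_per_block": cfg.trials_per_block,
    })
    return log, truth


def session_timeline(log: SessionLog,
                     timing: Optional[TrialTiming] = None) -> tuple:
    """Lay a session out in time; returns ``(trials_df, events_df)``.

    Each trial occupies a fixed period; the (possibly irrelevant) grating
    runs from ``visual_onset`` for ``visual_duration`` and the odour, when
    present, starts ``odour_delay`` after the grating offset -- the same
    latency at which an expected odour fails to arrive on prediction-error
    trials.
    """
    timing = timing or TrialTiming()
    rows, events = [], []
    for i, t in enumerate(log.trials):
        t0 = i * timing.trial_period
        visual_cue, odour_cue = "", ""
        v_on = v_off = o_on = np.nan
        licked_visual = licked_odour = False
        for cue, action, _r, _f in t.steps:
            if cue in (TaskCue.VISUAL_1, TaskCue.VISUAL_2):
                visual_cue = TaskCue(cue).name
                v_on, v_off = t0 + timing.visual_onset, t0 + timing.visual_offset
                licked_visual = bool(action)
                events.append(("visual_onset", v_on, i))
                events.append(("visual_offset", v_off, i))
                if action:
                    events.append(("lick", v_on + 0.5, i))
            elif cue in (TaskCue.ODOUR_1, TaskCue.ODOUR_2):
                odour_cue = TaskCue(cue).name
                o_on = t0 + timing.odour_onset
                licked_odour = bool(action)
                events.append(("odour_onset", o_on, i))
                if action:
                    events.append(("lick", o_on + 0.5, i))
                    if cue == TaskCue.ODOUR_1:
                        events.append(("reward", o_on + 0.5, i))
        rows.append((i, t.block_index, BlockType(t.block_type).name,
                     bool(t.transition_phase), t0, visual_cue, v_on, v_off,
                     licked_visual, odour_cue, o_on, licked_odour,
                     bool(t.relevant_correct)))
    trials_df = pd.DataFrame(rows, columns=[
        "trial_index", "block_index", "block_type", "transition_phase",
        "t_start", "visual_cue", "visual_onset_s", "visual_offset_s",
        "licked_visual", "odour_cue", "odour_onset_s", "licked_odour",
        "relevant_correct"])
    events_df = pd.DataFrame(events, columns=["event_type", "time_s",
                                              "trial_index"])
    return trials_df, events_df


def generate_calcium(cfg: SyntheticNeuralConfig, log: SessionLog,
                     timing: Optional[TrialTiming] = None):
    """Synthesise a :class:`CalciumRecording` with planted neuron classes.

    Planted classes are defined by which screening epochs they respond in:
    prediction-error positive/negative neurons emit a positive/negative
    transient only at the prediction-error epoch of the first
    post-transition trial; Type A neurons respond at every odour onset;
    Type B neurons respond both at odour onsets and at prediction-error
    epochs (hence differ from the no-odour condition only).
    Returns ``(CalciumRecording, GroundTruth)``.
    """
    cfg.validate()
    if not log.block_boundaries:
        raise ValueError("session log contains no block transitions")
    timing = timing or TrialTiming()
    trials_df, events_df = session_timeline(log, timing)
    fs = cfg.frame_rate
    n_frames = int(np.ceil(len(log.trials) * timing.trial_period * fs)) + 1
    rng = np.random.default_rng(cfg.seed)

    # epoch times, shared with the analysis side
    spec = EpochSpec(pe_offset_s=timing.odour_delay)
    epochs = transition_epoch_times(trials_df, spec)
    pe_times = [e["pe_time"] for e in epochs if e["pe_time"] is not None]
    if not cfg.pe_first_trial_only:
        # also respond on the 2nd and 3rd trials after the transition
        extra = []
        boundaries = trials_df.index[trials_df["block_index"].diff() > 0]
        for b in boundaries:
            block = trials_df.iloc[b:]
            block = block[block["block_index"] == block["block_index"].iloc[0]]
            if block["block_type"].iloc[0] != "VISUAL":
                continue
            vis = block[block["visual_cue"] != ""]
            for _, row in vis.iloc[1:3].iterrows():
                extra.append(row["visual_offset_s"] + timing.odour_delay)
        pe_times = pe_times + extra
    odour_times = list(trials_df.loc[trials_df["odour_cue"] != "",
                                     "odour_onset_s"])

    # class assignment
    n = cfg.n_neurons
    counts = {
        "prediction_error_positive": int(round(cfg.fraction_pe_positive * n)),
        "prediction_error_negative": int(round(cfg.fraction_pe_negative * n)),
        "type_A": int(round(cfg.fraction_type_a * n)),
        "type_B": int(round(cfg.fraction_type_b * n)),
    }
    labels = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    k = 0
    for cls, c in counts.items():
        labels[order[k:k + c]] = cls
        k += c

    def impulse_train(times, amplitude):
        x = np.zeros(n_frames)
        for t in times:
            i = int(round(t * fs))
            if 0 <= i < n_frames:
                x[i] += amplitude
        return x

    decay = np.exp(-1.0 / (fs * cfg.kernel_tau_s))
    a_coeffs = [1.0, -decay]
    A = cfg.response_amplitude
    signal = {
        "prediction_error_positive": lfilter([1.0], a_coeffs,
                                             impulse_train(pe_times, A)),
        "prediction_error_negative": lfilter([1.0], a_coeffs,
                                             impulse_train(pe_times, -A)),
        "type_A": lfilter([1.0], a_coeffs, impulse_train(odour_times, A)),
        "type_B": lfilter([1.0], a_coeffs,
                          impulse_train(odour_times + pe_times, A)),
    }
    dff = rng.normal(0.0, cfg.noise_sd, size=(n, n_frames)).astype(np.float64)
    for cls, tr in signal.items():
        idx = np.flatnonzero(labels == cls)
        if idx.size:
            dff[idx] += tr
    running = np.clip(lfilter([1.0], [1.0, -0.95],
                              rng.normal(0, 0.3, n_frames)), 0, None)
    rec = CalciumRecording(
        dff=dff, frame_rate=fs, trials=trials_df, events=events_df,
        running=running,
        neuron_meta=pd.DataFrame({"true_class": labels.astype(str)}))
    truth = GroundTruth(mode="calcium", params={
        "response_amplitude": A, "noise_sd": cfg.noise_sd,
        "kernel_tau_s": cfg.kernel_tau_s, "frame_rate": fs,
        **{f"n_{k}": v for k, v in counts.items()}},
        neuron_labels=labels.astype(str))
    return rec, truth
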