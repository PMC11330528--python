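"""Behavioural summary statistics.

* behavioural d' -- Phi^-1(hit rate) - Phi^-1(false-alarm rate), with rates
  clipped to [1/(2n), 1 - 1/(2n)] so the quantiles stay finite.
* switching speed -- the number of trials that elapse before the first run of
  three consecutive correct responses to the relevant stimuli of the new
  block begins.  Zero trials means the animal (or agent) happened to respond
  correctly to the very first rewarded stimulus, a *fluke*, excluded from
  switching statistics; one trial is a *one-shot* transition.
* prediction-error amplitude vs outcome -- the belief-state agent's mismatch
  amplitude |chi'_1| + |chi'_2| at the end of the first post-transition
  trial, compared between one-shot and slower transitions (two-sided
  rank-sum), the model counterpart of comparing neural prediction-error
  response amplitudes before fast vs slow behavioural switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm, ranksums

from .task_env import BlockType, SessionLog

__all__ = [
    "DprimeResult",
    "TransitionOutcome",
    "BehaviourSummary",
    "behavioural_dprime",
    "switching_speed",
    "transition_outcomes",
    "summarize_transitions",
    "pe_amplitude_by_outcome",
]


@dataclass(frozen=True)
class DprimeResult:
    hit_rate: float          # after clipping
    false_alarm_rate: float  # after clipping
    bd_prime: float
    n_trials: int


@dataclass
class TransitionOutcome:
    transition_index: int
    direction: BlockType          # block type switched *into*
    trials_to_switch: int
    is_fluke: bool
    is_one_shot: bool
    converged: bool = True
    pe_amplitude: float = np.nan  # |chi'_1|+|chi'_2| on the first new-block trial


@dataclass
class BehaviourSummary:
    histogram: dict               # direction name -> {trials_to_switch: count}
    one_shot_proportion: dict     # direction name -> proportion, flukes excluded
    dprime: dict                  # stimulus class -> DprimeResult
    n_transitions: int
    n_flukes: int
    outcomes: list = field(default_factory=list)


def behavioural_dprime(hit_rate: float, false_alarm_rate: float,
                       n_trials: int) -> DprimeResult:
    """bd' = Phi^-1(H) - Phi^-1(F) with 1/(2n) clipping of perfect rates."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo = 1.0 / (2 * n_trials)
    h = min(max(hit_rate, lo), 1.0 - lo)
    f = min(max(false_alarm_rate, lo), 1.0 - lo)
    return DprimeResult(h, f, float(norm.ppf(h) - norm.ppf(f)), n_trials)


def switching_speed(correct_sequence, transition_index: int = 0,
                    direction: BlockType = BlockType.VISUAL) -> TransitionOutcome:
    """Trials elapsed before the first run of 3 consecutive correct responses.

    ``correct_sequence`` is the per-trial correctness of responses to the
    new block's relevant stimuli, ordered from the first trial of the block.
    A result of 0 is a fluke (correct on the very first rewarded stimulus),
    1 is a one-shot transition.  If no run of three occurs, the block length
    is returned as a sentinel with ``converged=False``.
    """
    seq = [bool(c) for c in correct_sequence]
    tts, converged = len(seq), False
    for i in range(len(seq) - 2):
        if seq[i] and seq[i + 1] and seq[i + 2]:
            tts, converged = i, True
            break
    return TransitionOutcome(
        transition_index=transition_index, direction=direction,
        trials_to_switch=tts, is_fluke=converged and tts == 0,
        is_one_shot=converged and tts == 1, converged=converged,
    )


def _block_slices(log: SessionLog):
    """(start, stop) trial ranges for each post-transition block."""
    edges = list(log.block_boundaries) + [len(log.trials)]
    return [(edges[i], edges[i + 1]) for i in range(len(log.block_boundaries))]


def transition_outcomes(log: SessionLog) -> list:
    """A :class:`TransitionOutcome` for every block transition in the log.

    Correctness is judged on the trials presenting the criterion stimulus of
    the new block: the rewarded grating after a switch into a visual block,
    the irrelevant grating after a switch into an odour block (trials without
    an irrelevant grating do not enter the run of three, but do count as
    elapsed trials).
    """
    outcomes = []
    for k, (start, stop) in enumerate(_block_slices(log)):
        trials = log.trials[start:stop]
        if not trials:
            continue
        direction = trials[0].block_type
        if direction == BlockType.VISUAL:
            # only rewarded gratings qualify for the run of three ("licking
            # to the grating"); during the forced transition period every
            # post-transition grating is the rewarded one anyway
            from .task_env import TaskCue

            qualifying = [i for i, t in enumerate(trials)
                          if t.steps[-1][0] == TaskCue.VISUAL_1]
            seq = [trials[i].relevant_correct for i in qualifying]
        else:
            # the run of three counts (otherwise-)rewarded gratings only:
            # ignoring the never-rewarded grating is correct under either rule
            # and carries no evidence of a switch
            from .task_env import TaskCue

            qualifying = [i for i, t in enumerate(trials)
                          if t.irrelevant_shown
                          and t.steps[1][0] == TaskCue.VISUAL_1]
            seq = [trials[i].irrelevant_ignored for i in qualifying]
        base = switching_speed(seq, k, direction)
        if base.converged:
            # convert position among qualifying trials back to elapsed trials
            pos = base.trials_to_switch
            base.trials_to_switch = qualifying[pos] if pos < len(qualifying) else len(trials)
            base.is_fluke = base.trials_to_switch == 0
            base.is_one_shot = base.trials_to_switch == 1
        else:
            base.trials_to_switch = len(trials)
        outcomes.append(base)
    return outcomes


_STABLE_MARGIN = 5  # trials after the transition period before d' counts


def _stable_mask(log: SessionLog):
    mask = np.zeros(len(log.trials), dtype=bool)
    run_since_transition = None
    for i, t in enumerate(log.trials):
        if t.transition_phase:
            run_since_transition = 0
        elif run_since_transition is not None:
            run_since_transition += 1
        boundary = i in log.block_boundaries
        if boundary:
            run_since_transition = 0
        if run_since_transition is None or run_since_transition > _STABLE_MARGIN:
            mask[i] = not t.transition_phase
    return mask


def summarize_transitions(log: SessionLog) -> BehaviourSummary:
    """Per-direction switching histograms, one-shot proportions and stable d'."""
    if not log.block_boundaries:
        raise ValueError("session log contains no completed transitions")
    outcomes = transition_outcomes(log)
    histogram = {"to_visual": {}, "to_odour": {}}
    one_shot = {}
    for o in outcomes:
        key = "to_visual" if o.direction == BlockType.VISUAL else "to_odour"
        histogram[key][o.trials_to_switch] = \
            histogram[key].get(o.trials_to_switch, 0) + 1
    for key, d in (("to_visual", BlockType.VISUAL), ("to_odour", BlockType.ODOUR)):
        non_fluke = [o for o in outcomes if o.direction == d and not o.is_fluke]
        one_shot[key] = (sum(o.is_one_shot for o in non_fluke) / len(non_fluke)
                         if non_fluke else np.nan)

    # d' per stimulus class on stable-period trials
    from .task_env import TaskCue

    mask = _stable_mask(log)
    counts = {}  # (class, rewarded?) -> [licks, n]
    for i, t in enumerate(log.trials):
        if not mask[i]:
            continue
        for cue, action, _r, _f in t.steps:
            if cue == TaskCue.END_OF_TRIAL:
                continue
            if cue in (TaskCue.ODOUR_1, TaskCue.ODOUR_2):
                cls = "odour"
                hit_cue = cue == TaskCue.ODOUR_1
            elif t.block_type == BlockType.VISUAL:
                cls = "visual_in_visual"
                hit_cue = cue == TaskCue.VISUAL_1
            else:
                cls = "visual_in_odour"
                hit_cue = cue == TaskCue.VISUAL_1
            key = (cls, hit_cue)
            c = counts.setdefault(key, [0, 0])
            c[0] += action
            c[1] += 1
    dprime = {}
    for cls in ("visual_in_visual", "visual_in_odour", "odour"):
        hits = counts.get((cls, True))
        fas = counts.get((cls, False))
        if hits and fas and hits[1] and fas[1]:
            n = hits[1] + fas[1]
            dprime[cls] = behavioural_dprime(hits[0] / hits[1], fas[0] / fas[1], n)

    flukes = sum(o.is_fluke for o in outcomes)
    return BehaviourSummary(
        histogram=histogram, one_shot_proportion=one_shot, dprime=dprime,
        n_transitions=len(outcomes), n_flukes=flukes, outcomes=outcomes,
    )


def pe_amplitude_by_outcome(trace, outcomes, log: SessionLog,
                            n_sample: int = 70, direction: BlockType = BlockType.VISUAL,
                            use_noisy: bool = True, rng=None) -> dict:
    """Compare prediction-error amplitudes before one-shot vs slower switches.

    ``trace`` is the belief agent's per-trial mismatch trace aligned to
    ``log`` (entry i belongs to log.trials[i]).  The amplitude is
    |chi'_1| + |chi'_2| (or |chi| with ``use_noisy=False``) at the end of the
    first post-transition trial.  Up to ``n_sample`` transitions are sampled
    per group before a two-sided rank-sum test, emulating the down-sampling
    to the experimental transition count.
    """
    rng = rng or np.random.default_rng(0)
    fast, slow = [], []
    for o in outcomes:
        if o.direction != direction or o.is_fluke or not o.converged:
            continue
        b = log.block_boundaries[o.transition_index]
        if b >= len(trace):
            continue
        m = trace[b]
        sig = m.chi_noisy if use_noisy else m.chi
        amp = abs(sig[0]) + abs(sig[1])
        o.pe_amplitude = amp
        (fast if o.is_one_shot else slow).append(amp)
    fast, slow = np.asarray(fast), np.asarray(slow)
    if n_sample and len(fast) > n_sample:
        fast = rng.choice(fast, n_sample, replace=False)
    if n_sample and len(slow) > n_sample:
        slow = rng.choice(slow, n_sample, replace=False)
    report = {
        "n_one_shot": int(len(fast)), "n_slower": int(len(slow)),
        "median_one_shot": float(np.median(fast)) if len(fast) else np.nan,
        "median_slower": float(np.median(slow)) if len(slow) else np.nan,
        "statistic": np.nan, "p_value": np.nan,
    }
    if len(fast) and len(slow):
        stat, p = ranksums(fast, slow)
        report["statistic"], report["p_value"] = float(stat), float(p)
    return report
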