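"""Calcium-imaging analysis.

Covers the neural side of the task-switching analysis: ΔF/F computation from
raw fluorescence, extraction of the three trial epochs used to screen for
prediction-error neurons (odour prediction error / odour delivered / no
odour predicted), the dual rank-sum classification of neurons, sustained
per-frame significance, population decoding, percentile-bootstrap confidence
intervals for neuron-class proportions, and a ridge encoding model with
time-shifted event regressors.

The prediction-error epoch of a transition out of an odour block starts a
fixed delay (default 2.0 s, the visual-offset-to-odour latency) after the
offset of the first post-transition grating, provided the subject did not
lick to that grating; a response present there but absent both when the
odour actually arrives and when no odour was ever expected is the signature
of an expectation violation rather than a stimulus response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.stats import ranksums, ttest_rel

__all__ = [
    "CalciumRecording",
    "EpochSpec",
    "EpochResponses",
    "NeuronClassification",
    "DecodeResult",
    "BootstrapCI",
    "EncodingFit",
    "compute_dff",
    "transition_epoch_times",
    "epoch_responses",
    "classify_neurons",
    "sustained_significance",
    "decode_timecourse",
    "bootstrap_proportion_ci",
    "fit_encoding_model",
]

CONDITIONS = ("prediction_error", "odour", "no_odour")


@dataclass
class CalciumRecording:
    """ΔF/F matrix with the trial/event annotations the analyses consume.

    ``trials`` carries one row per behavioural trial with the stimulus and
    lick timing needed to place analysis epochs: columns ``trial_index``,
    ``block_index``, ``block_type`` ('VISUAL'/'ODOUR'), ``transition_phase``,
    ``visual_cue`` ('' when absent), ``visual_onset_s``, ``visual_offset_s``,
    ``licked_visual``, ``odour_cue``, ``odour_onset_s``, ``licked_odour``.
    ``events`` is the long-form (event_type, time_s, trial_index) table.
    """

    dff: np.ndarray                  # (n_neurons, n_frames)
    frame_rate: float
    trials: pd.DataFrame
    events: Optional[pd.DataFrame] = None
    running: Optional[np.ndarray] = None
    neuron_meta: Optional[pd.DataFrame] = None

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    def block_labels(self) -> np.ndarray:
        return self.trials["block_type"].to_numpy()

    # ---- HDF5 round trip -------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("dff", data=self.dff.astype(np.float32),
                             compression="gzip")
            f.create_dataset("frame_rate", data=float(self.frame_rate))
            if self.running is not None:
                f.create_dataset("running", data=self.running)
            for name, df in (("trials", self.trials), ("events", self.events)):
                if df is None:
                    continue
                g = f.create_group(name)
                for col in df.columns:
                    v = df[col].to_numpy()
                    if v.dtype == object or v.dtype.kind in "UO":
                        v = np.array([str(x) for x in v], dtype="S32")
                    g.create_dataset(col, data=v)

    @classmethod
    def from_hdf5(cls, path) -> "CalciumRecording":
        import h5py

        def read_group(g):
            data = {}
            for col in g:
                v = g[col][()]
                if v.dtype.kind == "S":
                    v = np.array([x.decode() for x in v])
                data[col] = v
            return pd.DataFrame(data)

        with h5py.File(path, "r") as f:
            rec = cls(
                dff=f["dff"][()].astype(np.float64),
                frame_rate=float(f["frame_rate"][()]),
                trials=read_group(f["trials"]),
                events=read_group(f["events"]) if "events" in f else None,
                running=f["running"][()] if "running" in f else None,
            )
        return rec


@dataclass
class EpochSpec:
    window_s: float = 1.5
    pe_offset_s: float = 2.0          # delay from visual offset to expected odour
    max_trials_averaged: int = 7
    exclude_block_end_trials: int = 10
    nearest_first: bool = True        # take the 7 nearest the transition


@dataclass
class EpochResponses:
    """Mean-response tensor (n_neurons, 3 conditions, n_transitions)."""

    responses: np.ndarray
    transition_ids: list
    conditions: tuple = CONDITIONS
    dropped: list = field(default_factory=list)


@dataclass
class NeuronClassification:
    labels: np.ndarray        # str per neuron
    p_vs_odour: np.ndarray
    p_vs_no_odour: np.ndarray
    condition_means: np.ndarray  # (n_neurons, 3)
    alpha: float

    def proportions(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        n = len(self.labels)
        return {v: c / n for v, c in zip(vals, counts)}


@dataclass
class DecodeResult:
    accuracy: np.ndarray      # per frame
    n_folds: int
    class_size: int


@dataclass
class BootstrapCI:
    proportion: float
    lower: float
    upper: float
    n_boot: int
    level: float
    reference: Optional[float] = None
    reference_outside: Optional[bool] = None


@dataclass
class EncodingFit:
    r2_full: np.ndarray
    r2_reduced: np.ndarray
    delta_r2: np.ndarray
    penalty: np.ndarray       # chosen ridge penalty per neuron (full model)


# ---------------------------------------------------------------------------
# ΔF/F
# ---------------------------------------------------------------------------

def _frames(duration_s: float, frame_rate: float) -> int:
    """Seconds to frames: round to nearest, minimum 1."""
    return max(1, int(round(duration_s * frame_rate)))


def compute_dff(raw_f: np.ndarray, frame_rate: float, smooth_s: float = 0.75,
                baseline_window_s: float = 60.0):
    """Baseline and ΔF/F from raw fluorescence.

    The baseline F0(t) is the running minimum, over the preceding
    ``baseline_window_s``, of the causally smoothed trace (moving average of
    ``smooth_s``); at the trace start the minimum runs over the available
    history.  ΔF/F = (F - F0) / F0.  Returns ``(baseline, dff, valid)``
    where ``valid`` flags neurons whose baseline stayed positive.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    raw_f = np.atleast_2d(np.asarray(raw_f, dtype=np.float64))
    k = _frames(smooth_s, frame_rate)
    m = _frames(baseline_window_s, frame_rate)
    # origin = size-1-size//2 turns the centred filters into trailing
    # (causal) windows ending at the current frame
    smoothed = uniform_filter1d(raw_f, size=k, axis=1, mode="nearest",
                                origin=k - 1 - k // 2)
    baseline = minimum_filter1d(smoothed, size=m, axis=1, mode="nearest",
                                origin=m - 1 - m // 2)
    valid = (baseline > 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (raw_f - baseline) / baseline
    dff[~valid] = np.nan
    return baseline, dff, valid


# ---------------------------------------------------------------------------
# Epoch extraction
# ---------------------------------------------------------------------------

def transition_epoch_times(trials: pd.DataFrame,
                           spec: Optional[EpochSpec] = None) -> list:
    """Epoch start times for every odour-to-visual transition.

    Returns a list of dicts with keys ``transition_id``, ``pe_time`` (None if
    the subject licked to the first post-transition grating), ``odour_times``
    and ``no_odour_times`` (each at most ``spec.max_trials_averaged`` long).

    * prediction error: ``spec.pe_offset_s`` after the offset of the first
      grating of the new visual block, lick-free trials only;
    * odour: odour onsets from the end of the preceding odour block, on
      trials whose irrelevant grating was correctly ignored;
    * no odour: the same post-offset delay after unrewarded gratings later
      in the visual block, outside the transition period and excluding the
      block's final ``spec.exclude_block_end_trials`` trials.
    """
    spec = spec or EpochSpec()
    t = trials.sort_values("trial_index").reset_index(drop=True)
    out = []
    block_ids = t["block_index"].to_numpy()
    changes = np.flatnonzero(np.diff(block_ids)) + 1
    for k, start in enumerate(changes):
        if t.loc[start, "block_type"] != "VISUAL":
            continue
        prev_block = t[t["block_index"] == block_ids[start - 1]]
        block = t[t["block_index"] == block_ids[start]]

        # condition 1: odour prediction error
        vis = block[block["visual_cue"] != ""]
        pe_time = None
        if len(vis):
            first = vis.iloc[0]
            if not first["licked_visual"]:
                pe_time = float(first["visual_offset_s"]) + spec.pe_offset_s

        # condition 2: odour delivered as expected
        elig = prev_block[(prev_block["odour_cue"] != "")
                          & (prev_block["visual_cue"] != "")
                          & (~prev_block["licked_visual"].astype(bool))]
        odour_times = list(elig["odour_onset_s"].astype(float))[
            -spec.max_trials_averaged:]

        # condition 3: no odour predicted
        n_block = len(block)
        later = block.iloc[1:max(1, n_block - spec.exclude_block_end_trials)]
        elig3 = later[(later["visual_cue"] == "VISUAL_2")
                      & (~later["transition_phase"].astype(bool))]
        times3 = list(elig3["visual_offset_s"].astype(float) + spec.pe_offset_s)
        no_odour_times = (times3[:spec.max_trials_averaged]
                          if spec.nearest_first
                          else times3[-spec.max_trials_averaged:])

        out.append({"transition_id": k, "pe_time": pe_time,
                    "odour_times": odour_times,
                    "no_odour_times": no_odour_times})
    return out


def _window_mean(dff: np.ndarray, frame_rate: float, t0: float,
                 window_s: float) -> np.ndarray:
    i0 = int(round(t0 * frame_rate))
    n = _frames(window_s, frame_rate)
    i0 = max(0, min(i0, dff.shape[1] - 1))
    return dff[:, i0:min(i0 + n, dff.shape[1])].mean(axis=1)


def epoch_responses(rec: CalciumRecording,
                    spec: Optional[EpochSpec] = None) -> EpochResponses:
    """Per-transition mean responses in the three screening epochs.

    Conditions 2 and 3 average up to ``spec.max_trials_averaged`` eligible
    trials per transition; transitions lacking a prediction-error epoch or
    any eligible trial in a condition are dropped (and reported).
    """
    spec = spec or EpochSpec()
    epochs = transition_epoch_times(rec.trials, spec)
    fs = rec.frame_rate
    cols, ids, dropped = [], [], []
    for e in epochs:
        if e["pe_time"] is None or not e["odour_times"] or not e["no_odour_times"]:
            dropped.append(e["transition_id"])
            continue
        pe = _window_mean(rec.dff, fs, e["pe_time"], spec.window_s)
        od = np.mean([_window_mean(rec.dff, fs, t, spec.window_s)
                      for t in e["odour_times"]], axis=0)
        no = np.mean([_window_mean(rec.dff, fs, t, spec.window_s)
                      for t in e["no_odour_times"]], axis=0)
        cols.append(np.stack([pe, od, no], axis=1))
        ids.append(e["transition_id"])
    if not cols:
        raise ValueError("no usable odour-to-visual transitions in recording")
    responses = np.stack(cols, axis=2)  # (n_neurons, 3, n_transitions)
    return EpochResponses(responses=responses, transition_ids=ids,
                          dropped=dropped)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_neurons(responses, alpha: float = 0.05,
                     min_transitions: int = 5) -> NeuronClassification:
    """Dual rank-sum screen for prediction-error neurons.

    Per neuron, the prediction-error epoch responses are compared across
    transitions with the odour and the no-odour conditions (two-sided
    Wilcoxon rank-sum, sample size = number of transitions).  Significance
    in *both* comparisons labels a prediction-error neuron, signed positive
    or negative when its prediction-error mean is the largest or smallest of
    the three conditions; significance in only the odour (or only the
    no-odour) comparison gives a Type A (or Type B) neuron.
    """
    r = responses.responses if isinstance(responses, EpochResponses) else responses
    n_neurons, _, n_trans = r.shape
    means = r.mean(axis=2)
    if n_trans < min_transitions:
        return NeuronClassification(
            labels=np.array(["indeterminate"] * n_neurons),
            p_vs_odour=np.full(n_neurons, np.nan),
            p_vs_no_odour=np.full(n_neurons, np.nan),
            condition_means=means, alpha=alpha)
    p1 = ranksums(r[:, 0, :], r[:, 1, :], axis=1).pvalue
    p2 = ranksums(r[:, 0, :], r[:, 2, :], axis=1).pvalue
    labels = np.empty(n_neurons, dtype=object)
    for i in range(n_neurons):
        s1, s2 = p1[i] < alpha, p2[i] < alpha
        if s1 and s2:
            if means[i, 0] >= means[i].max():
                labels[i] = "prediction_error_positive"
            elif means[i, 0] <= means[i].min():
                labels[i] = "prediction_error_negative"
            else:
                labels[i] = "prediction_error_other"
        elif s1:
            labels[i] = "type_A"
        elif s2:
            labels[i] = "type_B"
        else:
            labels[i] = "none"
    return NeuronClassification(labels=labels.astype(str), p_vs_odour=p1,
                                p_vs_no_odour=p2, condition_means=means,
                                alpha=alpha)


def sustained_significance(traces_a: np.ndarray, traces_b: np.ndarray,
                           frame_rate: float, alpha: float = 0.01,
                           min_duration_s: float = 0.5) -> np.ndarray:
    """Frames inside runs of paired-t significance longer than ``min_duration_s``.

    ``traces_a``/``traces_b`` are paired observations of shape
    (n_pairs, n_frames).  A frame is flagged only when it belongs to a run of
    consecutive frames with two-sided paired-t p < alpha whose total duration
    strictly exceeds ``min_duration_s``.
    """
    a = np.asarray(traces_a, dtype=float)
    b = np.asarray(traces_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired traces must have identical shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 pairs for the paired t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ttest_rel(a, b, axis=0).pvalue
    sig = np.nan_to_num(p, nan=1.0) < alpha
    mask = np.zeros_like(sig)
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j < n and sig[j]:
                j += 1
            if (j - i) / frame_rate > min_duration_s:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decode_timecourse(activity: np.ndarray, labels: Sequence, n_folds: int = 5,
                      C: float = 1.0, seed: int = 0) -> DecodeResult:
    """Per-frame binary decoding with an L2 logistic classifier.

    ``activity`` has shape (n_trials, n_neurons, n_frames).  Classes are
    balanced by randomly subsampling the larger class, then accuracy is the
    mean over stratified k-fold test splits, computed independently at each
    frame.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(activity, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("decoding requires exactly two classes")
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(y == classes[0])
    idx1 = np.flatnonzero(y == classes[1])
    m = min(len(idx0), len(idx1))
    if m < n_folds:
        raise ValueError("each class needs at least n_folds trials")
    keep = np.concatenate([rng.choice(idx0, m, replace=False),
                           rng.choice(idx1, m, replace=False)])
    X, y = X[keep], y[keep]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    acc = np.zeros(X.shape[2])
    for f in range(X.shape[2]):
        Xf = X[:, :, f]
        scores = []
        for train, test in splits:
            clf = LogisticRegression(C=C, max_iter=1000)  # L2 penalty (default)
            clf.fit(Xf[train], y[train])
            scores.append(clf.score(Xf[test], y[test]))
        acc[f] = np.mean(scores)
    return DecodeResult(accuracy=acc, n_folds=n_folds, class_size=m)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_proportion_ci(labels: Sequence, subset_n: Optional[int] = None,
                            n_boot: int = 10_000, level: float = 0.99,
                            reference: Optional[float] = None,
                            seed: int = 0) -> BootstrapCI:
    """Percentile-bootstrap CI for a proportion.

    Resamples ``subset_n`` items with replacement from the binary ``labels``
    ``n_boot`` times; the CI spans the (1-level)/2 and 1-(1-level)/2
    percentiles of the resampled proportions (0.5th/99.5th at 99%).
    """
    x = np.asarray(labels, dtype=float)
    if subset_n is None:
        subset_n = len(x)
    if subset_n > len(x):
        raise ValueError("subset_n exceeds the population size")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(x), size=(n_boot, subset_n))
    props = x[draws].mean(axis=1)
    tail = (1.0 - level) / 2 * 100
    lower, upper = np.percentile(props, [tail, 100 - tail])
    out = BootstrapCI(proportion=float(x.mean()), lower=float(lower),
                      upper=float(upper), n_boot=n_boot, level=level)
    if reference is not None:
        out.reference = reference
        out.reference_outside = bool(reference < lower or reference > upper)
    return out


# ---------------------------------------------------------------------------
# Encoding model
# ---------------------------------------------------------------------------

def _shift(x: np.ndarray, s: int) -> np.ndarray:
    y = np.zeros_like(x)
    if s >= 0:
        y[s:] = x[:len(x) - s] if s else x
    else:
        y[:s] = x[-s:]
    return y


def build_design_matrix(regressors: dict, frame_rate: float,
                        motor_names: Sequence = ()) -> tuple:
    """Time-shifted design matrix.

    Sensory regressors contribute copies shifted 0 to +2 s; motor regressors
    (running, licking) -0.5 to +2 s, in one-frame steps.  Returns
    ``(X, column_is_motor)``.
    """
    fwd = _frames(2.0, frame_rate)
    back = _frames(0.5, frame_rate)
    cols, is_motor = [], []
    for name, x in regressors.items():
        x = np.asarray(x, dtype=float)
        motor = name in motor_names
        shifts = range(-back, fwd + 1) if motor else range(0, fwd + 1)
        for s in shifts:
            cols.append(_shift(x, s))
            is_motor.append(motor)
    return np.column_stack(cols), np.asarray(is_motor)


def _cv_r2(X: np.ndarray, y: np.ndarray, alphas: np.ndarray,
           n_folds: int, seed: int):
    """Best held-out R^2 over the penalty grid, via k-fold ridge."""
    from sklearn.linear_model import Ridge
    from sklearn.metrics import r2_score
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best_r2, best_alpha = -np.inf, alphas[0]
    for a in alphas:
        pred = np.zeros_like(y)
        for train, test in splits:
            model = Ridge(alpha=a)
            model.fit(X[train], y[train])
            pred[test] = model.predict(X[test])
        r2 = r2_score(y, pred)
        if r2 > best_r2:
            best_r2, best_alpha = r2, a
    return best_r2, best_alpha


def fit_encoding_model(dff: np.ndarray, frame_rate: float, regressors: dict,
                       motor_names: Sequence = ("running", "lick"),
                       alphas: Optional[np.ndarray] = None, n_folds: int = 5,
                       seed: int = 0) -> EncodingFit:
    """Ridge encoding model with per-neuron penalty selection.

    The penalty is chosen per neuron from 36 logarithmically spaced values in
    [1e-2, 1e5] by cross-validated R^2; the reduced model drops the motor
    (running/licking) regressors, and ΔR^2 = R^2(full) - R^2(reduced)
    quantifies overt-behaviour coding.
    """
    if alphas is None:
        alphas = np.logspace(-2, 5, 36)
    X, is_motor = build_design_matrix(regressors, frame_rate, motor_names)
    Xr = X[:, ~is_motor]
    dff = np.atleast_2d(dff)
    n = dff.shape[0]
    r2f = np.zeros(n)
    r2r = np.zeros(n)
    pen = np.zeros(n)
    for i in range(n):
        r2f[i], pen[i] = _cv_r2(X, dff[i], alphas, n_folds, seed)
        r2r[i], _ = _cv_r2(Xr, dff[i], alphas, n_folds, seed)
    return EncodingFit(r2_full=r2f, r2_reduced=r2r, delta_r2=r2f - r2r,
                       penalty=pen)
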