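"""Compiled simulation kernels for model fitting.

Fitting evaluates hundreds of candidate parameter sets, each requiring a
fresh multi-seed simulation of the agent in the task; the pure-Python
environment/agent classes are the reference implementation, and these
numba-jitted kernels reproduce their trial semantics at a per-step cost low
enough for dense grids and simplex refinement.  The kernels return per-trial
indicator arrays (cue shown / licked, block type, transition flags) from the
test phase, from which transition-aligned lick curves are assembled in
numpy.  Equivalence with the reference implementation is asserted
statistically in the test suite (the two paths use different random number
generators, so trajectories cannot match bit-for-bit).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


# cue codes follow task_env.TaskCue; block 0 = visual, 1 = odour
_V1, _V2, _O1, _O2, _END = 0, 1, 2, 3, 4


@njit(cache=True)
def _eps_greedy(q_nl, q_l, eps):
    if eps > 0.0 and np.random.random() < eps:
        return 1 if np.random.random() < 0.5 else 0
    if q_l > q_nl:
        return 1
    if q_nl > q_l:
        return 0
    return 1 if np.random.random() < 0.5 else 0


@njit(cache=True)
def _sim_session(is_belief, zeta, beta, eps, eps_p, alpha_train, basic_alpha,
                 factor_v, factor_o, p_irr, variant, n_train, n_test, seed,
                 max_block, thresh, acc_win, ign_win):
    """Simulate train then test phase; record test-phase trials.

    Returns (n_trials, shown, licked, block_type, is_boundary, n_capped).
    """
    np.random.seed(seed)
    # Q tables: [context, cue, action]; basic agent uses context 0 only
    q = np.zeros((2, 4, 2))
    bv, bo = 0.5, 0.5       # belief over (visual, odour)
    assumed = 0
    floor = 1e-9

    block = 0               # 0 visual, 1 odour
    in_trans = False
    cons_correct = 0
    trans_irr = 0
    # block-criterion ring buffers
    rel_ring = np.zeros(acc_win, dtype=np.uint8)
    irr_ring = np.zeros(ign_win, dtype=np.uint8)  # 0 none, 1 ignored, 2 licked
    block_len = 0
    rel_sum = 0
    need = int(thresh * acc_win)  # strictly greater than this count required

    max_out = n_test // 2 + 8
    shown = np.zeros((max_out, 4), dtype=np.uint8)
    licked = np.zeros((max_out, 4), dtype=np.uint8)
    block_type = np.zeros(max_out, dtype=np.uint8)
    is_boundary = np.zeros(max_out, dtype=np.uint8)
    n_out = 0
    n_capped = 0

    steps_done = 0
    total_steps = n_train + n_test
    pending_boundary = False

    cues = np.empty(3, dtype=np.int64)
    while steps_done < total_steps:
        in_test = steps_done >= n_train
        # ---- build the trial's cue sequence --------------------------
        n_cues = 0
        cues[0] = _END
        n_cues = 1
        if block == 0:
            if in_trans:
                final = _V1
            else:
                final = _V1 if np.random.random() < 0.5 else _V2
            cues[1] = final
            n_cues = 2
        else:
            has_irr = np.random.random() < p_irr
            odour = _O1 if np.random.random() < 0.5 else _O2
            if has_irr:
                if in_trans:
                    vis = _V2 if (variant == 1 and trans_irr == 0) else _V1
                else:
                    vis = _V1 if np.random.random() < 0.5 else _V2
                cues[1] = vis
                cues[2] = odour
                n_cues = 3
            else:
                cues[1] = odour
                n_cues = 2

        # ---- agent runs the trial ------------------------------------
        if is_belief:
            if bv > bo:
                assumed = 0
            elif bo > bv:
                assumed = 1
            ctx = assumed
        else:
            ctx = 0
        alpha = 0.0
        if is_belief:
            if not in_test:
                alpha = alpha_train
        else:
            alpha = basic_alpha

        prev_s = -1
        prev_a = 0
        prev_r = 0.0
        final_licked = False
        irr_licked = False
        for k in range(n_cues):
            cue = cues[k]
            e = eps_p if cue == _V2 else eps
            if cue == _END:
                a = _eps_greedy(0.0, 0.0, e)
            else:
                a = _eps_greedy(q[ctx, cue, 0], q[ctx, cue, 1], e)
            is_final = k == n_cues - 1
            if is_final:
                if a == 1:
                    r = 1.0 if (cue == _V1 or cue == _O1) else -1.0
                else:
                    r = 0.0
                if a == 1:
                    final_licked = True
            else:
                r = -1.0 if a == 1 else 0.0
                if a == 1 and k == 1 and n_cues == 3:
                    irr_licked = True
            # SARSA update for the previous step now that (s', a') is known
            if alpha > 0.0 and prev_s >= 0 and prev_s != _END:
                q_next = 0.0 if cue == _END else q[ctx, cue, a]
                q[ctx, prev_s, prev_a] += alpha * (prev_r + q_next
                                                   - q[ctx, prev_s, prev_a])
            prev_s, prev_a, prev_r = cue, a, r
        # final step bootstraps against the (zero-valued) end-of-trial cue
        if alpha > 0.0 and prev_s != _END:
            q[ctx, prev_s, prev_a] += alpha * (prev_r - q[ctx, prev_s, prev_a])
        steps_done += n_cues

        final_cue = cues[n_cues - 1]
        if final_cue == _V1 or final_cue == _O1:
            rel_correct = final_licked
        else:
            rel_correct = not final_licked

        # ---- record test-phase trial ---------------------------------
        if in_test and n_out < max_out:
            for k in range(n_cues):
                c = cues[k]
                if c < 4:
                    shown[n_out, c] = 1
            if irr_licked and n_cues == 3:
                licked[n_out, cues[1]] = 1
            if final_licked:
                licked[n_out, final_cue] = 1
            block_type[n_out] = block
            if pending_boundary:
                is_boundary[n_out] = 1
                pending_boundary = False
            n_out += 1

        # ---- belief update at trial end ------------------------------
        if is_belief:
            d_vis = final_cue == _V1 or final_cue == _V2
            chi_v = (1.0 - bv) if d_vis else (0.0 - bv)
            chi_o = (0.0 - bo) if d_vis else (1.0 - bo)
            factor = 1.0
            if in_test:
                factor = factor_v if d_vis else factor_o
            xi = np.random.normal()
            g = factor * (1.0 + beta * xi)
            nbv = bv + zeta * chi_v * g
            nbo = bo + zeta * chi_o * g
            if nbv < floor:
                nbv = floor
            if nbo < floor:
                nbo = floor
            if nbv <= floor and nbo <= floor:
                nbv, nbo = 0.5, 0.5
            z = nbv + nbo
            bv, bo = nbv / z, nbo / z

        # ---- transition-period bookkeeping ---------------------------
        if in_trans:
            if block == 0:
                if rel_correct:
                    cons_correct += 1
                else:
                    cons_correct = 0
            else:
                if n_cues == 3:
                    trans_irr += 1
                    if irr_licked:
                        cons_correct = 0
                    else:
                        cons_correct += 1
            if cons_correct >= 3:
                in_trans = False

        # ---- block-switch criterion ----------------------------------
        pos = block_len % acc_win
        if block_len >= acc_win:
            rel_sum -= rel_ring[pos]
        rel_ring[pos] = 1 if rel_correct else 0
        rel_sum += rel_ring[pos]
        ipos = block_len % ign_win
        if n_cues == 3 and block == 1:
            irr_ring[ipos] = 2 if irr_licked else 1
        else:
            irr_ring[ipos] = 0
        block_len += 1

        switched = False
        if block_len >= acc_win and rel_sum > need:
            if block == 1:
                ok = True
                lim = ign_win if block_len >= ign_win else block_len
                for k in range(lim):
                    if irr_ring[k] == 2:
                        ok = False
                        break
                switched = ok
            else:
                switched = True
        capped = (not switched) and block_len >= max_block
        if capped:
            n_capped += 1
        if switched or capped:
            block = 1 - block
            in_trans = True
            cons_correct = 0
            trans_irr = 0
            block_len = 0
            rel_sum = 0
            rel_ring[:] = 0
            irr_ring[:] = 0
            pending_boundary = True

    return n_out, shown, licked, block_type, is_boundary, n_capped


def simulate_arrays(model_kind: str, params: dict, env: dict,
                    n_train: int, n_test: int, seed: int, variant: int):
    """Run the jitted kernel; returns test-phase per-trial arrays.

    ``env`` keys: p_irrelevant_visual, max_block_trials,
    block_accuracy_threshold, block_accuracy_window, ignore_window.
    """
    is_belief = model_kind == "belief"
    n, shown, licked, block, bnd, n_capped = _sim_session(
        is_belief,
        float(params.get("zeta", 0.0)), float(params.get("beta", 0.0)),
        float(params.get("epsilon", 0.0)),
        float(params.get("epsilon_prime", params.get("epsilon", 0.0))
              if is_belief else params.get("epsilon", 0.0)),
        float(params.get("alpha_train", 0.1)),
        float(params.get("alpha", 0.1)),
        float(params.get("silencing_factor_visual", 1.0)),
        float(params.get("silencing_factor_odour", 1.0)),
        float(env.get("p_irrelevant_visual", 0.70)), int(variant),
        int(n_train), int(n_test), int(seed),
        int(env.get("max_block_trials", 500)),
        float(env.get("block_accuracy_threshold", 0.80)),
        int(env.get("block_accuracy_window", 30)),
        int(env.get("ignore_window", 10)),
    )
    boundaries = np.flatnonzero(bnd[:n])
    return (shown[:n].astype(np.float64), licked[:n].astype(np.float64),
            block[:n], boundaries, int(n_capped))
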