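"""Compiled array engine for the synchronous network loop.

This module implements exactly the semantics of
:class:`signet.network_sim.ReferenceSimulator` over flat numpy arrays,
jitted with numba, so that 50x50 grids can be run for 10^5-10^6 steps.
Because all randomness is counter-based (:mod:`signet.rng`), the two
engines produce bit-identical trajectories; the test suite asserts this
on small grids.

The only structural difference from the reference loop is *when* the
forgetting rule is evaluated: the reference checks every subthreshold
step, while the kernel checks only when the occurrence count can have
changed — on a spike arrival, when an event ages out of the context
window (tracked via a per-neuron next-expiry bound), or on the first
subthreshold step after a burst/refractory period.  Occurrence counts
are pure functions of the windowed context, so the outcomes coincide.

Per-neuron context memory is a fixed ring buffer per input channel,
sized from the parameters so the window can never overflow it.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from numba import njit

from .core_model import NeuralSignature
from .network_sim import (
    ActivityRecord,
    SimulationConfig,
    build_torus_grid,
    generate_random_signatures,
    initial_potentials,
    resolve_stimuli,
)
from .rng import SALT_CHANNEL_ORDER, SALT_DYNAMICS, _uniform

_INF = np.int64(1) << np.int64(62)


@njit(cache=True)
def _ctx_append(ctx_time, ctx_start, ctx_cnt, i, ch, t):
    cap = ctx_time.shape[2]
    if ctx_cnt[i, ch] == cap:  # should not happen with a properly sized cap
        ctx_start[i, ch] = (ctx_start[i, ch] + 1) % cap
        ctx_cnt[i, ch] -= 1
    slot = (ctx_start[i, ch] + ctx_cnt[i, ch]) % cap
    ctx_time[i, ch, slot] = t
    ctx_cnt[i, ch] += 1


@njit(cache=True)
def _ctx_get(ctx_time, ctx_start, i, ch, idx):
    cap = ctx_time.shape[2]
    return ctx_time[i, ch, (ctx_start[i, ch] + idx) % cap]


@njit(cache=True)
def _ctx_prune(ctx_time, ctx_start, ctx_cnt, i, ch, t, M):
    cap = ctx_time.shape[2]
    cutoff = t - M
    while ctx_cnt[i, ch] > 0 and ctx_time[i, ch, ctx_start[i, ch]] < cutoff:
        ctx_start[i, ch] = (ctx_start[i, ch] + 1) % cap
        ctx_cnt[i, ch] -= 1


@njit(cache=True)
def _candidate(ctx_time, ctx_start, ctx_cnt, i, ch, K, gap, cand):
    """Trailing-K ISIs of the run ending at the newest event, if any."""
    cnt = ctx_cnt[i, ch]
    if cnt < K + 1:
        return False
    for j in range(K):
        a = _ctx_get(ctx_time, ctx_start, i, ch, cnt - K - 1 + j)
        b = _ctx_get(ctx_time, ctx_start, i, ch, cnt - K + j)
        isi = b - a
        if isi > gap:
            return False
        cand[j] = isi
    return True


@njit(cache=True)
def _count_tail(ctx_time, ctx_start, ctx_cnt, i, ch, pat, K, gap):
    """Number of runs whose trailing K ISIs equal ``pat``."""
    cnt = ctx_cnt[i, ch]
    if cnt < K + 1:
        return 0
    hits = 0
    run_start = 0
    for idx in range(1, cnt + 1):
        run_ends = idx == cnt or (
            _ctx_get(ctx_time, ctx_start, i, ch, idx)
            - _ctx_get(ctx_time, ctx_start, i, ch, idx - 1)
            > gap
        )
        if run_ends:
            if idx - run_start >= K + 1:
                ok = True
                for j in range(K):
                    a = _ctx_get(ctx_time, ctx_start, i, ch, idx - 1 - K + j)
                    b = _ctx_get(ctx_time, ctx_start, i, ch, idx - K + j)
                    if b - a != pat[j]:
                        ok = False
                        break
                if ok:
                    hits += 1
            run_start = idx
    return hits


@njit(cache=True)
def _recompute_expiry(ctx_time, ctx_start, ctx_cnt, i, t, M):
    oldest = _INF
    for ch in range(9):
        _ctx_prune(ctx_time, ctx_start, ctx_cnt, i, ch, t, M)
        if ctx_cnt[i, ch] > 0:
            first = ctx_time[i, ch, ctx_start[i, ch]]
            if first < oldest:
                oldest = first
    if oldest == _INF:
        return _INF
    return oldest + M + 1


@njit(cache=True)
def _match_tracked(cand, tracked, K):
    for r in range(tracked.shape[0]):
        ok = True
        for j in range(K):
            if tracked[r, j] != cand[j]:
                ok = False
                break
        if ok:
            return r
    return -2


@njit(cache=True)
def _set_label(pref_label, tracked_counts, i, lab):
    old = pref_label[i]
    if old >= 0:
        tracked_counts[old] -= 1
    if lab >= 0:
        tracked_counts[lab] += 1
    pref_label[i] = lab


@njit(cache=True)
def _advance_chunk(
    t0,
    nsteps,
    seed,
    n,
    p,
    TH,
    RP,
    AP,
    g,
    M,
    L,
    gap,
    K,
    nbr,
    stim_cell,
    stim_period,
    stim_start,
    stim_end,
    stim_ge,
    V,
    mode,
    t1,
    rp,
    spike_idx,
    seq_off,
    seq_len,
    sig,
    pref,
    pref_len,
    pref_label,
    ctx_time,
    ctx_start,
    ctx_cnt,
    pending,
    next_expiry,
    check_flag,
    spk_prev,
    n_spk_prev,
    tracked,
    tracked_counts,
    store_v,
    v_out,
    counts_out,
    store_labels,
    label_out,
    record_raster,
    spike_t_buf,
    spike_c_buf,
    isyn,
    spk_now,
    cand,
):
    useed = np.uint64(seed)
    salt_dyn = np.uint64(SALT_DYNAMICS)
    salt_perm = np.uint64(SALT_CHANNEL_ORDER)
    Tk = tracked.shape[0]
    n_spk = n_spk_prev
    n_raster = 0
    raster_cap = spike_t_buf.shape[0]
    overflow = 0
    keys = np.empty(9, dtype=np.float64)
    chs = np.empty(9, dtype=np.int64)

    for step in range(nsteps):
        t = t0 + 1 + step

        # --- deliver last step's spikes (one-step delay) -----------------
        for i in range(n):
            isyn[i] = 0
        for s in range(n_spk):
            j = spk_prev[s]
            for k in range(8):
                i = nbr[j, k]
                ch = 7 - k  # receiver's channel for a sender at -offset
                _ctx_append(ctx_time, ctx_start, ctx_cnt, i, ch, t)
                pending[i, ch] = 1
                if t + M + 1 < next_expiry[i]:
                    next_expiry[i] = t + M + 1
                isyn[i] += g
        for s in range(stim_cell.shape[0]):
            if (
                stim_start[s] <= t
                and t <= stim_end[s]
                and (t - stim_start[s]) % stim_period[s] == 0
            ):
                c = stim_cell[s]
                _ctx_append(ctx_time, ctx_start, ctx_cnt, c, 8, t)
                pending[c, 8] = 1
                if t + M + 1 < next_expiry[c]:
                    next_expiry[c] = t + M + 1
                isyn[c] += stim_ge[s]

        # --- plasticity + dynamics, per neuron ---------------------------
        n_now = 0
        for i in range(n):
            m = mode[i]
            if m == 0:  # SUBTHRESHOLD
                has_pending = False
                for ch in range(9):
                    if pending[i, ch] == 1:
                        has_pending = True
                        break
                expiry_due = t >= next_expiry[i]
                flagged = check_flag[i] == 1
                if has_pending:
                    # fresh random processing order over arrived channels
                    nch = 0
                    for ch in range(9):
                        if pending[i, ch] == 1:
                            key = _uniform(
                                useed,
                                np.uint64(i * 16 + ch),
                                np.uint64(t),
                                salt_perm,
                            )
                            pos = nch
                            while pos > 0 and keys[pos - 1] > key:
                                keys[pos] = keys[pos - 1]
                                chs[pos] = chs[pos - 1]
                                pos -= 1
                            keys[pos] = key
                            chs[pos] = ch
                            nch += 1
                            pending[i, ch] = 0
                    for q in range(nch):
                        ch = chs[q]
                        _ctx_prune(ctx_time, ctx_start, ctx_cnt, i, ch, t, M)
                        if _candidate(
                            ctx_time, ctx_start, ctx_cnt, i, ch, K, gap, cand
                        ):
                            # occurrences pooled over the whole context
                            cnt = 0
                            for ch2 in range(9):
                                _ctx_prune(
                                    ctx_time, ctx_start, ctx_cnt, i, ch2, t, M
                                )
                                cnt += _count_tail(
                                    ctx_time, ctx_start, ctx_cnt, i, ch2,
                                    cand, K, gap,
                                )
                            if cnt >= L:
                                for j in range(K):
                                    pref[i, j] = cand[j]
                                pref_len[i] = K
                                lab = _match_tracked(cand, tracked, K)
                                _set_label(pref_label, tracked_counts, i, lab)
                if pref_len[i] > 0 and (has_pending or expiry_due or flagged):
                    total = 0
                    for ch in range(9):
                        _ctx_prune(ctx_time, ctx_start, ctx_cnt, i, ch, t, M)
                        total += _count_tail(
                            ctx_time, ctx_start, ctx_cnt, i, ch, pref[i], K, gap
                        )
                        if total >= L:
                            break
                    if total < L:
                        pref_len[i] = 0
                        _set_label(pref_label, tracked_counts, i, -1)
                if expiry_due or flagged:
                    next_expiry[i] = _recompute_expiry(
                        ctx_time, ctx_start, ctx_cnt, i, t, M
                    )
                check_flag[i] = 0
                u = _uniform(useed, np.uint64(i), np.uint64(t), salt_dyn)
                if u < p:
                    V[i] += isyn[i] + 1
                else:
                    V[i] += isyn[i]
                if V[i] >= TH:
                    # freeze the firing sequence from (signature, preferred)
                    off = 0
                    seq_off[i, 0] = 0
                    sl = 1
                    for j in range(K):
                        off += sig[i, j]
                        seq_off[i, sl] = off
                        sl += 1
                    if pref_len[i] > 0:
                        for j in range(K):
                            off += pref[i, j]
                            seq_off[i, sl] = off
                            sl += 1
                    seq_len[i] = sl
                    t1[i] = t + 1
                    spike_idx[i] = 0
                    mode[i] = 1
            elif m == 1:  # BURSTING
                dt = t - t1[i]
                kk = spike_idx[i]
                sl = seq_len[i]
                if kk < sl and dt == seq_off[i, kk]:
                    V[i] = AP
                    spike_idx[i] = kk + 1
                    spk_now[n_now] = i
                    n_now += 1
                    if record_raster == 1:
                        if n_raster < raster_cap:
                            spike_t_buf[n_raster] = t
                            spike_c_buf[n_raster] = i
                            n_raster += 1
                        else:
                            overflow = 1
                elif kk == sl and dt == seq_off[i, sl - 1] + 1:
                    V[i] = 0
                    if RP > 0:
                        mode[i] = 2
                        rp[i] = RP
                    else:
                        mode[i] = 0
                        check_flag[i] = 1
                elif kk > 0 and dt == seq_off[i, kk - 1] + 1:
                    V[i] = TH + 1
                else:
                    u = _uniform(useed, np.uint64(i), np.uint64(t), salt_dyn)
                    if u < p:
                        V[i] += 1
            else:  # REFRACTORY
                V[i] = 0
                rp[i] -= 1
                if rp[i] <= 0:
                    mode[i] = 0
                    check_flag[i] = 1

        # --- log ---------------------------------------------------------
        if store_v == 1:
            for i in range(n):
                v_out[step, i] = V[i]
        for k in range(Tk):
            counts_out[step, k] = tracked_counts[k]
        if store_labels == 1:
            for i in range(n):
                if pref_len[i] == 0:
                    label_out[step, i] = -1
                else:
                    label_out[step, i] = pref_label[i]

        for s in range(n_now):
            spk_prev[s] = spk_now[s]
        n_spk = n_now

    return n_spk, n_raster, overflow


def _context_capacity(config: SimulationConfig) -> int:
    """Ring size per channel such that a full window always fits."""
    pl = config.plasticity
    lo, _ = config.isi_range
    max_spikes = 2 * pl.pattern_len + 1
    min_burst = 2 * pl.pattern_len * lo + 1
    min_cycle = max(1, min_burst + config.neuron.RP + 1)
    cap = (pl.M // min_cycle + 2) * max_spikes + 4
    periods = [s.period for s in config.stimuli]
    if periods:
        cap = max(cap, pl.M // min(periods) + 4)
    return int(cap)


def run_fast(
    config: SimulationConfig,
    frame_stride: int = 0,
    record_raster: bool = False,
    label_stride: int = 0,
    track_complexity: bool = False,
    complexity_eps: Optional[float] = None,
    tracked_cells: Optional[Sequence[int]] = None,
    chunk_steps: int = 2048,
) -> ActivityRecord:
    """Run the compiled engine and assemble an :class:`ActivityRecord`.

    frame_stride / label_stride of 0 disable V-frame / label-frame
    storage (the per-step signature counts are always kept).  With
    ``track_complexity`` the 2D Haar complexity C(t) is computed inline
    for *every* step without retaining the frames.
    """
    config.validate()
    cfg = config
    n = cfg.n_cells
    K = cfg.plasticity.pattern_len
    topo = build_torus_grid(cfg.rows, cfg.cols, cfg.g)
    stimuli = resolve_stimuli(cfg)
    if cfg.signatures is not None:
        sigs = list(cfg.signatures)
    else:
        sigs = generate_random_signatures(
            n, cfg.signature_spikes, cfg.isi_range, cfg.seed
        )
    sig_arr = np.array([s.isis for s in sigs], dtype=np.int64).reshape(n, K)

    if tracked_cells is None:
        tracked_cells = tuple(dict.fromkeys(s.cell for s in stimuli))
    else:
        tracked_cells = tuple(int(c) for c in tracked_cells)
    tracked_sigs = tuple(sigs[c] for c in tracked_cells)
    Tk = len(tracked_cells)
    tracked = np.array(
        [s.isis for s in tracked_sigs], dtype=np.int64
    ).reshape(Tk, K)

    stim_cell = np.array([s.cell for s in stimuli], dtype=np.int64)
    stim_period = np.array([s.period for s in stimuli], dtype=np.int64)
    stim_start = np.array([s.t_start for s in stimuli], dtype=np.int64)
    stim_end = np.array(
        [cfg.duration if s.t_end is None else s.t_end for s in stimuli],
        dtype=np.int64,
    )
    stim_ge = np.array([s.g_e for s in stimuli], dtype=np.int64)

    # dynamic state
    V = initial_potentials(cfg).astype(np.int64)
    mode = np.zeros(n, dtype=np.int64)
    t1 = np.full(n, -1, dtype=np.int64)
    rp = np.zeros(n, dtype=np.int64)
    spike_idx = np.zeros(n, dtype=np.int64)
    seq_off = np.zeros((n, 2 * K + 1), dtype=np.int64)
    seq_len = np.zeros(n, dtype=np.int64)
    pref = np.zeros((n, K), dtype=np.int64)
    pref_len = np.zeros(n, dtype=np.int64)
    pref_label = np.full(n, -1, dtype=np.int64)
    cap = _context_capacity(cfg)
    ctx_time = np.zeros((n, 9, cap), dtype=np.int64)
    ctx_start = np.zeros((n, 9), dtype=np.int64)
    ctx_cnt = np.zeros((n, 9), dtype=np.int64)
    pending = np.zeros((n, 9), dtype=np.int64)
    next_expiry = np.full(n, _INF, dtype=np.int64)
    check_flag = np.zeros(n, dtype=np.int64)
    spk_prev = np.zeros(n, dtype=np.int64)
    tracked_counts = np.zeros(Tk, dtype=np.int64)
    isyn = np.zeros(n, dtype=np.int64)
    spk_now = np.zeros(n, dtype=np.int64)
    cand = np.zeros(K, dtype=np.int64)

    T = cfg.duration
    store_v = 1 if (frame_stride > 0 or track_complexity) else 0
    store_labels = 1 if label_stride > 0 else 0

    counts_full = np.zeros((Tk, T + 1), dtype=np.int64)
    if track_complexity:
        from .analysis import complexity_of_frames, default_eps

        eps = default_eps(cfg.neuron.AP) if complexity_eps is None else complexity_eps
        complexity = np.zeros(T + 1, dtype=np.int64)
        complexity[0] = complexity_of_frames(
            V.reshape(1, cfg.rows, cfg.cols), eps
        )[0]
    else:
        eps = None
        complexity = None

    if frame_stride > 0:
        frame_times = np.arange(0, T + 1, frame_stride)
        v_frames = np.zeros(
            (len(frame_times), cfg.rows, cfg.cols), dtype=np.int32
        )
        v_frames[0] = V.reshape(cfg.rows, cfg.cols)
    else:
        frame_times = None
        v_frames = None
    if label_stride > 0:
        label_times = np.arange(0, T + 1, label_stride)
        label_frames = np.full(
            (len(label_times), cfg.rows, cfg.cols), -1, dtype=np.int16
        )
    else:
        label_times = None
        label_frames = None

    raster_t: list = []
    raster_c: list = []

    chunk = max(1, int(chunk_steps))
    v_chunk = np.zeros((chunk if store_v else 1, n), dtype=np.int32)
    counts_chunk = np.zeros((chunk, Tk), dtype=np.int64)
    label_chunk = np.zeros((chunk if store_labels else 1, n), dtype=np.int16)
    raster_cap = chunk * (n // 2 + 1) if record_raster else 1
    spike_t_buf = np.zeros(raster_cap, dtype=np.int64)
    spike_c_buf = np.zeros(raster_cap, dtype=np.int32)

    n_spk_prev = 0
    t0 = 0
    while t0 < T:
        nsteps = min(chunk, T - t0)
        n_spk_prev, n_raster, overflow = _advance_chunk(
            t0, nsteps, cfg.seed, n,
            cfg.neuron.p, cfg.neuron.TH, cfg.neuron.RP, cfg.neuron.AP,
            cfg.g,
            cfg.plasticity.M, cfg.plasticity.L, cfg.plasticity.gap, K,
            topo.neighbor_array,
            stim_cell, stim_period, stim_start, stim_end, stim_ge,
            V, mode, t1, rp, spike_idx, seq_off, seq_len,
            sig_arr, pref, pref_len, pref_label,
            ctx_time, ctx_start, ctx_cnt, pending, next_expiry, check_flag,
            spk_prev, n_spk_prev, tracked, tracked_counts,
            store_v, v_chunk[:nsteps] if store_v else v_chunk,
            counts_chunk[:nsteps],
            store_labels, label_chunk[:nsteps] if store_labels else label_chunk,
            1 if record_raster else 0, spike_t_buf, spike_c_buf,
            isyn, spk_now, cand,
        )
        if overflow:
            raise RuntimeError(
                "spike raster buffer overflow; increase chunk raster capacity"
            )
        ts = np.arange(t0 + 1, t0 + nsteps + 1)
        counts_full[:, ts] = counts_chunk[:nsteps].T
        if track_complexity:
            complexity[ts] = complexity_of_frames(
                v_chunk[:nsteps].reshape(nsteps, cfg.rows, cfg.cols), eps
            )
        if frame_stride > 0:
            sel = np.flatnonzero(ts % frame_stride == 0)
            if sel.size:
                rows = ts[sel] // frame_stride
                v_frames[rows] = v_chunk[sel].reshape(
                    -1, cfg.rows, cfg.cols
                )
        if label_stride > 0:
            sel = np.flatnonzero(ts % label_stride == 0)
            if sel.size:
                rows = ts[sel] // label_stride
                label_frames[rows] = label_chunk[sel].reshape(
                    -1, cfg.rows, cfg.cols
                )
        if record_raster and n_raster:
            raster_t.append(spike_t_buf[:n_raster].copy())
            raster_c.append(spike_c_buf[:n_raster].copy())
        t0 += nsteps

    if record_raster:
        spike_times = (
            np.concatenate(raster_t) if raster_t else np.zeros(0, dtype=np.int64)
        )
        spike_cells = (
            np.concatenate(raster_c) if raster_c else np.zeros(0, dtype=np.int32)
        )
    else:
        spike_times = spike_cells = None

    return ActivityRecord(
        config=cfg,
        stimuli=stimuli,
        tracked_cells=tracked_cells,
        tracked_signatures=tracked_sigs,
        signature_counts=counts_full,
        frame_stride=frame_stride,
        v_frames=v_frames,
        frame_times=frame_times,
        label_stride=label_stride,
        label_frames=label_frames,
        label_times=label_times,
        spike_times=spike_times,
        spike_cells=spike_cells,
        complexity=complexity,
        complexity_eps=eps,
    )
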