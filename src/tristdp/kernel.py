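"""Flat-array simulation kernel.

One tight loop advances LIF membranes, the delay ring buffer, post-synaptic
event histories and lazily processed plastic rows over the whole run.  The
algorithm is identical to the object-level machinery in
:mod:`tristdp.engine` (the test suite asserts agreement to floating-point
round-off); this version lays every structure out in numpy arrays so the
loop can be compiled with numba.  When numba is unavailable the same
function runs as plain Python.

Conventions
-----------
* Pre-synaptic entities are numbered ``0..n_pre-1``; entity ``e`` is LIF
  neuron ``e`` when ``e < n_neurons``, otherwise an external spike source.
* All event arrays are int64 step times, sorted ascending.
* Histories are fixed-capacity per-neuron arrays; when one fills up, entries
  older than the oldest unprocessed-row time are compacted away (always
  keeping the entry immediately preceding it).  A run whose history cannot
  be compacted aborts with a nonzero status.
* Within a step: ring-buffer consumption and membrane update, forced
  spikes, dopamine history entries, post-spike history entries, row
  processing for every pre entity that spiked, then any scheduled weight
  snapshot (a semantics-preserving flush of all rows).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(f):
        return _njit(f)

except ImportError:  # pragma: no cover
    def _jit(f):
        return f

POST = 0
DOPAMINE = 1

STATUS_OK = 0
STATUS_HISTORY_OVERFLOW = 1
STATUS_SPIKES_TRUNCATED = 2


@_jit
def _last_le(arr, n, x):
    """Index of the last of arr[:n] that is <= x, or -1."""
    lo = 0
    hi = n
    while lo < hi:
        mid = (lo + hi) // 2
        if arr[mid] <= x:
            lo = mid + 1
        else:
            hi = mid
    return lo - 1


@_jit
def _hist_append(
    hist_t, hist_s, hist_d, hist_kind, hist_len,
    rev_ptr, rev_row, row_t_old,
    j, t, kind, d_c, tau_s, tau_d,
):
    """Append one history entry for neuron j, compacting if full.

    Returns 0 on success, -1 if the history is full and nothing can be
    dropped (every entry may still be needed by a lagging row).
    """
    cap = hist_t.shape[1]
    length = hist_len[j]
    if length == cap:
        if rev_ptr[j] == rev_ptr[j + 1]:
            keep_from = length - 1  # no plastic row targets j: last entry suffices
        else:
            m = 9223372036854775807
            for q in range(rev_ptr[j], rev_ptr[j + 1]):
                t_old = row_t_old[rev_row[q]]
                if t_old < m:
                    m = t_old
            keep_from = _last_le(hist_t[j], length, m)
            if keep_from < 0:
                keep_from = 0
        if keep_from <= 0:
            return -1
        for q in range(keep_from, length):
            hist_t[j, q - keep_from] = hist_t[j, q]
            hist_s[j, q - keep_from] = hist_s[j, q]
            hist_d[j, q - keep_from] = hist_d[j, q]
            hist_kind[j, q - keep_from] = hist_kind[j, q]
        length -= keep_from
        hist_len[j] = length
    if length == 0:
        s = 0.0
        d = 0.0
    else:
        dt = t - hist_t[j, length - 1]
        s = hist_s[j, length - 1] * np.exp(-dt / tau_s)
        d = hist_d[j, length - 1] * np.exp(-dt / tau_d)
    if kind == POST:
        s += 1.0
    else:
        d += d_c
    hist_t[j, length] = t
    hist_s[j, length] = s
    hist_d[j, length] = d
    hist_kind[j, length] = kind
    hist_len[j] = length + 1
    return 0


@_jit
def _advance_row(
    e, t, full,
    p_ptr, p_tgt, p_delay, p_w, p_c, row_t_old, row_s_i,
    hist_t, hist_s, hist_d, hist_kind, hist_len,
    a_plus, a_minus, tau_plus, tau_minus, tau_c, tau_d, w_min, w_max,
    rb_exc, rb_inh,
):
    """Bring row e up to time t (three-factor rule).

    ``full`` marks a real pre spike: apply the depression term, deposit the
    weights into the ring buffer and increment the pre trace.  Otherwise
    this is a semantics-preserving flush (snapshot / end of run).
    """
    t_old = row_t_old[e]
    if t <= t_old:
        return
    size = rb_exc.shape[0]
    k_sum = 1.0 / tau_c + 1.0 / tau_d
    s_i = row_s_i[e]
    for kk in range(p_ptr[e], p_ptr[e + 1]):
        j = p_tgt[kk]
        length = hist_len[j]
        ip = _last_le(hist_t[j], length, t_old)
        if ip >= 0:
            d = hist_d[j, ip] * np.exp(-(t_old - hist_t[j, ip]) / tau_d)
        else:
            d = 0.0
        t_c = t_old
        w = p_w[kk]
        c = p_c[kk]
        q = ip + 1
        while q < length and hist_t[j, q] <= t:
            tj = hist_t[j, q]
            if c != 0.0 and d != 0.0 and tj > t_c:
                dtq = tj - t_c
                w += c * d / (-k_sum) * (
                    np.exp(-dtq / tau_c) * np.exp(-dtq / tau_d) - 1.0
                )
            c *= np.exp(-(tj - t_c) / tau_c)
            if hist_kind[j, q] == POST:
                c += a_plus * s_i * np.exp(-(tj - t_old) / tau_plus)
            d = hist_d[j, q]
            t_c = tj
            q += 1
        if c != 0.0 and d != 0.0 and t > t_c:
            dtq = t - t_c
            w += c * d / (-k_sum) * (
                np.exp(-dtq / tau_c) * np.exp(-dtq / tau_d) - 1.0
            )
        c *= np.exp(-(t - t_c) / tau_c)
        if full:
            il = length - 1
            if il >= 0:
                s = hist_s[j, il]
                # a pre spike never pairs with a simultaneous post spike
                if hist_t[j, il] == t and hist_kind[j, il] == POST:
                    s -= 1.0
                c -= a_minus * s * np.exp(-(t - hist_t[j, il]) / tau_minus)
        if w < w_min:
            w = w_min
        elif w > w_max:
            w = w_max
        p_w[kk] = w
        p_c[kk] = c
        if full:
            slot = (t + p_delay[kk]) % size
            if w >= 0.0:
                rb_exc[slot, j] += w
            else:
                rb_inh[slot, j] += w
    if full:
        row_s_i[e] = s_i * np.exp(-(t - t_old) / tau_plus) + 1.0
    else:
        row_s_i[e] = s_i * np.exp(-(t - t_old) / tau_plus)
    row_t_old[e] = t


@_jit
def _record_snapshot(p_w, mask, snap_mask_mean, snap_global_mean, si):
    total = 0.0
    n_total = 0
    masked = 0.0
    n_masked = 0
    for kk in range(p_w.shape[0]):
        total += p_w[kk]
        n_total += 1
        if mask[kk]:
            masked += p_w[kk]
            n_masked += 1
    snap_global_mean[si] = total / n_total if n_total > 0 else np.nan
    snap_mask_mean[si] = masked / n_masked if n_masked > 0 else np.nan


@_jit
def simulate_core(
    n_steps,
    # neuron state (modified in place)
    v, isyn_e, isyn_i, refrac,
    # per-neuron parameters
    vrest, vreset, vthresh, ioff, rm, dec_m, dec_e, dec_i, refrac_steps,
    # plastic rows (CSR over pre entities)
    p_ptr, p_tgt, p_delay, p_w, p_c, row_t_old, row_s_i,
    # static rows (CSR over pre entities)
    st_ptr, st_tgt, st_delay, st_w,
    # sorted event streams
    ext_t, ext_pre,          # external-entity spikes
    f_t, f_n,                # forced neuron spikes
    da_t, da_tgt, da_dc,     # dopaminergic spikes (bypass the ring buffer)
    pu_t, pu_n, pu_amp,      # 1 ms current pulses
    # plasticity parameters
    a_plus, a_minus, tau_plus, tau_minus, tau_c, tau_d, w_min, w_max,
    # post-synaptic histories
    hist_t, hist_s, hist_d, hist_kind, hist_len, rev_ptr, rev_row,
    # ring buffers [slot, neuron]
    rb_exc, rb_inh,
    # outputs
    spike_t, spike_n,
    snap_times, snap_mask_mean, snap_global_mean, mask,
    record_spikes,
):
    n = v.shape[0]
    n_pre = p_ptr.shape[0] - 1
    size = rb_exc.shape[0]
    spiked = np.zeros(n, dtype=np.uint8)
    spike_list = np.empty(n, dtype=np.int64)
    iext = np.zeros(n)
    pe = 0
    pf = 0
    pda = 0
    ppu = 0
    si = 0
    ns = 0
    status = STATUS_OK

    for t in range(n_steps):
        slot = t % size
        ppu0 = ppu
        while ppu < pu_t.shape[0] and pu_t[ppu] == t:
            iext[pu_n[ppu]] += pu_amp[ppu]
            ppu += 1
        nspk = 0
        for j in range(n):
            isyn_e[j] += rb_exc[slot, j]
            rb_exc[slot, j] = 0.0
            isyn_i[j] += rb_inh[slot, j]
            rb_inh[slot, j] = 0.0
            if refrac[j] > 0:
                refrac[j] -= 1
                v[j] = vreset[j]
            else:
                i_total = isyn_e[j] + isyn_i[j] + ioff[j] + iext[j]
                v_inf = vrest[j] + rm[j] * i_total
                v[j] = v_inf + (v[j] - v_inf) * dec_m[j]
                if v[j] >= vthresh[j]:
                    v[j] = vreset[j]
                    refrac[j] = refrac_steps[j]
                    spiked[j] = 1
                    spike_list[nspk] = j
                    nspk += 1
            isyn_e[j] *= dec_e[j]
            isyn_i[j] *= dec_i[j]
        for q in range(ppu0, ppu):
            iext[pu_n[q]] = 0.0
        # forced spikes (override threshold and refractoriness)
        while pf < f_t.shape[0] and f_t[pf] == t:
            j = f_n[pf]
            pf += 1
            if spiked[j] == 0:
                spiked[j] = 1
                spike_list[nspk] = j
                nspk += 1
                v[j] = vreset[j]
                refrac[j] = refrac_steps[j]
        if record_spikes:
            for q in range(nspk):
                if ns < spike_t.shape[0]:
                    spike_t[ns] = t
                    spike_n[ns] = spike_list[q]
                    ns += 1
                else:
                    status = STATUS_SPIKES_TRUNCATED
        # dopamine entries precede post entries at equal times
        while pda < da_t.shape[0] and da_t[pda] == t:
            ok = _hist_append(
                hist_t, hist_s, hist_d, hist_kind, hist_len,
                rev_ptr, rev_row, row_t_old,
                da_tgt[pda], t, DOPAMINE, da_dc[pda], tau_minus, tau_d,
            )
            if ok < 0:
                return ns, STATUS_HISTORY_OVERFLOW
            pda += 1
        for q in range(nspk):
            ok = _hist_append(
                hist_t, hist_s, hist_d, hist_kind, hist_len,
                rev_ptr, rev_row, row_t_old,
                spike_list[q], t, POST, 0.0, tau_minus, tau_d,
            )
            if ok < 0:
                return ns, STATUS_HISTORY_OVERFLOW
        # process rows of every pre entity that spiked this step
        for q in range(nspk):
            e = spike_list[q]
            if e < n_pre:
                _advance_row(
                    e, t, True,
                    p_ptr, p_tgt, p_delay, p_w, p_c, row_t_old, row_s_i,
                    hist_t, hist_s, hist_d, hist_kind, hist_len,
                    a_plus, a_minus, tau_plus, tau_minus, tau_c, tau_d,
                    w_min, w_max, rb_exc, rb_inh,
                )
                for kk in range(st_ptr[e], st_ptr[e + 1]):
                    s2 = (t + st_delay[kk]) % size
                    if st_w[kk] >= 0.0:
                        rb_exc[s2, st_tgt[kk]] += st_w[kk]
                    else:
                        rb_inh[s2, st_tgt[kk]] += st_w[kk]
        while pe < ext_t.shape[0] and ext_t[pe] == t:
            e = ext_pre[pe]
            pe += 1
            _advance_row(
                e, t, True,
                p_ptr, p_tgt, p_delay, p_w, p_c, row_t_old, row_s_i,
                hist_t, hist_s, hist_d, hist_kind, hist_len,
                a_plus, a_minus, tau_plus, tau_minus, tau_c, tau_d,
                w_min, w_max, rb_exc, rb_inh,
            )
            for kk in range(st_ptr[e], st_ptr[e + 1]):
                s2 = (t + st_delay[kk]) % size
                if st_w[kk] >= 0.0:
                    rb_exc[s2, st_tgt[kk]] += st_w[kk]
                else:
                    rb_inh[s2, st_tgt[kk]] += st_w[kk]
        for q in range(nspk):
            spiked[spike_list[q]] = 0
        # scheduled weight snapshots: flush every row, then record means
        while si < snap_times.shape[0] and snap_times[si] == t:
            for e in range(n_pre):
                _advance_row(
                    e, t, False,
                    p_ptr, p_tgt, p_delay, p_w, p_c, row_t_old, row_s_i,
                    hist_t, hist_s, hist_d, hist_kind, hist_len,
                    a_plus, a_minus, tau_plus, tau_minus, tau_c, tau_d,
                    w_min, w_max, rb_exc, rb_inh,
                )
            _record_snapshot(p_w, mask, snap_mask_mean, snap_global_mean, si)
            si += 1

    # end-of-run flush so reported weights include pending drift
    for e in range(n_pre):
        _advance_row(
            e, n_steps, False,
            p_ptr, p_tgt, p_delay, p_w, p_c, row_t_old, row_s_i,
            hist_t, hist_s, hist_d, hist_kind, hist_len,
            a_plus, a_minus, tau_plus, tau_minus, tau_c, tau_d,
            w_min, w_max, rb_exc, rb_inh,
        )
    while si < snap_times.shape[0]:
        _record_snapshot(p_w, mask, snap_mask_mean, snap_global_mean, si)
        si += 1
    return ns, status
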