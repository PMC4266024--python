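"""Event-driven compiled simulation kernel.

The network is flattened into a single synapse table (presynaptic index,
postsynaptic index, weight, rule, bound, plastic flag) stored in CSR
order by presynaptic neuron, with a CSC permutation for fast afferent
access.  Presynaptic indices live in a global space: source neurons first
(0..K-1, spike trains supplied by the encoder), then the K.. offsets of
the internal neurons (reservoir E, reservoir I, sink E, sink I).

Per step and in this order: conductances decay and absorb last step's
spikes (one-step synaptic delay), membrane potentials advance one Euler
step and threshold crossings spike and reset, STDP runs for afferents of
each spiking neuron (against the presynaptic neuron's previous spike)
and efferents of each spiking neuron (against the postsynaptic neuron's
latest spike, so simultaneous pairs enter once at dt=0), and finally the
spikes are queued for delivery at the next step.

Excitatory STDP supports two pairing schemes.  The default all-to-all
scheme keeps one potentiation trace per (potential) presynaptic neuron
(decaying with tau+) and one depression trace per internal neuron
(decaying with tau-); a postsynaptic spike potentiates each plastic
afferent by A+ times the presynaptic trace, a presynaptic spike
depresses each plastic efferent by A- times the postsynaptic trace.
Traces decay exactly (exp(-dt/tau)), so an isolated spike pair
reproduces the closed-form STDP curve to machine precision.  The
nearest-neighbour scheme pairs against single stored last-spike times
instead.  Inhibitory STDP is always evaluated against last-spike times:
the symmetric rule's sign depends on |dt| alone.

Semantics match the reference implementations in
:mod:`spikedisc.neurons` and :mod:`spikedisc.plasticity`; the
equivalence is asserted by tests on small networks.
"""

import numpy as np
from numba import njit

_NEVER = -1.0e18


@njit(cache=True)
def run_segment(n_steps, t0,
                src_spk,          # (n_steps, n_active) uint8 source spikes
                src_idx,          # (n_active,) int64 global source indices
                K,                # number of source neurons
                V, g_ex, g_inh,   # (N,) internal neuron state
                pend_ex, pend_inh,  # (D, N) delay ring buffers
                last_spike,       # (K+N,) last spike time, _NEVER if silent
                prev_spike,       # (K+N,) spike before last (pairing bound)
                syn_pre, syn_post, syn_w, syn_rule, syn_gmax, syn_plastic,
                syn_delay,        # (S,) transmission delay in steps (>= 1)
                csr_indptr,       # (K+N+1,) synapses sorted by pre
                csc_indptr, csc_syn,  # (N+1,), synapse ids sorted by post
                NR,               # number of reservoir neurons (diagnostics slice)
                inv_g_unit,       # converts nS conductances to membrane-equation units
                dt, tau_m, V_T, V_rest, V_reset, E_ex, E_inh,
                dec_ex, dec_inh,
                A_plus, A_minus, tau_plus, tau_minus,
                B_plus, B_minus, tau_i,
                plasticity_on,
                all_to_all,       # bool: trace-based E-STDP pairing
                trace_pre,        # (K+N,) potentiation traces, decay tau+
                trace_post,       # (N,) depression traces, decay tau-
                spike_counts,     # (N,) int64, accumulated
                record,           # bool: fill rec_nid/rec_t
                rec_nid, rec_t,   # int32 buffers, capacity n_steps*N
                diag,             # (5,) float64: sums of Iex, Iinh, Inet, |Inet|, src spikes
                ):
    N = V.shape[0]
    D = pend_ex.shape[0]
    n_rec = 0
    spiked = np.zeros(N, np.uint8)
    n_active = src_idx.shape[0]
    KN = trace_pre.shape[0]
    dec_tp = np.exp(-dt / tau_plus)
    dec_tm = np.exp(-dt / tau_minus)
    for s in range(n_steps):
        t = t0 + s

        if plasticity_on and all_to_all:
            for j in range(KN):
                trace_pre[j] *= dec_tp
            for j in range(N):
                trace_post[j] *= dec_tm

        # --- conductance decay + delayed delivery, membrane step, spikes ---
        slot = t % D
        for j in range(N):
            ge = g_ex[j] * dec_ex + pend_ex[slot, j]
            gi = g_inh[j] * dec_inh + pend_inh[slot, j]
            g_ex[j] = ge
            g_inh[j] = gi
            pend_ex[slot, j] = 0.0
            pend_inh[slot, j] = 0.0
            v = V[j]
            iex = (E_ex - v) * ge * inv_g_unit
            iinh = (E_inh - v) * gi * inv_g_unit
            if j < NR:
                inet = iex + iinh
                diag[0] += iex
                diag[1] += iinh
                diag[2] += inet
                diag[3] += abs(inet)
            v = v + (dt / tau_m) * ((V_rest - v) + iex + iinh)
            if not (v > -1.0e6 and v < 1.0e6):   # also catches NaN
                return -1, n_rec
            if v >= V_T:
                spiked[j] = 1
                V[j] = V_reset
                spike_counts[j] += 1
                if record:
                    rec_nid[n_rec] = j
                    rec_t[n_rec] = t
                    n_rec += 1
            else:
                spiked[j] = 0
                V[j] = v

        # --- afferent STDP: post spiked now, pair with pre's last spike.
        # Nearest mode pairs non-overlappingly: only if the pre spike is
        # more recent than the post's own previous spike, so each pre
        # spike enters at most one afferent pairing per synapse.
        if plasticity_on:
            for j in range(N):
                if spiked[j] == 1:
                    t_prev_post = last_spike[K + j]
                    for a in range(csc_indptr[j], csc_indptr[j + 1]):
                        sid = csc_syn[a]
                        if syn_plastic[sid] == 0:
                            continue
                        ls = last_spike[syn_pre[sid]]
                        if ls < _NEVER / 2.0:
                            continue
                        if (not all_to_all) and ls <= t_prev_post:
                            continue
                        dtt = ls - t   # < 0: pre preceded post
                        w = syn_w[sid]
                        if syn_rule[sid] == 0:
                            if all_to_all:
                                w += A_plus * trace_pre[syn_pre[sid]]
                            else:
                                w += A_plus * np.exp(dtt / tau_plus)
                        else:
                            adt = -dtt
                            if adt <= tau_i:
                                w += B_plus * np.exp(-adt / tau_i)
                            else:
                                w -= B_minus * np.exp(-adt / tau_i)
                        if w < 0.0:
                            w = 0.0
                        elif w > syn_gmax[sid]:
                            w = syn_gmax[sid]
                        syn_w[sid] = w

        # --- record internal spike times (and depression traces) before
        # --- the efferent passes: simultaneous pairs enter once, at dt=0
        for j in range(N):
            if spiked[j] == 1:
                prev_spike[K + j] = last_spike[K + j]
                last_spike[K + j] = t

        # --- efferent STDP for internal spikers: dt = t - last_post >= 0 ---
        if plasticity_on:
            for j in range(N):
                if spiked[j] == 1:
                    p = K + j
                    t_prev_pre = prev_spike[p]
                    for sid in range(csr_indptr[p], csr_indptr[p + 1]):
                        if syn_plastic[sid] == 0:
                            continue
                        lsp = last_spike[K + syn_post[sid]]
                        if lsp < _NEVER / 2.0:
                            continue
                        if (not all_to_all) and lsp <= t_prev_pre:
                            continue
                        dtt = t - lsp
                        w = syn_w[sid]
                        if syn_rule[sid] == 0:
                            if all_to_all:
                                w -= A_minus * trace_post[syn_post[sid]]
                            else:
                                w -= A_minus * np.exp(-dtt / tau_minus)
                        else:
                            if dtt <= tau_i:
                                w += B_plus * np.exp(-dtt / tau_i)
                            else:
                                w -= B_minus * np.exp(-dtt / tau_i)
                        if w < 0.0:
                            w = 0.0
                        elif w > syn_gmax[sid]:
                            w = syn_gmax[sid]
                        syn_w[sid] = w

        # --- source spikes: efferent STDP, bookkeeping, queued delivery ---
        for a in range(n_active):
            if src_spk[s, a] == 1:
                p = src_idx[a]
                diag[4] += 1.0
                if plasticity_on:
                    t_prev_pre = last_spike[p]
                    for sid in range(csr_indptr[p], csr_indptr[p + 1]):
                        if syn_plastic[sid] == 0:
                            continue
                        lsp = last_spike[K + syn_post[sid]]
                        if lsp < _NEVER / 2.0:
                            continue
                        if (not all_to_all) and lsp <= t_prev_pre:
                            continue
                        dtt = t - lsp
                        w = syn_w[sid]
                        # source synapses are excitatory
                        if all_to_all:
                            w -= A_minus * trace_post[syn_post[sid]]
                        else:
                            w -= A_minus * np.exp(-dtt / tau_minus)
                        if w < 0.0:
                            w = 0.0
                        syn_w[sid] = w
                last_spike[p] = t
                if plasticity_on and all_to_all:
                    trace_pre[p] += 1.0
                for sid in range(csr_indptr[p], csr_indptr[p + 1]):
                    pend_ex[(t + syn_delay[sid]) % D, syn_post[sid]] += syn_w[sid]

        # --- queue internal spikes for next-step delivery ---
        for j in range(N):
            if spiked[j] == 1:
                p = K + j
                if plasticity_on and all_to_all:
                    trace_pre[p] += 1.0
                    trace_post[j] += 1.0
                for sid in range(csr_indptr[p], csr_indptr[p + 1]):
                    slot2 = (t + syn_delay[sid]) % D
                    if syn_rule[sid] == 0:
                        pend_ex[slot2, syn_post[sid]] += syn_w[sid]
                    else:
                        pend_inh[slot2, syn_post[sid]] += syn_w[sid]

    return 0, n_rec
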