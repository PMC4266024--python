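"""Network construction, the simulation loop, and shuffle controls.

The compiled kernel is checked against an independent dense numpy
re-implementation of the update rules on a small network (delays pinned
to one step so the reference stays simple).
"""

import numpy as np
import pytest

from spikedisc import NetworkConfig, build_network, run, shuffle_connectivity
from spikedisc.encoding import (Segment, StimulusSchedule, generate_flag_patterns,
                                make_test_schedule, pattern_rates)
from spikedisc.network import PROJECTIONS, SHUFFLE_CASES


def tiny_cfg(**kw):
    params = dict(image_shape=(6, 6), N_E=20, N_I=5, M=4, M_I=2,
                  delay_ee=(1.0, 1.0), delay_inh_loop=(1.0, 1.0))
    params.update(kw)
    return NetworkConfig.desk(**params)


@pytest.fixture
def tiny_pats(rng):
    return generate_flag_patterns(3, 6, rng)


class TestBuild:
    def test_zero_connectivity_gives_empty_projection(self, rng):
        net = build_network(tiny_cfg(c_ee_12=0.0), rng)
        assert net.proj_synapses("EE12").size == 0

    def test_full_connectivity_sink_loop(self, rng):
        cfg = tiny_cfg()
        net = build_network(cfg, rng)
        assert net.proj_synapses("EI33").size == cfg.M * cfg.M_I
        assert net.proj_synapses("IE33").size == cfg.M * cfg.M_I

    def test_density_within_binomial_ci(self):
        cfg = NetworkConfig.desk()
        net = build_network(cfg, np.random.default_rng(0))
        n = cfg.K * cfg.N_E
        p = cfg.c_ee_12
        got = net.proj_synapses("EE12").size
        assert abs(got - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_no_self_connections_in_recurrent_projections(self, rng):
        cfg = tiny_cfg(c_ee_22=1.0, c_ii_22=1.0)
        net = build_network(cfg, rng)
        for tag in ("EE22", "II22"):
            ids = net.proj_synapses(tag)
            pre_pop = PROJECTIONS[tag][0]
            pre0 = net._pop_range(pre_pop)[0]
            post0 = cfg.K + net.pop_slices[pre_pop].start
            assert not np.any((net.syn_pre[ids] - pre0)
                              == (net.syn_post[ids] + cfg.K - post0))

    def test_initial_weights_within_ranges(self, rng):
        cfg = tiny_cfg()
        net = build_network(cfg, rng)
        for tag, (lo, hi) in [("EE12", cfg.w_init_12), ("EE23", cfg.w_init_23),
                              ("IE22", cfg.z_init)]:
            w = net.syn_w[net.proj_synapses(tag)]
            assert (w >= lo).all() and (w <= hi).all()

    def test_zero_size_layer_rejected(self, rng):
        with pytest.raises(ValueError):
            build_network(tiny_cfg(N_I=0), rng)

    def test_build_reproducible_from_seed(self):
        a = build_network(tiny_cfg(), np.random.default_rng(3))
        b = build_network(tiny_cfg(), np.random.default_rng(3))
        assert np.array_equal(a.syn_pre, b.syn_pre)
        assert np.array_equal(a.syn_w, b.syn_w)
        assert np.array_equal(a.syn_delay, b.syn_delay)


class TestRun:
    def test_empty_schedule_is_noop(self, rng, tiny_pats):
        net = build_network(tiny_cfg(), rng)
        w0 = net.syn_w.copy()
        res = run(net, StimulusSchedule([]), tiny_pats, rng)
        assert len(res.diagnostics) == 0
        assert np.array_equal(net.syn_w, w0)

    def test_frozen_plasticity_keeps_weights_bit_identical(self, rng, tiny_pats):
        net = build_network(tiny_cfg(), rng)
        w0 = net.syn_w.copy()
        sched = make_test_schedule(tiny_pats, 0.5, 2, net.cfg)
        run(net, sched, tiny_pats, rng, plasticity_on=False)
        assert np.array_equal(net.syn_w, w0)

    def test_identical_seeds_give_bit_identical_runs(self, tiny_pats):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            net = build_network(tiny_cfg(), rng)
            sched = make_test_schedule(tiny_pats, 1.0, 2, net.cfg)
            res = run(net, sched, tiny_pats, rng, record_spikes=True)
            outs.append((net.syn_w.copy(), res.sink_counts.copy(),
                         res.spike_neuron.copy(), res.spike_time.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])
        assert np.array_equal(outs[0][3], outs[1][3])

    def test_weights_stay_clipped_during_training(self, rng, tiny_pats):
        net = build_network(tiny_cfg(), rng)
        sched = make_test_schedule(tiny_pats, 2.0, 2, net.cfg)
        run(net, sched, tiny_pats, rng, plasticity_on=True)
        assert (net.syn_w >= 0).all()
        assert (net.syn_w <= net.syn_gmax).all()

    def test_snapshot_restore_round_trip(self, rng, tiny_pats):
        net = build_network(tiny_cfg(), rng)
        sched = make_test_schedule(tiny_pats, 1.0, 1, net.cfg)
        run(net, sched, tiny_pats, rng)
        snap = net.snapshot()
        run(net, sched, tiny_pats, rng)
        net.restore(snap)
        assert np.array_equal(net.V, snap["V"])
        assert np.array_equal(net.syn_w, snap["syn_w"])
        assert net.t_step == snap["t_step"]

    def test_spikes_frame_layers(self, rng, tiny_pats):
        net = build_network(tiny_cfg(), rng)
        sched = make_test_schedule(tiny_pats, 1.0, 1, net.cfg)
        res = run(net, sched, tiny_pats, rng, record_spikes=True)
        df = res.spikes_frame(net)
        assert set(df.columns) == {"layer", "neuron_id", "time_ms"}
        assert set(df.layer.unique()) <= {"resE", "resI", "sinkE", "sinkI"}

    def test_checkpoint_round_trip(self, tmp_path, rng, tiny_pats):
        from spikedisc import NetworkTopology
        net = build_network(tiny_cfg(), rng)
        sched = make_test_schedule(tiny_pats, 0.5, 1, net.cfg)
        run(net, sched, tiny_pats, rng)
        path = tmp_path / "ckpt.h5"
        net.save(path)
        back = NetworkTopology.load(path)
        for k in ("syn_w", "V", "g_ex", "last_spike", "syn_delay"):
            assert np.array_equal(getattr(net, k), getattr(back, k))
        assert back.cfg.N_E == net.cfg.N_E


class TestShuffles:
    @pytest.mark.parametrize("case", list(SHUFFLE_CASES))
    def test_weight_multiset_and_degrees_preserved(self, rng, tiny_pats, case):
        net = build_network(tiny_cfg(), rng)
        sched = make_test_schedule(tiny_pats, 1.0, 1, net.cfg)
        run(net, sched, tiny_pats, rng)
        shuffled = shuffle_connectivity(net, case, rng)
        for tag in PROJECTIONS:
            a = np.sort(net.syn_w[net.proj_synapses(tag)])
            b = np.sort(shuffled.syn_w[shuffled.proj_synapses(tag)])
            assert np.array_equal(a, b), tag
            # per-post in-degrees preserved
            pa = np.bincount(net.syn_post[net.proj_synapses(tag)],
                             minlength=net.cfg.n_internal)
            pb = np.bincount(shuffled.syn_post[shuffled.proj_synapses(tag)],
                             minlength=net.cfg.n_internal)
            assert np.array_equal(pa, pb), tag

    def test_shuffle_changes_presynaptic_assignment(self, rng, tiny_pats):
        net = build_network(tiny_cfg(), rng)
        shuffled = shuffle_connectivity(net, 1, rng)
        ids_a = net.proj_synapses("EE12")
        ids_b = shuffled.proj_synapses("EE12")
        assert not np.array_equal(net.syn_pre[ids_a], shuffled.syn_pre[ids_b])

    def test_untouched_projections_identical(self, rng):
        net = build_network(tiny_cfg(), rng)
        shuffled = shuffle_connectivity(net, 5, rng)  # only EE23 moves
        for tag in ("EE12", "EE22", "IE22"):
            a, b = net.proj_synapses(tag), shuffled.proj_synapses(tag)
            assert np.array_equal(net.syn_pre[a], shuffled.syn_pre[b])

    def test_unknown_case_rejected(self, rng):
        net = build_network(tiny_cfg(), rng)
        with pytest.raises(ValueError):
            shuffle_connectivity(net, 7, rng)


# ----------------------------------------------------------------------
def reference_simulation(net, src_spk_per_seg, seg_steps, plasticity_on):
    """Dense numpy mirror of the kernel (all delays = 1 step, nearest pairing).

    Independent oracle: global dense weight matrices, explicit pending
    buffers, and the non-overlapping nearest-neighbour pairing written out
    directly.
    """
    cfg = net.cfg
    K, N = cfg.K, cfg.n_internal
    NEVER = -1.0e18
    # dense global structures
    W = np.zeros((K + N, N))
    RULE = np.zeros((K + N, N), dtype=int)
    MASK = np.zeros((K + N, N), dtype=bool)
    GMAX = np.zeros((K + N, N))
    for tag in PROJECTIONS:
        ids = net.proj_synapses(tag)
        W[net.syn_pre[ids], net.syn_post[ids]] = net.syn_w[ids]
        RULE[net.syn_pre[ids], net.syn_post[ids]] = net.syn_rule[ids]
        MASK[net.syn_pre[ids], net.syn_post[ids]] = True
        GMAX[net.syn_pre[ids], net.syn_post[ids]] = net.syn_gmax[ids]

    V = np.full(N, cfg.V_rest)
    g_ex = np.zeros(N)
    g_inh = np.zeros(N)
    pend_ex = np.zeros(N)
    pend_inh = np.zeros(N)
    last = np.full(K + N, NEVER)
    prev = np.full(K + N, NEVER)
    dec_ex = cfg.decay_factor(cfg.tau_ampa)
    dec_inh = cfg.decay_factor(cfg.tau_gaba)
    counts = np.zeros(N, dtype=int)

    def e_delta(dtt):
        return (cfg.A_plus * np.exp(dtt / cfg.tau_plus) if dtt < 0
                else -cfg.A_minus * np.exp(-dtt / cfg.tau_minus))

    def i_delta(dtt):
        a = abs(dtt)
        mag = np.exp(-a / cfg.tau_i)
        return cfg.B_plus * mag if a <= cfg.tau_i else -cfg.B_minus * mag

    t = 0
    for src_spk, steps in zip(src_spk_per_seg, seg_steps):
        for s in range(steps):
            g_ex = g_ex * dec_ex + pend_ex
            g_inh = g_inh * dec_inh + pend_inh
            pend_ex = np.zeros(N)
            pend_inh = np.zeros(N)
            iex = (cfg.E_ex - V) * g_ex / cfg.g_unit
            iinh = (cfg.E_inh - V) * g_inh / cfg.g_unit
            Vn = V + (cfg.dt / cfg.tau_m) * ((cfg.V_rest - V) + iex + iinh)
            fired = Vn >= cfg.V_T
            V = np.where(fired, cfg.V_reset, Vn)
            counts += fired

            src_now = np.flatnonzero(src_spk[s])
            if plasticity_on:
                # afferent: post fired now, pair with pre's last spike if it
                # is newer than the post's own previous spike
                for j in np.flatnonzero(fired):
                    for i in np.flatnonzero(MASK[:, j]):
                        ls = last[i]
                        if ls < NEVER / 2 or ls <= last[K + j]:
                            continue
                        d = (e_delta if RULE[i, j] == 0 else i_delta)(ls - t)
                        W[i, j] = min(max(W[i, j] + d, 0.0), GMAX[i, j])
            for j in np.flatnonzero(fired):
                prev[K + j] = last[K + j]
                last[K + j] = t
            if plasticity_on:
                # efferent: pre fired now (internal then source order)
                for j in np.flatnonzero(fired):
                    for m in np.flatnonzero(MASK[K + j]):
                        lsp = last[K + m]
                        if lsp < NEVER / 2 or lsp <= prev[K + j]:
                            continue
                        d = (e_delta if RULE[K + j, m] == 0 else i_delta)(t - lsp)
                        W[K + j, m] = min(max(W[K + j, m] + d, 0.0), GMAX[K + j, m])
            for i in src_now:
                if plasticity_on:
                    t_prev_pre = last[i]
                    for m in np.flatnonzero(MASK[i]):
                        lsp = last[K + m]
                        if lsp < NEVER / 2 or lsp <= t_prev_pre:
                            continue
                        W[i, m] = min(max(W[i, m] + e_delta(t - lsp), 0.0),
                                      GMAX[i, m])
                prev[i] = last[i]
                last[i] = t
                pend_ex += W[i] * MASK[i]
            for j in np.flatnonzero(fired):
                row = K + j
                pend_ex += np.where(RULE[row] == 0, W[row], 0.0) * MASK[row]
                pend_inh += np.where(RULE[row] == 1, W[row], 0.0) * MASK[row]
            t += 1
    return W, MASK, counts


@pytest.mark.parametrize("plasticity_on", [False, True])
def test_kernel_matches_dense_reference(plasticity_on):
    """Compiled kernel vs an independent dense numpy mirror, spike-for-spike."""
    cfg = tiny_cfg()
    rng = np.random.default_rng(21)
    pats = generate_flag_patterns(2, 6, rng)
    net = build_network(cfg, rng)

    # pre-draw the source spike streams exactly as run() draws them
    seg_ms = [120.0, 80.0]
    sched = StimulusSchedule([Segment(pats[0].id, 0.0, seg_ms[0]),
                              Segment(pats[1].id, seg_ms[0], seg_ms[1])])
    rng_run = np.random.default_rng(77)
    rng_ref = np.random.default_rng(77)

    src_spk_per_seg, steps = [], []
    for seg, pat in zip(sched, pats):
        rates = pattern_rates(pat, cfg, rng_ref)
        p = rates * cfg.dt / 1000.0
        n = int(round(seg.duration_ms / cfg.dt))
        active = np.flatnonzero(p > 0)
        spk = rng_ref.random((n, active.size)) < p[active]
        full = np.zeros((n, cfg.K), dtype=bool)
        full[:, active] = spk
        src_spk_per_seg.append(full)
        steps.append(n)

    ref_net = net.copy()
    W_ref, MASK, counts_ref = reference_simulation(
        ref_net, src_spk_per_seg, steps, plasticity_on)

    run(net, sched, pats, rng_run, plasticity_on=plasticity_on)

    W_got = np.zeros_like(W_ref)
    W_got[net.syn_pre, net.syn_post] = net.syn_w
    assert np.array_equal(net.spike_counts, counts_ref)
    assert np.allclose(W_got[MASK], W_ref[MASK], atol=1e-12)
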