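"""Three-layer network construction, the simulation loop, and shuffle controls.

Architecture: a source layer of K excitatory Poisson neurons (one per
image pixel) projects sparsely onto the excitatory population of a
recurrent excitatory-inhibitory reservoir (N_E + N_I neurons), which in
turn projects onto M excitatory readout ("sink") neurons; the sink layer
holds a small inhibitory population reciprocally coupled to the readouts
and receives no other drive.  Eight projections are realised with
independent Bernoulli connectivity:

    EE12 source->res E    EE22, EI22, IE22, II22 within the reservoir
    EI12 source->res I    EE23 res E->sink E     EI33, IE33 in the sink layer

Reservoir neurons of both types receive source projections; the direct
source->I pathway provides feedforward inhibition from the first
presentation, before the recurrent E->I loop has potentiated.

Recurrent projections exclude self-loops.  Excitatory synapses follow
E-STDP, inhibitory ones I-STDP; every synapse is plastic at all times
unless frozen (testing probes, or the inhibitory-plasticity ablation).

The simulation state lives in flat arrays shared with the compiled
kernel (:mod:`spikedisc._kernel`); internal neurons are indexed
reservoir-E, reservoir-I, sink-E, sink-I in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import yaml

from . import _kernel
from .config import NetworkConfig
from .encoding import Pattern, StimulusSchedule, pattern_rates
from .neurons import _NEVER
from .plasticity import SynapseClassMatrix

__all__ = ["NetworkTopology", "build_network", "run", "RunResult",
           "shuffle_connectivity", "SHUFFLE_CASES", "PROJECTIONS"]

# tag -> (pre population, post population, config probability attr, rule, init attr)
PROJECTIONS: dict[str, tuple[str, str, str, str, str]] = {
    "EE12": ("src", "resE", "c_ee_12", "e", "w_init_12"),
    "EI12": ("src", "resI", "c_ei_12", "e", "w_init_12"),
    "EE22": ("resE", "resE", "c_ee_22", "e", "w_init_22"),
    "EI22": ("resE", "resI", "c_ei_22", "e", "w_init_22"),
    "IE22": ("resI", "resE", "c_ie_22", "i", "z_init"),
    "II22": ("resI", "resI", "c_ii_22", "i", "z_init"),
    "EE23": ("resE", "sinkE", "c_ee_23", "e", "w_init_23"),
    "EI33": ("sinkE", "sinkI", "c_ei_33", "e", "w_init_22"),
    "IE33": ("sinkI", "sinkE", "c_ie_33", "i", "z_init"),
}
_PROJ_TAGS = list(PROJECTIONS)

# connectivity-shuffle control cases
SHUFFLE_CASES: dict[int, tuple[str, ...]] = {
    1: ("EE12",),
    2: ("EE22", "EI22", "IE22", "II22"),
    3: ("IE22", "II22"),
    4: ("EE22", "EI22"),
    5: ("EE23",),
    6: ("EE12", "EE22", "EI22", "IE22", "II22", "EE23"),
}


@dataclass
class NetworkTopology:
    """Structure plus dynamical state of one network instance."""

    cfg: NetworkConfig
    # synapse table (CSR order by global presynaptic index)
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_w: np.ndarray
    syn_rule: np.ndarray
    syn_gmax: np.ndarray
    syn_plastic: np.ndarray
    syn_class: np.ndarray
    syn_delay: np.ndarray
    csr_indptr: np.ndarray
    csc_indptr: np.ndarray
    csc_syn: np.ndarray
    # neuron state
    V: np.ndarray = None
    g_ex: np.ndarray = None
    g_inh: np.ndarray = None
    pend_ex: np.ndarray = None
    pend_inh: np.ndarray = None
    last_spike: np.ndarray = None
    prev_spike: np.ndarray = None
    spike_counts: np.ndarray = None
    trace_pre: np.ndarray = None
    trace_post: np.ndarray = None
    t_step: int = 0

    def __post_init__(self):
        cfg = self.cfg
        N = cfg.n_internal
        if self.V is None:
            d_hi = max(self.cfg.delay_ee[1], self.cfg.delay_inh_loop[1])
            D = max(1, int(round(d_hi / self.cfg.dt))) + 1
            self.V = np.full(N, cfg.V_rest)
            self.g_ex = np.zeros(N)
            self.g_inh = np.zeros(N)
            self.pend_ex = np.zeros((D, N))
            self.pend_inh = np.zeros((D, N))
            self.last_spike = np.full(cfg.K + N, _NEVER)
            self.prev_spike = np.full(cfg.K + N, _NEVER)
            self.spike_counts = np.zeros(N, dtype=np.int64)
        if self.trace_pre is None:
            self.trace_pre = np.zeros(cfg.K + N)
            self.trace_post = np.zeros(N)

    # -- population index ranges (internal space) --
    @property
    def pop_slices(self) -> dict[str, slice]:
        cfg = self.cfg
        a, b, c = cfg.N_E, cfg.N_E + cfg.N_I, cfg.N_E + cfg.N_I + cfg.M
        return {"resE": slice(0, a), "resI": slice(a, b),
                "sinkE": slice(b, c), "sinkI": slice(c, cfg.n_internal)}

    def _pop_range(self, pop: str) -> tuple[int, int, bool]:
        """(global start, size, is_source) for a population."""
        if pop == "src":
            return 0, self.cfg.K, True
        s = self.pop_slices[pop]
        return self.cfg.K + s.start, s.stop - s.start, False

    def proj_synapses(self, tag: str) -> np.ndarray:
        """Synapse-table indices belonging to one projection."""
        return np.flatnonzero(self.syn_class == _PROJ_TAGS.index(tag))

    def weight_matrix(self, tag: str) -> SynapseClassMatrix:
        """Dense (pre x post) weight matrix for one projection."""
        pre_pop, post_pop, _, rule, _ = PROJECTIONS[tag]
        pre0, n_pre, _ = self._pop_range(pre_pop)
        post_sl = self.pop_slices[post_pop]
        n_post = post_sl.stop - post_sl.start
        ids = self.proj_synapses(tag)
        mask = np.zeros((n_pre, n_post), dtype=bool)
        W = np.zeros((n_pre, n_post))
        rows = self.syn_pre[ids] - pre0
        cols = self.syn_post[ids] - post_sl.start
        mask[rows, cols] = True
        W[rows, cols] = self.syn_w[ids]
        gmax = self.cfg.gE_max if rule == "e" else self.cfg.gI_max
        return SynapseClassMatrix(tag, mask, W, gmax, rule)

    # -- plasticity gating --
    def set_plastic(self, rule: str | None = None, on: bool = True) -> None:
        """Freeze or thaw synapses; ``rule`` 'e'/'i' restricts to one rule."""
        sel = np.ones(len(self.syn_w), dtype=bool)
        if rule is not None:
            sel = self.syn_rule == (0 if rule == "e" else 1)
        self.syn_plastic[sel] = 1 if on else 0

    def set_weights(self, tag: str, values: np.ndarray) -> None:
        """Overwrite the weights of one projection (synapse-table order)."""
        ids = self.proj_synapses(tag)
        self.syn_w[ids] = np.clip(values, 0.0, self.syn_gmax[ids])

    # -- state snapshot for side-effect-free probing --
    _STATE = ("V", "g_ex", "g_inh", "pend_ex", "pend_inh",
              "last_spike", "prev_spike", "spike_counts", "syn_w", "trace_pre", "trace_post")

    def snapshot(self) -> dict:
        s = {k: getattr(self, k).copy() for k in self._STATE}
        s["t_step"] = self.t_step
        return s

    def restore(self, snap: dict) -> None:
        for k in self._STATE:
            getattr(self, k)[:] = snap[k]
        self.t_step = snap["t_step"]

    def copy(self) -> "NetworkTopology":
        kw = {k: getattr(self, k).copy() for k in (
            "syn_pre", "syn_post", "syn_w", "syn_rule", "syn_gmax",
            "syn_plastic", "syn_class", "syn_delay",
            "csr_indptr", "csc_indptr", "csc_syn",
            "V", "g_ex", "g_inh", "pend_ex", "pend_inh",
            "last_spike", "prev_spike", "spike_counts", "trace_pre", "trace_post")}
        return NetworkTopology(cfg=self.cfg, t_step=self.t_step, **kw)

    # -- checkpointing --
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["config"] = yaml.safe_dump(self.cfg.to_dict())
            f.attrs["t_step"] = self.t_step
            for k in ("syn_pre", "syn_post", "syn_w", "syn_rule", "syn_gmax",
                      "syn_plastic", "syn_class", "syn_delay",
                      "csr_indptr", "csc_indptr",
                      "csc_syn", "V", "g_ex", "g_inh", "pend_ex", "pend_inh",
                      "last_spike", "prev_spike", "spike_counts",
                      "trace_pre", "trace_post"):
                f.create_dataset(k, data=getattr(self, k))

    @classmethod
    def load(cls, path) -> "NetworkTopology":
        with h5py.File(path, "r") as f:
            cfg = NetworkConfig.from_dict(yaml.safe_load(f.attrs["config"]))
            kw = {k: f[k][...] for k in f.keys()}
            return cls(cfg=cfg, t_step=int(f.attrs["t_step"]), **kw)


# ----------------------------------------------------------------------
def _assemble(cfg: NetworkConfig, parts: list[tuple]) -> NetworkTopology:
    """Sort a synapse list into CSR/CSC order and wrap it in a topology."""
    pre = np.concatenate([p[0] for p in parts])
    post = np.concatenate([p[1] for p in parts])
    w = np.concatenate([p[2] for p in parts])
    rule = np.concatenate([p[3] for p in parts])
    gmax = np.concatenate([p[4] for p in parts])
    cls = np.concatenate([p[5] for p in parts])
    delay = np.concatenate([p[6] for p in parts])

    order = np.argsort(pre, kind="stable")
    pre, post, w, rule, gmax, cls, delay = (
        a[order] for a in (pre, post, w, rule, gmax, cls, delay))
    n_pre_total = cfg.K + cfg.n_internal
    csr_indptr = np.zeros(n_pre_total + 1, dtype=np.int64)
    np.add.at(csr_indptr, pre + 1, 1)
    csr_indptr = np.cumsum(csr_indptr)

    csc_order = np.argsort(post, kind="stable").astype(np.int64)
    csc_indptr = np.zeros(cfg.n_internal + 1, dtype=np.int64)
    np.add.at(csc_indptr, post + 1, 1)
    csc_indptr = np.cumsum(csc_indptr)

    return NetworkTopology(
        cfg=cfg,
        syn_pre=pre.astype(np.int64), syn_post=post.astype(np.int64),
        syn_w=w.astype(np.float64), syn_rule=rule.astype(np.uint8),
        syn_gmax=gmax.astype(np.float64),
        syn_plastic=np.ones(len(w), dtype=np.uint8),
        syn_class=cls.astype(np.uint8),
        syn_delay=delay.astype(np.int64),
        csr_indptr=csr_indptr, csc_indptr=csc_indptr, csc_syn=csc_order,
    )


def build_network(cfg: NetworkConfig, rng: np.random.Generator) -> NetworkTopology:
    """Construct a network with independent Bernoulli(c) connectivity.

    Weights are drawn uniformly from the per-projection initial ranges;
    recurrent projections exclude self-connections.  Fully reproducible
    from the generator state.
    """
    cfg.validate()
    parts = []
    pops = {"src": (0, cfg.K)}
    # internal populations in global pre space
    tmp = NetworkTopology.__new__(NetworkTopology)
    tmp.cfg = cfg
    for pop, sl in tmp.pop_slices.items():
        pops[pop] = (cfg.K + sl.start, sl.stop - sl.start)

    for ci, (tag, (pre_pop, post_pop, p_attr, rule, init_attr)) in enumerate(PROJECTIONS.items()):
        pre0, n_pre = pops[pre_pop]
        post0, n_post = pops[post_pop]
        p = getattr(cfg, p_attr)
        mask = rng.random((n_pre, n_post)) < p
        if pre_pop == post_pop:
            np.fill_diagonal(mask, False)
        lo, hi = getattr(cfg, init_attr)
        w_full = rng.uniform(lo, hi, size=mask.shape)
        rows, cols = np.nonzero(mask)
        gmax = cfg.gE_max if rule == "e" else cfg.gI_max
        rng_d = cfg.delay_ee if tag in ("EE12", "EI12", "EE22", "EE23") else cfg.delay_inh_loop
        d_lo = max(1, int(round(rng_d[0] / cfg.dt)))
        d_hi = max(d_lo, int(round(rng_d[1] / cfg.dt)))
        parts.append((
            (pre0 + rows).astype(np.int64),
            (post0 - cfg.K + cols).astype(np.int64),   # post index is internal-local
            np.clip(w_full[rows, cols], 0.0, gmax),
            np.full(rows.size, 0 if rule == "e" else 1, dtype=np.uint8),
            np.full(rows.size, gmax),
            np.full(rows.size, ci, dtype=np.uint8),
            rng.integers(d_lo, d_hi + 1, size=rows.size).astype(np.int64),
        ))
    return _assemble(cfg, parts)


# ----------------------------------------------------------------------
@dataclass
class RunResult:
    """Per-segment diagnostics and spike data from one simulation run."""

    diagnostics: pd.DataFrame           # one row per schedule segment
    sink_counts: np.ndarray             # (n_segments, M) readout spike counts
    segment_patterns: np.ndarray        # (n_segments,) pattern ids
    spike_neuron: np.ndarray | None = None   # internal neuron ids (if recorded)
    spike_time: np.ndarray | None = None     # step times, ms (if recorded)

    def spikes_frame(self, net: NetworkTopology) -> pd.DataFrame:
        """Recorded spikes as a ``layer,neuron_id,time_ms`` table."""
        if self.spike_neuron is None:
            return pd.DataFrame(columns=["layer", "neuron_id", "time_ms"])
        layers = np.empty(len(self.spike_neuron), dtype=object)
        nid = self.spike_neuron.copy()
        for name, sl in net.pop_slices.items():
            sel = (self.spike_neuron >= sl.start) & (self.spike_neuron < sl.stop)
            layers[sel] = name
            nid[sel] = self.spike_neuron[sel] - sl.start
        return pd.DataFrame({"layer": layers, "neuron_id": nid,
                             "time_ms": self.spike_time})


def run(net: NetworkTopology,
        schedule: StimulusSchedule,
        patterns: dict[int, Pattern] | list[Pattern],
        rng: np.random.Generator,
        *,
        plasticity_on: bool = True,
        record_spikes: bool = False) -> RunResult:
    """Advance the network through a stimulus schedule.

    Each schedule segment draws a fresh Poisson realisation (and noise
    subset) of its pattern, feeds it to the compiled kernel, and logs
    population rates and reservoir current means.  With
    ``plasticity_on=False`` weights are bit-identical before and after
    (the frozen-probe contract).  Diverging dynamics (non-finite or
    runaway membrane potential) abort with ``FloatingPointError``.
    """
    cfg = net.cfg
    if isinstance(patterns, list):
        patterns = {p.id: p for p in patterns}
    NR = cfg.N_E + cfg.N_I
    sink_sl = net.pop_slices["sinkE"]

    dec_ex = cfg.decay_factor(cfg.tau_ampa)
    dec_inh = cfg.decay_factor(cfg.tau_gaba)

    rows = []
    sink_counts = np.zeros((len(schedule), cfg.M), dtype=np.int64)
    seg_patterns = np.zeros(len(schedule), dtype=np.int64)
    rec_nid_all, rec_t_all = [], []

    for si, seg in enumerate(schedule):
        pat = patterns[seg.pattern_id]
        rates = pattern_rates(pat, cfg, rng)
        p_spk = rates * cfg.dt / 1000.0
        active = np.flatnonzero(p_spk > 0)
        n_steps = int(round(seg.duration_ms / cfg.dt))
        src_spk = (rng.random((n_steps, active.size)) < p_spk[active]).astype(np.uint8)

        if record_spikes:
            cap = n_steps * cfg.n_internal
            rec_nid = np.empty(cap, dtype=np.int32)
            rec_t = np.empty(cap, dtype=np.int32)
        else:
            rec_nid = np.empty(1, dtype=np.int32)
            rec_t = np.empty(1, dtype=np.int32)

        diag = np.zeros(5)
        counts_before = net.spike_counts.copy()
        err, n_rec = _kernel.run_segment(
            n_steps, net.t_step,
            src_spk, active.astype(np.int64), cfg.K,
            net.V, net.g_ex, net.g_inh, net.pend_ex, net.pend_inh,
            net.last_spike, net.prev_spike,
            net.syn_pre, net.syn_post, net.syn_w, net.syn_rule,
            net.syn_gmax, net.syn_plastic, net.syn_delay,
            net.csr_indptr, net.csc_indptr, net.csc_syn,
            NR,
            1.0 / cfg.g_unit,
            cfg.dt, cfg.tau_m, cfg.V_T, cfg.V_rest, cfg.V_reset,
            cfg.E_ex, cfg.E_inh, dec_ex, dec_inh,
            cfg.A_plus, cfg.A_minus, cfg.tau_plus, cfg.tau_minus,
            cfg.B_plus, cfg.B_minus, cfg.tau_i,
            plasticity_on,
            cfg.pairing == "all_to_all", net.trace_pre, net.trace_post,
            net.spike_counts,
            record_spikes, rec_nid, rec_t, diag)
        if err != 0:
            raise FloatingPointError(
                f"membrane potential diverged in segment {si} "
                f"(pattern {seg.pattern_id}, t={net.t_step * cfg.dt} ms)")
        net.t_step += n_steps

        delta = net.spike_counts - counts_before
        sink_counts[si] = delta[sink_sl]
        seg_patterns[si] = seg.pattern_id
        dur_s = n_steps * cfg.dt / 1000.0
        denom = n_steps * NR
        rows.append((seg.onset_ms, seg.duration_ms, seg.pattern_id,
                     delta[:NR].sum() / (NR * dur_s),
                     delta[sink_sl].sum() / (cfg.M * dur_s),
                     diag[4] / (cfg.K * dur_s),
                     diag[0] / denom, diag[1] / denom,
                     diag[2] / denom, diag[3] / denom))
        if record_spikes and n_rec:
            rec_nid_all.append(rec_nid[:n_rec].copy())
            rec_t_all.append(rec_t[:n_rec].astype(np.float64) * cfg.dt)

    diag_df = pd.DataFrame(rows, columns=[
        "onset_ms", "duration_ms", "pattern_id", "res_rate_hz", "sink_rate_hz",
        "src_rate_hz", "mean_Iex", "mean_Iinh", "mean_Inet", "mean_absInet"])
    return RunResult(
        diagnostics=diag_df, sink_counts=sink_counts, segment_patterns=seg_patterns,
        spike_neuron=np.concatenate(rec_nid_all) if rec_nid_all else (
            np.empty(0, dtype=np.int32) if record_spikes else None),
        spike_time=np.concatenate(rec_t_all) if rec_t_all else (
            np.empty(0) if record_spikes else None),
    )


# ----------------------------------------------------------------------
def shuffle_connectivity(net: NetworkTopology, case: int,
                         rng: np.random.Generator) -> NetworkTopology:
    """Return a copy with the connectivity of one control case shuffled.

    For every projection in the case, each postsynaptic neuron's afferent
    synapses are reassigned to presynaptic neurons drawn uniformly without
    replacement from the projection's presynaptic population (excluding
    self-connections).  Weights travel with their synapses, so the weight
    multiset, the per-projection synapse count, and each neuron's
    in-degree are preserved exactly; only *which* presynaptic neuron each
    weight attaches to changes.
    """
    if case not in SHUFFLE_CASES:
        raise ValueError(f"unknown shuffle case {case}; valid: 1..6")
    cfg = net.cfg
    new = net.copy()
    pre = new.syn_pre.copy()
    for tag in SHUFFLE_CASES[case]:
        pre_pop, post_pop, _, _, _ = PROJECTIONS[tag]
        pre0, n_pre, _ = net._pop_range(pre_pop)
        ids = net.proj_synapses(tag)
        posts = net.syn_post[ids]
        for j in np.unique(posts):
            sel = ids[posts == j]
            pool = np.arange(pre0, pre0 + n_pre)
            if pre_pop == post_pop:  # guard recurrent self-loops
                pool = pool[pool != cfg.K + j]
            pre[sel] = rng.choice(pool, size=sel.size, replace=False)
    # re-sort into CSR/CSC order
    parts = [(pre, new.syn_post, new.syn_w, new.syn_rule, new.syn_gmax,
              new.syn_class, new.syn_delay)]
    rebuilt = _assemble(cfg, parts)
    rebuilt.syn_plastic[:] = 0  # shuffled copies are evaluation-only
    for k in ("V", "g_ex", "g_inh", "pend_ex", "pend_inh", "last_spike",
              "prev_spike", "spike_counts", "trace_pre", "trace_post"):
        getattr(rebuilt, k)[:] = getattr(net, k)
    rebuilt.t_step = net.t_step
    return rebuilt
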