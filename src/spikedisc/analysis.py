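"""Receptive fields, synaptic distance, and structural/functional back-tracing.

Additive E-STDP drives excitatory weights toward a bimodal distribution,
so a projection's state is well summarised by *binarising* it: a synapse
counts as strong when its weight exceeds 0.7 x g_max.  The *synaptic
distance* phi between two binarised snapshots of the same projection is
their Hamming distance normalised by all pre x post positions; comparing
it with the mean distance to density-preserving random shuffles of the
later snapshot (phi_shuffled) yields the *relative distance*
phi_rel = |phi - phi_shuffled| / phi_shuffled.  phi_rel near 1 means the
weights moved far less than chance — learning has stabilised; it is
undefined (nan) when phi_shuffled is 0.

The *back-trace* diagnostics reconstruct, for one presentation, the
structural subnetwork of reservoir neurons strongly wired to the
maximally firing readouts, and the functional graph of spike transitions
actually traversed within it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .config import NetworkConfig
from .network import NetworkTopology

__all__ = [
    "BinaryWeightSnapshot", "binarize_weights", "synaptic_distance",
    "shuffled_distance", "relative_distance", "receptive_field",
    "strong_synapse_fraction", "backtrace_networks", "export_graph",
]


@dataclass
class BinaryWeightSnapshot:
    """Thresholded weight matrix of one projection at one time."""

    time_s: float
    class_tag: str
    W: np.ndarray   # uint8 pre x post; 1 = strong synapse

    def __post_init__(self):
        self.W = np.asarray(self.W).astype(np.uint8)
        if not np.isin(self.W, (0, 1)).all():
            raise ValueError("snapshot entries must be binary")


def binarize_weights(net: NetworkTopology, tag: str,
                     time_s: float | None = None) -> BinaryWeightSnapshot:
    """Snapshot one projection, thresholded at ``strong_fraction * g_max``."""
    sm = net.weight_matrix(tag)
    thr = net.cfg.strong_fraction * sm.g_max
    t = net.t_step * net.cfg.dt / 1000.0 if time_s is None else time_s
    return BinaryWeightSnapshot(t, tag, (sm.weights > thr))


def synaptic_distance(snap1: BinaryWeightSnapshot,
                      snap2: BinaryWeightSnapshot) -> float:
    """Normalised Hamming distance over all #pre * #post positions."""
    if snap1.W.shape != snap2.W.shape:
        raise ValueError("snapshot shape mismatch")
    return float(np.abs(snap2.W.astype(int) - snap1.W.astype(int)).mean())


def shuffled_distance(snap1: BinaryWeightSnapshot,
                      snap2: BinaryWeightSnapshot,
                      n_shuffles: int,
                      rng: np.random.Generator) -> float:
    """Chance-level distance: mean over density-preserving shuffles of snap2.

    Each shuffle permutes the entries of the later snapshot uniformly over
    all positions (preserving its number of strong synapses — the pattern
    of synapses "formed by chance") and measures the distance to snap1.
    """
    if snap1.W.shape != snap2.W.shape:
        raise ValueError("snapshot shape mismatch")
    flat2 = snap2.W.ravel()
    flat1 = snap1.W.ravel().astype(int)
    acc = 0.0
    for _ in range(n_shuffles):
        perm = rng.permutation(flat2)
        acc += np.abs(perm.astype(int) - flat1).mean()
    return float(acc / n_shuffles)


def relative_distance(phi: float, phi_shuffled: float) -> float:
    """|phi - phi_shuffled| / phi_shuffled; nan (undefined) when chance level is 0."""
    if phi_shuffled == 0:
        return math.nan
    return abs(phi - phi_shuffled) / phi_shuffled


# ----------------------------------------------------------------------
def receptive_field(net: NetworkTopology, reservoir_neuron_id: int,
                    image_shape: tuple[int, int] | None = None):
    """Incoming source weights of one reservoir E neuron, as an image.

    Returns ``(field, strong_mask)``: the weight vector of the neuron's
    source afferents reshaped to the image (row-major, zeros where no
    synapse exists) and the boolean mask of strong synapses.
    """
    cfg = net.cfg
    if not (0 <= reservoir_neuron_id < cfg.N_E):
        raise IndexError(f"reservoir E neuron id out of range: {reservoir_neuron_id}")
    shape = cfg.image_shape if image_shape is None else image_shape
    sm = net.weight_matrix("EE12")
    col = sm.weights[:, reservoir_neuron_id]
    field = col.reshape(shape)
    strong = field > cfg.strong_fraction * cfg.gE_max
    return field, strong


def strong_synapse_fraction(net: NetworkTopology, tag: str = "EE12") -> float:
    """Fraction of realised synapses above the strong threshold."""
    ids = net.proj_synapses(tag)
    if ids.size == 0:
        return 0.0
    thr = net.cfg.strong_fraction * net.syn_gmax[ids]
    return float((net.syn_w[ids] > thr).mean())


# ----------------------------------------------------------------------
def backtrace_networks(net: NetworkTopology,
                       spike_neuron: np.ndarray,
                       spike_time: np.ndarray,
                       sink_counts: np.ndarray,
                       cfg: NetworkConfig | None = None):
    """Back-trace from the maximally firing readouts into the reservoir.

    ``sink_counts`` are the readout spike counts of the presentation and
    ``spike_neuron`` / ``spike_time`` its recorded internal spikes.  The
    *structural* graph contains every reservoir E neuron with a strong
    synapse onto a maximally firing readout (count ratio in the top code
    band), the strong E->E edges among those neurons, and the strong
    edges to the readouts.  The *functional* graph, on the same node set,
    weights each directed reservoir pair (a, b) by how often b spiked
    within one STDP window (``transition_window``, default tau+) after a.

    Returns ``(structural, functional)`` as networkx DiGraphs whose
    reservoir nodes are labelled ``E<i>`` and readouts ``R<i>``.
    """
    cfg = net.cfg if cfg is None else cfg
    structural = nx.DiGraph()
    functional = nx.DiGraph()
    counts = np.asarray(sink_counts, dtype=float)
    if counts.max() == 0 or len(spike_neuron) == 0:
        return structural, functional

    from .metrics import code_thresholds
    top_edge = code_thresholds(cfg.C)[-1]
    max_readouts = np.flatnonzero(counts / counts.max() >= top_edge)

    sm23 = net.weight_matrix("EE23")
    thr23 = cfg.strong_fraction * sm23.g_max
    members = np.flatnonzero((sm23.weights[:, max_readouts] > thr23).any(axis=1))
    for r in max_readouts:
        structural.add_node(f"R{r}", layer="sink")
    for e in members:
        structural.add_node(f"E{e}", layer="reservoir")
        for r in max_readouts:
            if sm23.weights[e, r] > thr23:
                structural.add_edge(f"E{e}", f"R{r}",
                                    weight=float(sm23.weights[e, r] / sm23.g_max))
    sm22 = net.weight_matrix("EE22")
    thr22 = cfg.strong_fraction * sm22.g_max
    for a in members:
        for b in members:
            if a != b and sm22.weights[a, b] > thr22:
                structural.add_edge(f"E{a}", f"E{b}",
                                    weight=float(sm22.weights[a, b] / sm22.g_max))

    # functional transitions among structural reservoir nodes
    sel = np.isin(spike_neuron, members)
    nid = np.asarray(spike_neuron)[sel]
    ts = np.asarray(spike_time)[sel]
    order = np.argsort(ts, kind="stable")
    nid, ts = nid[order], ts[order]
    win = cfg.transition_window
    for i in range(len(nid)):
        j = i + 1
        while j < len(nid) and ts[j] - ts[i] <= win:
            if nid[j] != nid[i] and ts[j] > ts[i]:
                a, b = f"E{nid[i]}", f"E{nid[j]}"
                if functional.has_edge(a, b):
                    functional[a][b]["weight"] += 1
                else:
                    functional.add_node(a, layer="reservoir")
                    functional.add_node(b, layer="reservoir")
                    functional.add_edge(a, b, weight=1)
            j += 1
    return structural, functional


def export_graph(graph: nx.DiGraph, csv_path=None, graphml_path=None) -> None:
    """Write a back-trace graph as ``src,dst,weight`` CSV and/or GraphML."""
    if csv_path is not None:
        import pandas as pd
        rows = [(u, v, d.get("weight", 1.0)) for u, v, d in graph.edges(data=True)]
        pd.DataFrame(rows, columns=["src", "dst", "weight"]).to_csv(csv_path, index=False)
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
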