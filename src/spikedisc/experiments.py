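"""Experiment drivers: training with periodic frozen probes, the
inhibitory-plasticity ablation, connectivity-shuffle controls, parameter
sweeps, and the stability-plasticity protocol.

All drivers are pure functions of (config, patterns, seeds): they build or
continue a network, alternate training segments with side-effect-free
discriminability probes (plasticity frozen, full state restored
afterwards, a dedicated random stream), and return tidy tables plus the
trained topology.  Probe wall-time never counts toward training time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis, metrics
from .config import NetworkConfig
from .encoding import (Pattern, make_test_schedule, make_training_schedule)
from .metrics import DIReport, RateCode, compute_di, rate_code
from .network import (NetworkTopology, build_network, run,
                      shuffle_connectivity)

__all__ = [
    "probe_di", "train_and_probe", "TrainResult", "istdp_ablation",
    "AblationResult", "shuffle_controls", "readout_code_shuffle_di",
    "parameter_sweeps", "stability_plasticity", "StabilityResult",
    "fano_curve_for_network", "fix_inhibitory_weights",
]


# ----------------------------------------------------------------------
def probe_di(net: NetworkTopology, patterns: list[Pattern],
             rng: np.random.Generator,
             d_s: float | None = None, J: int | None = None,
             restore: bool = True) -> DIReport:
    """Frozen-plasticity discriminability probe.

    Presents each pattern J times for d seconds with all plasticity off,
    codes each presentation's readout counts, and computes the DI.  The
    full dynamical state (and, trivially, the weights) is restored
    afterwards so training resumes exactly where it left off.
    """
    cfg = net.cfg
    d_s = cfg.d_test if d_s is None else d_s
    J = cfg.J if J is None else J
    snap = net.snapshot() if restore else None
    plastic_before = net.syn_plastic.copy()
    try:
        net.syn_plastic[:] = 0
        sched = make_test_schedule(patterns, d_s, J, cfg)
        res = run(net, sched, patterns, rng, plasticity_on=False)
        codes: dict[int, list[RateCode]] = {p.id: [] for p in patterns}
        for counts, pid in zip(res.sink_counts, res.segment_patterns):
            codes[int(pid)].append(rate_code(counts, C=cfg.C, pattern_id=int(pid)))
        report = compute_di(codes, rng, C=cfg.C)
    finally:
        net.syn_plastic[:] = plastic_before
        if restore:
            net.restore(snap)
    return report


def probe_counts(net: NetworkTopology, pattern: Pattern, d_s: float,
                 trials: int, rng: np.random.Generator) -> np.ndarray:
    """Readout spike counts over repeated frozen presentations, (trials, M)."""
    cfg = net.cfg
    snap = net.snapshot()
    plastic_before = net.syn_plastic.copy()
    try:
        net.syn_plastic[:] = 0
        sched = make_test_schedule([pattern], d_s, trials, cfg)
        res = run(net, sched, [pattern], rng, plasticity_on=False)
    finally:
        net.syn_plastic[:] = plastic_before
        net.restore(snap)
    return res.sink_counts


# ----------------------------------------------------------------------
@dataclass
class TrainResult:
    net: NetworkTopology
    di_series: pd.DataFrame        # time_s, DI, separability, uniqueness, ...
    diagnostics: pd.DataFrame      # per-interval rates and currents
    reports: list[DIReport] = field(default_factory=list)


def train_and_probe(cfg: NetworkConfig,
                    patterns: list[Pattern],
                    total_s: float,
                    probe_every_s: float,
                    seed: int | np.random.SeedSequence,
                    *,
                    net: NetworkTopology | None = None,
                    istdp_on: bool = True,
                    probe_patterns: list[Pattern] | None = None,
                    probe_at_start: bool = False,
                    snapshot_tags: tuple[str, ...] = ()) -> TrainResult:
    """Train on a random pattern stream, probing DI at regular intervals.

    Training presents patterns in random order with exponential durations;
    every ``probe_every_s`` seconds plasticity is frozen and a DI probe
    runs on ``probe_patterns`` (default: the training set).  With
    ``istdp_on=False`` the inhibitory weights are re-drawn once (fixed-z
    ablation, see :func:`fix_inhibitory_weights`) and frozen.  Optional
    binarised weight snapshots of chosen projections are collected for
    synaptic-distance tracking.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    train_rng, probe_rng, build_rng = (np.random.default_rng(s)
                                       for s in ss.spawn(3))
    if net is None:
        net = build_network(cfg, build_rng)
        if not istdp_on:
            fix_inhibitory_weights(net, build_rng)
    elif not istdp_on:
        net.set_plastic(rule="i", on=False)
    probe_patterns = patterns if probe_patterns is None else probe_patterns

    di_rows, reports = [], []
    diag_frames = []
    snapshots: dict[str, list] = {tag: [] for tag in snapshot_tags}

    def take_probe(t_s):
        rep = probe_di(net, probe_patterns, probe_rng)
        reports.append(rep)
        di_rows.append((t_s, rep.DI, rep.separability, rep.uniqueness,
                        rep.D_intra, rep.D_inter))

    def take_snapshots(t_s):
        for tag in snapshot_tags:
            snapshots[tag].append(analysis.binarize_weights(net, tag, time_s=t_s))

    if probe_at_start:
        take_probe(0.0)
    take_snapshots(0.0)

    t = 0.0
    while t < total_s:
        chunk = min(probe_every_s, total_s - t)
        sched = make_training_schedule(patterns, chunk * 1000.0, cfg, train_rng)
        res = run(net, sched, patterns, train_rng, plasticity_on=True)
        d = res.diagnostics
        d["onset_ms"] += t * 1000.0
        diag_frames.append(d)
        t += chunk
        take_probe(t)
        take_snapshots(t)

    di_df = pd.DataFrame(di_rows, columns=[
        "time_s", "DI", "separability", "uniqueness", "D_intra", "D_inter"])
    result = TrainResult(net=net, di_series=di_df,
                         diagnostics=pd.concat(diag_frames, ignore_index=True),
                         reports=reports)
    result.snapshots = snapshots
    return result


def fix_inhibitory_weights(net: NetworkTopology, rng: np.random.Generator) -> None:
    """Ablate inhibitory plasticity: re-draw z once, then freeze it.

    The fixed values are uniform on (0, g_I_max) when
    ``cfg.z_fixed_mode == 'normalized'`` (the (0, 1) range read in units
    of the inhibitory bound) or on the plastic-run initial range when
    'absolute'.
    """
    cfg = net.cfg
    inh = net.syn_rule == 1
    if cfg.z_fixed_mode == "normalized":
        lo, hi = 0.0, cfg.gI_max
    else:
        lo, hi = cfg.z_init
    net.syn_w[inh] = rng.uniform(lo, hi, size=int(inh.sum()))
    net.set_plastic(rule="i", on=False)


# ----------------------------------------------------------------------
@dataclass
class AblationResult:
    on: TrainResult
    off: TrainResult

    def summary(self) -> pd.DataFrame:
        rows = []
        for tag, tr in (("istdp_on", self.on), ("istdp_off", self.off)):
            d = tr.diagnostics
            rows.append((tag,
                         float(np.average(d.res_rate_hz, weights=d.duration_ms)),
                         float(np.average(d.mean_absInet, weights=d.duration_ms)),
                         float(np.average(d.mean_Iex, weights=d.duration_ms)),
                         float(tr.di_series.DI.mean()),
                         analysis.strong_synapse_fraction(tr.net, "EE12")))
        return pd.DataFrame(rows, columns=[
            "condition", "mean_res_rate_hz", "mean_absInet", "mean_Iex",
            "mean_DI", "strong_fraction_12"])


def istdp_ablation(cfg: NetworkConfig, patterns: list[Pattern],
                   total_s: float, probe_every_s: float,
                   seed: int) -> AblationResult:
    """Matched-seed comparison of balanced training vs fixed inhibition.

    Both conditions start from the identical topology and weight draw and
    consume identical training/probing random streams; the only difference
    is that the 'off' condition re-draws z once and freezes it.
    """
    on = train_and_probe(cfg, patterns, total_s, probe_every_s, seed, istdp_on=True)
    off = train_and_probe(cfg, patterns, total_s, probe_every_s, seed, istdp_on=False)
    return AblationResult(on=on, off=off)


# ----------------------------------------------------------------------
def shuffle_controls(net: NetworkTopology, patterns: list[Pattern],
                     seed: int, n_shuffles: int = 10,
                     cases: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
                     J: int | None = None) -> pd.DataFrame:
    """DI of a trained network under the six connectivity-shuffle controls.

    For each case the connectivity is re-shuffled ``n_shuffles`` times
    (weights and synapse counts preserved) and the frozen-probe DI is
    averaged; the unshuffled network's DI is reported as case 0.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    rng0 = np.random.default_rng(ss.spawn(1)[0])
    base = probe_di(net, patterns, rng0, J=J)
    rows.append((0, base.DI, 0.0))
    for case in cases:
        dis = []
        for child in ss.spawn(n_shuffles):
            rng = np.random.default_rng(child)
            shuffled = shuffle_connectivity(net, case, rng)
            dis.append(probe_di(shuffled, patterns, rng, J=J).DI)
        rows.append((case, float(np.mean(dis)), float(np.std(dis))))
    return pd.DataFrame(rows, columns=["case", "DI_mean", "DI_std"])


def readout_code_shuffle_di(net: NetworkTopology, patterns: list[Pattern],
                            seed: int, n_shuffles: int = 10,
                            J: int | None = None) -> pd.DataFrame:
    """Control for the *location* of activity within the readout code.

    Records one probe's raw codes, then independently permutes the symbol
    positions of every recorded code ``n_shuffles`` times and recomputes
    the DI from the permuted codes.  Destroying the neuron identity while
    keeping each code's symbol multiset isolates the contribution of
    learned readout targeting.
    """
    cfg = net.cfg
    ss = np.random.SeedSequence(seed)
    rng0 = np.random.default_rng(ss.spawn(1)[0])
    J = cfg.J if J is None else J
    snap = net.snapshot()
    plastic_before = net.syn_plastic.copy()
    try:
        net.syn_plastic[:] = 0
        sched = make_test_schedule(patterns, cfg.d_test, J, cfg)
        res = run(net, sched, patterns, rng0, plasticity_on=False)
    finally:
        net.syn_plastic[:] = plastic_before
        net.restore(snap)
    codes: dict[int, list[RateCode]] = {p.id: [] for p in patterns}
    for counts, pid in zip(res.sink_counts, res.segment_patterns):
        codes[int(pid)].append(rate_code(counts, C=cfg.C, pattern_id=int(pid)))
    base = compute_di(codes, rng0, C=cfg.C).DI

    dis = []
    for child in ss.spawn(n_shuffles):
        rng = np.random.default_rng(child)
        shuf = {pid: [RateCode(pid, tuple(np.array(c.symbols)[rng.permutation(cfg.M)]))
                      for c in cs]
                for pid, cs in codes.items()}
        dis.append(compute_di(shuf, rng, C=cfg.C).DI)
    return pd.DataFrame({"condition": ["original", "code_shuffled"],
                         "DI_mean": [base, float(np.mean(dis))],
                         "DI_std": [0.0, float(np.std(dis))]})


# ----------------------------------------------------------------------
def parameter_sweeps(cfg: NetworkConfig, patterns: list[Pattern],
                     total_s: float, probe_every_s: float,
                     sweep: dict[str, list], seeds: list[int]) -> pd.DataFrame:
    """DI after training for each value of each swept parameter.

    ``sweep`` maps a config field (``C``, ``M``, ``c_ee_22``, ``c_ee_23``)
    to a list of values; every (field, value, seed) cell trains a fresh
    network and reports the mean DI over the probes in the last half of
    training.  Returns mean and sd per cell.
    """
    import dataclasses

    rows = []
    for name, values in sweep.items():
        for v in values:
            c = dataclasses.replace(cfg, **{name: v})
            for seed in seeds:
                tr = train_and_probe(c, patterns, total_s, probe_every_s, seed)
                tail = tr.di_series[tr.di_series.time_s > total_s / 2]
                rows.append((name, v, seed, float(tail.DI.mean())))
    df = pd.DataFrame(rows, columns=["param", "value", "seed", "DI"])
    return (df.groupby(["param", "value"], as_index=False)
              .agg(DI_mean=("DI", "mean"), DI_std=("DI", "std")))


# ----------------------------------------------------------------------
@dataclass
class StabilityResult:
    net: NetworkTopology
    di_series: pd.DataFrame        # DI on the union of old and new patterns
    phi_series: pd.DataFrame       # time_s, phi, phi_shuffled, phi_rel vs phase-1 end
    diagnostics: pd.DataFrame


def stability_plasticity(net: NetworkTopology,
                         old_patterns: list[Pattern],
                         new_patterns: list[Pattern],
                         mode: str,
                         total_s: float,
                         probe_every_s: float,
                         seed: int,
                         phi_every_s: float = 10.0) -> StabilityResult:
    """Second-phase training: old+new or new-only, with DI and phi_rel tracking.

    Continues training a phase-1 network either on the union of pattern
    sets (``mode='old+new'``) or on the new set alone (``mode='new-only'``).
    DI probes run on the union throughout; the relative synaptic distance
    of the source->reservoir projection is tracked against the phase-1
    endpoint snapshot every ``phi_every_s`` seconds.
    """
    if mode not in ("old+new", "new-only"):
        raise ValueError("mode must be 'old+new' or 'new-only'")
    cfg = net.cfg
    train_set = old_patterns + new_patterns if mode == "old+new" else new_patterns
    union = old_patterns + new_patterns
    ss = np.random.SeedSequence(seed)
    train_rng, probe_rng, shuf_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    ref = analysis.binarize_weights(net, "EE12")
    di_rows, phi_rows, diag_frames = [], [], []
    t = 0.0
    next_probe = probe_every_s
    next_phi = phi_every_s
    while t < total_s:
        chunk = min(next_probe - t, next_phi - t, total_s - t)
        sched = make_training_schedule(train_set, chunk * 1000.0, cfg, train_rng)
        res = run(net, sched, train_set, train_rng, plasticity_on=True)
        d = res.diagnostics
        d["onset_ms"] += t * 1000.0
        diag_frames.append(d)
        t += chunk
        if t >= next_phi - 1e-9:
            snap = analysis.binarize_weights(net, "EE12")
            phi = analysis.synaptic_distance(ref, snap)
            phi_sh = analysis.shuffled_distance(ref, snap, cfg.n_shuffles, shuf_rng)
            phi_rows.append((t, phi, phi_sh, analysis.relative_distance(phi, phi_sh)))
            next_phi += phi_every_s
        if t >= next_probe - 1e-9:
            rep = probe_di(net, union, probe_rng)
            di_rows.append((t, rep.DI, rep.separability, rep.uniqueness))
            next_probe += probe_every_s

    return StabilityResult(
        net=net,
        di_series=pd.DataFrame(di_rows, columns=["time_s", "DI", "separability",
                                                 "uniqueness"]),
        phi_series=pd.DataFrame(phi_rows, columns=["time_s", "phi", "phi_shuffled",
                                                   "phi_rel"]),
        diagnostics=pd.concat(diag_frames, ignore_index=True))


# ----------------------------------------------------------------------
def fano_curve_for_network(net: NetworkTopology, patterns: list[Pattern],
                           d_grid, trials: int, seed: int) -> pd.DataFrame:
    """Fano-factor-vs-d curve for a trained network (frozen weights)."""
    rng = np.random.default_rng(seed)

    def sampler(pattern, d_s, n_trials):
        return probe_counts(net, pattern, d_s, n_trials, rng)

    return metrics.fano_factor_curve(sampler, patterns, d_grid, trials, net.cfg.M)
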