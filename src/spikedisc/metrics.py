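"""Firing-rate codes and the discriminability index (DI).

During a frozen-plasticity probe each pattern is presented J times for a
window of *d* seconds.  The spike counts of the M readout neurons in each
window are banded by their ratio to the window's maximum count into a
C-level symbol vector (the *rate code*; ternary by default: ratio < 0.4
-> 0, [0.4, 0.9) -> 1, [0.9, 1.0] -> 2).  Per pattern, the modal code over
the J repeats is its *prototype*.

The DI combines two quantities computed from 0/1 symbol disagreements:

* ``D_inter`` — mean pairwise distance between prototype codes over all
  unordered pattern pairs, summed over neurons;
* ``D_intra`` — mean pairwise distance between the J codes of the same
  pattern, averaged over patterns;

as ``DI = separability * uniqueness`` with separability
``eps = 1 - D_intra / D_inter`` and uniqueness ``gamma`` the fraction of
distinct prototypes.  DI is 1 for perfectly repeatable, all-distinct
codes, and 0 when every pattern maps to the same code.

The test-window length *d* is chosen by minimising the Fano factor
(variance/mean of readout spike counts over repeated trials): the readout
of a trained balanced network is sub-Poisson (FF < 1) at intermediate
windows, and the FF minimum marks the most reliable code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NetworkConfig

__all__ = [
    "RateCode", "DIReport", "code_thresholds", "rate_code", "prototype_code",
    "inter_pattern_distance", "intra_pattern_distance", "max_inter_distance",
    "discriminability_index", "compute_di", "fano_factor", "fano_factor_curve",
]


@dataclass(frozen=True)
class RateCode:
    pattern_id: int
    symbols: tuple[int, ...]   # length M, values in {0..C-1}


@dataclass
class DIReport:
    D_intra: float
    D_inter: float
    D_inter_max: float
    separability: float
    uniqueness: float
    DI: float
    prototypes: dict[int, RateCode] = field(default_factory=dict)
    pair_distances: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "D_intra": self.D_intra, "D_inter": self.D_inter,
            "D_inter_max": self.D_inter_max, "separability": self.separability,
            "uniqueness": self.uniqueness, "DI": self.DI,
            "prototypes": {pid: list(c.symbols) for pid, c in self.prototypes.items()},
        }


def code_thresholds(C: int, cfg: NetworkConfig | None = None) -> np.ndarray:
    """Band edges for a C-level rate code.

    Ternary uses the standard edges (0.4, 0.9).  Binary thresholds at 0.5.
    For other C the interior [0, 0.9) is split into C-1 equal bands below
    a fixed top band [0.9, 1].  Explicit ``cfg.code_thresholds`` wins.
    """
    if cfg is not None and cfg.code_thresholds is not None:
        edges = np.asarray(cfg.code_thresholds, dtype=float)
        if len(edges) != C - 1:
            raise ValueError("need C-1 threshold edges")
        return edges
    if C == 2:
        return np.array([0.5])
    if C == 3:
        return np.array([0.4, 0.9])
    return np.append(0.9 * np.arange(1, C - 1) / (C - 1), 0.9)


def rate_code(readout_spike_counts, C: int = 3,
              thresholds: np.ndarray | None = None,
              pattern_id: int = -1) -> RateCode:
    """Band readout spike counts into a C-level symbol vector.

    Each neuron's count is divided by the maximum count across neurons and
    banded against the threshold edges; the top band is closed at ratio
    1.0 so the maximal neuron always holds symbol C-1.  All-zero counts
    yield the all-zero code (degenerate-window guard).
    """
    counts = np.asarray(readout_spike_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("spike counts must be non-negative")
    edges = code_thresholds(C) if thresholds is None else np.asarray(thresholds, float)
    fmax = counts.max()
    if fmax == 0:
        return RateCode(pattern_id, tuple([0] * len(counts)))
    ratio = counts / fmax
    symbols = np.searchsorted(edges, ratio, side="right")
    symbols = np.minimum(symbols, C - 1)   # ratio == 1.0 lands in the top band
    return RateCode(pattern_id, tuple(int(s) for s in symbols))


def prototype_code(codes: list[RateCode], rng: np.random.Generator) -> RateCode:
    """Modal code across J repeats; ties or no repeats resolved uniformly at random."""
    if not codes:
        raise ValueError("need at least one code")
    counts: dict[tuple[int, ...], int] = {}
    for c in codes:
        counts[c.symbols] = counts.get(c.symbols, 0) + 1
    best = max(counts.values())
    winners = [s for s, n in counts.items() if n == best]
    chosen = winners[rng.integers(len(winners))] if len(winners) > 1 else winners[0]
    return RateCode(codes[0].pattern_id, chosen)


def _pair_distance(a: RateCode, b: RateCode) -> np.ndarray:
    """Per-neuron 0/1 symbol disagreement."""
    return (np.array(a.symbols) != np.array(b.symbols)).astype(float)


def inter_pattern_distance(prototypes: list[RateCode]):
    """Average pairwise prototype distance.

    Returns ``(D_inter, per_neuron)``: ``per_neuron[i]`` is the mean 0/1
    disagreement at neuron *i* over all P(P-1)/2 unordered pattern pairs,
    and D_inter is its sum over the M neurons.
    """
    P = len(prototypes)
    if P < 2:
        raise ValueError("need at least two prototypes")
    M = len(prototypes[0].symbols)
    acc = np.zeros(M)
    n_pairs = 0
    for a, b in itertools.combinations(prototypes, 2):
        acc += _pair_distance(a, b)
        n_pairs += 1
    per_neuron = acc / n_pairs
    return float(per_neuron.sum()), per_neuron


def intra_pattern_distance(codes_per_pattern: dict[int, list[RateCode]]) -> float:
    """Mean within-pattern pairwise code distance, averaged over patterns.

    For each pattern the J codes give J(J-1)/2 unordered pairs; the mean
    pairwise distance (summed over neurons) is averaged, unweighted,
    across patterns.
    """
    vals = []
    for pid, codes in codes_per_pattern.items():
        if len(codes) < 2:
            raise ValueError(f"pattern {pid}: need J >= 2 codes")
        d = [_pair_distance(a, b).sum() for a, b in itertools.combinations(codes, 2)]
        vals.append(float(np.mean(d)))
    return float(np.mean(vals))


def max_inter_distance(P: int, C: int, M: int, method: str = "formula") -> float:
    """Theoretical upper bound on D_inter for P patterns, C levels, M neurons.

    ``method='formula'`` evaluates the parity-cased closed form: per
    neuron, P(C-1)/(C(P-1)) for odd P and (P+1)(C-1)/(CP) for even P,
    times M.  (With M=8, C=2, P=15 this is the canonical 4.28.)

    ``method='exact'`` maximises the mean pairwise disagreement directly:
    with symbol multiplicities n_1..n_C as equal as possible, the maximum
    per-neuron mean distance is (P^2 - sum n_c^2) / (P(P-1)).  The two
    agree when C divides P; otherwise the closed form deviates slightly
    from the true combinatorial maximum (both are kept: the closed form is
    the conventional bound, the exact value is what enumeration attains).
    """
    if P < 2 or C < 2 or M < 1:
        raise ValueError("require P >= 2, C >= 2, M >= 1")
    if method == "formula":
        if P % 2 == 1:
            per = P * (C - 1) / (C * (P - 1))
        else:
            per = (P + 1) * (C - 1) / (C * P)
    elif method == "exact":
        q, r = divmod(P, C)
        sum_sq = r * (q + 1) ** 2 + (C - r) * q ** 2
        per = (P ** 2 - sum_sq) / (P * (P - 1))
    else:
        raise ValueError("method must be 'formula' or 'exact'")
    return M * per


def discriminability_index(D_intra: float, D_inter: float,
                           prototypes: list[RateCode], P: int,
                           C: int | None = None) -> DIReport:
    """Combine distances and prototype uniqueness into a DIReport.

    separability eps = 1 - D_intra/D_inter (DI forced to 0 when D_inter is
    0: identical prototypes carry no information); uniqueness gamma =
    #distinct prototypes / P; DI = eps * gamma.  DI may be negative when
    within-pattern variability exceeds between-pattern variability.
    """
    M = len(prototypes[0].symbols) if prototypes else 0
    gamma = len({c.symbols for c in prototypes}) / P if P else 0.0
    dmax = max_inter_distance(P, C, M) if (C and P >= 2 and M) else float("nan")
    if D_inter == 0:
        return DIReport(D_intra, 0.0, dmax, 0.0, gamma, 0.0,
                        {c.pattern_id: c for c in prototypes})
    eps = 1.0 - D_intra / D_inter
    return DIReport(D_intra, D_inter, dmax, eps, gamma, eps * gamma,
                    {c.pattern_id: c for c in prototypes})


def compute_di(codes_per_pattern: dict[int, list[RateCode]],
               rng: np.random.Generator, C: int = 3) -> DIReport:
    """Full DI pipeline from raw per-presentation codes."""
    prototypes = [prototype_code(codes, rng) for codes in codes_per_pattern.values()]
    D_inter, _ = inter_pattern_distance(prototypes)
    D_intra = intra_pattern_distance(codes_per_pattern)
    return discriminability_index(D_intra, D_inter, prototypes,
                                  P=len(codes_per_pattern), C=C)


# ----------------------------------------------------------------------
def fano_factor(counts) -> float:
    """Variance-to-mean ratio of spike counts (ddof=1); nan if the mean is 0."""
    counts = np.asarray(counts, dtype=float)
    m = counts.mean()
    if m == 0:
        return float("nan")
    return float(counts.var(ddof=1) / m)


def fano_factor_curve(count_sampler, patterns, d_grid, trials: int,
                      M: int) -> pd.DataFrame:
    """Fano factor of readout counts as a function of the window length d.

    ``count_sampler(pattern, d_s, trials)`` must return an (trials, M)
    array of readout spike counts from repeated frozen presentations (the
    network drivers in :mod:`spikedisc.experiments` provide one).  The FF
    is the across-trial variance/mean per neuron — the M*trials counts of
    a pattern yield M per-neuron ratios — averaged over neurons and then
    over patterns.  (Pooling counts across neurons instead would measure
    the between-neuron rate differences that constitute the code itself.)
    Neurons with zero mean count are excluded; a cell where every neuron
    is silent is reported as nan.
    """
    rows = []
    for d in d_grid:
        ffs = []
        for p in patterns:
            counts = np.asarray(count_sampler(p, float(d), trials))
            if counts.shape != (trials, M):
                raise ValueError("count_sampler returned wrong shape")
            per_neuron = [fano_factor(counts[:, i]) for i in range(M)]
            per_neuron = [f for f in per_neuron if not np.isnan(f)]
            if per_neuron:
                ffs.append(float(np.mean(per_neuron)))
        rows.append((float(d), float(np.mean(ffs)) if ffs else float("nan")))
    return pd.DataFrame(rows, columns=["d_s", "fano_factor"])
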