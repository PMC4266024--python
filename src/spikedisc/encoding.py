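"""Binary image patterns, Poisson spike encoding, and stimulus schedules.

Source-layer neurons map one-to-one onto image pixels (row-major
flattening).  During a presentation, neurons under black pixels fire as
Bernoulli(f_black * dt) per step; a randomly drawn subset
(``noise_fraction``) of the white-pixel neurons fires at the low noise
rate f_noise to emulate image noise, and the remaining white-pixel
neurons stay silent.  The noise subset is redrawn at every presentation.

Training presents patterns in i.i.d. random order with exponentially
distributed durations (mean 30 ms); testing presents each pattern in a
fixed sequence for a fixed duration *d*.

:func:`generate_flag_patterns` builds synthetic "flag" imagery — binary
patterns composed of horizontal/vertical stripes, blocks, diagonals, and
discs — standing in for a training set of national-flag bitmaps that was
never published.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NetworkConfig

__all__ = [
    "Pattern", "StimulusSchedule", "Segment",
    "pattern_rates", "encode_poisson",
    "make_training_schedule", "make_test_schedule",
    "generate_flag_patterns",
]


@dataclass
class Pattern:
    """A binary image: 1 = black (driven) pixel, 0 = white."""

    id: int
    pixels: np.ndarray  # 2-D uint8 array of {0, 1}

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if not np.isin(px, (0, 1)).all():
            raise ValueError("pixels must be binary")
        self.pixels = px.astype(np.uint8)

    @property
    def flat(self) -> np.ndarray:
        """Row-major flattened pixel vector (length K)."""
        return self.pixels.ravel()

    # -- plain-text grid I/O: one row per line, characters '0'/'1' --
    def to_text(self, path: str | Path) -> None:
        lines = ["".join(str(v) for v in row) for row in self.pixels]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path, id: int = 0) -> "Pattern":
        rows = [[int(c) for c in line] for line in Path(path).read_text().split()]
        return cls(id=id, pixels=np.array(rows, dtype=np.uint8))


@dataclass
class Segment:
    pattern_id: int
    onset_ms: float
    duration_ms: float


@dataclass
class StimulusSchedule:
    """Contiguous, non-overlapping sequence of pattern presentations."""

    segments: list[Segment] = field(default_factory=list)

    @property
    def total_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.pattern_id, s.onset_ms, s.duration_ms) for s in self.segments],
            columns=["pattern_id", "onset_ms", "duration_ms"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StimulusSchedule":
        df = pd.read_csv(path)
        return cls([Segment(int(r.pattern_id), float(r.onset_ms), float(r.duration_ms))
                    for r in df.itertuples()])


# ----------------------------------------------------------------------
def pattern_rates(pattern: Pattern, cfg: NetworkConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-source-neuron Poisson rate (Hz) for one presentation.

    Black pixels fire at f_black; a fresh random ``noise_fraction`` of the
    white pixels fires at f_noise; other white pixels are silent.
    """
    flat = pattern.flat
    if flat.size != cfg.K:
        raise ValueError(f"pattern has {flat.size} pixels, config expects K={cfg.K}")
    rates = np.where(flat == 1, cfg.f_black, 0.0)
    white = np.flatnonzero(flat == 0)
    n_noise = int(round(cfg.noise_fraction * white.size))
    if n_noise:
        noisy = rng.choice(white, size=n_noise, replace=False)
        rates[noisy] = cfg.f_noise
    return rates


def encode_poisson(pattern: Pattern, duration_ms: float, cfg: NetworkConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Encode one pattern as source-layer spikes for ``duration_ms``.

    Returns a spike table with columns ``neuron_id`` and ``time_ms``; the
    per-step spike probability of a neuron with rate f is f*dt.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rates = pattern_rates(pattern, cfg, rng)
    p = rates * cfg.dt / 1000.0
    if (p > 1.0).any():
        raise ValueError("f*dt > 1: cannot encode as Bernoulli per step")
    n_steps = int(round(duration_ms / cfg.dt))
    active = np.flatnonzero(p > 0)
    spk = rng.random((n_steps, active.size)) < p[active]
    step, col = np.nonzero(spk)
    return pd.DataFrame({"neuron_id": active[col], "time_ms": step * cfg.dt})


# ----------------------------------------------------------------------
def make_training_schedule(patterns: list[Pattern], total_ms: float,
                           cfg: NetworkConfig, rng: np.random.Generator) -> StimulusSchedule:
    """Random-order presentations with exponential durations until total_ms is covered.

    Durations are rounded up to at least one dt.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    ids = [p.id for p in patterns]
    segs, t = [], 0.0
    while t < total_ms:
        pid = ids[rng.integers(len(ids))]
        dur = max(cfg.dt, np.ceil(rng.exponential(cfg.mean_pattern_duration) / cfg.dt) * cfg.dt)
        dur = min(dur, total_ms - t) if total_ms - t >= cfg.dt else cfg.dt
        segs.append(Segment(pid, t, dur))
        t += dur
    return StimulusSchedule(segs)


def make_test_schedule(patterns: list[Pattern], d_s: float, J: int,
                       cfg: NetworkConfig) -> StimulusSchedule:
    """Fixed-sequence probe: each pattern presented J times for d seconds.

    Pattern-major ordering (all J repeats of a pattern before the next);
    J * P segments in total.
    """
    if d_s <= 0:
        raise ValueError("test duration d must be positive")
    if J < 1:
        raise ValueError("J must be >= 1")
    d_ms = round(d_s * 1000.0 / cfg.dt) * cfg.dt
    segs, t = [], 0.0
    for p in patterns:
        for _ in range(J):
            segs.append(Segment(p.id, t, d_ms))
            t += d_ms
    return StimulusSchedule(segs)


# ----------------------------------------------------------------------
# synthetic flag-like fixtures
def _motif(kind: str, size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((size, size), dtype=np.uint8)
    thick = int(rng.integers(max(2, size // 8), max(3, size // 4)))
    if kind == "hbar":
        r = int(rng.integers(0, size - thick))
        img[r:r + thick, :] = 1
    elif kind == "vbar":
        c = int(rng.integers(0, size - thick))
        img[:, c:c + thick] = 1
    elif kind == "block":
        h = int(rng.integers(size // 3, 2 * size // 3))
        w = int(rng.integers(size // 3, 2 * size // 3))
        r = int(rng.integers(0, size - h))
        c = int(rng.integers(0, size - w))
        img[r:r + h, c:c + w] = 1
    elif kind == "diag":
        sign = 1 if rng.random() < 0.5 else -1
        if sign == 1:   # main diagonal: i - j constant in [-(s-1), s-1]
            off = int(rng.integers(-size // 3, size // 3 + 1))
        else:           # anti-diagonal: i + j constant in [0, 2s-2]
            off = int(rng.integers(2 * size // 3, 4 * size // 3 + 1))
        i, j = np.indices((size, size))
        img[np.abs(i - sign * j - off) <= thick // 2 + 1] = 1
    elif kind == "disc":
        rad = int(rng.integers(size // 5, size // 3))
        cy = int(rng.integers(rad, size - rad))
        cx = int(rng.integers(rad, size - rad))
        i, j = np.indices((size, size))
        img[(i - cy) ** 2 + (j - cx) ** 2 <= rad ** 2] = 1
    else:
        raise ValueError(f"unknown motif kind: {kind}")
    return img


MOTIF_MIXES = {
    # stripes/blocks emulate the original flag-like training set
    "stripes": ("hbar", "vbar", "block"),
    # diagonal and circular features emulate the novel second set
    "diag_disc": ("diag", "disc"),
    "all": ("hbar", "vbar", "block", "diag", "disc"),
}


def generate_flag_patterns(count: int, size: int, rng: np.random.Generator,
                           motif_mix: str = "stripes",
                           max_overlap: float = 0.6,
                           fill_range: tuple[float, float] = (0.22, 0.38),
                           id_offset: int = 0) -> list[Pattern]:
    """Generate ``count`` distinct binary flag-like patterns of shape size x size.

    Each pattern is a union of 1-3 motifs from the chosen mix.  Candidates
    whose pixel overlap (Jaccard index) with an accepted pattern exceeds
    ``max_overlap`` are rejected and redrawn, keeping the set mutually
    discriminable; candidates outside ``fill_range`` (black-pixel
    fraction) are rejected so that total input intensity is roughly
    matched across the set and discrimination must rely on *where* the
    pixels are, not on how many there are.  Fully reproducible from the
    generator state.
    """
    if size < 5:
        raise ValueError("size must be >= 5")
    kinds = MOTIF_MIXES[motif_mix]
    out: list[np.ndarray] = []
    attempts = 0
    while len(out) < count:
        attempts += 1
        if attempts > 500 * count:
            raise RuntimeError("could not generate enough distinct patterns; "
                               "relax max_overlap/fill_range or use a larger size")
        n_motifs = int(rng.integers(1, 4))
        img = np.zeros((size, size), dtype=np.uint8)
        for _ in range(n_motifs):
            img |= _motif(kinds[rng.integers(len(kinds))], size, rng)
        frac = img.mean()
        if not (fill_range[0] <= frac <= fill_range[1]):
            continue
        ok = True
        for other in out:
            inter = (img & other).sum()
            union = (img | other).sum()
            if union == 0 or inter / union > max_overlap:
                ok = False
                break
        if ok:
            out.append(img)
    return [Pattern(id=id_offset + i, pixels=img) for i, img in enumerate(out)]
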