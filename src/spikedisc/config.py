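"""Model and protocol configuration.

A single flat :class:`NetworkConfig` holds every scalar that enters the
neuron dynamics, the two STDP rules, the architecture, the Poisson image
encoder, and the testing protocol.  Defaults reproduce the full-size
network (900 source neurons driven by 30x30 binary images, a 250-neuron
reservoir, 8 readout neurons); :meth:`NetworkConfig.desk` returns a
scaled-down preset suitable for desktop-scale experiments.

Units: times in ms (except ``d_test`` in seconds, as the testing window is
conventionally quoted in seconds), voltages in mV, rates in Hz.  Synaptic
conductances ``w``/``z`` are dimensionless multipliers of the driving
force in the membrane equation; the "nS" naming of their bounds is kept as
a convention only, since the membrane equation consumes them unscaled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["NetworkConfig"]


@dataclass
class NetworkConfig:
    # --- neuron dynamics ---
    tau_m: float = 20.0          # membrane time constant, ms
    V_T: float = -54.0           # spike threshold, mV
    V_rest: float = -74.0        # resting potential, mV
    V_reset: float = -60.0       # post-spike reset, mV
    E_ex: float = 0.0            # excitatory reversal potential, mV
    E_inh: float = -80.0         # inhibitory reversal potential, mV
    tau_ampa: float = 40.0       # excitatory conductance decay, ms
    tau_gaba: float = 50.0       # inhibitory conductance decay, ms
    dt: float = 1.0              # Euler step, ms

    # --- excitatory STDP (anti-symmetric, additive) ---
    A_plus: float = 0.005        # max potentiation per pairing, "nS"
    beta: float = 1.05           # depression/potentiation area ratio |A- tau-|/|A+ tau+|
    tau_plus: float = 20.0       # potentiation window, ms
    tau_minus: float = 20.0      # depression window, ms
    gE_max: float = 0.3          # hard upper bound on w

    # --- inhibitory STDP (symmetric, proximity-potentiating) ---
    B_plus: float = 0.0015       # potentiation amplitude, "nS"
    B_minus: float = 0.0003      # depression amplitude, "nS"
    tau_i: float = 10.0          # proximity window, ms
    gI_max: float = 0.2          # hard upper bound on z

    # --- architecture ---
    image_shape: tuple[int, int] = (30, 30)   # source layer = one neuron per pixel
    N_E: int = 200               # reservoir excitatory neurons
    N_I: int = 50                # reservoir inhibitory neurons
    M: int = 8                   # readout (sink) excitatory neurons
    M_I: int = 2                 # sink inhibitory neurons (4:1 E:I, as in the reservoir)

    # connection probabilities, per projection (layer1=source, 2=reservoir, 3=sink)
    c_ee_12: float = 0.20
    c_ei_12: float = 0.20
    c_ee_22: float = 0.40
    c_ei_22: float = 0.40
    c_ie_22: float = 0.50
    c_ii_22: float = 0.50
    c_ee_23: float = 0.30
    c_ei_33: float = 1.00
    c_ie_33: float = 1.00

    # --- initial weights (uniform ranges) ---
    w_init_12: tuple[float, float] = (0.0, 0.1)
    w_init_22: tuple[float, float] = (0.0, 0.1)
    w_init_23: tuple[float, float] = (0.0, 0.2)
    z_init: tuple[float, float] = (0.0, 0.1)
    # When inhibitory plasticity is ablated, z is fixed at a random draw.
    # 'normalized' reads the fixed-z range (0, 1) as fractions of gI_max;
    # 'absolute' reuses z_init unchanged.
    z_fixed_mode: str = "normalized"

    # --- input encoding ---
    f_black: float = 90.0        # Poisson rate of neurons under black pixels, Hz
    f_noise: float = 10.0        # Poisson rate of the white-pixel noise subset, Hz
    noise_fraction: float = 0.10  # fraction of white-pixel neurons carrying noise
    mean_pattern_duration: float = 30.0  # exponential mean of training presentations, ms

    # --- testing protocol ---
    d_test: float = 1.4          # test presentation duration, s
    J: int = 10                  # repeats per pattern in a probe
    C: int = 3                   # rate-code alphabet size (ternary)
    code_thresholds: tuple[float, ...] | None = None  # None -> standard bands for C

    # --- analysis ---
    strong_fraction: float = 0.7  # w > strong_fraction * g_max counts as a strong synapse
    n_shuffles: int = 10          # shuffles for the chance-level synaptic distance
    transition_window: float = 20.0  # ms window for functional-graph transitions (= tau_plus)

    # Per-synapse transmission delays, drawn uniformly on the integer grid
    # [min, max] ms.  Heterogeneous delays desynchronise recurrent volleys
    # (at dt=1 ms a single shared delay makes a whole-network synchronous
    # limit cycle absorbing); the E->I / I->* loop is kept fast, as for
    # perisomatic inhibition, so that inhibition tracks excitation tightly.
    delay_ee: tuple[float, float] = (1.0, 10.0)
    delay_inh_loop: tuple[float, float] = (1.0, 2.0)

    # Synaptic conductances w, z are specified in "nS"; the membrane
    # equation consumes them relative to the leak conductance, i.e. as
    # g / g_unit.  g_unit (nS) sets the overall coupling strength.
    g_unit: float = 1.0

    # --- numerics ---
    exact_decay: bool = False    # exact exponential conductance decay instead of Euler
    # E-STDP pairing: 'nearest' pairs each spike at most once per synapse
    # and direction (non-overlapping nearest-neighbour, via stored last and
    # previous spike times), which keeps the mean drift depression-biased
    # at every rate combination; 'all_to_all' pairs against full spike
    # traces (classical additive STDP, prone to runaway potentiation when
    # post rates far exceed pre rates).
    pairing: str = "nearest"
    rng_seed: int | None = None

    # ------------------------------------------------------------------
    @property
    def K(self) -> int:
        """Source-layer size (one neuron per pixel)."""
        return int(self.image_shape[0] * self.image_shape[1])

    @property
    def A_minus(self) -> float:
        """Depression amplitude; not free, fixed by beta = |A- tau-| / |A+ tau+|."""
        return self.beta * self.A_plus * self.tau_plus / self.tau_minus

    @property
    def n_internal(self) -> int:
        return self.N_E + self.N_I + self.M + self.M_I

    def decay_factor(self, tau: float) -> float:
        """Per-step conductance decay multiplier."""
        import math

        if self.exact_decay:
            return math.exp(-self.dt / tau)
        return 1.0 - self.dt / tau

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if not (self.V_reset < self.V_T):
            raise ValueError("V_reset must lie below the threshold V_T")
        if not (self.E_inh < self.V_rest < self.V_T < self.E_ex):
            raise ValueError("require E_inh < V_rest < V_T < E_ex")
        for name in ("gE_max", "gI_max", "tau_m", "tau_ampa", "tau_gaba",
                     "tau_plus", "tau_minus", "tau_i", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("c_ee_12", "c_ei_12", "c_ee_22", "c_ei_22", "c_ie_22", "c_ii_22",
                     "c_ee_23", "c_ei_33", "c_ie_33", "noise_fraction"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")
        for f in (self.f_black, self.f_noise):
            if f * self.dt / 1000.0 > 1.0:
                raise ValueError("f*dt exceeds 1: Bernoulli encoding invalid")
        if min(self.K, self.N_E, self.N_I, self.M, self.M_I) <= 0:
            raise ValueError("all layer sizes must be positive")
        if self.C < 2:
            raise ValueError("rate code needs at least two levels")
        if self.z_fixed_mode not in ("normalized", "absolute"):
            raise ValueError("z_fixed_mode must be 'normalized' or 'absolute'")
        if self.pairing not in ("all_to_all", "nearest"):
            raise ValueError("pairing must be 'all_to_all' or 'nearest'")
        if self.g_unit <= 0:
            raise ValueError("g_unit must be positive")
        for lo, hi in (self.delay_ee, self.delay_inh_loop):
            if not (self.dt <= lo <= hi):
                raise ValueError("delay ranges must satisfy dt <= min <= max")

    # ------------------------------------------------------------------
    @classmethod
    def desk(cls, **overrides) -> "NetworkConfig":
        """Scaled-down preset: 15x15 images, 125-neuron reservoir.

        Keeps every dynamical parameter at its default; only sizes and the
        testing protocol are reduced so that complete training/probing
        experiments run in minutes on one CPU core.
        """
        params = dict(
            image_shape=(15, 15), N_E=100, N_I=25, M=8, M_I=2,
        )
        params.update(overrides)
        return cls(**params)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-friendly: tuples -> lists
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        kwargs = {}
        fields = {f.name for f in dataclasses.fields(cls)}
        for k, v in d.items():
            if k not in fields:
                raise KeyError(f"unknown config key: {k}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
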