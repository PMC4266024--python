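"""Conductance-based leaky integrate-and-fire dynamics.

Reference (vectorised numpy) implementation of the membrane and
conductance update used throughout the package.  The simulation loop in
:mod:`spikedisc.network` runs a compiled event-driven kernel for speed;
these functions define the semantics that kernel must match and are the
ones exercised directly by unit tests and small-scale analyses.

The membrane potential of neuron *i* follows

    tau_m dV/dt = (V_rest - V) + (E_ex - V) g_ex + (E_inh - V) g_inh

advanced by explicit Euler at a fixed step ``dt``.  When V crosses the
threshold V_T the neuron emits a spike and V is reset to V_reset; there is
no refractory period.  Conductances decay with AMPA/GABA time constants
and jump by the summed synaptic weight of presynaptic spikes (delta
input).  Conductances are dimensionless multipliers of the driving force;
see :mod:`spikedisc.config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig

__all__ = ["NeuronState", "step_membrane", "step_conductances", "net_currents"]

_NEVER = -1.0e18  # sentinel for "has not spiked yet"


@dataclass
class NeuronState:
    """Per-neuron dynamical variables for one population."""

    V: np.ndarray                 # membrane potential, mV
    g_ex: np.ndarray              # summed excitatory conductance
    g_inh: np.ndarray             # summed inhibitory conductance
    spiked_now: np.ndarray = field(default=None)   # bool, spike emitted this step
    last_spike_time: np.ndarray = field(default=None)  # ms; _NEVER if silent so far

    def __post_init__(self):
        n = len(self.V)
        self.V = np.asarray(self.V, dtype=float)
        self.g_ex = np.asarray(self.g_ex, dtype=float)
        self.g_inh = np.asarray(self.g_inh, dtype=float)
        if self.spiked_now is None:
            self.spiked_now = np.zeros(n, dtype=bool)
        if self.last_spike_time is None:
            self.last_spike_time = np.full(n, _NEVER)

    @classmethod
    def resting(cls, n: int, cfg: NetworkConfig) -> "NeuronState":
        return cls(V=np.full(n, cfg.V_rest), g_ex=np.zeros(n), g_inh=np.zeros(n))


def step_conductances(state: NeuronState,
                      incoming_ex_weight_sum: np.ndarray,
                      incoming_inh_weight_sum: np.ndarray,
                      cfg: NetworkConfig) -> NeuronState:
    """Decay conductances one step and add this step's synaptic input.

    ``incoming_*_weight_sum`` are the per-neuron totals of synaptic weights
    on synapses whose presynaptic neuron spiked (delta input of the
    conductance equations).  Negative input sums are rejected: they can
    only arise from corrupted weights.
    """
    ex_in = np.asarray(incoming_ex_weight_sum, dtype=float)
    inh_in = np.asarray(incoming_inh_weight_sum, dtype=float)
    if (ex_in < 0).any() or (inh_in < 0).any():
        raise ValueError("negative synaptic weight sums")
    state.g_ex = state.g_ex * cfg.decay_factor(cfg.tau_ampa) + ex_in
    state.g_inh = state.g_inh * cfg.decay_factor(cfg.tau_gaba) + inh_in
    return state


def step_membrane(state: NeuronState, cfg: NetworkConfig, t_now: float = 0.0) -> NeuronState:
    """Advance membrane potentials one Euler step; emit and reset spikes.

    Pre-condition: conductances already updated for this step.  Neurons at
    or above threshold after integration fire (``>=`` comparison) and are
    reset.  Non-finite potentials raise ``FloatingPointError`` — they signal
    a parameter blow-up, not a recoverable state.
    """
    v = state.V
    dv = ((cfg.V_rest - v) + (cfg.E_ex - v) * state.g_ex / cfg.g_unit
          + (cfg.E_inh - v) * state.g_inh / cfg.g_unit)
    v = v + (cfg.dt / cfg.tau_m) * dv
    if not np.isfinite(v).all():
        raise FloatingPointError("non-finite membrane potential")
    fired = (v >= cfg.V_T) | (state.V >= cfg.V_T)
    v = np.where(fired, cfg.V_reset, v)
    state.V = v
    state.spiked_now = fired
    state.last_spike_time = np.where(fired, t_now, state.last_spike_time)
    return state


def net_currents(state: NeuronState, cfg: NetworkConfig):
    """Excitatory, inhibitory and net synaptic drive (mV * weight units).

    These are the terms the membrane equation integrates; the balance
    diagnostics track their population means over time.
    """
    i_ex = (cfg.E_ex - state.V) * state.g_ex / cfg.g_unit
    i_inh = (cfg.E_inh - state.V) * state.g_inh / cfg.g_unit
    return i_ex, i_inh, i_ex + i_inh
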