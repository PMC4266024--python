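"""Excitatory and inhibitory spike-timing-dependent plasticity.

Two additive rules act every step on all four synapse classes
(E->E, E->I under the excitatory rule; I->E, I->I under the inhibitory
rule), with hard clipping to [0, g_max]:

* **E-STDP** is anti-symmetric in the pre-post timing difference
  ``dt = t_pre - t_post``: causal pairings (pre before post, dt < 0)
  potentiate by ``A+ exp(dt / tau+)``, anti-causal or simultaneous
  pairings depress by ``A- exp(-dt / tau-)``.  The depression amplitude is
  tied to the potentiation amplitude through the area ratio
  ``beta = |A- tau-| / |A+ tau+|`` (default 1.05, a slight depression
  bias).

* **I-STDP** is symmetric: pairings closer than the proximity window
  ``tau_i`` potentiate by ``B+ exp(-|dt|/tau_i)`` regardless of order,
  more distant pairings depress by ``B- exp(-|dt|/tau_i)``.

Together the two rules partition the timing axis into four regimes
(:func:`classify_regime`); the proximal-causal "balance" regime — where
both excitation and inhibition grow — is the one that drives the network
toward balanced currents.

Pairing scheme: nearest-neighbour, using each neuron's single stored last
spike time.  On every postsynaptic spike each afferent synapse is updated
against the presynaptic neuron's last spike, and on every presynaptic
spike each efferent synapse is updated against the postsynaptic neuron's
last spike (simultaneous spikes pair once, at dt = 0, through the
presynaptic branch).  At 1 ms resolution and reservoir rates well below
the STDP window this closely approximates all-to-all pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig
from .neurons import _NEVER

__all__ = [
    "SynapseClassMatrix", "estdp_delta", "istdp_delta",
    "apply_stdp", "classify_regime", "initial_weights",
]

REGIMES = ("balance", "accelerated_potentiation", "decelerated_depression", "quiescent")


@dataclass
class SynapseClassMatrix:
    """Dense weight matrix (pre x post) for one synapse class.

    ``rule`` is 'e' for excitatory synapses (E-STDP) or 'i' for inhibitory
    ones (I-STDP).  The connectivity mask is fixed at construction: there
    is no structural plasticity, weights simply move within [0, g_max] on
    the realised synapses and stay 0 elsewhere.
    """

    class_tag: str                # e.g. "EE12", "IE22"
    mask: np.ndarray              # bool, pre x post
    weights: np.ndarray           # float, pre x post; 0 off-mask
    g_max: float
    rule: str                     # 'e' | 'i'

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.mask.shape != self.weights.shape:
            raise ValueError("mask/weights shape mismatch")
        if self.rule not in ("e", "i"):
            raise ValueError("rule must be 'e' or 'i'")
        self.weights = np.where(self.mask, np.clip(self.weights, 0.0, self.g_max), 0.0)


def estdp_delta(delta_t, cfg: NetworkConfig):
    """Excitatory weight change for timing difference ``delta_t = t_pre - t_post`` (ms)."""
    dt = np.asarray(delta_t, dtype=float)
    # clamp the inactive branch's argument: both sides of the select are
    # evaluated, and exp overflows for huge |delta_t|
    pot = cfg.A_plus * np.exp(np.minimum(dt, 0.0) / cfg.tau_plus)
    dep = -cfg.A_minus * np.exp(-np.maximum(dt, 0.0) / cfg.tau_minus)
    out = np.where(dt < 0, pot, dep)
    return out if out.ndim else float(out)


def istdp_delta(delta_t, cfg: NetworkConfig):
    """Inhibitory weight change; symmetric in ``delta_t`` (ms)."""
    adt = np.abs(np.asarray(delta_t, dtype=float))
    mag = np.exp(-adt / cfg.tau_i)
    out = np.where(adt <= cfg.tau_i, cfg.B_plus * mag, -cfg.B_minus * mag)
    return out if out.ndim else float(out)


def classify_regime(delta_t: float, cfg: NetworkConfig) -> str:
    """Name the joint E/I-STDP regime for a timing difference.

    proximal causal -> 'balance' (dw>0, dz>0); distal causal ->
    'accelerated_potentiation' (dw>0 small, dz<0); distal anti-causal ->
    'decelerated_depression' (dw<0, dz<0); proximal anti-causal ->
    'quiescent' (dw<0 strong, dz>0).
    """
    causal = delta_t < 0
    proximal = abs(delta_t) <= cfg.tau_i
    if causal and proximal:
        return "balance"
    if causal:
        return "accelerated_potentiation"
    if proximal:
        return "quiescent"
    return "decelerated_depression"


def _delta(rule: str, dt, cfg: NetworkConfig):
    return estdp_delta(dt, cfg) if rule == "e" else istdp_delta(dt, cfg)


def apply_stdp(synapses: SynapseClassMatrix,
               pre_spikes: np.ndarray,
               post_spikes: np.ndarray,
               last_pre: np.ndarray,
               last_post: np.ndarray,
               t_now: float,
               cfg: NetworkConfig) -> SynapseClassMatrix:
    """Apply one step of STDP to a dense synapse class, in place.

    ``pre_spikes`` / ``post_spikes`` flag the neurons spiking at ``t_now``;
    ``last_pre`` / ``last_post`` are their stored last spike times *before*
    this step.  Both pairing directions are applied: afferent updates for
    every postsynaptic spike (against the pre's previous spike) and
    efferent updates for every presynaptic spike (against the post's most
    recent spike, including one at ``t_now``).  Weights are clipped to
    [0, g_max].
    """
    W, mask = synapses.weights, synapses.mask
    pre_spikes = np.asarray(pre_spikes, dtype=bool)
    post_spikes = np.asarray(post_spikes, dtype=bool)

    # postsynaptic spikes: pair with the pre's previous spike (dt < 0)
    post_idx = np.flatnonzero(post_spikes)
    if post_idx.size:
        valid = last_pre > _NEVER / 2
        dw = np.where(valid, _delta(synapses.rule, last_pre - t_now, cfg), 0.0)
        W[:, post_idx] += dw[:, None] * mask[:, post_idx]

    # presynaptic spikes: pair with the post's latest spike (dt >= 0)
    pre_idx = np.flatnonzero(pre_spikes)
    if pre_idx.size:
        eff_last_post = np.where(post_spikes, t_now, last_post)
        valid = eff_last_post > _NEVER / 2
        dw = np.where(valid, _delta(synapses.rule, t_now - eff_last_post, cfg), 0.0)
        W[pre_idx, :] += dw[None, :] * mask[pre_idx, :]

    np.clip(W, 0.0, synapses.g_max, out=W)
    W[~mask] = 0.0
    return synapses


def initial_weights(shape, mask, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform initial weights on (lo, hi), zero off-mask."""
    w = rng.uniform(lo, hi, size=shape)
    return np.where(mask, w, 0.0)
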