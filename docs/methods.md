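# Methods

`spikedisc` simulates a three-layer spiking network that learns to
discriminate binary images without supervision, and provides the
measurement apparatus for that claim: rate-code readouts, the
discriminability index (DI), Fano-factor selection of the test window,
synaptic-distance stability diagnostics, shuffle controls, and
stability-plasticity protocols.

## Model

**Architecture.** A source layer of K Poisson neurons (one per image
pixel) projects to a recurrent excitatory-inhibitory reservoir (N_E
excitatory, N_I inhibitory neurons, 4:1), which projects to M excitatory
readout ("sink") neurons reciprocally coupled to a small sink inhibitory
population (M_I, keeping the 4:1 ratio). Connectivity is independent
Bernoulli per projection (defaults: source→res E 20%, source→res I 20%,
E→E 40%, E→I 40%, I→E 50%, I→I 50% within the reservoir, res E→sink E
30%, and all-to-all within the sink layer), with no self-loops and no
structural plasticity. Both reservoir populations receive source input;
the direct source→I pathway supplies feedforward inhibition from the
first stimulus onward, which is what allows the balanced regime to be
reached from random initial weights (without it the inhibitory
population is recruited only through reservoir E→I synapses, and those
are depressed to zero during the initial high-rate transient — an
absorbing silent-inhibition state).

**Neurons.** Conductance-based leaky integrate-and-fire:

    tau_m dV/dt = (V_rest − V) + (E_ex − V) Σ g_ex + (E_inh − V) Σ g_inh

with tau_m = 20 ms, V_T = −54 mV, V_rest = −74 mV, V_reset = −60 mV,
E_ex = 0, E_inh = −80 mV, explicit Euler at dt = 1 ms, threshold crossing
(≥) emits a spike and resets; no refractory period. Conductances decay
with tau_AMPA = 40 ms / tau_GABA = 50 ms (Euler decay by default, exact
exponential behind `exact_decay`) and jump by the synaptic weight on
presynaptic spike arrival. Weights are quoted in "nS" but enter the
membrane equation as dimensionless multipliers of the driving force
(`g_unit`, default 1, converts between the two; the default reproduces
the intended dynamics without rescaling).

**Synaptic delays.** Each synapse carries an integer transmission delay:
E→E and cross-layer excitatory synapses draw uniformly from 1–10 ms,
the inhibitory loops (E→I, I→E, I→I inside a layer) from 1–2 ms, as for
fast perisomatic inhibition. Heterogeneous delays matter at this
discretisation: with a single shared 1-step delay and no refractory
period, the fully synchronous fire-every-step state is an absorbing
limit cycle of the update map, and the network ignites into it from
sub-threshold initial conditions. Spreading the delays removes that
artifact while keeping the inhibitory feedback fast.

**Excitatory STDP** (all E→E and E→I synapses, always on): additive,
anti-symmetric in Δt = t_pre − t_post; potentiation A⁺ exp(Δt/τ⁺) for
Δt < 0, depression A⁻ exp(−Δt/τ⁻) for Δt ≥ 0, hard clip to [0, gᴱ_max].
A⁺ = 0.005, τ⁺ = τ⁻ = 20 ms, gᴱ_max = 0.3; A⁻ is not free — it is set
by the area ratio β = |A⁻τ⁻|/|A⁺τ⁺| = 1.05, a slight depression bias
that makes uncorrelated inputs lose the competition.

**Inhibitory STDP** (I→E, I→I): symmetric; pairings closer than
τ_i = 10 ms potentiate by B⁺ exp(−|Δt|/τ_i) regardless of order, more
distant ones depress by B⁻ exp(−|Δt|/τ_i); B⁺ = 0.0015, B⁻ = 0.0003,
clip to [0, gᴵ_max] with gᴵ_max = 0.2. Coincidence-driven potentiation
is the balancing mechanism: whenever excitation drives spiking,
inhibitory synapses onto the same targets strengthen until the net
current returns toward zero.

**Pairing scheme.** The default is *non-overlapping nearest-neighbour*
pairing: on each postsynaptic spike a synapse pairs with the
presynaptic neuron's last spike only if that spike is more recent than
the postsynaptic neuron's own previous spike, and symmetrically for
presynaptic spikes, so each spike enters at most one pairing per synapse
and direction (implemented with stored last- and previous-spike times).
This bounds the drift of an excitatory synapse by
min(r_pre, r_post)·(A⁺ − A⁻·…) < 0 for β > 1 at *every* rate
combination. The textbook alternatives fail here: single-last-spike
pairing re-pairs one presynaptic spike with every subsequent
postsynaptic spike, so potentiation scales with r_post alone and any
transiently over-excited network potentiates itself into permanent
saturation; all-to-all trace pairing restores the β bias only in the
mean field, and the correlation term overwhelms the 5 % margin at high
rates with the same outcome. Both observations are from direct
simulation of this model; `pairing="all_to_all"` (exact exponential
traces, so an isolated pair reproduces the closed-form curve) is kept
for comparison. The inhibitory rule always pairs against last-spike
times; its symmetric window makes the refinement immaterial in the
regimes the network visits.

Simultaneous (same-step) pairs enter once, at Δt = 0, through the
presynaptic branch (depression for the excitatory rule, as the Δt ≥ 0
case prescribes; potentiation for the inhibitory rule).

**Initial weights.** Excitatory: uniform (0, 0.1) for source→reservoir
and intra-reservoir synapses, (0, 0.2) for reservoir→sink. Inhibitory:
uniform (0, 0.1). When inhibitory plasticity is ablated ("fixed-z"), z
is re-drawn once on (0, 1) in units of gᴵ_max — i.e. (0, 0.2) — and
frozen (`z_fixed_mode="normalized"`; the literal reading of (0, 0.1) is
available as `"absolute"`).

## Stimuli

Binary images (30×30 by default; one pixel per source neuron,
row-major). During a presentation, black-pixel neurons fire Bernoulli
(f·dt) with f = 90 Hz; a freshly drawn 10 % of the white-pixel neurons
fire at 10 Hz (image noise; redrawn every presentation); the rest are
silent. Training presents patterns in i.i.d. random order with
exponential durations (mean 30 ms, floored at one step). Testing
presents each pattern in a fixed sequence for d = 1.4 s, J = 10 repeats.

The built-in pattern generator emulates flag-like imagery: each pattern
is a union of 1–3 motifs (horizontal/vertical bars and blocks for the
primary set; diagonals and discs for the "novel" set), with a pairwise
Jaccard-overlap cap (0.6) so the set stays mutually discriminable, and
a black-pixel fraction between 10 % and 60 %. The generator reproduces
the *statistics* of such a training set, not any specific published
bitmaps (none exist); real images would have richer correlation
structure, so passing results here demonstrate the mechanism, not
performance on natural stimuli.

## Measurements

**Rate code.** Per probe presentation, each readout's spike count is
divided by the maximum count across readouts and banded: ternary
default 0 (< 0.4), 1 ([0.4, 0.9)), 2 ([0.9, 1.0]). The printed top band
excludes ratio 1.0, which would exclude the maximal neuron itself; the
band is closed at 1.0 here. All-zero windows code as all-zero. For
C ≠ 3: binary thresholds at 0.5; otherwise C−2 equal-width bands below
a fixed top band at 0.9.

**DI.** Prototypes are modal codes over J repeats (ties and no-repeat
cases broken uniformly at random). D_inter = mean pairwise prototype
distance (0/1 per neuron, summed over neurons) over unordered pattern
pairs; D_intra = the same within pattern, averaged (unweighted) over
patterns; separability ε = 1 − D_intra/D_inter (DI ≡ 0 when D_inter = 0);
uniqueness γ = #distinct prototypes / P; DI = ε·γ.

**D_inter bound.** `max_inter_distance` evaluates the conventional
parity-cased closed form — per neuron P(C−1)/(C(P−1)) for odd P,
(P+1)(C−1)/(CP) for even P, times M (giving the canonical 4.28 for
M=8, C=2, P=15) — and, as `method="exact"`, the true combinatorial
maximum (P² − Σ n_c²)/(P(P−1))·M with symbol multiplicities as equal as
possible. The two agree when C divides P (odd P); elsewhere the closed
form deviates slightly from what enumeration attains, so tests anchor
on the exact method.

**Fano factor.** For a window length d, pooled readout spike counts
over repeated frozen presentations give FF = var/mean per pattern,
averaged over patterns. Poisson input reproduces FF ≈ 1 − f·dt (the
Bernoulli-thinning correction, ≈ 1 at low rates); a trained balanced
network is sub-Poisson at intermediate d, and the FF minimum selects
the operating window (d = 1.4 s).

**Synaptic distance.** Binarise a projection at w > 0.7·g_max; φ is the
Hamming distance between two snapshots normalised by all pre×post
positions; φ_shuffled is the mean distance after density-preserving
random permutations of the later snapshot (10 shuffles); φ_rel =
|φ − φ_shuffled| / φ_shuffled (undefined — NaN — when φ_shuffled = 0).
φ_rel near 1 means the weights moved far less than chance.

**Back-trace.** For one presentation, the structural graph holds the
reservoir E neurons with strong synapses onto the maximally firing
readouts (top code band) plus strong E→E edges among them; the
functional graph, on the same nodes, counts directed spike transitions
within one STDP window (τ⁺ = 20 ms, config-exposed). Raw transition
counts are stored; normalisation is left to presentation.

## Protocols

Training alternates with frozen probes: plasticity off, the full test
schedule presented, DI computed, and the complete dynamical state
(including membrane potentials, conductances, pairing bookkeeping and
STDP traces) restored afterwards, so probing is bit-exactly
side-effect-free; probes use a dedicated random stream and their
duration never counts toward training time. The ablation driver runs
matched seeds (identical topology and initial weights) with inhibitory
plasticity on vs off. Shuffle controls re-wire one group of projections
at a time — preserving each weight, the synapse count, and every
neuron's in-degree — and re-probe; the readout-code control instead
permutes symbol positions within each recorded code. The
stability-plasticity protocol continues a trained network on old+new or
new-only pattern sets while probing DI on the union and tracking
φ_rel of the source→reservoir projection against the phase-1 endpoint.

## Scale and run sizes

The default configuration is the full-size network (K = 900, N_E = 200,
N_I = 50, M = 8). Analyses and the acceptance script use
`NetworkConfig.desk()`: 15×15 images (K = 225), N_E = 100, N_I = 25,
M = 8, M_I = 2, with every dynamical parameter and the full testing
protocol (d = 1.4 s, J = 10) unchanged; training phases are 1800 s
with probes every 180 s, 5 seeds for the ablation/DI comparisons and 3
seeds for the two-phase stability protocols. At this scale the
event-driven compiled kernel advances roughly two orders of magnitude
faster than real time on one core, so the protocol lengths are a
deliberate choice of statistical resolution, with phase lengths half
the full-size study's hour per phase.

At desk scale the qualitative picture of the full-size study holds
(balance with inhibitory plasticity, bimodal source→reservoir weights
with a small strong fraction, inhibitory projections unimodal at their
bound, DI contrast between balanced and ablated conditions,
non-catastrophic forgetting), but absolute numbers shift: the ablated
network settles at a few tens of Hz rather than ~120 Hz — the fixed-z
feedforward inhibition still restrains a 4×-smaller input convergence —
the DI plateau sits below the full-size value, and reservoir→sink
weights potentiate only partially within the shorter phases. The
acceptance script reports whatever the runs produce.

## Numerical and degenerate-input conventions

Exact-threshold membrane states fire (≥). Conductances and weights are
clipped non-negative; weight updates clip to [0, g_max] per event.
Never-spiked partners contribute no pairing. Zero-duration schedules
are rejected; empty spike records yield empty graphs; FF cells with
zero mean count are excluded as undefined; φ_rel returns NaN when the
chance-level distance is zero (e.g. both snapshots saturated). The
simulation aborts with `FloatingPointError` if any membrane potential
leaves ±10⁶ mV (parameter blow-up). All randomness flows through
`numpy.random.Generator` objects; identical seeds give bit-identical
spike records, and experiment drivers spawn independent child streams
for building, training, probing, and shuffling.

## Known limitations

Desk-scale quantitative gaps above; nearest-pairing refinement and
heterogeneous delays are this package's choices where the source
material is silent or its literal reading is unstable (details in the
pairing and delay sections); the supervised-learning extensions and
GPU execution are out of scope; mutual-information analyses of the
readout are not implemented (the DI is the implemented measure).
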