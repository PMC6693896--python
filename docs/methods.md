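# Methods

This note documents the models, parameters, numerical choices and
limitations behind `isnsim`, in the spirit of the methods documentation
of mature simulation packages.

## Neuron models

**Exponential integrate-and-fire (exp-I&F).** Subthreshold dynamics

    C dV/dt = g_L (E_L − V) + g_L Δ_T exp((V − V_T)/Δ_T)
              + Σ_s g_s (E_s − V) + I_inj

with a spike registered when V first reaches the cutoff `V_cut`, reset
to `V_reset`, and an absolute refractory period `t_ref` during which V
is held at the reset value while synaptic conductances keep evolving.
The network literature this model family comes from does not pin a
single canonical parameter set for the E/I network used here, so the
package pins reproducible defaults consistent with that family and
makes every value config-overridable:

| parameter | default | unit | meaning |
|---|---|---|---|
| C | 200 | pF | membrane capacitance |
| g_L | 10 | nS | leak conductance (τ_m = 20 ms) |
| E_L | −70 | mV | leak reversal / rest |
| V_T | −50 | mV | exponential threshold |
| Δ_T | 2 | mV | spike-initiation slope factor |
| V_cut | 0 | mV | spike-detection cutoff |
| V_reset | −60 | mV | post-spike reset |
| t_ref | 2 | ms | absolute refractory period |

Setting `Δ_T = 0` disables the spike-initiation current exactly,
leaving a passive leaky integrator; several tests and the
inhibition-dominance analysis use this degenerate case because it has
closed-form solutions.

**Hodgkin–Huxley point neuron.** Single compartment with transient Na⁺
(m³h), delayed-rectifier K⁺ (n⁴), slow non-inactivating M-type K⁺ (p),
high-threshold L-type Ca²⁺ (q²) and leak. The spike-generating Na⁺/K⁺
kinetics are Traub-style rate functions referenced to −55 mV; the
M-current uses a sigmoidal steady state at −35 mV with a
bell-shaped time constant scaled by `tau_max_M` (default 1000 ms,
which produces spike-frequency adaptation); the Ca²⁺ current is treated
as ohmic with a fixed reversal of +120 mV, deliberately ignoring GHK
rectification and Ca²⁺ accumulation. `V_shift` translates the Na⁺
gating curves only and stands in for the "voltage dependence of the Na⁺
conductance" degree of freedom of the tuning stage. All conductances
are whole-cell totals in nS; the defaults (C = 100 pF, ḡ_Na = 5000 nS,
ḡ_Kd = 1000 nS, ḡ_M = 30 nS, ḡ_CaL = 20 nS, ḡ_leak = 5 nS) describe a
regular-spiking cell of roughly 10⁴ µm² membrane: resting near −70 mV,
rheobase between 100 and 150 pA on 1-s pulses, adapting spike trains,
monotonically increasing spike count with stimulus amplitude. The model
is temperature-independent by construction (no Q10 scaling).

**Cable model.** A passive compartmental tree: spherical root (soma,
area πd²) plus cylindrical compartments (lateral area πdL), specific
membrane parameters c_m = 1 µF/cm², g_pas = 5·10⁻⁵ S/cm² (τ_m = 20 ms),
e_pas = −70 mV and axial resistivity Ra = 150 Ω·cm. Axial coupling
between neighboring compartments uses the standard half-cylinder
series-resistance rule; a spherical soma contributes no axial
resistance of its own. The hybrid network's detailed cell is a
ball-and-stick stand-in (synthetic, generated by
`synthetic.make_ball_and_stick`): 20 µm soma, 500 µm × 2 µm dendrite in
20 compartments. Channel complements per compartment are structurally
supported but the stand-in is purely passive — it cannot spike, which
is acceptable because the replaced cells' axonal output is omitted
anyway and the readout is a somatic voltage clamp.

## Synapses

Conductance-based, single-exponential: each delivered presynaptic spike
increments the class conductance by the peak value w; between events
g decays as exp(−dt/τ). Excitation: E_syn = 0 mV, τ = 5 ms; inhibition:
E_syn = −75 mV, τ = 10 ms. The reversal potentials and peak
conductances (0.1 nS E, 0.2 nS I, 0.1 nS background) are the study's
stated values; the decay constants are not stated there and are package
defaults. One synapse per connected pair, uniform weight per
projection, uniform 1 ms delay (a positive delay is required for
well-defined event ordering in the clock-driven loop).

## Network

800 excitatory and 200 inhibitory cells. Binomial wiring: each ordered
pair is connected independently with probability 0.15 when the
presynaptic cell is excitatory and 1.0 when inhibitory; autapses are
excluded (which also makes p = 1 well defined). Every cell receives an
independent homogeneous 9600 Hz Poisson background through a 0.1 nS
excitatory synapse. 3D positions are cosmetic, uniform in a
500×500×200 µm box. Connectivity is sampled once per realization and
stored explicitly, so serialized networks are independent of RNG
implementation details.

**Hybridization** replaces a chosen number of E cells with the cable
model: afferent synapses are reassigned to dendritic compartments
(uniformly at random, seeded; a soma-only placement rule is also
available), background input is delivered to the soma, and *all*
efferent connections of replaced cells are removed — including their
synapses onto other replaced cells, which is the consistent reading of
omitting their axons.

## Simulation engine

Clock-driven, default dt = 0.1 ms (0.025–0.05 ms required for HH
cells). Per step: (1) due delayed conductance increments are applied;
(2) background events are drawn per cell as Poisson counts with mean
rate·dt (exact for a homogeneous process, and windowed rate changes
simply modify the per-step mean, preserving the pre-window random
stream); (3) voltages advance — forward Euler for point neurons,
unconditionally stable backward Euler with a batched tree solve for
cables; (4) threshold crossings are timestamped at the end of the step,
reset/refractory bookkeeping runs, and outgoing spikes are queued into
a delay ring buffer; (5) conductances decay by their exact exponential
factors. Initial voltages are rest plus a seeded uniform jitter in
[0, 5] mV to break symmetry. Non-finite voltages abort with a
diagnostic naming the first offending cell and time.

**Voltage clamp** is an algebraic constraint, not a large series
conductance: the clamped compartment's row of the implicit system is
replaced by V = level, and the electrode current is computed as the
negative sum of membrane, synaptic, axial and injected currents at the
held potential. Consequently a synapse class whose reversal equals the
holding level contributes *exactly* zero — the property the −80/0 mV
readout relies on. Clamp records carry per-synapse-class components so
E and I currents can be read out separately. (Dendritic synapses still
reach the soma through axial current; as in real somatic clamp
experiments, space-clamp error is not corrected.)

All randomness derives from a single seed per run through
`numpy.random.SeedSequence`; the two internal streams (initial
conditions, background) are derived statelessly, so identical
(network, config, interventions, seed) give bit-identical spikes.

## The ISN experiments

**Windows.** The study's perturbation window is shown but not stated
numerically; the package defaults to 1 s baseline, 1 s perturbation,
0.5 s recovery (2.5 s per trial), with a 100 ms guard band after
perturbation onset excluded from window means (the baseline window is
trimmed to keep both means over equal durations).

**Calibration.** Because the exp-I&F parameter set is pinned by this
package rather than by the study, being in the ISN regime is treated as
the scientific precondition, established explicitly: a global
recurrent-weight scale (multiplying all four recurrent projections,
background untouched) is stepped through a fixed grid and the first
scale passing `check_isn_regime` is used. The regime check runs the
intact network and a copy with inhibitory weights zeroed; "unstable" is
operationalized as the E-population 100-ms windowed rate exceeding
100 Hz for at least 200 ms after a 200 ms transient. With the default
parameters the check selects a scale of 1.5 (intact E rate ≈ 5 Hz;
uninhibited runaway ≈ 150 Hz).

**Perturbations.** Rate-reduction mode subtracts 400 Hz from the
background of a seeded 90% subset of I cells inside the window
(9600 → 9200 Hz); the halorhodopsin-like mode injects a constant
negative current instead. The perturbed subset and the connectivity are
fixed per realization; trials differ only in input/initial-condition
seeds derived from the protocol's base seed. The paradox statistic is
the across-trial mean change in window-mean per-cell rate for the
perturbed-I, unperturbed-I and E subsets; the ISN signature is a
positive change for the perturbed inhibitory cells. The feedforward
control zeroes recurrent excitatory weights, under which the same
protocol must *decrease* the perturbed cells' rate.

**Clamp readout.** In the hybrid network, two cable cells' somata are
clamped at −80 mV and at 0 mV while the perturbation protocol runs,
over independent realizations (connectivity and input seeds both
redrawn). The sign check is that the mean absolute holding current in
the perturbation window exceeds the baseline window at both levels —
the burst of synaptic input during disinhibition.

## Analysis

Two per-cell-average rate estimators: Gaussian-kernel smoothing
(default σ = 30 ms — "width" is read as σ, not FWHM, and is
configurable) on a 1 ms grid, and piecewise-constant 100 ms windows.
Both conserve the spike count (∫rate·N dt = spikes), verified to 0.1%.
Connectivity summaries: the population adjacency entry is the signed
mean summed conductance from a presynaptic population onto an average
postsynaptic cell, ±(connections × weight)/N_post, with sign taken
from the synapse reversal relative to −55 mV; chord lists carry raw
connection counts; the graph spec applies floor values to node size and
edge width for legibility.

## Tuning stage

Features per sweep: spike times (upward crossings of −20 mV, one spike
per crossing), spike count, absolute peak height of spiking sweeps,
and the subthreshold steady state (mean V over the final 10% of the
pulse) of non-spiking sweeps. The feature distance is a weighted sum of
normalized discrepancies (scales: 1 spike, 10 ms, 5 mV, 2 mV; default
weights 1), with spike times paired first-to-first and count mismatch
penalized through the count term. The optimizer is a seeded elitist
evolutionary search (tournament selection, blend crossover, bounded
Gaussian mutation); candidates are simulated in vectorized batches
across (candidate × sweep). Any seeded global optimizer passing the
recovery test would do; correctness is defined by parameter recovery on
noiseless synthetic targets, not by matching a specific optimizer
trajectory. Reversal-potential bounds for tuning are package defaults
("physiologically plausible" ranges such as E_Na ∈ [40, 60] mV are the
user's choice), not values taken from the study.

## Synthetic recordings

The tuning target generator simulates a known HH cell under a step
protocol (default −100 to +300 pA in 50 pA steps, 1-s pulses in 1.3-s
sweeps) and adds white Gaussian voltage noise (default SD 0.5 mV, small
relative to spike height). It emulates the *feature content* of real
current-clamp sweeps — spike timing, height, subthreshold steady
states — not their full biophysics: no electrode artifacts, no
channel noise, no sag/rebound beyond what the model produces, and the
generating model lies inside the fitted model class. Passing recovery
tests therefore demonstrates that the pipeline is self-consistent and
identifiable on clean data, not that it would fit arbitrary real cells.

## Validation layer

Expected-properties YAML documents (resting potential, spike times,
spike count, total membrane area) plus per-observable tolerances;
scalars pass iff |measured − expected| ≤ tolerance, spike-time lists
iff counts match and the max absolute difference is within tolerance.
The schema is this package's own dialect; temperature consistency
reduces to a declared-constant check because the dynamics are
temperature-independent. Reports are pure functions of (outputs, spec),
and the CLI returns a nonzero exit code on failure for CI use.

## Problem sizes used in the test suite

The full study protocol (40 trials, 10 clamp realizations, a
morphologically detailed reconstruction) is scaled to what a single CPU
handles comfortably while preserving every qualitative contrast: 10
trials of 2.5 s for the paradox test, 5 for the halorhodopsin variant,
3 clamp realizations with the 21-compartment ball-and-stick, and a
single-free-parameter recovery fit (population 16, 8 generations).
Effect sizes here are far larger than trial-to-trial noise, so the sign
tests are stable at these counts.

## Known limitations

- The exp-I&F parameters and synaptic time constants are package
  defaults, not published values; quantitative rates are therefore not
  comparable to the original figures — only the qualitative ISN
  contrasts are.
- The hybrid cell is passive; dendritic nonlinearities and their effect
  on the paradox magnitude are out of scope.
- Forward Euler for point-neuron voltage is first-order; the
  dt-convergence test bounds the rate error at ~3% between 0.1 and
  0.05 ms.
- The clamp readout ignores series resistance and space-clamp error,
  as the idealized experiment does.
- No parallel execution; a 2.5 s trial of the 1000-cell network takes
  a few seconds of wall time.
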