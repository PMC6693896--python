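"""The inhibition-stabilized-network (ISN) experiments.

Four protocols are encoded:

* **rate-reduction perturbation** -- the background drive of a targeted
  fraction (default 90%) of the inhibitory cells is reduced by 400 Hz
  (9600 -> 9200 Hz) during a window, and window-mean rates are averaged
  over trials. In an ISN the perturbed inhibitory cells paradoxically
  *increase* their firing rate.
* **halorhodopsin-like perturbation** -- a constant hyperpolarizing
  current is injected into the targeted inhibitory cells instead,
  mimicking optogenetic silencing; in the ISN regime the excitatory
  rate increases (disinhibition).
* **ISN-regime check** -- the defining property is probed directly: the
  intact network must show stable moderate rates while a copy with all
  inhibitory weights removed must escape to saturation.
* **voltage-clamp readout** -- in the hybrid network the somata of two
  morphologically extended cells are clamped at -80 mV and 0 mV,
  isolating the excitatory and inhibitory synaptic currents; repeated
  over independent network realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ProtocolError
from .engine import (
    CurrentInjection,
    RateChange,
    SimulationConfig,
    SpikeData,
    VoltageClamp,
    run,
)
from .analysis import windowed_rate
from .network import NetworkModel, build_isn_pointnet

__all__ = [
    "PerturbationProtocol",
    "TrialResults",
    "RegimeReport",
    "run_perturbation",
    "run_halorhodopsin",
    "check_isn_regime",
    "calibrate_isn",
    "strip_inhibition",
    "strip_excitation",
    "run_clamp_readout",
]


@dataclass(frozen=True)
class PerturbationProtocol:
    """How, when and how strongly the inhibitory population is perturbed.

    ``mode`` selects between reducing the Poisson background rate of the
    targeted cells (``rate_reduction``, by ``delta_rate`` Hz, default
    -400) and injecting a constant hyperpolarizing current
    (``hyperpolarizing_current``, amplitude ``i_hyp`` pA < 0).
    """

    mode: str = "rate_reduction"     # | "hyperpolarizing_current"
    target: str = "I"
    fraction: float = 0.9
    delta_rate: float = -400.0       # Hz
    i_hyp: Optional[float] = None    # pA
    window: tuple = (1000.0, 2000.0)  # ms
    n_trials: int = 40
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("rate_reduction", "hyperpolarizing_current"):
            raise ProtocolError(f"unknown perturbation mode {self.mode!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ProtocolError("targeted fraction must lie in [0, 1]")
        if self.n_trials < 1:
            raise ProtocolError("n_trials must be >= 1")
        if self.window[1] <= self.window[0]:
            raise ProtocolError("perturbation window must have positive length")
        if self.mode == "hyperpolarizing_current":
            if self.i_hyp is None or self.i_hyp > 0:
                raise ProtocolError("hyperpolarizing mode requires i_hyp <= 0")


@dataclass
class TrialResults:
    """Per-trial spikes plus the cell-subset bookkeeping for analysis."""

    spike_data: list                 # SpikeData per trial
    perturbed_cells: np.ndarray      # global ids
    unperturbed_inh_cells: np.ndarray
    exc_cells: np.ndarray
    protocol: PerturbationProtocol
    trial_seeds: list
    bg_counts: list = field(default_factory=list)   # per trial: engine bg_counts


def _perturbed_set(net: NetworkModel, prot: PerturbationProtocol):
    lo, hi = net.pop_slices()[prot.target]
    n = hi - lo
    rng = np.random.default_rng(np.random.SeedSequence((prot.base_seed, 0xC0FFEE)))
    order = rng.permutation(n)
    k = int(round(prot.fraction * n))
    local = np.sort(order[:k])
    return local, local + lo


def _trial_seeds(prot: PerturbationProtocol):
    return np.random.SeedSequence(prot.base_seed).spawn(prot.n_trials)


def _run_trials(net, prot, sim, interventions) -> TrialResults:
    local, perturbed = _perturbed_set(net, prot)
    slices = net.pop_slices()
    lo_i, hi_i = slices[prot.target]
    lo_e, hi_e = slices["E"]
    unpert = np.setdiff1d(np.arange(lo_i, hi_i), perturbed)
    # exclude cable-substituted cells from the E rate subset: they are
    # passive stand-ins without spike output
    e_pop = net.population("E")
    exc = np.array([lo_e + i for i in range(e_pop.size) if i not in e_pop.detailed])

    seeds = _trial_seeds(prot)
    spikes, bgs = [], []
    for s in seeds:
        res = run(net, dc_replace(sim, seed=s), interventions(local))
        spikes.append(res.spikes)
        bgs.append(res.bg_counts)
    return TrialResults(spikes, perturbed, unpert, exc, prot, seeds, bgs)


def run_perturbation(
    net: NetworkModel,
    prot: PerturbationProtocol,
    sim: SimulationConfig,
) -> TrialResults:
    """Rate-reduction perturbation over ``prot.n_trials`` trials.

    The targeted inhibitory cells receive background at rate
    lambda + delta_rate inside the window and lambda outside; all other
    cells are untouched. Trials share the connectivity realization and
    the perturbed set; only input / initial-condition seeds differ.
    """
    if prot.mode != "rate_reduction":
        raise ProtocolError("run_perturbation requires mode='rate_reduction'")
    if prot.window[1] > sim.duration:
        raise ProtocolError("perturbation window outside the simulation")
    for bg in net.backgrounds:
        if bg.target == prot.target and bg.rate + prot.delta_rate < 0:
            raise ProtocolError("delta_rate would make the background rate negative")

    def interventions(local):
        return [RateChange(prot.target, local, prot.delta_rate, *prot.window)]

    return _run_trials(net, prot, sim, interventions)


def run_halorhodopsin(
    net: NetworkModel,
    prot: PerturbationProtocol,
    sim: SimulationConfig,
) -> TrialResults:
    """Halorhodopsin-like perturbation: constant hyperpolarizing current
    into the targeted cells during the window; background untouched."""
    if prot.mode != "hyperpolarizing_current":
        raise ProtocolError("run_halorhodopsin requires mode='hyperpolarizing_current'")
    if prot.window[1] > sim.duration:
        raise ProtocolError("perturbation window outside the simulation")

    def interventions(local):
        if prot.i_hyp == 0:
            return []
        return [CurrentInjection(prot.target, local, prot.i_hyp, *prot.window)]

    return _run_trials(net, prot, sim, interventions)


def strip_inhibition(net: NetworkModel) -> NetworkModel:
    """Copy of the network with every inhibitory projection weight zeroed."""
    projs = [
        dc_replace(p, weight=0.0) if net.population(p.pre).role == "I" else dc_replace(p)
        for p in net.projections
    ]
    return NetworkModel(net.populations, projs, net.backgrounds, net.seed,
                        {**net.meta, "stripped": "inhibition"})


def strip_excitation(net: NetworkModel) -> NetworkModel:
    """Copy with every recurrent excitatory projection weight zeroed
    (feedforward control: only background excitation remains)."""
    projs = [
        dc_replace(p, weight=0.0) if net.population(p.pre).role == "E" else dc_replace(p)
        for p in net.projections
    ]
    return NetworkModel(net.populations, projs, net.backgrounds, net.seed,
                        {**net.meta, "stripped": "excitation"})


@dataclass
class RegimeReport:
    stable_with_inhibition: bool
    unstable_without_inhibition: bool
    e_rate_intact: float          # Hz, mean post-transient E rate, intact
    e_rate_no_inh: float          # Hz, peak sustained E rate without inhibition

    @property
    def is_isn(self) -> bool:
        return self.stable_with_inhibition and self.unstable_without_inhibition


def check_isn_regime(
    net: NetworkModel,
    sim: SimulationConfig,
    saturation_rate: float = 100.0,
    sustain: float = 200.0,
    transient: float = 200.0,
) -> RegimeReport:
    """Probe the defining ISN property.

    Runs the intact network and a copy with all inhibitory weights set
    to zero. The network is inhibition stabilized if the intact E rate
    stays below ``saturation_rate`` (Hz) after the initial transient
    while the inhibition-free copy exceeds it for at least ``sustain``
    ms (runaway of the unstable excitatory subnetwork).
    """
    has_inh_proj = any(net.population(p.pre).role == "I" for p in net.projections)
    if not has_inh_proj:
        raise ProtocolError("network has no inhibitory projections to remove")
    slices = net.pop_slices()
    lo_e, hi_e = slices["E"]
    e_pop = net.population("E")
    e_cells = np.array([lo_e + i for i in range(e_pop.size) if i not in e_pop.detailed])

    def sustained_exceeds(spikes: SpikeData, bound: float) -> tuple:
        rs = windowed_rate(spikes, e_cells, window=100.0)
        rates = rs.rate[rs.times >= transient]
        need = max(1, int(round(sustain / 100.0)))
        exceeded, runs = False, 0
        for r in rates:
            runs = runs + 1 if r > bound else 0
            exceeded = exceeded or runs >= need
        return exceeded, rates

    res_intact = run(net, sim)
    exceeded_i, rates_i = sustained_exceeds(res_intact.spikes, saturation_rate)
    res_free = run(strip_inhibition(net), sim)
    exceeded_f, rates_f = sustained_exceeds(res_free.spikes, saturation_rate)

    return RegimeReport(
        stable_with_inhibition=not exceeded_i,
        unstable_without_inhibition=exceeded_f,
        e_rate_intact=float(rates_i.mean()) if len(rates_i) else 0.0,
        e_rate_no_inh=float(rates_f.max()) if len(rates_f) else 0.0,
    )


def calibrate_isn(
    build: Callable[..., NetworkModel] | None = None,
    seed: int = 0,
    scales: Sequence[float] = (1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0),
    sim: SimulationConfig | None = None,
    config: dict | None = None,
):
    """Find a global recurrent-weight scale that puts the network in the
    ISN regime.

    The candidate scales are tried in order on a short probe simulation;
    the first network for which :func:`check_isn_regime` reports both
    flags true is returned together with its report and the scale used.
    """
    if build is None:
        build = build_isn_pointnet
    if sim is None:
        sim = SimulationConfig(dt=0.1, duration=1000.0, seed=seed)
    base_cfg = dict(config or {})
    last_report = None
    for s in scales:
        cfg = {**base_cfg, "recurrent_scale": s}
        net = build(cfg, seed=seed)
        report = check_isn_regime(net, sim)
        last_report = (net, report, s)
        if report.is_isn:
            return net, report, s
    net, report, s = last_report
    raise ProtocolError(
        f"no candidate scale produced an ISN (last scale {s}: "
        f"stable={report.stable_with_inhibition}, "
        f"unstable_without={report.unstable_without_inhibition})"
    )


def run_clamp_readout(
    hybrid_builder: Callable[[int], NetworkModel],
    prot: PerturbationProtocol,
    sim: SimulationConfig,
    levels: Sequence[float] = (-80.0, 0.0),
    n_targets: int = 2,
    n_realizations: int = 10,
):
    """Voltage-clamp readout of synaptic input in the hybrid network.

    For each of ``n_realizations`` independent network realizations
    (``hybrid_builder(realization_seed)`` must return a hybrid network),
    the somata of ``n_targets`` cable cells are clamped at each level in
    ``levels`` while the perturbation protocol runs, and the holding
    currents are collected. Clamping at a synapse class's reversal
    nulls that class's contribution, so -80 mV (~E_inh) isolates the
    excitatory and 0 mV (=E_exc) the inhibitory synaptic currents.

    Returns {level: [list over realizations of ClampRecord lists]}.
    """
    out = {float(lv): [] for lv in levels}
    seeds = np.random.SeedSequence((prot.base_seed, 0x5EED)).spawn(n_realizations)
    for r, ss in enumerate(seeds):
        realization_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        net = hybrid_builder(realization_seed)
        e_pop = net.population("E")
        cable_locals = sorted(e_pop.detailed)
        if len(cable_locals) < n_targets:
            raise ProtocolError(
                f"hybrid network has {len(cable_locals)} cable cells, "
                f"need {n_targets} clamp targets"
            )
        targets = cable_locals[:n_targets]
        local, _ = _perturbed_set(net, prot)
        if prot.mode == "rate_reduction":
            ivs = [RateChange(prot.target, local, prot.delta_rate, *prot.window)]
        else:
            ivs = [CurrentInjection(prot.target, local, prot.i_hyp, *prot.window)]
        for lv in levels:
            clamps = [
                VoltageClamp("E", int(c), float(lv), compartment=0) for c in targets
            ]
            res = run(net, dc_replace(sim, seed=realization_seed), ivs + clamps)
            out[float(lv)].append(res.clamps)
    return out
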