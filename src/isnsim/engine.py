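"""Clock-driven network simulation.

The integrator advances all cells on a fixed grid of step ``dt``:
Poisson background events are drawn per cell and per step, presynaptic
spikes are delivered after their projection delay as conductance jumps,
conductances decay exponentially between events (exponential Euler,
exact for the single-exponential kinetics), point-neuron voltages use
forward Euler and cable compartments an unconditionally stable backward
Euler solve. Spikes are timestamped at the step where the membrane
first crosses the detection level. A somatic voltage clamp is realized
as an algebraic constraint — the clamped compartment is held exactly at
the holding level and the electrode current required to do so is
recorded — so a synapse class whose reversal equals the holding level
contributes exactly zero to the clamp current.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.SeedSequence``; identical (network, config,
interventions) produce bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidParameterError, NumericalInstabilityError, ProtocolError
from .model_core import (
    CableModel,
    ExpIFParams,
    HHPointParams,
    _EXP_CLIP,
    _na_rates,
    _kd_rates,
    _m_current_gate,
    _ca_rates,
    cable_axial_conductances,
    hh_steady_state_gates,
)
from .network import NetworkModel

__all__ = [
    "SimulationConfig",
    "RateChange",
    "CurrentInjection",
    "VoltageClamp",
    "SpikeData",
    "TraceData",
    "ClampRecord",
    "SimResult",
    "poisson_train",
    "run",
    "voltage_clamp",
]


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    dt: float = 0.1                      # ms
    duration: float = 1000.0             # ms
    seed: int | np.random.SeedSequence = 0
    record_spikes: bool = True
    record_traces: Sequence = ()         # (pop, local_idx[, compartment]) tuples
    record_background_windows: Sequence = ()  # (t0, t1) ms
    init_jitter: float = 5.0             # mV, uniform jitter above rest

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise InvalidParameterError("dt and duration must be positive")


@dataclass(frozen=True)
class RateChange:
    """Add ``delta`` Hz to the background rate of selected cells in a window."""

    population: str
    cells: Optional[np.ndarray]          # local indices; None = whole population
    delta: float                         # Hz
    t_start: float
    t_stop: float


@dataclass(frozen=True)
class CurrentInjection:
    """Inject a constant current into selected cells in a window."""

    population: str
    cells: Optional[np.ndarray]
    amplitude: float                     # pA
    t_start: float
    t_stop: float


@dataclass(frozen=True)
class VoltageClamp:
    """Hold one compartment of one cell at a fixed potential."""

    population: str
    cell: int
    level: float                         # mV
    compartment: int = 0
    t_start: float = 0.0
    t_stop: Optional[float] = None       # None = whole simulation


@dataclass
class SpikeData:
    """Time-sorted spikes as parallel (time, global cell id) arrays."""

    times: np.ndarray                    # ms
    ids: np.ndarray                      # global cell indices
    duration: float
    pop_slices: dict

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=int)

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def for_cells(self, cells) -> "SpikeData":
        mask = np.isin(self.ids, np.asarray(cells, dtype=int))
        return SpikeData(self.times[mask], self.ids[mask], self.duration, self.pop_slices)

    def for_population(self, name: str) -> "SpikeData":
        lo, hi = self.pop_slices[name]
        mask = (self.ids >= lo) & (self.ids < hi)
        return SpikeData(self.times[mask], self.ids[mask], self.duration, self.pop_slices)

    def counts_per_cell(self, n_cells: int) -> np.ndarray:
        return np.bincount(self.ids, minlength=n_cells)


@dataclass
class TraceData:
    """Uniformly sampled recordings of one variable for several targets."""

    name: str
    unit: str
    times: np.ndarray                    # ms
    values: np.ndarray                   # (n_samples, n_targets)
    targets: list                        # (pop, local_idx, compartment) labels

    def column(self, target) -> np.ndarray:
        return self.values[:, self.targets.index(tuple(target))]


@dataclass
class ClampRecord:
    """Holding current of one voltage-clamped compartment.

    ``components`` maps each synapse class (E_syn, tau_syn) to the
    synaptic part g_class * (E_class - level) of the clamp current, so
    currents carried by E and I synapses can be read out separately.
    """

    target: tuple                        # (pop, local_idx, compartment)
    level: float                         # mV
    times: np.ndarray
    current: np.ndarray                  # pA, electrode current
    components: dict


@dataclass
class SimResult:
    spikes: SpikeData
    traces: Optional[TraceData]
    clamps: list
    bg_counts: list                      # [(window, per-cell event counts)]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Poisson input generator
# ---------------------------------------------------------------------------

def poisson_train(rate: float, t_start: float, t_stop: float, seed=0) -> np.ndarray:
    """Spike times of a homogeneous Poisson process on (t_start, t_stop].

    Times are in ms, ``rate`` in Hz. Deterministic given seed.
    """
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    if t_stop <= t_start:
        raise InvalidParameterError("t_stop must exceed t_start")
    if rate == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    rate_per_ms = rate * 1e-3
    span = t_stop - t_start
    out = []
    t = t_start
    block = max(16, int(1.2 * rate_per_ms * span) + 4 * int(np.sqrt(rate_per_ms * span) + 1))
    while t <= t_stop:
        isis = rng.exponential(1.0 / rate_per_ms, size=block)
        times = t + np.cumsum(isis)
        out.append(times)
        t = times[-1]
    times = np.concatenate(out)
    return times[times <= t_stop]


# ---------------------------------------------------------------------------
# the integrator
# ---------------------------------------------------------------------------

class _Compiled:
    """Flattened network arrays, built once per run."""

    def __init__(self, net: NetworkModel, dt: float):
        self.net = net
        self.slices = net.pop_slices()
        self.N = net.n_cells

        # channels: unique (E_syn, tau_syn) classes
        keys = []
        for proj in net.projections:
            keys.append((round(proj.e_syn, 9), round(proj.tau_syn, 9)))
        for bg in net.backgrounds:
            keys.append((round(bg.e_syn, 9), round(bg.tau_syn, 9)))
        self.channels = sorted(set(keys))
        self.ch_index = {k: i for i, k in enumerate(self.channels)}
        self.n_ch = len(self.channels)
        self.ch_e = np.array([k[0] for k in self.channels])
        self.ch_decay = np.exp(-dt / np.array([k[1] for k in self.channels]))

        # per-cell model membership and parameters
        self.model_of = np.zeros(self.N, dtype=np.int8)  # 0 expif, 1 hh, 2 cable
        self.cable_cells = []                            # (global id, CableModel)
        expif_fields = ("C", "g_L", "E_L", "V_T", "Delta_T", "V_cut", "V_reset", "t_ref")
        self.expif = {f: np.full(self.N, np.nan) for f in expif_fields}
        self.hh_params = {}
        for pop in net.populations:
            lo, hi = self.slices[pop.name]
            if pop.model == "expif":
                p: ExpIFParams = pop.params
                for f in expif_fields:
                    self.expif[f][lo:hi] = getattr(p, f)
            elif pop.model == "hh":
                self.model_of[lo:hi] = 1
                self.hh_params[pop.name] = pop.params
            elif pop.model == "cable":
                self.model_of[lo:hi] = 2
                for i in range(pop.size):
                    self.cable_cells.append((lo + i, pop.params))
            for local, cab in pop.detailed.items():
                gid = lo + local
                self.model_of[gid] = 2
                self.cable_cells.append((gid, cab))
        self.cable_cells.sort()
        self.cable_slot = np.full(self.N, -1, dtype=int)
        for s, (gid, _) in enumerate(self.cable_cells):
            self.cable_slot[gid] = s
        self.expif_idx = np.nonzero(self.model_of == 0)[0]
        self.hh_idx = np.nonzero(self.model_of == 1)[0]

        # connection CSR sorted by presynaptic global id
        pre_l, post_l, ch_l, dly_l, w_l, comp_l = [], [], [], [], [], []
        self.max_delay_steps = 1
        for proj in net.projections:
            if not len(proj.connections):
                continue
            plo, _ = self.slices[proj.pre]
            qlo, _ = self.slices[proj.post]
            pre_l.append(proj.connections[:, 0] + plo)
            post_l.append(proj.connections[:, 1] + qlo)
            ch = self.ch_index[(round(proj.e_syn, 9), round(proj.tau_syn, 9))]
            n = len(proj.connections)
            ch_l.append(np.full(n, ch, dtype=np.int16))
            d = max(1, int(round(proj.delay / dt)))
            self.max_delay_steps = max(self.max_delay_steps, d)
            dly_l.append(np.full(n, d, dtype=np.int32))
            w_l.append(np.full(n, proj.weight))
            if proj.post_compartments is not None:
                comp_l.append(proj.post_compartments)
            else:
                comp_l.append(np.full(n, -1, dtype=int))
        if pre_l:
            pre = np.concatenate(pre_l)
            order = np.argsort(pre, kind="stable")
            self.conn_pre = pre[order]
            self.conn_post = np.concatenate(post_l)[order]
            self.conn_ch = np.concatenate(ch_l)[order]
            self.conn_delay = np.concatenate(dly_l)[order]
            self.conn_w = np.concatenate(w_l)[order]
            self.conn_comp = np.concatenate(comp_l)[order]
            self.indptr = np.searchsorted(self.conn_pre, np.arange(self.N + 1))
        else:
            self.conn_pre = np.empty(0, dtype=int)
            self.indptr = np.zeros(self.N + 1, dtype=int)


def run(net: NetworkModel, sim: SimulationConfig, interventions: Sequence = ()) -> SimResult:
    """Simulate a network under an optional list of interventions.

    Interventions are RateChange / CurrentInjection / VoltageClamp
    instances; their windows must lie inside [0, duration].
    """
    dt = sim.dt
    n_steps = int(round(sim.duration / dt))
    comp = _Compiled(net, dt)
    N = comp.N

    for iv in interventions:
        t0 = getattr(iv, "t_start", 0.0)
        t1 = getattr(iv, "t_stop", None)
        if t0 < 0 or (t1 is not None and t1 > sim.duration + 1e-9):
            raise ProtocolError("intervention window outside the simulation")
        if iv.population not in comp.slices:
            raise ProtocolError(f"intervention targets unknown population {iv.population!r}")

    if len(comp.hh_idx) and dt > 0.05:
        raise InvalidParameterError("networks with HH point cells require dt <= 0.05 ms")

    ss = sim.seed if isinstance(sim.seed, np.random.SeedSequence) else np.random.SeedSequence(sim.seed)
    # derive the two internal streams statelessly (generate_state is pure,
    # unlike spawn), so reusing one SeedSequence object reproduces the run
    s_init, s_bg = (int(x) for x in ss.generate_state(2, dtype=np.uint64))
    rng_init = np.random.default_rng(np.random.SeedSequence([s_init, 0x11]))
    rng_bg = np.random.default_rng(np.random.SeedSequence([s_bg, 0x22]))

    # --- state -------------------------------------------------------------
    V = np.full(N, np.nan)
    e0 = np.where(np.isnan(comp.expif["E_L"]), -70.0, comp.expif["E_L"])
    V[:] = e0 + sim.init_jitter * rng_init.random(N)
    refr = np.zeros(N, dtype=np.int32)
    t_ref_steps = np.zeros(N, dtype=np.int32)
    if len(comp.expif_idx):
        t_ref_steps[comp.expif_idx] = np.maximum(
            1, np.round(comp.expif["t_ref"][comp.expif_idx] / dt).astype(np.int32)
        )

    hh_gates = {}
    for pop in net.populations:
        if pop.model != "hh":
            continue
        lo, hi = comp.slices[pop.name]
        idx = np.nonzero(comp.model_of[lo:hi] == 1)[0] + lo
        V[idx] = pop.params.E_leak + sim.init_jitter * rng_init.random(len(idx))
        gates = hh_steady_state_gates(V[idx], pop.params)
        hh_gates[pop.name] = (idx, [np.asarray(g, dtype=float).copy() for g in gates])
    hh_in_spike = np.zeros(N, dtype=bool)

    g_point = np.zeros((comp.n_ch, N))
    D = comp.max_delay_steps
    ring = np.zeros((D + 1, comp.n_ch, N))

    # cable state (shared-geometry batch)
    n_cab = len(comp.cable_cells)
    cab_models = [m for (_, m) in comp.cable_cells]
    if n_cab:
        n_comp_c = cab_models[0].n_comp
        if any(m is not cab_models[0] for m in cab_models):
            if any(m.n_comp != n_comp_c for m in cab_models):
                raise InvalidParameterError("cable cells must share one morphology per run")
        cab = cab_models[0]
        cab_V = np.full((n_cab, cab.n_comp), cab.e_pas)
        g_cable = np.zeros((n_cab, comp.n_ch, cab.n_comp))
        ring_cab = np.zeros((D + 1, n_cab, comp.n_ch, cab.n_comp))
        cab_C = cab.capacitance_pF()
        cab_gl = cab.g_leak_nS()
        g_ax = cable_axial_conductances(cab)
        A0 = np.diag(cab_C / dt + cab_gl)
        for i in range(1, cab.n_comp):
            j = cab.parent[i]
            A0[i, i] += g_ax[i]
            A0[j, j] += g_ax[i]
            A0[i, j] -= g_ax[i]
            A0[j, i] -= g_ax[i]
        diag = np.arange(cab.n_comp)
        cable_gids = np.array([g for (g, _) in comp.cable_cells])
        V[cable_gids] = cab.e_pas

    # --- interventions, flattened ------------------------------------------
    def _global_cells(iv):
        lo, hi = comp.slices[iv.population]
        if iv.cells is None:
            return np.arange(lo, hi)
        return np.asarray(iv.cells, dtype=int) + lo

    rate_ivs, curr_ivs, clamp_ivs = [], [], []
    for iv in interventions:
        if isinstance(iv, RateChange):
            rate_ivs.append((_global_cells(iv), iv.delta, iv.t_start, iv.t_stop))
        elif isinstance(iv, CurrentInjection):
            curr_ivs.append((_global_cells(iv), iv.amplitude, iv.t_start, iv.t_stop))
        elif isinstance(iv, VoltageClamp):
            lo, _ = comp.slices[iv.population]
            gid = lo + iv.cell
            t1 = sim.duration if iv.t_stop is None else iv.t_stop
            clamp_ivs.append((gid, iv.level, iv.compartment, iv.t_start, t1))
        else:
            raise ProtocolError(f"unknown intervention type {type(iv).__name__}")

    # background rate per cell and per step (base; deltas applied per window)
    bg_specs = []
    for bg in net.backgrounds:
        lo, hi = comp.slices[bg.target]
        ch = comp.ch_index[(round(bg.e_syn, 9), round(bg.tau_syn, 9))]
        base_lam = np.full(hi - lo, bg.rate * dt * 1e-3)
        for cells, delta, *_ in rate_ivs:
            sel = cells[(cells >= lo) & (cells < hi)] - lo
            if len(sel) and bg.rate + delta < 0:
                raise ProtocolError("rate change would make the background rate negative")
        bg_specs.append((lo, hi, ch, bg.weight, base_lam, bg.rate))

    windows = [(float(a), float(b)) for (a, b) in sim.record_background_windows]
    bg_counts = [np.zeros(N) for _ in windows]

    # trace recording targets
    targets = []
    for t in sim.record_traces:
        pop, local = t[0], t[1]
        c = t[2] if len(t) > 2 else 0
        targets.append((pop, int(local), int(c)))
    trace_vals = np.zeros((n_steps + 1, len(targets))) if targets else None
    trace_gid = [comp.slices[p][0] + i for (p, i, _) in targets]

    clamp_records = []
    for gid, level, k_comp, t0, t1 in clamp_ivs:
        if comp.model_of[gid] == 2:
            if comp.cable_slot[gid] < 0:
                raise ProtocolError("clamp target is not a simulated cable cell")
            if not (0 <= k_comp < cab_models[comp.cable_slot[gid]].n_comp):
                raise ProtocolError("clamp compartment does not exist on target cell")
        elif k_comp != 0:
            raise ProtocolError("point cells have a single compartment (index 0)")
        clamp_records.append({
            "gid": gid, "level": level, "comp": k_comp, "t0": t0, "t1": t1,
            "current": np.zeros(n_steps + 1),
            "components": {key: np.zeros(n_steps + 1) for key in comp.channels},
        })

    spike_t, spike_id = [], []
    exi = comp.expif_idx
    eC = comp.expif["C"][exi]
    egL = comp.expif["g_L"][exi]
    eEL = comp.expif["E_L"][exi]
    eVT = comp.expif["V_T"][exi]
    eDT = comp.expif["Delta_T"][exi]
    eVcut = comp.expif["V_cut"][exi]
    eVreset = comp.expif["V_reset"][exi]
    has_exp = np.any(eDT > 0)
    ch_e = comp.ch_e

    I_inj = np.zeros(N)

    def record_traces(k):
        if trace_vals is None:
            return
        for col, ((pop, local, c), gid) in enumerate(zip(targets, trace_gid)):
            if comp.model_of[gid] == 2 and n_cab:
                trace_vals[k, col] = cab_V[comp.cable_slot[gid], c]
            else:
                trace_vals[k, col] = V[gid]

    record_traces(0)

    for k in range(n_steps):
        t = k * dt
        slot = k % (D + 1)

        # deliver due conductance jumps
        g_point += ring[slot]
        ring[slot] = 0.0
        if n_cab:
            g_cable += ring_cab[slot]
            ring_cab[slot] = 0.0

        # background events
        for (lo, hi, ch, w, base_lam, base_rate) in bg_specs:
            lam = base_lam
            for cells, delta, t0, t1 in rate_ivs:
                if t0 <= t < t1:
                    sel = cells[(cells >= lo) & (cells < hi)]
                    if len(sel):
                        if lam is base_lam:
                            lam = base_lam.copy()
                        lam[sel - lo] = np.maximum(lam[sel - lo] + delta * dt * 1e-3, 0.0)
            counts = rng_bg.poisson(lam)
            if counts.any():
                g_point[ch, lo:hi] += counts * w
                for wi, (t0, t1) in enumerate(windows):
                    if t0 <= t < t1:
                        bg_counts[wi][lo:hi] += counts
                if n_cab:
                    # background onto cable cells acts at the soma
                    gids = np.nonzero(comp.model_of[lo:hi] == 2)[0]
                    for g_loc in gids:
                        gid = lo + g_loc
                        g_cable[comp.cable_slot[gid], ch, 0] += counts[g_loc] * w
                        g_point[ch, gid] = 0.0

        # injected currents
        I_inj[:] = 0.0
        for cells, amp, t0, t1 in curr_ivs:
            if t0 <= t < t1:
                I_inj[cells] += amp

        active_clamps = [c for c in clamp_records if c["t0"] <= t < c["t1"]]
        # point-cell clamps: pin the voltage and suppress integration/spiking
        # for this step before the membrane update runs
        clamped_point = set()
        for c in active_clamps:
            gid = c["gid"]
            if comp.model_of[gid] != 2:
                V[gid] = c["level"]
                refr[gid] = max(refr[gid], 2)
                clamped_point.add(gid)

        # ---- exp-I&F update ----
        if len(exi):
            v = V[exi]
            gsl = g_point[:, exi]
            I_syn = np.einsum("c,cn->n", ch_e, gsl) - gsl.sum(axis=0) * v
            I = egL * (eEL - v) + I_syn + I_inj[exi]
            if has_exp:
                with np.errstate(over="ignore"):
                    arg = np.minimum((v - eVT) / np.where(eDT > 0, eDT, 1.0), _EXP_CLIP)
                    I = I + np.where(eDT > 0, egL * eDT * np.exp(arg), 0.0)
            active = refr[exi] <= 0
            v_new = np.where(active, v + dt * I / eC, v)
            if not np.all(np.isfinite(v_new)):
                bad = int(exi[np.nonzero(~np.isfinite(v_new))[0][0]])
                raise NumericalInstabilityError(
                    f"non-finite membrane potential for cell {bad} at t={t:.3f} ms"
                )
            spk = np.nonzero(active & (v_new >= eVcut))[0]
            if len(spk):
                v_new[spk] = eVreset[spk]
                gids = exi[spk]
                refr[gids] = t_ref_steps[gids]
                if sim.record_spikes:
                    ts = t + dt
                    for gid in gids:
                        spike_t.append(ts)
                        spike_id.append(int(gid))
                _deliver(comp, gids, k, ring, ring_cab if n_cab else None, D)
            V[exi] = v_new
            refr[exi] = np.maximum(refr[exi] - 1, 0)

        # ---- HH point update ----
        for pop_name, (idx, gates) in hh_gates.items():
            p: HHPointParams = comp.hh_params[pop_name]
            v = V[idx]
            m, h, nn, pg, q = gates
            a_m, b_m, a_h, b_h = _na_rates(v, p.V_shift)
            a_n, b_n = _kd_rates(v)
            p_inf, tau_p = _m_current_gate(v, p.tau_max_M)
            a_q, b_q = _ca_rates(v)
            for g_arr, a, b in ((m, a_m, b_m), (h, a_h, b_h), (nn, a_n, b_n), (q, a_q, b_q)):
                tau = 1.0 / (a + b)
                x_inf = a * tau
                g_arr[:] = x_inf + (g_arr - x_inf) * np.exp(-dt / tau)
            pg[:] = p_inf + (pg - p_inf) * np.exp(-dt / tau_p)
            gsl = g_point[:, idx]
            I_syn = np.einsum("c,cn->n", ch_e, gsl) - gsl.sum(axis=0) * v
            I_ion = (
                p.gbar_Na * m ** 3 * h * (p.E_Na - v)
                + p.gbar_Kd * nn ** 4 * (p.E_K - v)
                + p.gbar_M * pg * (p.E_K - v)
                + p.gbar_CaL * q ** 2 * (p.E_Ca - v)
                + p.gbar_leak * (p.E_leak - v)
            )
            v_new = v + dt * (I_ion + I_syn + I_inj[idx]) / p.C
            if not np.all(np.isfinite(v_new)):
                bad = int(idx[np.nonzero(~np.isfinite(v_new))[0][0]])
                raise NumericalInstabilityError(
                    f"non-finite membrane potential for cell {bad} at t={t:.3f} ms"
                )
            crossed = (v_new >= 0.0) & ~hh_in_spike[idx]
            if clamped_point:
                crossed &= ~np.isin(idx, list(clamped_point))
            if crossed.any():
                gids = idx[np.nonzero(crossed)[0]]
                hh_in_spike[gids] = True
                if sim.record_spikes:
                    ts = t + dt
                    for gid in gids:
                        spike_t.append(ts)
                        spike_id.append(int(gid))
                _deliver(comp, gids, k, ring, ring_cab if n_cab else None, D)
            hh_in_spike[idx] &= ~(v_new < -20.0)
            V[idx] = v_new

        # ---- point-cell clamp currents ----
        for c in active_clamps:
            gid = c["gid"]
            if comp.model_of[gid] == 2:
                continue
            level = c["level"]
            V[gid] = level
            I_mem = 0.0
            if comp.model_of[gid] == 0:
                gl = comp.expif["g_L"][gid]
                el = comp.expif["E_L"][gid]
                dT = comp.expif["Delta_T"][gid]
                vT = comp.expif["V_T"][gid]
                I_mem = gl * (el - level)
                if dT > 0:
                    I_mem += gl * dT * np.exp(min((level - vT) / dT, _EXP_CLIP))
            I_syn_tot = 0.0
            for ci, key in enumerate(comp.channels):
                part = g_point[ci, gid] * (key[0] - level)
                c["components"][key][k + 1] = part
                I_syn_tot += part
            c["current"][k + 1] = -(I_mem + I_syn_tot + I_inj[gid])

        # ---- cable update (batched backward Euler) ----
        if n_cab:
            cab_clamps = {comp.cable_slot[c["gid"]]: c for c in active_clamps
                          if comp.model_of[c["gid"]] == 2}
            g_tot = g_cable.sum(axis=1)                       # (n_cab, n_comp)
            drive = np.einsum("scp,c->sp", g_cable, ch_e)     # sum g*E
            A = np.broadcast_to(A0, (n_cab, cab.n_comp, cab.n_comp)).copy()
            A[:, diag, diag] += g_tot
            b = cab_C / dt * cab_V + cab_gl * cab.e_pas + drive + I_inj[cable_gids][:, None] \
                * (np.arange(cab.n_comp) == 0)
            for s, c in cab_clamps.items():
                kcmp = c["comp"]
                A[s, kcmp, :] = 0.0
                A[s, kcmp, kcmp] = 1.0
                b[s, kcmp] = c["level"]
            cab_V_new = np.linalg.solve(A, b[..., None])[..., 0]
            for s, c in cab_clamps.items():
                kcmp = c["comp"]
                level = c["level"]
                I_mem = cab_gl[kcmp] * (cab.e_pas - level)
                I_syn_tot = 0.0
                for ci, key in enumerate(comp.channels):
                    part = g_cable[s, ci, kcmp] * (key[0] - level)
                    c["components"][key][k + 1] = part
                    I_syn_tot += part
                I_ax = 0.0
                for i in range(1, cab.n_comp):
                    if i == kcmp:
                        I_ax += g_ax[i] * (cab_V_new[s, cab.parent[i]] - level)
                    elif cab.parent[i] == kcmp:
                        I_ax += g_ax[i] * (cab_V_new[s, i] - level)
                inj = I_inj[cable_gids[s]] if kcmp == 0 else 0.0
                c["current"][k + 1] = -(I_mem + I_syn_tot + I_ax + inj)
            cab_V = cab_V_new
            V[cable_gids] = cab_V[:, 0]

        # decay all conductances
        g_point *= comp.ch_decay[:, None]
        if n_cab:
            g_cable *= comp.ch_decay[None, :, None]

        record_traces(k + 1)

    times = np.arange(n_steps + 1) * dt
    order = np.argsort(spike_t, kind="stable") if spike_t else []
    spikes = SpikeData(
        np.asarray(spike_t)[order] if len(spike_t) else np.empty(0),
        np.asarray(spike_id, dtype=int)[order] if len(spike_id) else np.empty(0, dtype=int),
        sim.duration,
        comp.slices,
    )
    trace = None
    if trace_vals is not None:
        trace = TraceData("V", "mV", times, trace_vals, targets)
    clamps = [
        ClampRecord(
            target=(_pop_of(comp, c["gid"]), _local_of(comp, c["gid"]), c["comp"]),
            level=c["level"],
            times=times,
            current=c["current"],
            components=c["components"],
        )
        for c in clamp_records
    ]
    return SimResult(spikes, trace, clamps, list(zip(windows, bg_counts)), sim)


def _deliver(comp: _Compiled, gids, k, ring, ring_cab, D):
    """Queue the conductance jumps caused by spikes of cells ``gids``."""
    for gid in gids:
        a, b = comp.indptr[gid], comp.indptr[gid + 1]
        if a == b:
            continue
        post = comp.conn_post[a:b]
        ch = comp.conn_ch[a:b]
        dly = comp.conn_delay[a:b]
        w = comp.conn_w[a:b]
        cmp_ = comp.conn_comp[a:b]
        slots = (k + dly) % (D + 1)
        pt = cmp_ < 0
        if pt.any():
            np.add.at(ring, (slots[pt], ch[pt], post[pt]), w[pt])
        if (~pt).any() and ring_cab is not None:
            cb = ~pt
            np.add.at(
                ring_cab,
                (slots[cb], comp.cable_slot[post[cb]], ch[cb], cmp_[cb]),
                w[cb],
            )


def _pop_of(comp: _Compiled, gid: int) -> str:
    for name, (lo, hi) in comp.slices.items():
        if lo <= gid < hi:
            return name
    raise KeyError(gid)


def _local_of(comp: _Compiled, gid: int) -> int:
    return gid - comp.slices[_pop_of(comp, gid)][0]


def voltage_clamp(net: NetworkModel, sim: SimulationConfig, targets, level: float):
    """Run the network with the listed (pop, cell[, compartment]) targets
    voltage clamped at ``level`` mV for the whole simulation; returns the
    list of ClampRecord holding-current traces."""
    ivs = []
    for tgt in targets:
        pop, cell = tgt[0], tgt[1]
        cmp_ = tgt[2] if len(tgt) > 2 else 0
        ivs.append(VoltageClamp(pop, int(cell), float(level), compartment=int(cmp_)))
    res = run(net, sim, ivs)
    return res.clamps
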