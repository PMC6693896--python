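"""Synthetic inputs for every stage of the pipeline.

Nothing in the package requires a download: this module generates

* surrogate current-clamp recordings (1-s step currents, additive
  Gaussian voltage noise) from a known HH point cell, standing in for
  real electrophysiology sweeps as the target of the tuning stage,
* simple ball-and-stick morphologies standing in for the
  morphologically detailed layer-2/3 cell of the hybrid network,
* small fully specified toy networks for connectivity-summary tests.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, ProtocolError, SchemaError
from .model_core import (
    CableModel,
    ExpIFParams,
    HHPointParams,
    _ca_rates,
    _kd_rates,
    _m_current_gate,
    _na_rates,
    hh_steady_state_gates,
)
from .network import BackgroundInput, NetworkModel, Population, Projection

__all__ = [
    "StimulusProtocol",
    "SyntheticRecording",
    "simulate_hh_sweeps",
    "make_target_recording",
    "make_ball_and_stick",
    "make_toy_network",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """A family of step-current sweeps.

    Each sweep injects ``amplitude`` pA from ``onset`` for ``duration``
    ms into a sweep of ``total`` ms. The default grid spans -100 to
    +300 pA in 50 pA steps with 1-s pulses.
    """

    amplitudes: tuple = tuple(float(a) for a in range(-100, 301, 50))
    onset: float = 100.0      # ms
    duration: float = 1000.0  # ms
    total: float = 1300.0     # ms

    def __post_init__(self) -> None:
        if self.onset + self.duration > self.total:
            raise InvalidParameterError("stimulus must end within the sweep")
        if not len(self.amplitudes):
            raise InvalidParameterError("protocol must contain at least one sweep")
        if not np.all(np.isfinite(self.amplitudes)):
            raise InvalidParameterError("amplitudes must be finite")

    @property
    def n_sweeps(self) -> int:
        return len(self.amplitudes)


def simulate_hh_sweeps(
    params: HHPointParams | Sequence[HHPointParams],
    protocol: StimulusProtocol,
    dt: float = 0.05,
) -> tuple:
    """Voltage responses of HH point cells to the step-current protocol.

    ``params`` may be one parameter set or a sequence (a candidate
    population); all (parameter set, sweep) combinations are integrated
    in one vectorized batch. Returns (times, V) with V of shape
    (n_params, n_sweeps, n_samples); a single parameter set yields
    (n_sweeps, n_samples).
    """
    single = isinstance(params, HHPointParams)
    plist = [params] if single else list(params)
    n_p, n_s = len(plist), protocol.n_sweeps
    B = n_p * n_s
    n_steps = int(round(protocol.total / dt))

    def col(name):
        return np.repeat([getattr(p, name) for p in plist], n_s)

    C = col("C")
    gna, gkd, gm, gca, gl = (col(n) for n in
                             ("gbar_Na", "gbar_Kd", "gbar_M", "gbar_CaL", "gbar_leak"))
    ena, ek, eca, eleak = (col(n) for n in ("E_Na", "E_K", "E_Ca", "E_leak"))
    vshift = col("V_shift")
    tau_max = col("tau_max_M")
    amps = np.tile(np.asarray(protocol.amplitudes, dtype=float), n_p)

    V = eleak.copy()
    # start every gate at its steady state for the resting potential
    m = np.empty(B); h = np.empty(B); n_g = np.empty(B); pg = np.empty(B); q = np.empty(B)
    for i in range(B):
        p_i = plist[i // n_s]
        g0 = hh_steady_state_gates(p_i.E_leak, p_i)
        m[i], h[i], n_g[i], pg[i], q[i] = (float(x) for x in g0)

    out = np.empty((B, n_steps + 1))
    out[:, 0] = V
    k_on = int(round(protocol.onset / dt))
    k_off = int(round((protocol.onset + protocol.duration) / dt))

    for k in range(n_steps):
        a_m, b_m, a_h, b_h = _na_rates(V, vshift)
        a_n, b_n = _kd_rates(V)
        p_inf, tau_p = _m_current_gate(V, tau_max)
        a_q, b_q = _ca_rates(V)
        for g_arr, a, b in ((m, a_m, b_m), (h, a_h, b_h), (n_g, a_n, b_n), (q, a_q, b_q)):
            tau = 1.0 / (a + b)
            x_inf = a * tau
            g_arr[:] = x_inf + (g_arr - x_inf) * np.exp(-dt / tau)
        pg[:] = p_inf + (pg - p_inf) * np.exp(-dt / tau_p)
        I = (gna * m ** 3 * h * (ena - V)
             + gkd * n_g ** 4 * (ek - V)
             + gm * pg * (ek - V)
             + gca * q ** 2 * (eca - V)
             + gl * (eleak - V))
        if k_on <= k < k_off:
            I = I + amps
        V = V + dt * I / C
        out[:, k + 1] = V

    if not np.all(np.isfinite(out)):
        raise InvalidParameterError("HH sweep simulation produced non-finite voltages")
    times = np.arange(n_steps + 1) * dt
    traces = out.reshape(n_p, n_s, n_steps + 1)
    return times, (traces[0] if single else traces)


@dataclass
class SyntheticRecording:
    """Surrogate current-clamp recording with known ground truth.

    ``traces`` are the (possibly noisy) sweeps, ``features`` the feature
    set extracted from the *noiseless* traces during generation (the
    generator-side bookkeeping that recovery tests compare against).
    """

    protocol: StimulusProtocol
    times: np.ndarray              # ms
    traces: np.ndarray             # (n_sweeps, n_samples) mV
    true_params: HHPointParams
    noise_sd: float
    seed: int
    features: object = None

    def sweep(self, amplitude: float) -> np.ndarray:
        i = list(self.protocol.amplitudes).index(amplitude)
        return self.traces[i]


def make_target_recording(
    true_params: HHPointParams,
    protocol: StimulusProtocol | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    dt: float = 0.05,
) -> SyntheticRecording:
    """Generate a surrogate recording from a known HH parameter set.

    Additive white Gaussian noise of SD ``noise_sd`` mV is applied to
    the voltage traces; with ``noise_sd=0`` the output is exactly the
    deterministic model response. A parameter set that spikes at rest
    (spikes during a zero-amplitude sweep) is rejected as an unsuitable
    tuning target.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    protocol = protocol or StimulusProtocol()
    times, clean = simulate_hh_sweeps(true_params, protocol, dt=dt)

    from .tuning import extract_features  # local import avoids a module cycle

    # reject cells that fire without stimulation
    zero_prot = StimulusProtocol((0.0,), protocol.onset, protocol.duration, protocol.total)
    _, rest = simulate_hh_sweeps(true_params, zero_prot, dt=dt)
    rest_features = extract_features(times, rest, zero_prot)
    if rest_features.spike_counts[0] > 0:
        raise ProtocolError("parameter set spikes at rest; unsuitable tuning target")

    features = extract_features(times, clean, protocol)
    rng = np.random.default_rng(seed)
    noisy = clean + (rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else 0.0)
    return SyntheticRecording(protocol, times, noisy, true_params, noise_sd, seed, features)


def make_ball_and_stick(
    soma_diam: float = 20.0,
    dend_len: float = 500.0,
    dend_diam: float = 2.0,
    n_comp: int = 20,
    **cable_kw,
) -> CableModel:
    """Spherical soma plus an ``n_comp``-compartment dendritic cylinder.

    Total membrane area is pi*soma_diam^2 + pi*dend_diam*dend_len by
    construction (sphere plus cylinder lateral area).
    """
    if soma_diam <= 0 or dend_len <= 0 or dend_diam <= 0:
        raise InvalidParameterError("geometry must be positive")
    if n_comp < 1:
        raise InvalidParameterError("n_comp must be >= 1")
    seg = dend_len / n_comp
    length = np.concatenate([[soma_diam], np.full(n_comp, seg)])
    diam = np.concatenate([[soma_diam], np.full(n_comp, dend_diam)])
    parent = np.arange(-1, n_comp)
    ctype = np.concatenate([[1], np.full(n_comp, 3)]).astype(int)
    return CableModel(length, diam, parent, comp_type=ctype,
                      name="ball_and_stick", **cable_kw)


def make_toy_network(spec: dict) -> NetworkModel:
    """Build a small, fully deterministic network from an explicit spec.

    ``spec['populations']`` is a list of {name, size, role[, model]},
    ``spec['projections']`` a list of {pre, post, weight, e_syn
    [, tau_syn, delay]}; every projection is all-to-all (excluding
    self-connections within a population). Optional
    ``spec['backgrounds']``: {target, rate, weight[, e_syn, tau_syn]}.
    """
    pops = []
    for p in spec.get("populations", []):
        model = p.get("model", "expif")
        params = ExpIFParams() if model == "expif" else HHPointParams()
        pops.append(Population(p["name"], int(p["size"]), model, params,
                               role=p.get("role", "E")))
    sizes = {p.name: p.size for p in pops}
    projections = []
    for pr in spec.get("projections", []):
        pre, post = pr["pre"], pr["post"]
        if pre not in sizes or post not in sizes:
            raise SchemaError(f"projection references unknown population {pre}->{post}")
        n_pre, n_post = sizes[pre], sizes[post]
        a, b = np.meshgrid(np.arange(n_pre), np.arange(n_post), indexing="ij")
        conns = np.column_stack([a.ravel(), b.ravel()])
        if pre == post:
            conns = conns[conns[:, 0] != conns[:, 1]]
        projections.append(Projection(
            pre, post, 1.0, float(pr["weight"]), float(pr["e_syn"]),
            float(pr.get("tau_syn", 5.0)), float(pr.get("delay", 1.0)), conns,
        ))
    backgrounds = [
        BackgroundInput(b["target"], float(b["rate"]), float(b["weight"]),
                        float(b.get("e_syn", 0.0)), float(b.get("tau_syn", 5.0)))
        for b in spec.get("backgrounds", [])
    ]
    return NetworkModel(pops, projections, backgrounds, seed=0,
                        meta={"builder": "make_toy_network"})
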