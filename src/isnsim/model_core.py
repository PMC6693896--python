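"""Neuron and synapse dynamics at three levels of biological detail.

Three cell models are provided, all sharing one unit convention
(mV, ms, nS, pA, pF, so that nS*mV = pA and pA/pF = mV/ms):

* exponential integrate-and-fire (exp-I&F) point neurons without
  adaptation -- the workhorse of the large recurrent network,
* Hodgkin-Huxley-type point neurons with a Pospischil-style conductance
  complement (fast Na+, delayed-rectifier and M-type K+, L-type Ca2+,
  leak) -- the biophysically detailed point cells,
* a reduced passive multicompartment cable model -- the morphologically
  extended cells of the hybrid network.

Synapses are conductance based: each presynaptic spike increments a
per-class conductance by the peak conductance w, which then decays as a
single exponential with time constant tau_syn and drives the membrane
through g_syn * (E_syn - V).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError, NumericalInstabilityError, TopologyError

__all__ = [
    "ExpIFParams",
    "SynapseParams",
    "HHPointParams",
    "CableModel",
    "exp_if_derivative",
    "decay_synapse",
    "hh_steady_state_gates",
    "hh_step",
    "cable_axial_conductances",
    "cable_step",
]

# exponent clip keeps the spike-initiation current finite past V_cut
_EXP_CLIP = 30.0


@dataclass(frozen=True)
class ExpIFParams:
    """Exponential integrate-and-fire parameters (no adaptation).

    The subthreshold dynamics are

        C dV/dt = g_L (E_L - V) + g_L Delta_T exp((V - V_T)/Delta_T)
                  + sum_s g_s (E_s - V) + I_inj

    with a spike registered when V reaches ``V_cut``, after which V is
    reset to ``V_reset`` and held for the refractory period ``t_ref``.
    Setting ``Delta_T = 0`` disables the spike-initiation current and
    leaves a purely passive leaky integrator.
    """

    C: float = 200.0        # pF
    g_L: float = 10.0       # nS  (tau_m = C/g_L = 20 ms)
    E_L: float = -70.0      # mV
    V_T: float = -50.0      # mV
    Delta_T: float = 2.0    # mV
    V_cut: float = 0.0      # mV
    V_reset: float = -60.0  # mV
    t_ref: float = 2.0      # ms

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.g_L > 0):
            raise InvalidParameterError("C and g_L must be positive")
        if self.Delta_T < 0:
            raise InvalidParameterError("Delta_T must be >= 0")
        if not self.V_cut > self.V_T:
            raise InvalidParameterError("V_cut must exceed V_T")
        if not self.V_reset < self.V_cut:
            raise InvalidParameterError("V_reset must lie below V_cut")
        if self.t_ref < 0:
            raise InvalidParameterError("t_ref must be >= 0")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C/g_L in ms."""
        return self.C / self.g_L


@dataclass(frozen=True)
class SynapseParams:
    """One conductance-based synapse class.

    ``w`` is the peak conductance increment per delivered presynaptic
    spike; the conductance decays exponentially with ``tau_syn`` and
    pulls the membrane toward ``E_syn``.
    """

    E_syn: float   # mV
    tau_syn: float  # ms
    w: float       # nS

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise InvalidParameterError("tau_syn must be positive")
        if self.w < 0:
            raise InvalidParameterError("synaptic weight must be >= 0")


# default synapse classes of the recurrent network: excitation reverses at
# 0 mV, inhibition at -75 mV; decay constants are 5 ms (E) and 10 ms (I)
EXC_SYNAPSE = SynapseParams(E_syn=0.0, tau_syn=5.0, w=0.1)
INH_SYNAPSE = SynapseParams(E_syn=-75.0, tau_syn=10.0, w=0.2)


def exp_if_derivative(V, p: ExpIFParams, g_syn_list=(), I_inj=0.0):
    """Instantaneous dV/dt (mV/ms) of an exp-I&F membrane.

    Parameters
    ----------
    V : float or ndarray
        Membrane potential in mV.
    p : ExpIFParams
    g_syn_list : iterable of (conductance nS, reversal mV)
        Active synaptic conductances.
    I_inj : float or ndarray
        Injected current in pA.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise InvalidParameterError("membrane potential must be finite")
    I = p.g_L * (p.E_L - V)
    if p.Delta_T > 0:
        arg = np.minimum((V - p.V_T) / p.Delta_T, _EXP_CLIP)
        I = I + p.g_L * p.Delta_T * np.exp(arg)
    for g, e_rev in g_syn_list:
        if np.any(np.asarray(g) < 0):
            raise InvalidParameterError("synaptic conductances must be >= 0")
        I = I + np.asarray(g) * (e_rev - V)
    out = (I + I_inj) / p.C
    return float(out) if out.ndim == 0 else out


def decay_synapse(g, dt: float, tau_syn: float):
    """Exponential conductance decay g <- g * exp(-dt/tau_syn)."""
    if tau_syn <= 0:
        raise InvalidParameterError("tau_syn must be positive")
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise InvalidParameterError("conductance must be >= 0")
    out = g * np.exp(-dt / tau_syn)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Hodgkin-Huxley point neuron, Pospischil-style conductance complement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HHPointParams:
    """Single-compartment HH-type cell.

    Conductances are whole-cell totals in nS (density times membrane
    area, folded into one number). The complement is: transient Na+
    (m^3 h), delayed-rectifier K+ (n^4), slow non-inactivating M-type
    K+ (p), high-threshold L-type Ca2+ (q^2, treated as ohmic with a
    fixed Ca reversal), and leak. ``V_shift`` translates the Na+
    activation/inactivation curves along the voltage axis and is one of
    the free parameters of the tuning stage. ``tau_max_M`` sets the
    M-current time-constant scale.
    """

    C: float = 100.0          # pF
    gbar_Na: float = 5000.0   # nS
    gbar_Kd: float = 1000.0   # nS
    gbar_M: float = 30.0      # nS
    gbar_CaL: float = 20.0    # nS
    gbar_leak: float = 5.0    # nS
    E_Na: float = 50.0        # mV
    E_K: float = -90.0        # mV
    E_Ca: float = 120.0       # mV
    E_leak: float = -70.0     # mV
    V_shift: float = 0.0      # mV, extra shift of the Na gating curves
    tau_max_M: float = 1000.0  # ms

    def __post_init__(self) -> None:
        for name in ("gbar_Na", "gbar_Kd", "gbar_M", "gbar_CaL", "gbar_leak"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.C <= 0:
            raise InvalidParameterError("C must be positive")
        if not self.E_Na > self.E_K:
            raise InvalidParameterError("E_Na must exceed E_K")

    def with_updates(self, **kw) -> "HHPointParams":
        return replace(self, **kw)


# Traub-style spike-generating kinetics are written relative to this
# reference voltage; the cell-specific V_shift is added on top for Na+.
_VT_REF = -55.0


def _vtrap(x, y):
    """x / (exp(x/y) - 1), continuous through x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    out = np.where(small, y * (1.0 - x / (2.0 * y)), safe / np.expm1(safe / y))
    return out


def _na_rates(V, v_shift):
    v = np.asarray(V, dtype=float) - _VT_REF - v_shift
    a_m = 0.32 * _vtrap(13.0 - v, 4.0)
    b_m = 0.28 * _vtrap(v - 40.0, 5.0)
    a_h = 0.128 * np.exp(-(v - 17.0) / 18.0)
    b_h = 4.0 / (1.0 + np.exp(-(v - 40.0) / 5.0))
    return a_m, b_m, a_h, b_h


def _kd_rates(V):
    v = np.asarray(V, dtype=float) - _VT_REF
    a_n = 0.032 * _vtrap(15.0 - v, 5.0)
    b_n = 0.5 * np.exp(-(v - 10.0) / 40.0)
    return a_n, b_n


def _m_current_gate(V, tau_max):
    V = np.asarray(V, dtype=float)
    p_inf = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    tau_p = tau_max / (3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0))
    return p_inf, tau_p


def _ca_rates(V):
    V = np.asarray(V, dtype=float)
    a_q = 0.055 * _vtrap(-27.0 - V, 3.8)
    b_q = 0.94 * np.exp((-75.0 - V) / 17.0)
    return a_q, b_q


def hh_steady_state_gates(V, params: HHPointParams):
    """Voltage-dependent steady-state values (m, h, n, p, q) at fixed V."""
    a_m, b_m, a_h, b_h = _na_rates(V, params.V_shift)
    a_n, b_n = _kd_rates(V)
    p_inf, _ = _m_current_gate(V, params.tau_max_M)
    a_q, b_q = _ca_rates(V)
    return (
        a_m / (a_m + b_m),
        a_h / (a_h + b_h),
        a_n / (a_n + b_n),
        p_inf,
        a_q / (a_q + b_q),
    )


def hh_ionic_current(V, gates, params: HHPointParams):
    """Total ionic membrane current (pA, inward positive) at state (V, gates)."""
    m, h, n, p_gate, q = gates
    V = np.asarray(V, dtype=float)
    I = params.gbar_Na * m ** 3 * h * (params.E_Na - V)
    I = I + params.gbar_Kd * n ** 4 * (params.E_K - V)
    I = I + params.gbar_M * p_gate * (params.E_K - V)
    I = I + params.gbar_CaL * q ** 2 * (params.E_Ca - V)
    I = I + params.gbar_leak * (params.E_leak - V)
    return I


def hh_step(state, params: HHPointParams, dt: float, I_syn=0.0, I_inj=0.0):
    """Advance an HH point cell one step of ``dt`` ms.

    Gates use exponential-Euler updates (exact for frozen rates), the
    voltage a forward-Euler update. ``state`` is (V, m, h, n, p, q);
    scalars and equal-length arrays are both accepted, so a whole batch
    of cells can be advanced in one call.
    """
    if dt > 0.05:
        raise InvalidParameterError("hh_step requires dt <= 0.05 ms for stability")
    V, m, h, n, p_gate, q = (np.asarray(x, dtype=float) for x in state)
    gates = np.stack([m, h, n, p_gate, q]) if V.ndim else np.array([m, h, n, p_gate, q])
    if np.any(gates < 0) or np.any(gates > 1):
        raise NumericalInstabilityError("gating variable outside [0, 1]")

    a_m, b_m, a_h, b_h = _na_rates(V, params.V_shift)
    a_n, b_n = _kd_rates(V)
    p_inf, tau_p = _m_current_gate(V, params.tau_max_M)
    a_q, b_q = _ca_rates(V)

    def _exp_euler(x, alpha, beta):
        tau = 1.0 / (alpha + beta)
        x_inf = alpha * tau
        return x_inf + (x - x_inf) * np.exp(-dt / tau)

    m = _exp_euler(m, a_m, b_m)
    h = _exp_euler(h, a_h, b_h)
    n = _exp_euler(n, a_n, b_n)
    p_gate = p_inf + (p_gate - p_inf) * np.exp(-dt / tau_p)
    q = _exp_euler(q, a_q, b_q)

    I_ion = hh_ionic_current(V, (m, h, n, p_gate, q), params)
    V_new = V + dt * (I_ion + I_syn + I_inj) / params.C
    if not np.all(np.isfinite(V_new)):
        raise NumericalInstabilityError("non-finite membrane potential in hh_step")
    out = tuple(
        float(x) if x.ndim == 0 else x for x in (np.asarray(V_new), m, h, n, p_gate, q)
    )
    return out


# ---------------------------------------------------------------------------
# Reduced multicompartment cable model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CableModel:
    """Passive compartmental cable on a rooted tree.

    Compartment 0 is the root (soma). If ``spherical_root`` is set, its
    membrane area is that of a sphere (pi d^2), all other compartments
    are cylinders with lateral area pi d L. Passive properties are
    specified as densities and converted to whole-compartment values
    through the areas; axial coupling follows the usual half-cylinder
    series-resistance rule with resistivity ``Ra``.
    """

    length: np.ndarray        # um, per compartment (soma: its diameter)
    diam: np.ndarray          # um, per compartment
    parent: np.ndarray        # int, -1 for root
    Ra: float = 150.0         # ohm cm
    cm: float = 1.0           # uF / cm^2
    g_pas: float = 5e-5       # S / cm^2  (tau_m = cm/g_pas = 20 ms)
    e_pas: float = -70.0      # mV
    spherical_root: bool = True
    name: str = "cable"
    comp_type: np.ndarray = field(default=None)  # SWC-style type codes

    def __post_init__(self) -> None:
        length = np.asarray(self.length, dtype=float)
        diam = np.asarray(self.diam, dtype=float)
        parent = np.asarray(self.parent, dtype=int)
        object.__setattr__(self, "length", length)
        object.__setattr__(self, "diam", diam)
        object.__setattr__(self, "parent", parent)
        if self.comp_type is None:
            ct = np.full(len(length), 3, dtype=int)
            ct[0] = 1
            object.__setattr__(self, "comp_type", ct)
        else:
            object.__setattr__(self, "comp_type", np.asarray(self.comp_type, dtype=int))
        if np.any(length <= 0) or np.any(diam <= 0):
            raise InvalidParameterError("compartment lengths and diameters must be positive")
        n = len(length)
        if len(diam) != n or len(parent) != n:
            raise InvalidParameterError("length, diam and parent must have equal length")
        if parent[0] != -1 or np.any(parent[1:] < 0) or np.any(parent[1:] >= np.arange(1, n)):
            raise TopologyError("compartments must form a rooted tree with parent < child")

    @property
    def n_comp(self) -> int:
        return len(self.length)

    def areas_um2(self) -> np.ndarray:
        """Membrane area per compartment in um^2."""
        area = np.pi * self.diam * self.length
        if self.spherical_root:
            area = area.copy()
            area[0] = np.pi * self.diam[0] ** 2
        return area

    def total_area_um2(self) -> float:
        return float(self.areas_um2().sum())

    def capacitance_pF(self) -> np.ndarray:
        # uF/cm^2 * um^2 -> pF :  1 um^2 = 1e-8 cm^2, 1 uF = 1e6 pF
        return self.cm * self.areas_um2() * 1e-2

    def g_leak_nS(self) -> np.ndarray:
        # S/cm^2 * um^2 -> nS :  1e-8 cm^2/um^2 * 1e9 nS/S = 10
        return self.g_pas * self.areas_um2() * 10.0


def cable_axial_conductances(model: CableModel) -> np.ndarray:
    """Axial coupling conductance (nS) between each compartment and its parent.

    Entry 0 (the root) is zero. Each coupling is the series combination
    of the two half-cylinder axial resistances; a spherical root
    contributes no axial resistance of its own.
    """
    L_cm = model.length * 1e-4
    d_cm = model.diam * 1e-4
    # half-cylinder axial resistance in ohm
    r_half = 0.5 * 4.0 * model.Ra * L_cm / (np.pi * d_cm ** 2)
    if model.spherical_root:
        r_half = r_half.copy()
        r_half[0] = 0.0
    g = np.zeros(model.n_comp)
    for i in range(1, model.n_comp):
        r = r_half[i] + r_half[model.parent[i]]
        g[i] = 1e9 / r  # ohm^-1 -> nS
    return g


def cable_step(
    model: CableModel,
    V: np.ndarray,
    dt: float,
    g_syn=None,
    I_inj=None,
    clamp=None,
):
    """Advance the cable one backward-Euler step of ``dt`` ms.

    Parameters
    ----------
    V : (n_comp,) array, mV
    g_syn : optional list of (g_vector nS per compartment, E_syn mV)
    I_inj : optional (n_comp,) injected current, pA
    clamp : optional (compartment index, holding level mV); the clamped
        compartment is held exactly at the level and the electrode
        current needed to do so is returned.

    Returns
    -------
    (V_new, clamp_current_pA or None)

    The implicit update is unconditionally stable, so the network time
    step can be used even for stiff axial coupling.
    """
    V = np.asarray(V, dtype=float)
    n = model.n_comp
    if V.shape != (n,):
        raise InvalidParameterError(f"V must have shape ({n},)")
    C = model.capacitance_pF()
    gl = model.g_leak_nS()
    g_ax = cable_axial_conductances(model)

    # assemble (C/dt + G) V' = C/dt V + b
    A = np.zeros((n, n))
    b = C / dt * V + gl * model.e_pas
    np.fill_diagonal(A, C / dt + gl)
    if g_syn:
        for g_vec, e_rev in g_syn:
            g_vec = np.asarray(g_vec, dtype=float)
            A[np.arange(n), np.arange(n)] += g_vec
            b += g_vec * e_rev
    if I_inj is not None:
        b = b + np.asarray(I_inj, dtype=float)
    for i in range(1, n):
        j = model.parent[i]
        A[i, i] += g_ax[i]
        A[j, j] += g_ax[i]
        A[i, j] -= g_ax[i]
        A[j, i] -= g_ax[i]

    I_hold = None
    if clamp is not None:
        k, level = clamp
        if not (0 <= k < n):
            raise InvalidParameterError("clamp compartment out of range")
        A_c = A.copy()
        A_c[k, :] = 0.0
        A_c[k, k] = 1.0
        b_c = b.copy()
        b_c[k] = level
        V_new = np.linalg.solve(A_c, b_c)
        # electrode current that zeroes dV/dt at the clamped compartment
        I_mem = gl[k] * (model.e_pas - level)
        if g_syn:
            for g_vec, e_rev in g_syn:
                I_mem += np.asarray(g_vec, dtype=float)[k] * (e_rev - level)
        if I_inj is not None:
            I_mem += np.asarray(I_inj, dtype=float)[k]
        I_ax = 0.0
        for i in range(1, n):
            if i == k:
                I_ax += g_ax[i] * (V_new[model.parent[i]] - level)
            elif model.parent[i] == k:
                I_ax += g_ax[i] * (V_new[i] - level)
        I_hold = -(I_mem + I_ax)
    else:
        V_new = np.linalg.solve(A, b)
    if not np.all(np.isfinite(V_new)):
        raise NumericalInstabilityError("non-finite compartment voltage in cable_step")
    return V_new, I_hold
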