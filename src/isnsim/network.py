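"""Construction of the recurrent network models.

The default cortical network has 800 excitatory (E) and 200 inhibitory
(I) cells with binomial connectivity: every ordered pair with an
excitatory presynaptic cell is connected independently with probability
0.15, every pair with an inhibitory presynaptic cell with probability
1.0 (no autapses). Peak synaptic conductances are 0.1 nS (E) and
0.2 nS (I), reversing at 0 mV and -75 mV. Each cell additionally
receives an independent homogeneous 9600 Hz Poisson background through
0.1 nS excitatory synapses.

The hybrid variant replaces a subset of E cells with multicompartment
cable models; the replaced cells keep all their afferents (redistributed
onto dendritic compartments) but lose every efferent connection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InvalidParameterError, SchemaError
from .model_core import CableModel, ExpIFParams, HHPointParams

__all__ = [
    "Population",
    "Projection",
    "BackgroundInput",
    "NetworkModel",
    "sample_connections",
    "build_isn_pointnet",
    "hybridize",
    "DEFAULT_NET_CONFIG",
]

DEFAULT_NET_CONFIG = {
    "cell_model": "expif",        # "expif" | "hh"
    "n_exc": 800,
    "n_inh": 200,
    "p_exc": 0.15,
    "p_inh": 1.0,
    "w_exc": 0.1,                 # nS
    "w_inh": 0.2,                 # nS
    "e_exc": 0.0,                 # mV
    "e_inh": -75.0,               # mV
    "tau_exc": 5.0,               # ms
    "tau_inh": 10.0,              # ms
    "delay": 1.0,                 # ms
    "bg_rate": 9600.0,            # Hz per cell
    "bg_weight": 0.1,             # nS
    "recurrent_scale": 1.0,       # global multiplier on all recurrent weights
    "box_um": (500.0, 500.0, 200.0),
}


@dataclass
class Population:
    """A homogeneous cell population.

    ``detailed`` optionally maps local cell indices to CableModel
    instances; those cells are simulated as multicompartment cables
    while the rest of the population keeps the point model in
    ``params``.
    """

    name: str
    size: int
    model: str                      # "expif" | "hh" | "cable"
    params: object                  # ExpIFParams | HHPointParams | CableModel
    role: str = "E"                 # "E" | "I"
    positions: Optional[np.ndarray] = None  # (size, 3) um
    detailed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size < 0:
            raise InvalidParameterError("population size must be >= 0")
        if self.model not in ("expif", "hh", "cable"):
            raise SchemaError(f"unknown cell model level {self.model!r}")
        if self.role not in ("E", "I"):
            raise SchemaError("population role must be 'E' or 'I'")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.size, 3):
                raise SchemaError("positions must have shape (size, 3)")


@dataclass
class Projection:
    """Sampled connections between two populations.

    ``connections`` is an (n, 2) int array of (pre local index, post
    local index). ``post_compartments`` optionally assigns a target
    compartment to each connection (used when the postsynaptic cell is
    a cable model; -1 means the point membrane / soma).
    """

    pre: str
    post: str
    p: float
    weight: float                  # nS
    e_syn: float                   # mV
    tau_syn: float                 # ms
    delay: float                   # ms
    connections: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    post_compartments: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise InvalidParameterError("connection probability must lie in [0, 1]")
        if self.delay <= 0:
            raise InvalidParameterError("synaptic delay must be positive")
        self.connections = np.asarray(self.connections, dtype=int).reshape(-1, 2)
        if self.pre == self.post and len(self.connections):
            if np.any(self.connections[:, 0] == self.connections[:, 1]):
                raise InvalidParameterError("autapses are not allowed")
        if len(self.connections):
            uniq = {(int(a), int(b)) for a, b in self.connections}
            if len(uniq) != len(self.connections):
                raise InvalidParameterError("duplicate (pre, post) pairs in projection")

    @property
    def n_connections(self) -> int:
        return len(self.connections)


@dataclass
class BackgroundInput:
    """Independent per-cell Poisson drive onto one population."""

    target: str
    rate: float                    # Hz per cell
    weight: float                  # nS
    e_syn: float = 0.0             # mV
    tau_syn: float = 5.0           # ms

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise InvalidParameterError("background rate must be >= 0")


@dataclass
class NetworkModel:
    """A fully realized network: populations, sampled projections, drive."""

    populations: list
    projections: list
    backgrounds: list
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate population names")
        for proj in self.projections:
            if proj.pre not in names or proj.post not in names:
                raise SchemaError(
                    f"projection {proj.pre}->{proj.post} references unknown population"
                )
        for bg in self.backgrounds:
            if bg.target not in names:
                raise SchemaError(f"background targets unknown population {bg.target!r}")

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def pop_slices(self) -> dict:
        """Global cell-index ranges, populations concatenated in order."""
        out, start = {}, 0
        for p in self.populations:
            out[p.name] = (start, start + p.size)
            start += p.size
        return out

    @property
    def n_cells(self) -> int:
        return sum(p.size for p in self.populations)

    def total_connections(self) -> int:
        return sum(p.n_connections for p in self.projections)


def sample_connections(
    n_pre: int,
    n_post: int,
    p: float,
    same_population: bool = False,
    seed=0,
) -> np.ndarray:
    """Sample an independent-Bernoulli (binomial) connection list.

    Every eligible ordered pair (excluding self-pairs when
    ``same_population``) is connected independently with probability
    ``p``; at most one connection per pair. Deterministic given seed.
    """
    if not (0.0 <= p <= 1.0):
        raise InvalidParameterError("connection probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if p == 0.0 or n_pre == 0 or n_post == 0:
        return np.empty((0, 2), dtype=int)
    mask = rng.random((n_pre, n_post)) < p
    if same_population:
        np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    return np.column_stack([pre, post]).astype(int)


def _positions(rng: np.random.Generator, n: int, box) -> np.ndarray:
    return rng.random((n, 3)) * np.asarray(box, dtype=float)


def build_isn_pointnet(config: dict | None = None, seed: int = 0) -> NetworkModel:
    """Build the default recurrent E/I point-neuron network.

    Four recurrent projections are sampled (E->E, E->I at p=0.15 and
    w=0.1 nS; I->E, I->I at p=1.0 and w=0.2 nS) and every cell gets an
    independent 9600 Hz background. ``config['recurrent_scale']``
    multiplies all recurrent weights (used by the inhibition-
    stabilization calibration); background weights are untouched.
    """
    cfg = dict(DEFAULT_NET_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise SchemaError(f"unknown network config keys: {sorted(unknown)}")
        cfg.update(config)
    if cfg["cell_model"] not in ("expif", "hh"):
        raise SchemaError(f"unknown cell model level {cfg['cell_model']!r}")
    params = ExpIFParams() if cfg["cell_model"] == "expif" else HHPointParams()

    ss = np.random.SeedSequence(seed)
    s_pos, s_ee, s_ei, s_ie, s_ii = ss.spawn(5)
    rng_pos = np.random.default_rng(s_pos)
    n_e, n_i = int(cfg["n_exc"]), int(cfg["n_inh"])
    scale = float(cfg["recurrent_scale"])

    pops = [
        Population("E", n_e, cfg["cell_model"], params, role="E",
                   positions=_positions(rng_pos, n_e, cfg["box_um"])),
        Population("I", n_i, cfg["cell_model"], params, role="I",
                   positions=_positions(rng_pos, n_i, cfg["box_um"])),
    ]

    def proj(pre, post, p, w, e, tau, s):
        n_pre = n_e if pre == "E" else n_i
        n_post = n_e if post == "E" else n_i
        conns = sample_connections(n_pre, n_post, p, same_population=(pre == post), seed=s)
        return Projection(pre, post, p, w * scale, e, tau, cfg["delay"], conns)

    projections = [
        proj("E", "E", cfg["p_exc"], cfg["w_exc"], cfg["e_exc"], cfg["tau_exc"], s_ee),
        proj("E", "I", cfg["p_exc"], cfg["w_exc"], cfg["e_exc"], cfg["tau_exc"], s_ei),
        proj("I", "E", cfg["p_inh"], cfg["w_inh"], cfg["e_inh"], cfg["tau_inh"], s_ie),
        proj("I", "I", cfg["p_inh"], cfg["w_inh"], cfg["e_inh"], cfg["tau_inh"], s_ii),
    ]
    backgrounds = [
        BackgroundInput("E", cfg["bg_rate"], cfg["bg_weight"], cfg["e_exc"], cfg["tau_exc"]),
        BackgroundInput("I", cfg["bg_rate"], cfg["bg_weight"], cfg["e_exc"], cfg["tau_exc"]),
    ]
    return NetworkModel(pops, projections, backgrounds, seed=seed,
                        meta={"config": cfg, "builder": "build_isn_pointnet"})


def hybridize(
    net: NetworkModel,
    n_replace: int,
    cable: CableModel,
    placement: str = "uniform_dendrite",
    seed: int = 0,
) -> NetworkModel:
    """Replace ``n_replace`` E cells by a multicompartment cable model.

    Replaced cells keep their identity and their incoming connections —
    each afferent synapse is assigned a target compartment according to
    the placement rule — but every outgoing (axonal) connection of a
    replaced cell is removed; consequently afferents that originate
    from another replaced cell disappear as well. ``placement='uniform_dendrite'`` draws compartments
    uniformly from the dendritic compartments; ``'soma'`` puts all
    synapses on compartment 0.
    """
    e_pop = net.population("E")
    if n_replace < 0 or n_replace > e_pop.size:
        raise InvalidParameterError("n_replace must lie in [0, E population size]")
    if n_replace == 0:
        return net
    if placement not in ("uniform_dendrite", "soma"):
        raise SchemaError(f"unknown synapse placement rule {placement!r}")

    rng = np.random.default_rng(seed)
    replaced = np.sort(rng.choice(e_pop.size, size=n_replace, replace=False))
    replaced_set = set(int(i) for i in replaced)

    dend = np.nonzero(cable.comp_type != 1)[0]
    if placement == "soma" or len(dend) == 0:
        dend = np.array([0])

    new_pops = []
    for p in net.populations:
        if p.name == "E":
            new_pops.append(replace(
                p, detailed={int(i): cable for i in replaced},
            ))
        else:
            new_pops.append(replace(p))

    new_projs = []
    for proj in net.projections:
        conns = proj.connections
        comps = None
        if proj.pre == "E" and len(conns):
            keep = ~np.isin(conns[:, 0], replaced)
            conns = conns[keep]
        if proj.post == "E" and len(conns):
            comps = np.full(len(conns), -1, dtype=int)
            onto = np.isin(conns[:, 1], replaced)
            comps[onto] = rng.choice(dend, size=int(onto.sum()), replace=True)
        new_projs.append(replace(proj, connections=conns, post_compartments=comps))

    meta = dict(net.meta)
    meta["hybrid"] = {"replaced": [int(i) for i in replaced], "placement": placement,
                      "seed": seed}
    return NetworkModel(new_pops, new_projs, list(net.backgrounds), seed=net.seed, meta=meta)
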