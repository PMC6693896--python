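"""Population-rate estimators, the paradoxical-effect statistic and
population-level connectivity summaries.

Two per-cell-averaged rate estimators are provided: a Gaussian-kernel
smoothed rate (default sigma 30 ms) and a piecewise-constant windowed
rate (default 100 ms bins). Both conserve the spike count: the time
integral of the rate times the cell count equals the number of spikes.

The paradoxical-effect statistic compares window-mean rates before and
during a perturbation across trials, separately for the perturbed
inhibitory cells, the unperturbed inhibitory cells and the excitatory
population: in an inhibition-stabilized network the perturbed
inhibitory cells *increase* their rate although their excitatory drive
was reduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidParameterError, ProtocolError
from .engine import SpikeData
from .network import NetworkModel

__all__ = [
    "RateSeries",
    "ParadoxReport",
    "ConnectivitySummary",
    "population_rate",
    "windowed_rate",
    "window_mean_rate",
    "paradox_statistic",
    "connectivity_summary",
]

# a synapse class reversing above this potential is counted as excitatory
EXC_REVERSAL_CUTOFF = -55.0


@dataclass
class RateSeries:
    """Per-cell-average population rate (Hz) on a uniform time grid."""

    times: np.ndarray       # ms (bin centers)
    rate: np.ndarray        # Hz
    n_cells: int
    kernel: str             # descriptor of the estimator

    def integral_spikes(self) -> float:
        """Time integral of rate * n_cells, in spikes (conservation check)."""
        dt_s = (self.times[1] - self.times[0]) * 1e-3 if len(self.times) > 1 else 0.0
        return float(self.rate.sum() * dt_s * self.n_cells)

    def mean_in_window(self, t0: float, t1: float) -> float:
        mask = (self.times >= t0) & (self.times < t1)
        return float(self.rate[mask].mean()) if mask.any() else 0.0


def _cell_set_spikes(spikes: SpikeData, cells) -> np.ndarray:
    cells = np.asarray(cells, dtype=int)
    if cells.size == 0:
        raise InvalidParameterError("cell set must be non-empty")
    mask = np.isin(spikes.ids, cells)
    return spikes.times[mask]


def population_rate(
    spikes: SpikeData,
    cells,
    kernel_sd: float = 30.0,
    bin_ms: float = 1.0,
) -> RateSeries:
    """Gaussian-kernel smoothed per-cell firing rate.

    rate(t) = (1/N) * sum_spikes Gaussian(t - t_spike; sigma=kernel_sd),
    evaluated on a grid of ``bin_ms`` bins. The time integral of the
    series equals spike_count / N (up to edge truncation).
    """
    if kernel_sd <= 0:
        raise InvalidParameterError("kernel_sd must be positive")
    cells = np.asarray(cells, dtype=int)
    t_sp = _cell_set_spikes(spikes, cells)
    n_bins = max(1, int(np.ceil(spikes.duration / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(t_sp, bins=edges)
    # counts / (N * bin) in kHz -> *1e3 Hz; smoothing preserves the sum
    rate = counts / (len(cells) * bin_ms * 1e-3)
    rate = gaussian_filter1d(rate, sigma=kernel_sd / bin_ms, mode="constant")
    times = (edges[:-1] + edges[1:]) / 2.0
    return RateSeries(times, rate, len(cells), f"gaussian(sd={kernel_sd}ms)")


def windowed_rate(spikes: SpikeData, cells, window: float = 100.0) -> RateSeries:
    """Piecewise-constant rate: counts / (N * window) per consecutive bin."""
    if window <= 0:
        raise InvalidParameterError("window must be positive")
    cells = np.asarray(cells, dtype=int)
    t_sp = _cell_set_spikes(spikes, cells)
    if window > spikes.duration:
        warnings.warn("window exceeds the simulation duration; returning one bin")
        window = spikes.duration
    n_bins = max(1, int(np.ceil(spikes.duration / window)))
    edges = np.arange(n_bins + 1) * window
    counts, _ = np.histogram(t_sp, bins=edges)
    widths = np.diff(edges)
    rate = counts / (len(cells) * widths * 1e-3)
    times = (edges[:-1] + edges[1:]) / 2.0
    return RateSeries(times, rate, len(cells), f"window({window}ms)")


def window_mean_rate(spikes: SpikeData, cells, t0: float, t1: float) -> float:
    """Mean per-cell rate (Hz) of a cell set inside [t0, t1)."""
    cells = np.asarray(cells, dtype=int)
    t_sp = _cell_set_spikes(spikes, cells)
    n = np.count_nonzero((t_sp >= t0) & (t_sp < t1))
    return n / (len(cells) * (t1 - t0) * 1e-3)


@dataclass
class ParadoxReport:
    """Baseline vs perturbation window rates per cell subset.

    ``delta`` holds the across-trial mean rate change per subset and
    ``delta_sd`` its across-trial standard deviation. The
    inhibition-stabilization signature is a *positive* rate change of
    the perturbed inhibitory cells despite their reduced drive.
    """

    baseline: dict
    perturbed: dict
    delta: dict
    delta_sd: dict
    n_trials: int
    windows: dict
    isn_signature: bool = field(init=False)

    def __post_init__(self) -> None:
        self.isn_signature = bool(self.delta.get("I_perturbed", 0.0) > 0.0)


def paradox_statistic(
    trials,
    baseline_window,
    perturb_window,
    guard_band: float = 100.0,
) -> ParadoxReport:
    """Across-trial window-mean rate changes for the three cell subsets.

    ``trials`` is a TrialResults (or anything with ``spike_data`` list,
    ``perturbed_cells``, ``unperturbed_inh_cells`` and ``exc_cells``
    attributes). Both windows must be disjoint and, after applying the
    onset ``guard_band`` (ms skipped at the start of the perturbation
    window to avoid transients), of equal duration.
    """
    b0, b1 = map(float, baseline_window)
    p0, p1 = map(float, perturb_window)
    if not (b1 <= p0 or p1 <= b0):
        if (b0, b1) != (p0, p1):
            raise ProtocolError("analysis windows must be disjoint")
    if guard_band > 0 and (b0, b1) != (p0, p1):
        if p1 - (p0 + guard_band) <= 0:
            warnings.warn("guard band swallows the perturbation window; not applied")
        else:
            p0 = p0 + guard_band
            b1 = b0 + (p1 - p0)  # keep window durations identical
            warnings.warn(
                f"guard band of {guard_band} ms applied after perturbation onset",
                stacklevel=2,
            )

    subsets = {
        "I_perturbed": np.asarray(trials.perturbed_cells, dtype=int),
        "I_unperturbed": np.asarray(trials.unperturbed_inh_cells, dtype=int),
        "E": np.asarray(trials.exc_cells, dtype=int),
    }
    base, pert, delta, delta_sd = {}, {}, {}, {}
    for name, cells in subsets.items():
        if cells.size == 0:
            base[name] = pert[name] = delta[name] = delta_sd[name] = float("nan")
            continue
        b_rates = [window_mean_rate(sp, cells, b0, b1) for sp in trials.spike_data]
        p_rates = [window_mean_rate(sp, cells, p0, p1) for sp in trials.spike_data]
        d = np.asarray(p_rates) - np.asarray(b_rates)
        base[name] = float(np.mean(b_rates))
        pert[name] = float(np.mean(p_rates))
        delta[name] = float(np.mean(d))
        delta_sd[name] = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return ParadoxReport(
        base, pert, delta, delta_sd,
        n_trials=len(trials.spike_data),
        windows={"baseline": (b0, b1), "perturbation": (p0, p1)},
    )


@dataclass
class ConnectivitySummary:
    """Population-level summaries of a realized network.

    ``adjacency[i, j]`` is the signed mean summed synaptic conductance
    (nS) from presynaptic population i onto an average cell of
    postsynaptic population j: +/- (connection count * weight) / N_post,
    positive for excitatory synapse classes, negative for inhibitory
    ones. ``chords`` lists realized connection counts per ordered
    population pair, and ``graph`` carries a drawing spec (node size
    proportional to population size, edge width to |weight|, both with
    floor values for visual clarity).
    """

    populations: list
    adjacency: np.ndarray
    chords: list                       # (pre, post, connection count)
    graph: dict


def connectivity_summary(
    net: NetworkModel,
    min_node_size: float = 0.05,
    min_edge_width: float = 0.1,
) -> ConnectivitySummary:
    names = [p.name for p in net.populations]
    sizes = {p.name: p.size for p in net.populations}
    n = len(names)
    adjacency = np.zeros((n, n))
    chords = []
    edges = []
    for proj in net.projections:
        count = proj.n_connections
        if count == 0 and proj.p == 0:
            continue
        i, j = names.index(proj.pre), names.index(proj.post)
        sign = 1.0 if proj.e_syn > EXC_REVERSAL_CUTOFF else -1.0
        n_post = sizes[proj.post]
        if n_post > 0:
            adjacency[i, j] += sign * count * proj.weight / n_post
        chords.append((proj.pre, proj.post, count))
        edges.append({
            "pre": proj.pre,
            "post": proj.post,
            "sign": "+" if sign > 0 else "-",
            "width": max(min_edge_width, abs(count * proj.weight / max(n_post, 1))),
        })
    total = max(1, sum(sizes.values()))
    graph = {
        "nodes": [
            {"name": nm, "size": max(min_node_size, sizes[nm] / total), "role": p.role}
            for nm, p in zip(names, net.populations)
        ],
        "edges": edges,
    }
    return ConnectivitySummary(names, adjacency, chords, graph)
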