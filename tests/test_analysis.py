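"""Rate estimators, the paradox statistic and connectivity summaries."""

import numpy as np
import pytest

from isnsim.analysis import (
    connectivity_summary,
    paradox_statistic,
    population_rate,
    window_mean_rate,
    windowed_rate,
)
from isnsim.engine import SpikeData
from isnsim.errors import InvalidParameterError, ProtocolError
from isnsim.network import build_isn_pointnet
from isnsim.protocols import PerturbationProtocol, TrialResults
from isnsim.synthetic import make_toy_network


def spikes_from(times, ids, duration=3000.0, pops=None):
    return SpikeData(np.asarray(times, dtype=float), np.asarray(ids, dtype=int),
                     duration, pops or {"all": (0, 10)})


class TestPopulationRate:
    def test_no_spikes_zero_series(self):
        rs = population_rate(spikes_from([], []), cells=[0, 1], kernel_sd=30.0)
        assert np.all(rs.rate == 0.0)

    def test_empty_cell_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            population_rate(spikes_from([10.0], [0]), cells=[])

    def test_single_spike_gaussian_peak(self):
        # peak of a unit-mass Gaussian with sigma = 30 ms for one cell:
        # 1/(sigma sqrt(2 pi)) in 1/ms = 13.30 Hz
        rs = population_rate(spikes_from([1500.0], [0]), cells=[0], kernel_sd=30.0)
        peak = rs.rate.max()
        assert peak == pytest.approx(1000.0 / (30.0 * np.sqrt(2 * np.pi)), rel=0.01)
        assert rs.times[np.argmax(rs.rate)] == pytest.approx(1500.0, abs=1.0)

    def test_integral_conserves_spike_count(self):
        rng = np.random.default_rng(1)
        times = rng.uniform(500, 2500, size=400)
        ids = rng.integers(0, 5, size=400)
        rs = population_rate(spikes_from(times, ids), cells=np.arange(5),
                             kernel_sd=30.0)
        assert rs.integral_spikes() == pytest.approx(400, rel=1e-3)


class TestWindowedRate:
    def test_arithmetic(self):
        # 5 spikes among 2 cells in one 100-ms bin -> 25 Hz
        sp = spikes_from([10, 20, 30, 40, 50], [0, 1, 0, 1, 0], duration=100.0)
        rs = windowed_rate(sp, cells=[0, 1], window=100.0)
        assert rs.rate[0] == pytest.approx(25.0)

    def test_empty_zero(self):
        rs = windowed_rate(spikes_from([], [], duration=500.0), cells=[0],
                           window=100.0)
        assert np.all(rs.rate == 0.0)

    def test_integral_conserves_spike_count(self):
        rng = np.random.default_rng(2)
        times = rng.uniform(0, 1000, size=250)
        ids = rng.integers(0, 4, size=250)
        rs = windowed_rate(spikes_from(times, ids, duration=1000.0),
                           cells=np.arange(4), window=100.0)
        assert rs.integral_spikes() == pytest.approx(250, rel=1e-9)

    def test_oversized_window_warns(self):
        with pytest.warns(UserWarning):
            rs = windowed_rate(spikes_from([10.0], [0], duration=100.0),
                               cells=[0], window=500.0)
        assert len(rs.rate) == 1

    def test_poisson_fluctuations(self):
        # homogeneous Poisson spikes: bin values scatter around the rate
        rng = np.random.default_rng(3)
        rate, n_cells, T = 20.0, 50, 10_000.0
        n = rng.poisson(rate * n_cells * T / 1000.0)
        times = np.sort(rng.uniform(0, T, size=n))
        ids = rng.integers(0, n_cells, size=n)
        rs = windowed_rate(spikes_from(times, ids, duration=T),
                           cells=np.arange(n_cells), window=100.0)
        assert rs.rate.mean() == pytest.approx(rate, rel=0.05)
        # per-bin count variance ~ Poisson mean
        counts = rs.rate * n_cells * 0.1
        assert counts.var() == pytest.approx(counts.mean(), rel=0.3)


def _fixture_trials(step=2.0, base_rate=10.0, n_trials=4):
    """Deterministic trains with exact per-window spike counts; the
    perturbed subset steps its count from base_rate to base_rate + step
    spikes inside (1000, 2000) ms."""
    perturbed, unperturbed, exc = np.arange(0, 3), np.arange(3, 6), np.arange(6, 10)
    trials = []
    for _ in range(n_trials):
        times, ids = [], []
        for c in range(10):
            n1 = int(base_rate + (step if c < 3 else 0.0))
            for t in (np.arange(int(base_rate)) + 0.5) * (1000.0 / base_rate):
                times.append(t); ids.append(c)
            for t in 1000.0 + (np.arange(n1) + 0.5) * (1000.0 / n1):
                times.append(t); ids.append(c)
        order = np.argsort(times)
        trials.append(spikes_from(np.asarray(times)[order],
                                  np.asarray(ids)[order]))
    return TrialResults(trials, perturbed, unperturbed, exc,
                        PerturbationProtocol(n_trials=n_trials), [])


class TestParadoxStatistic:
    def test_identical_windows_zero_delta(self):
        trials = _fixture_trials()
        rep = paradox_statistic(trials, (0, 1000), (0, 1000))
        assert all(v == 0.0 for v in rep.delta.values())

    def test_constructed_step_recovered_exactly(self):
        trials = _fixture_trials(step=2.0)
        rep = paradox_statistic(trials, (0, 1000), (1000, 2000), guard_band=0.0)
        assert rep.delta["I_perturbed"] == pytest.approx(2.0, abs=1e-9)
        assert rep.delta["E"] == pytest.approx(0.0, abs=1e-9)
        assert rep.isn_signature

    def test_sign_flip(self):
        trials = _fixture_trials(step=-2.0, base_rate=10.0)
        rep = paradox_statistic(trials, (0, 1000), (1000, 2000), guard_band=0.0)
        assert rep.delta["I_perturbed"] == pytest.approx(-2.0, abs=1e-9)
        assert not rep.isn_signature

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ProtocolError):
            paradox_statistic(_fixture_trials(), (0, 1500), (1000, 2000))

    def test_guard_band_preserves_window_durations(self):
        trials = _fixture_trials()
        with pytest.warns(UserWarning):
            rep = paradox_statistic(trials, (0, 1000), (1000, 2000),
                                    guard_band=100.0)
        b0, b1 = rep.windows["baseline"]
        p0, p1 = rep.windows["perturbation"]
        assert (b1 - b0) == pytest.approx(p1 - p0)
        assert p0 == pytest.approx(1100.0)


class TestConnectivitySummary:
    def test_hand_enumerated_toy(self):
        spec = {
            "populations": [
                {"name": "A", "size": 2, "role": "I"},
                {"name": "B", "size": 2, "role": "E"},
            ],
            "projections": [
                {"pre": "A", "post": "B", "weight": 0.2, "e_syn": -75.0},
            ],
        }
        s = connectivity_summary(make_toy_network(spec))
        i, j = s.populations.index("A"), s.populations.index("B")
        # 4 connections x 0.2 nS / 2 postsynaptic cells, inhibitory sign
        assert s.adjacency[i, j] == pytest.approx(-0.4)
        assert ("A", "B", 4) in s.chords

    def test_no_projections_zero_matrix(self):
        spec = {"populations": [{"name": "A", "size": 3}]}
        s = connectivity_summary(make_toy_network(spec))
        assert np.all(s.adjacency == 0.0)

    def test_default_network_inhibitory_column(self):
        net = build_isn_pointnet(seed=1)
        s = connectivity_summary(net)
        i, e = s.populations.index("I"), s.populations.index("E")
        # I->E: in-degree 200 x 0.2 nS onto every E cell, sign negative
        assert s.adjacency[i, e] == pytest.approx(-40.0)
        # I->I: in-degree 199 x 0.2 nS
        assert s.adjacency[i, i] == pytest.approx(-(200 * 200 - 200) * 0.2 / 200)
        assert s.adjacency[e, e] > 0

    def test_population_order_invariance(self):
        spec = {
            "populations": [
                {"name": "A", "size": 2, "role": "E"},
                {"name": "B", "size": 3, "role": "I"},
            ],
            "projections": [
                {"pre": "A", "post": "B", "weight": 0.1, "e_syn": 0.0},
                {"pre": "B", "post": "A", "weight": 0.2, "e_syn": -75.0},
            ],
        }
        spec_rev = {
            "populations": list(reversed(spec["populations"])),
            "projections": spec["projections"],
        }
        s1 = connectivity_summary(make_toy_network(spec))
        s2 = connectivity_summary(make_toy_network(spec_rev))
        for pre in ("A", "B"):
            for post in ("A", "B"):
                v1 = s1.adjacency[s1.populations.index(pre),
                                  s1.populations.index(post)]
                v2 = s2.adjacency[s2.populations.index(pre),
                                  s2.populations.index(post)]
                assert v1 == pytest.approx(v2)

    def test_graph_minima_applied(self):
        spec = {
            "populations": [
                {"name": "A", "size": 1, "role": "E"},
                {"name": "B", "size": 1000, "role": "E"},
            ],
            "projections": [
                {"pre": "A", "post": "B", "weight": 1e-6, "e_syn": 0.0},
            ],
        }
        s = connectivity_summary(make_toy_network(spec), min_node_size=0.05,
                                 min_edge_width=0.1)
        assert min(n["size"] for n in s.graph["nodes"]) >= 0.05
        assert all(e["width"] >= 0.1 for e in s.graph["edges"])


class TestWindowMeanRate:
    def test_arithmetic(self):
        sp = spikes_from([100, 200, 300, 1200], [0, 0, 1, 0], duration=2000.0)
        assert window_mean_rate(sp, [0, 1], 0, 1000) == pytest.approx(1.5)
        assert window_mean_rate(sp, [0, 1], 1000, 2000) == pytest.approx(0.5)
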