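"""Simulation-engine correctness: Poisson drive, integration fixed
points, spike handling, delivery, determinism and voltage clamp."""

import numpy as np
import pytest
from scipy import optimize, stats

from isnsim.engine import (
    CurrentInjection,
    SimulationConfig,
    VoltageClamp,
    poisson_train,
    run,
    voltage_clamp,
)
from isnsim.errors import InvalidParameterError, ProtocolError
from isnsim.model_core import ExpIFParams, exp_if_derivative
from isnsim.network import (
    BackgroundInput,
    NetworkModel,
    Population,
    build_isn_pointnet,
)
from isnsim.synthetic import make_toy_network
from isnsim.analysis import window_mean_rate


def single_cell_net(params=None, backgrounds=()):
    pop = Population("cell", 1, "expif", params or ExpIFParams())
    return NetworkModel([pop], [], list(backgrounds), seed=0)


class TestPoissonTrain:
    def test_zero_rate_empty(self):
        assert len(poisson_train(0.0, 0.0, 1000.0, seed=1)) == 0

    def test_count_within_four_se(self):
        # 9600 Hz over 10 s: expectation 96000, Poisson SD sqrt(96000)
        times = poisson_train(9600.0, 0.0, 10_000.0, seed=2)
        assert abs(len(times) - 96_000) < 4 * np.sqrt(96_000)
        assert np.all(np.diff(times) > 0)

    def test_isi_distribution_ks(self):
        # exponential ISIs: KS at alpha=0.01 should pass in >= 95/100 seeds
        passed = 0
        for seed in range(100):
            t = poisson_train(1000.0, 0.0, 1000.0, seed=seed)
            isis = np.diff(t)
            p = stats.kstest(isis, "expon", args=(0, 1.0)).pvalue
            passed += p > 0.01
        assert passed >= 95

    def test_determinism_and_validation(self):
        assert np.array_equal(poisson_train(500.0, 0, 100, seed=5),
                              poisson_train(500.0, 0, 100, seed=5))
        with pytest.raises(InvalidParameterError):
            poisson_train(-1.0, 0, 100)
        with pytest.raises(InvalidParameterError):
            poisson_train(100.0, 50, 50)


class TestRun:
    def test_silent_without_input(self):
        net = build_isn_pointnet({"n_exc": 20, "n_inh": 5, "bg_rate": 0.0}, seed=1)
        res = run(net, SimulationConfig(duration=200.0, seed=1, init_jitter=0.0))
        assert res.spikes.n_spikes == 0

    def test_subthreshold_fixed_point_vs_root_finding(self):
        p = ExpIFParams()
        I = 120.0  # pA, subthreshold
        net = single_cell_net(p)
        sim = SimulationConfig(dt=0.1, duration=500.0, seed=0, init_jitter=0.0,
                               record_traces=[("cell", 0)])
        res = run(net, sim, [CurrentInjection("cell", None, I, 0.0, 500.0)])
        v_end = res.traces.values[-1, 0]
        v_star = optimize.brentq(
            lambda v: exp_if_derivative(v, p, I_inj=I), -75.0, p.V_T - 1.0)
        assert abs(v_end - v_star) < 0.1

    def test_refractory_gap_enforced(self):
        net = single_cell_net()
        sim = SimulationConfig(dt=0.1, duration=500.0, seed=0, init_jitter=0.0)
        res = run(net, sim, [CurrentInjection("cell", None, 600.0, 0.0, 500.0)])
        t = res.spikes.times
        assert len(t) > 5
        assert np.all(np.diff(t) >= ExpIFParams().t_ref - 1e-9)

    def test_spike_times_within_duration_and_sorted(self, small_net):
        res = run(small_net, SimulationConfig(duration=300.0, seed=2))
        t = res.spikes.times
        assert np.all((t >= 0) & (t <= 300.0))
        assert np.all(np.diff(t) >= 0)

    def test_determinism(self, small_net):
        a = run(small_net, SimulationConfig(duration=300.0, seed=9))
        b = run(small_net, SimulationConfig(duration=300.0, seed=9))
        assert np.array_equal(a.spikes.times, b.spikes.times)
        assert np.array_equal(a.spikes.ids, b.spikes.ids)

    def test_synaptic_delivery_through_projection(self):
        # a forced presynaptic spike must depolarize the target after the
        # projection delay
        spec = {
            "populations": [
                {"name": "pre", "size": 1, "role": "E"},
                {"name": "post", "size": 1, "role": "E"},
            ],
            "projections": [
                {"pre": "pre", "post": "post", "weight": 5.0, "e_syn": 0.0},
            ],
        }
        net = make_toy_network(spec)
        sim = SimulationConfig(dt=0.1, duration=200.0, seed=0, init_jitter=0.0,
                               record_traces=[("post", 0)])
        res = run(net, sim, [CurrentInjection("pre", None, 1000.0, 20.0, 30.0)])
        pre_spikes = res.spikes.for_population("pre").times
        assert len(pre_spikes) >= 1
        v = res.traces.values[:, 0]
        t = res.traces.times
        first = pre_spikes[0]
        # before delivery the target sits at rest (the exp-I&F spike-
        # initiation current leaves a tiny sub-mV offset above E_L)
        assert np.all(v[t <= first + 0.9] == pytest.approx(-70.0, abs=0.01))
        assert v[np.searchsorted(t, first + 5.0)] > -69.5

    def test_background_drives_depolarization(self):
        bg = BackgroundInput("cell", 9600.0, 0.1)
        net = single_cell_net(backgrounds=[bg])
        sim = SimulationConfig(duration=1000.0, seed=3, init_jitter=0.0)
        res = run(net, sim)
        assert res.spikes.n_spikes > 0  # mean drive is suprathreshold

    def test_full_isn_network_sustains_activity(self, calibrated_isn):
        net, _, _ = calibrated_isn
        res = run(net, SimulationConfig(duration=1000.0, seed=5))
        sl = res.spikes.pop_slices
        for name in ("E", "I"):
            cells = np.arange(*sl[name])
            assert window_mean_rate(res.spikes, cells, 200, 1000) > 0.5

    def test_dt_convergence_of_population_rates(self):
        net = build_isn_pointnet(seed=4)
        rates = {}
        for dt in (0.1, 0.05):
            res = run(net, SimulationConfig(dt=dt, duration=1000.0, seed=6))
            rates[dt] = window_mean_rate(
                res.spikes, np.arange(net.n_cells), 200, 1000)
        assert rates[0.05] > 0
        assert abs(rates[0.1] - rates[0.05]) / rates[0.05] < 0.05

    def test_intervention_window_validated(self, small_net):
        sim = SimulationConfig(duration=100.0, seed=0)
        with pytest.raises(ProtocolError):
            run(small_net, sim, [CurrentInjection("E", None, 10.0, 0.0, 500.0)])

    def test_bg_window_counts_match_rate(self):
        bg = BackgroundInput("cell", 9600.0, 0.1)
        net = single_cell_net(backgrounds=[bg])
        sim = SimulationConfig(duration=2000.0, seed=8, init_jitter=0.0,
                               record_background_windows=[(0.0, 2000.0)])
        res = run(net, sim)
        (window, counts), = res.bg_counts
        expect = 9600.0 * 2.0
        assert abs(counts[0] - expect) < 4 * np.sqrt(expect)


class TestVoltageClamp:
    def test_clamp_at_rest_zero_current(self):
        p = ExpIFParams(Delta_T=0.0)
        net = single_cell_net(p)
        sim = SimulationConfig(duration=100.0, seed=0, init_jitter=0.0)
        (rec,) = voltage_clamp(net, sim, [("cell", 0)], p.E_L)
        assert np.allclose(rec.current[1:], 0.0, atol=1e-9)

    def test_clamp_at_zero_nulls_excitatory_component(self):
        # only excitatory (E_syn = 0 mV) background; holding at 0 mV
        bg = BackgroundInput("cell", 9600.0, 0.1, e_syn=0.0, tau_syn=5.0)
        net = single_cell_net(ExpIFParams(Delta_T=0.0), backgrounds=[bg])
        sim = SimulationConfig(duration=500.0, seed=1, init_jitter=0.0)
        (rec,) = voltage_clamp(net, sim, [("cell", 0)], 0.0)
        exc = rec.components[(0.0, 5.0)]
        assert np.all(exc == 0.0)
        # the leak still flows: holding away from E_L costs current
        assert np.abs(rec.current[1:]).min() > 0

    def test_inhibitory_pulse_clamp_matches_analytic(self):
        # one forced inhibitory spike onto a cell clamped at -80 mV:
        # synaptic clamp-current component is w exp(-(t-t0)/tau) * (-80+75)
        spec = {
            "populations": [
                {"name": "inh", "size": 1, "role": "I"},
                {"name": "target", "size": 1, "role": "E"},
            ],
            "projections": [
                {"pre": "inh", "post": "target", "weight": 2.0, "e_syn": -75.0,
                 "tau_syn": 10.0, "delay": 1.0},
            ],
        }
        net = make_toy_network(spec)
        sim = SimulationConfig(dt=0.1, duration=300.0, seed=0, init_jitter=0.0)
        clamp = VoltageClamp("target", 0, -80.0)
        drive = CurrentInjection("inh", None, 8000.0, 50.0, 52.5)
        res = run(net, sim, [clamp, drive])
        (rec,) = res.clamps
        inh_spikes = res.spikes.for_population("inh").times
        assert len(inh_spikes) == 1
        t0 = inh_spikes[0] + 1.0  # delivery after the 1 ms delay
        comp = rec.components[(-75.0, 10.0)]
        t = rec.times
        sel = t > t0 + 0.1
        expected = 2.0 * np.exp(-(t[sel] - t0) / 10.0) * (-75.0 - (-80.0))
        assert np.allclose(comp[sel], expected, rtol=0.02, atol=0.05)

    def test_clamped_cell_never_spikes(self):
        bg = BackgroundInput("cell", 20_000.0, 0.5)
        net = single_cell_net(backgrounds=[bg])
        sim = SimulationConfig(duration=300.0, seed=2, init_jitter=0.0)
        res = run(net, sim, [VoltageClamp("cell", 0, 0.0)])
        assert res.spikes.n_spikes == 0

    def test_unknown_target_rejected(self, small_net):
        sim = SimulationConfig(duration=50.0, seed=0)
        with pytest.raises(ProtocolError):
            run(small_net, sim, [VoltageClamp("E", 0, -80.0, compartment=3)])
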