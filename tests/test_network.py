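"""Simulator mechanics: wiring contracts, exact integration, determinism,
refractoriness, drive calibration, and the stimulation protocols."""

import numpy as np
import pytest

from cortexval.network import (
    BrnConfig,
    RecordingSpec,
    build_network,
    excitability_test,
    external_rate_threshold,
    parameter_scan,
    preset,
    ramp_drive,
    simulate,
    table3_weak,
)
from cortexval.structural import MembraneParams, SynapseKernel, psp_max


def _quiet_cfg(Ne=50, Ni=10, theta=0.0, **kw):
    return BrnConfig(
        Ne=Ne, Ni=Ni, connectivity={"p": 0.0}, J=6.3, g=5.0,
        membrane=MembraneParams(), syn=SynapseKernel(J=6.3, tau_syn=5.0, delay=1.5),
        theta=theta, **kw,
    )


class TestWiring:
    def test_uniform_in_degrees_exact(self, tiny_cfg, tiny_net):
        de, di = tiny_net.in_degrees()
        assert (de == round(tiny_cfg.Ne * 0.1)).all()
        assert (di == round(tiny_cfg.Ni * 0.1)).all()

    def test_no_autapses_no_multapses(self, tiny_net):
        for s in range(0, tiny_net.N, 37):
            tg, _ = tiny_net.out_edges(s)
            assert s not in tg
            assert len(np.unique(tg)) == len(tg)

    def test_inhibitory_weights(self, tiny_cfg, tiny_net):
        tg, w = tiny_net.out_edges(tiny_net.Ne + 1)  # an inhibitory source
        assert (w == -tiny_cfg.g * tiny_cfg.J).all()
        tg, w = tiny_net.out_edges(0)  # an excitatory source
        assert (w == tiny_cfg.J).all()

    def test_per_type_in_degrees(self):
        cfg = table3_weak()
        cfg = BrnConfig(**{**cfg.__dict__, "Ne": 480, "Ni": 120})  # downscaled, same p
        net = build_network(cfg, seed=0)
        de, di = net.in_degrees()
        assert (de[: cfg.Ne] == round(480 * 0.07)).all()  # e<-e
        assert (de[cfg.Ne :] == round(480 * 0.24)).all()  # i<-e
        assert (di[: cfg.Ne] == round(120 * 0.24)).all()  # e<-i

    def test_seed_determinism(self, tiny_cfg):
        a = build_network(tiny_cfg, seed=3)
        b = build_network(tiny_cfg, seed=3)
        assert (a.targets == b.targets).all() and (a.weights == b.weights).all()

    def test_excessive_in_degree_rejected(self):
        cfg = BrnConfig(Ne=10, Ni=5, connectivity={"p": 1.0}, J=1.0)
        with pytest.raises(ValueError, match="in-degree"):
            build_network(cfg, seed=0)


class TestExternalRate:
    def test_closed_form_value(self):
        assert external_rate_threshold(preset("table2")) == pytest.approx(
            20.0 * 100.0 / (6.3 * 5.0 * 20.0)
        )

    def test_doubling_j_halves_rate(self):
        cfg = preset("table2")
        cfg2 = BrnConfig(**{**cfg.__dict__, "J": 2 * cfg.J})
        assert external_rate_threshold(cfg2) == pytest.approx(
            external_rate_threshold(cfg) / 2.0
        )

    def test_stationary_mean_reaches_threshold(self):
        """Driving passive neurons at exactly nu brings the mean potential
        to the nominal threshold (checked with the threshold moved away)."""
        nominal = MembraneParams()  # Vth = 20 mV
        lifted = MembraneParams(Vth=200.0, Vr=10.0)
        cfg = BrnConfig(
            Ne=50, Ni=1, connectivity={"p": 0.0}, J=6.3,
            membrane=lifted, syn=SynapseKernel(J=6.3, tau_syn=5.0, delay=1.5),
            theta=nominal.Vth / lifted.Vth,  # drive at the nominal nu
        )
        net = build_network(cfg, seed=0)
        res = simulate(net, cfg, 6000.0, seed=0, record=RecordingSpec(neuron_ids=list(range(50))))
        means = [tr.window(1000.0, 6000.0).mean() for tr in res.vm_traces.values()]
        assert np.mean(means) == pytest.approx(nominal.Vth, rel=0.02)


class TestIntegration:
    def test_zero_drive_stays_silent(self):
        cfg = _quiet_cfg()
        net = build_network(cfg, seed=0)
        res = simulate(net, cfg, 500.0, seed=0, record=None, init="rest")
        assert sum(t.size for t in res.raster.trains.values()) == 0

    def test_single_psc_matches_beta_function_peak(self):
        """Propagator correctness: one injected PSC reproduces the analytic
        PSP peak to 1e-4 relative."""
        cfg = _quiet_cfg()
        net = build_network(cfg, seed=0)
        res = simulate(
            net, cfg, 60.0, seed=0,
            record=RecordingSpec(neuron_ids=[0], vm_dt=cfg.dt),
            injections=[(5.0, 0, cfg.J)], init="rest",
        )
        vm = res.vm_traces[0].values
        expected = psp_max(cfg.membrane, cfg.syn)
        assert vm.max() - cfg.membrane.Vrest == pytest.approx(expected, rel=1e-4)

    def test_refractoriness_bounds_isi(self):
        cfg = BrnConfig(
            Ne=30, Ni=5, connectivity={"p": 0.0}, J=50.0,
            membrane=MembraneParams(tau_ref=2.0),
            syn=SynapseKernel(J=50.0, tau_syn=5.0, delay=1.5), theta=3.0,
        )
        net = build_network(cfg, seed=0)
        res = simulate(net, cfg, 2000.0, seed=1, record=None)
        for t in res.raster.trains.values():
            if t.size >= 2:
                assert np.diff(t).min() >= cfg.membrane.tau_ref + cfg.dt - 1e-9

    def test_spike_delivery_after_delay(self):
        """A presynaptic spike changes the target's synaptic current exactly
        one delay later."""
        cfg = BrnConfig(
            Ne=2, Ni=1, connectivity={"p": 0.0}, J=6.3, g=5.0,
            membrane=MembraneParams(), syn=SynapseKernel(J=6.3, tau_syn=5.0, delay=1.5),
            theta=0.0,
        )
        net = build_network(cfg, seed=0)
        # wire a single edge 0 -> 1 by hand
        net.indptr = np.array([0, 1, 1, 1], dtype=np.int64)
        net.targets = np.array([1], dtype=np.int32)
        net.weights = np.array([cfg.J])
        res = simulate(
            net, cfg, 50.0, seed=0,
            record=RecordingSpec(neuron_ids=[1], vm_dt=cfg.dt),
            injections=[(5.0, 0, 2000.0)], init="rest",  # force neuron 0 to spike
        )
        t_spike = res.raster.trains[0][0]
        ie = res.exc_current_traces[1]
        onset = ie.times()[np.flatnonzero(ie.values > 0)[0]]
        assert onset == pytest.approx(t_spike + cfg.syn.delay, abs=cfg.dt)

    def test_simulation_determinism(self, tiny_cfg, tiny_net):
        a = simulate(tiny_net, tiny_cfg, 400.0, seed=5, record=None)
        b = simulate(tiny_net, tiny_cfg, 400.0, seed=5, record=None)
        for nid in a.raster.trains:
            assert (a.raster.trains[nid] == b.raster.trains[nid]).all()

    def test_spike_times_on_grid(self, tiny_cfg, tiny_net):
        res = simulate(tiny_net, tiny_cfg, 300.0, seed=2, record=None)
        for t in res.raster.trains.values():
            assert np.allclose(t / tiny_cfg.dt, np.round(t / tiny_cfg.dt), atol=1e-9)


class TestProtocols:
    def test_constant_ramp_equals_simulate(self, tiny_cfg, tiny_net):
        a = simulate(tiny_net, tiny_cfg, 500.0, seed=4, record=None)
        b = ramp_drive(tiny_net, tiny_cfg, [tiny_cfg.theta], segment=500.0, seed=4, record=None)
        for nid in a.raster.trains:
            assert (a.raster.trains[nid] == b.raster.trains[nid]).all()

    def test_ramp_reduces_mean_drive_current(self, tiny_cfg, tiny_net):
        res = ramp_drive(
            tiny_net, tiny_cfg, [1.5, 1.2, 0.9], segment=400.0, seed=4,
            record=RecordingSpec(neuron_ids=list(range(10))),
        )
        means = []
        for k in range(3):
            seg = [tr.window(400.0 * k, 400.0 * (k + 1)).mean()
                   for tr in res.exc_current_traces.values()]
            means.append(np.mean(seg))
        assert means[0] > means[1] > means[2]

    def test_unconnected_network_dies_immediately(self):
        cfg = _quiet_cfg(theta=1.5)
        net = build_network(cfg, seed=0)
        survival, _ = excitability_test(net, cfg, warmup=600.0, tail=400.0, seed=0)
        assert survival < 100.0  # on the scale of a membrane time constant

    def test_parameter_scan_trivial_grid(self, tiny_cfg):
        table = parameter_scan(
            tiny_cfg, (1.0,), (1.0,), (1.0,), seeds=(0, 1), duration=1000.0,
            warmup=500.0, record=RecordingSpec(n_vm=5),
        )
        assert len(table) == 2
        assert not table["diverged"].any()
        assert {"rate_e", "cc", "cv_vm", "cv_ie"} <= set(table.columns)


class TestPresets:
    @pytest.mark.parametrize("name, J, Ne, delay, tau_ref", [
        ("table2", 6.3, 8000, 1.5, 2.0),
        ("table4", 25.4, 8000, 0.55, 0.5),
        ("table3-weak", 4.7, 4800, 1.5, 2.0),
        ("table3-strong", 28.4, 4800, 0.55, 0.5),
    ])
    def test_preset_parameters(self, name, J, Ne, delay, tau_ref):
        cfg = preset(name)
        assert cfg.J == J and cfg.Ne == Ne
        assert cfg.syn.delay == delay and cfg.membrane.tau_ref == tau_ref
        assert cfg.theta == 1.5 and cfg.g == 5.0 and cfg.syn.tau_syn == 5.0
        assert cfg.membrane.Vth == 20.0 and cfg.membrane.Vr == 10.0

    def test_table3_membrane_and_connectivity(self):
        cfg = preset("table3-weak")
        assert cfg.membrane.tau_m == 6.7
        assert cfg.connectivity == {"e<-e": 0.07, "i<-e": 0.24, "e<-i": 0.24, "i<-i": 0.24}

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset("table9")
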