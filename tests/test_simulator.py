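"""Network integration: synapse arithmetic, determinism, stability, stimulus."""

import numpy as np
import pytest

from cholnet import (DriveConfig, NoiseConfig, SimConfig, build_default_topology,
                     run_simulation)
from cholnet.gks_map import generate_map, homogeneous_map
from cholnet.model_core import NeuronParams, steady_state_gates
from cholnet.simulator import (SpikeRaster, initial_states, mean_rate,
                               read_raster, synaptic_current,
                               stimulus_experiment, write_raster)
from cholnet.topology import SynapseParams
from cholnet import _kernels


class TestSynapticCurrent:
    SYN = SynapseParams()

    def test_inhibitory_current_vanishes_at_reversal(self):
        presyn = [(0.04, [1.0, 5.0, 9.0], True)]
        assert synaptic_current(-75.0, presyn, 10.0, self.SYN) == 0.0

    def test_single_excitatory_spike_drives_depolarization(self):
        presyn = [(0.01, [10.0], False)]
        I = synaptic_current(-60.0, presyn, 10.0 + 1e-12, self.SYN)
        assert I == pytest.approx(0.01 * (-60.0), rel=1e-6)

    def test_kernel_decays_by_e_per_time_constant(self):
        presyn = [(0.01, [0.0], False)]
        I0 = synaptic_current(-60.0, presyn, 1e-12, self.SYN)
        I3 = synaptic_current(-60.0, presyn, 3.0, self.SYN)
        assert I3 / I0 == pytest.approx(np.exp(-1.0), rel=1e-9)


class TestMicroNetworkEquivalence:
    def test_auxiliary_variables_match_printed_sum(self):
        """On a 3-cell network (two driven sources -> one target), the kernel's
        decay-variable synapses reproduce a reference integrator that evaluates
        the printed exponential-sum synaptic current directly."""
        params = NeuronParams()
        dt, T = 0.05, 500.0
        w20, w21 = 0.02, 0.03   # cell0 excitatory, cell1 inhibitory onto cell2
        # kernel run: 2 "E" sources (only cell0's weight is excitatory-indexed)
        W = np.zeros((3, 3))
        W[2, 0] = w20
        W[2, 1] = w21
        gks = np.array([0.0, 0.0, 1.5])
        drive = np.array([1.5, 2.0, 0.0])
        V0 = np.array([-65.0, -70.0, -62.0])
        _, h0, n0, z0 = steady_state_gates(V0)
        st_, si_, Vrec, status = _kernels.run_network(
            V0.copy(), h0.copy(), n0.copy(), z0.copy(), gks,
            np.ascontiguousarray(W.T), 1,   # cell0 excitatory, cell1 inhibitory
            3.0, 3.0, 0.0, -75.0, drive, False, 0.0, 0.0, 0.0, 0,
            dt, int(T / dt),
            params.C, params.gNa, params.gKdr, params.gL,
            params.VNa, params.VK, params.VL, params.tau_z,
            np.array([2], np.int64), 1, 10_000)
        assert status == 0
        src_spikes = {0: st_[si_ == 0], 1: st_[si_ == 1]}

        # reference: scalar RK4 for cell2 with Isyn evaluated from the printed
        # sum over the recorded source spike times at each RK4 stage time.
        # A spike registered at a step boundary starts contributing from that
        # boundary on, so each stage sums the spikes present at step start.
        def isyn(V, t_stage, t_step):
            tot = 0.0
            for j, (w, E) in ((0, (w20, 0.0)), (1, (w21, -75.0))):
                # half-step tolerance: spike timestamps accumulate as t + dt
                # and can differ from k*dt by one ULP
                past = src_spikes[j][src_spikes[j] <= t_step + dt / 2]
                s = np.sum(np.exp(-(t_stage - past) / 3.0))
                tot += w * s * (V - E)
            return tot

        def rhs(V, h, n, z, t, t_step):
            m = 1 / (1 + np.exp((-V - 30) / 9.5))
            hi = 1 / (1 + np.exp((V + 40.5) / 6))
            ni = 1 / (1 + np.exp((-V - 30) / 10))
            zi = 1 / (1 + np.exp((-V - 39) / 5))
            th = 0.37 + 2.78 / (1 + np.exp((V + 40.5) / 6))
            tn = 0.37 + 1.85 / (1 + np.exp((V + 27) / 15))
            dV = (-24 * m**3 * h * (V - 55) - 3 * n**4 * (V + 90)
                  - 1.5 * z * (V + 90) - 0.02 * (V + 60) - isyn(V, t, t_step))
            return dV, (hi - h) / th, (ni - n) / tn, (zi - z) / 75.0

        V, h, n, z = V0[2], float(h0[2]), float(n0[2]), float(z0[2])
        trace = [V]
        for step in range(int(T / dt)):
            t = step * dt
            k1 = rhs(V, h, n, z, t, t)
            k2 = rhs(V + dt / 2 * k1[0], h + dt / 2 * k1[1],
                     n + dt / 2 * k1[2], z + dt / 2 * k1[3], t + dt / 2, t)
            k3 = rhs(V + dt / 2 * k2[0], h + dt / 2 * k2[1],
                     n + dt / 2 * k2[2], z + dt / 2 * k2[3], t + dt / 2, t)
            k4 = rhs(V + dt * k3[0], h + dt * k3[1],
                     n + dt * k3[2], z + dt * k3[3], t + dt, t)
            V += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            h += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            n += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            z += dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            trace.append(V)
        assert np.max(np.abs(np.array(trace) - Vrec[0])) < 1e-6


class TestRunSimulation:
    def test_seed_determinism_bit_identical(self, topology):
        gmap = generate_map([(10, 10)], target_radius=4.2)
        cfg = SimConfig(duration=1200.0, transient=200.0, seed=5)
        noise = NoiseConfig(enabled=True)
        r1, _ = run_simulation(topology, gmap, DriveConfig(), noise, cfg=cfg)
        r2, _ = run_simulation(topology, gmap, DriveConfig(), noise, cfg=cfg)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.ids, r2.ids)

    def test_raster_invariants(self, topology):
        gmap = generate_map([(10, 10)], target_radius=4.2)
        r, _ = run_simulation(topology, gmap, DriveConfig(),
                              cfg=SimConfig(duration=1500.0, seed=2))
        assert np.all((r.ids >= 1) & (r.ids <= 500))
        assert np.all((r.times >= 0) & (r.times <= r.duration))
        for cid in np.unique(r.ids)[:25]:
            t = r.spikes_of(int(cid))
            assert np.all(np.diff(t) >= _kernels.SPIKE_LOCKOUT - 1e-9)

    def test_undriven_network_is_silent(self, topology):
        gmap = homogeneous_map(1.5)
        r, _ = run_simulation(topology, gmap,
                              DriveConfig(I_base=0.0),
                              cfg=SimConfig(duration=800.0, transient=300.0, seed=3))
        assert len(r.after(300.0).times) == 0

    def test_population_rate_stable_under_step_halving(self, topology):
        gmap = generate_map([(10, 10)], target_radius=4.2)
        rates = []
        for dt in (0.05, 0.025):
            r, _ = run_simulation(topology, gmap, DriveConfig(),
                                  cfg=SimConfig(dt=dt, duration=2000.0, seed=4))
            rates.append(mean_rate(r, np.arange(1, 401)))
        assert abs(rates[1] - rates[0]) / rates[0] < 0.03

    def test_voltage_recording(self, topology):
        gmap = homogeneous_map(0.2)
        cfg = SimConfig(duration=600.0, seed=1, record_voltage=(1, 250),
                        record_every=10)
        _, volts = run_simulation(topology, gmap, DriveConfig(), cfg=cfg)
        assert set(volts) == {1, 250}
        assert len(volts[1]) == 600.0 / 0.05 // 10 + 1
        assert np.all(np.isfinite(volts[1]))

    def test_mismatched_map_rejected(self, topology):
        from cholnet.gks_map import GKsMap
        bad = GKsMap(E_values=np.full((10, 10), 1.0),
                     I_values=np.full((5, 5), 1.0))
        with pytest.raises(ValueError):
            run_simulation(topology, bad, DriveConfig(),
                           cfg=SimConfig(duration=500.0))

    def test_target_drive_validation(self):
        with pytest.raises(ValueError):
            DriveConfig(target_ids=(450,)).per_cell(500, 400)


class TestStimulus:
    def test_gating_signs(self, topology):
        """Stimulated cells inside a hotspot respond above the no-modulation
        control; outside, below it (the attention-gating signature)."""
        gmap = generate_map([(10, 10)], target_radius=5.0)
        homog = homogeneous_map(1.5)
        from cholnet.experiments import _disk_ids
        cfg = SimConfig(duration=2500.0, seed=31)
        noise = NoiseConfig(enabled=True)
        inside = stimulus_experiment(topology, gmap, homog,
                                     _disk_ids((10, 10), 2.0),
                                     cfg=cfg, noise=noise)
        outside = stimulus_experiment(topology, gmap, homog,
                                      _disk_ids((2, 2), 2.0),
                                      cfg=cfg, noise=noise)
        assert inside["relative_change"] > 0
        assert outside["relative_change"] < 0

    def test_empty_target_rejected(self, topology):
        with pytest.raises(ValueError):
            stimulus_experiment(topology, homogeneous_map(1.5),
                                homogeneous_map(1.5), ())


def test_raster_round_trip(tmp_path):
    r = SpikeRaster(times=np.array([10.0, 12.5, 900.0]),
                    ids=np.array([1, 450, 399]), duration=1000.0,
                    transient=100.0)
    path = tmp_path / "raster.tsv"
    write_raster(r, path)
    back = read_raster(path)
    assert np.allclose(back.times, r.times)
    assert np.array_equal(back.ids, r.ids)
    assert back.duration == r.duration
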