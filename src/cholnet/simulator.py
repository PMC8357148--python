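"""Full-network simulation: 400 E + 100 I Hodgkin-Huxley cells with per-cell
gKs from a spatial map, exponential-decay conductance synapses, constant
external drive and optional Poisson current-pulse noise.

All simulations are deterministic given their seeds.  Initial membrane
potentials are drawn uniformly from [-70, -55] mV with gates at their
voltage steady state; noise pulse trains are per-cell independent Poisson
processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .gks_map import GKsMap
from .model_core import NeuronParams, NeuronState, steady_state_gates
from .topology import NetworkTopology, SynapseParams


@dataclass(frozen=True)
class DriveConfig:
    """Constant external drive (uA/cm^2): ``I_base`` to every E cell (the
    "E-cell external current"), ``I_base_I`` to I cells (0 by default — I
    cells fire only when recruited by E input, the PING configuration), and
    optionally ``I_target`` to a targeted E subset (a "stimulus")."""

    I_base: float = 3.0
    I_base_I: float = 0.0
    target_ids: tuple[int, ...] = ()    # emitted (1-based) E-cell IDs
    I_target: float = 3.0

    def per_cell(self, n_cells: int, n_exc: int) -> np.ndarray:
        for v in (self.I_base, self.I_base_I, self.I_target):
            if not np.isfinite(v):
                raise ValueError("drives must be finite")
        drive = np.full(n_cells, self.I_base_I)
        drive[:n_exc] = self.I_base
        for cid in self.target_ids:
            if not 1 <= cid <= n_exc:
                raise ValueError(f"target ID {cid} is not an E cell")
            drive[cid - 1] = self.I_target
        return drive


@dataclass(frozen=True)
class NoiseConfig:
    """Poisson current-pulse noise: per-cell pulses of ``amp`` uA/cm^2 lasting
    ``width`` ms at rate ``rate`` per ms (default 1/150); overlapping pulses sum."""

    enabled: bool = False
    rate: float = 1.0 / 150.0
    amp: float = 6.0
    width: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rate, self.amp, self.width) < 0:
            raise ValueError("rate, amp and width must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Integration step, total duration, discarded transient (ms) and seed."""

    dt: float = 0.05
    duration: float = 5500.0
    transient: float = 500.0
    seed: int = 0
    record_voltage: tuple[int, ...] = ()   # emitted IDs to record, () = none
    record_every: int = 20                 # record every k-th step

    def __post_init__(self) -> None:
        if not 0.0 < self.dt <= 0.1:
            raise ValueError("dt must lie in (0, 0.1] ms")
        if not self.duration > self.transient >= 0.0:
            raise ValueError("need duration > transient >= 0")


@dataclass
class SpikeRaster:
    """Timestamped spike events; IDs are 1-based (E cells 1..400, I 401..500)."""

    times: np.ndarray          # ms, ordered
    ids: np.ndarray            # int, 1-based
    duration: float            # ms
    n_exc: int = 400
    n_cells: int = 500
    transient: float = 0.0     # suggested analysis cutoff, ms
    meta: dict = field(default_factory=dict)

    def population(self, which: str = "E") -> "SpikeRaster":
        if which == "E":
            m = self.ids <= self.n_exc
        elif which == "I":
            m = self.ids > self.n_exc
        else:
            m = np.ones(len(self.ids), bool)
        return SpikeRaster(self.times[m], self.ids[m], self.duration,
                           self.n_exc, self.n_cells, self.transient, self.meta)

    def spikes_of(self, cid: int) -> np.ndarray:
        return self.times[self.ids == cid]

    def after(self, t0: float) -> "SpikeRaster":
        m = self.times >= t0
        return SpikeRaster(self.times[m], self.ids[m], self.duration,
                           self.n_exc, self.n_cells, self.transient, self.meta)


def initial_states(n_cells: int, seed: int,
                   v_range: tuple[float, float] = (-70.0, -55.0)):
    """Random initial conditions: V uniform in ``v_range``, gates at their
    steady state for the drawn V."""
    rng = np.random.default_rng(seed)
    V = rng.uniform(v_range[0], v_range[1], n_cells)
    _, h, n, z = steady_state_gates(V)
    return V, h.copy(), n.copy(), z.copy()


def synaptic_current(V_i: float, presyn: list, t: float, syn: SynapseParams) -> float:
    """Direct evaluation of the synaptic current onto one cell (uA/cm^2).

    ``presyn`` is a list of (weight, spike_times, is_inhibitory) per source;
    each past spike contributes weight * exp(-(t - t_k)/tau) * (V_i - E_syn).
    This closed-form sum is the reference the simulator's auxiliary-variable
    scheme reproduces; it is exposed for tests and micro-network checks.
    """
    total = 0.0
    for weight, spike_times, is_inh in presyn:
        E_syn = syn.E_inh if is_inh else syn.E_exc
        tau = syn.tau_inh if is_inh else syn.tau_exc
        for tk in spike_times:
            if t > tk:
                total += weight * np.exp(-(t - tk) / tau) * (V_i - E_syn)
    return total


def run_simulation(topo: NetworkTopology, gmap: GKsMap,
                   drive: DriveConfig = DriveConfig(),
                   noise: NoiseConfig = NoiseConfig(),
                   syn: SynapseParams = SynapseParams(),
                   cfg: SimConfig = SimConfig(),
                   params: NeuronParams = NeuronParams()):
    """Integrate the network and return (SpikeRaster, voltage_record).

    ``voltage_record`` is a dict {emitted_id: V samples} on a grid of spacing
    ``cfg.dt * cfg.record_every`` (empty if no cells were requested).
    """
    N = topo.geometry.n_cells
    n_exc = topo.geometry.n_exc
    gks = gmap.per_cell()
    if gks.shape[0] != N:
        raise ValueError("gKs map size does not match the topology")
    V, h, n, z = initial_states(N, cfg.seed)
    WT = np.ascontiguousarray(topo.w.T)
    rec_idx = np.array([cid - 1 for cid in cfg.record_voltage], dtype=np.int64)
    n_steps = int(round(cfg.duration / cfg.dt))
    spike_cap = int(N * cfg.duration * 0.35) + 1000  # ~350 Hz/cell headroom
    spike_t, spike_i, Vrec, status = _kernels.run_network(
        V, h, n, z, gks, WT, n_exc,
        syn.tau_exc, syn.tau_inh, syn.E_exc, syn.E_inh,
        drive.per_cell(N, n_exc), noise.enabled, noise.rate, noise.amp,
        noise.width, noise.seed if noise.seed else cfg.seed + 10_000,
        cfg.dt, n_steps,
        params.C, params.gNa, params.gKdr, params.gL,
        params.VNa, params.VK, params.VL, params.tau_z,
        rec_idx, cfg.record_every, spike_cap)
    if status == _kernels.STATUS_BLOWUP:
        raise FloatingPointError(
            f"numerical blow-up (|V| > {_kernels.BLOWUP_MV} mV) near "
            f"t = {spike_t[-1] if len(spike_t) else 0.0:.1f} ms; reduce dt")
    if status == _kernels.STATUS_OVERFLOW:
        raise RuntimeError("spike buffer overflow: firing rates exceed 350 Hz/cell")
    raster = SpikeRaster(times=spike_t, ids=spike_i.astype(int) + 1,
                         duration=cfg.duration, n_exc=n_exc, n_cells=N,
                         transient=cfg.transient,
                         meta={"seed": cfg.seed, "dt": cfg.dt})
    voltages = {int(cid): Vrec[r] for r, cid in enumerate(cfg.record_voltage)}
    return raster, voltages


def integrate_single_cell(state: NeuronState, params: NeuronParams, gKs: float,
                          I_ext: float, duration: float, dt: float = 0.05) -> np.ndarray:
    """Integrate one isolated cell under constant drive; returns spike times (ms)."""
    V = np.array([state.V])
    h = np.array([state.h])
    n = np.array([state.n])
    z = np.array([state.z])
    WT = np.zeros((1, 1))
    spike_t, _, _, status = _kernels.run_network(
        V, h, n, z, np.array([gKs]), WT, 1,
        3.0, 3.0, 0.0, -75.0,
        np.array([I_ext]), False, 0.0, 0.0, 0.0, 0,
        dt, int(round(duration / dt)),
        params.C, params.gNa, params.gKdr, params.gL,
        params.VNa, params.VK, params.VL, params.tau_z,
        np.empty(0, np.int64), 1, int(duration * 0.4) + 100)
    if status != _kernels.STATUS_OK:
        raise FloatingPointError("single-cell integration failed")
    return spike_t


def record_single_cell_voltage(state: NeuronState, params: NeuronParams,
                               gKs: float, I_ext: float, duration: float,
                               dt: float = 0.05):
    """Voltage trace (t, V) of one isolated cell under constant drive."""
    V = np.array([state.V])
    h = np.array([state.h])
    n = np.array([state.n])
    z = np.array([state.z])
    _, _, Vrec, status = _kernels.run_network(
        V, h, n, z, np.array([gKs]), np.zeros((1, 1)), 1,
        3.0, 3.0, 0.0, -75.0,
        np.array([I_ext]), False, 0.0, 0.0, 0.0, 0,
        dt, int(round(duration / dt)),
        params.C, params.gNa, params.gKdr, params.gL,
        params.VNa, params.VK, params.VL, params.tau_z,
        np.array([0], np.int64), 1, int(duration * 0.4) + 100)
    if status != _kernels.STATUS_OK:
        raise FloatingPointError("single-cell integration failed")
    t = np.arange(Vrec.shape[1]) * dt
    return t, Vrec[0]


def mean_rate(raster: SpikeRaster, ids, t0: float | None = None,
              t1: float | None = None) -> float:
    """Mean firing rate (Hz) of the given emitted IDs over [t0, t1)."""
    t0 = raster.transient if t0 is None else t0
    t1 = raster.duration if t1 is None else t1
    ids = np.asarray(ids)
    m = np.isin(raster.ids, ids) & (raster.times >= t0) & (raster.times < t1)
    return float(np.sum(m)) / len(ids) / ((t1 - t0) / 1000.0)


def stimulus_experiment(topo: NetworkTopology, gmap_mod: GKsMap,
                        gmap_homog: GKsMap, target_ids,
                        I_base: float = 3.0, I_target: float = 4.5,
                        syn: SynapseParams = SynapseParams(),
                        cfg: SimConfig = SimConfig(),
                        noise: NoiseConfig = NoiseConfig(),
                        params: NeuronParams = NeuronParams()) -> dict:
    """Firing response of a stimulated E subset under spatial gKs modulation.

    Runs the stimulated network with the modulated map (the targeted cells may
    sit inside or outside a hotspot) and with the homogeneous control map, and
    returns the targeted set's mean rates plus the relative change
    (modulated - control) / control.
    """
    target_ids = tuple(int(i) for i in target_ids)
    if not target_ids:
        raise ValueError("target set is empty")
    drive = DriveConfig(I_base=I_base, target_ids=target_ids, I_target=I_target)
    raster_mod, _ = run_simulation(topo, gmap_mod, drive, noise, syn, cfg, params)
    raster_ctl, _ = run_simulation(topo, gmap_homog, drive, noise, syn, cfg, params)
    r_mod = mean_rate(raster_mod, target_ids)
    r_ctl = mean_rate(raster_ctl, target_ids)
    rel = (r_mod - r_ctl) / r_ctl if r_ctl > 0 else np.inf * np.sign(r_mod - r_ctl)
    return {"rate_modulated": r_mod, "rate_control": r_ctl,
            "relative_change": rel}


def write_raster(raster: SpikeRaster, path, header: dict | None = None) -> None:
    """Two-column delimited text (time_ms, neuron_ID) with a header block."""
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={raster.duration} n_exc={raster.n_exc} "
                 f"n_cells={raster.n_cells} transient_ms={raster.transient}\n")
        for k, v in (header or raster.meta).items():
            fh.write(f"# {k}={v}\n")
        fh.write("# time_ms\tneuron_id\n")
        for t, i in zip(raster.times, raster.ids):
            fh.write(f"{t:.3f}\t{i}\n")


def read_raster(path) -> SpikeRaster:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    for tok in first[1:].split():
        if "=" in tok:
            k, v = tok.split("=")
            meta[k] = float(v)
    data = np.loadtxt(path, comments="#", ndmin=2)
    times = data[:, 0] if data.size else np.empty(0)
    ids = data[:, 1].astype(int) if data.size else np.empty(0, int)
    return SpikeRaster(times=times, ids=ids, duration=meta["duration_ms"],
                       n_exc=int(meta["n_exc"]), n_cells=int(meta["n_cells"]),
                       transient=meta.get("transient_ms", 0.0))
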