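"""Single-neuron Hodgkin-Huxley dynamics with an M-type slow potassium current.

The neuron carries four currents: a fast inward Na+ current with instantaneous
activation (gate ``m``, inactivation gate ``h``), a delayed-rectifier K+ current
(gate ``n``), a slow low-threshold muscarine-sensitive K+ current (the M-current,
gate ``z``, maximal conductance ``gKs``), and an ohmic leak.  Acetylcholine acts
through muscarinic receptors to block the M-current, so ``gKs`` parameterizes the
local ACh level: 1.5 mS/cm^2 means no modulation, 0 means full blockade.  The
M-current produces spike-frequency adaptation (SFA) on the ~75 ms time scale of
its gate, which is the slow process behind the network theta rhythm.

Membrane potential is in mV, time in ms, currents in uA/cm^2, conductances in
mS/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

GKS_MAX = 1.5  # mS/cm^2, M-current conductance with no cholinergic modulation


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of the cortical neuron model."""

    C: float = 1.0        # membrane capacitance, uF/cm^2
    gNa: float = 24.0     # maximal Na+ conductance, mS/cm^2
    gKdr: float = 3.0     # maximal delayed-rectifier conductance, mS/cm^2
    gL: float = 0.02      # leak conductance, mS/cm^2
    VNa: float = 55.0     # Na+ reversal, mV
    VK: float = -90.0     # K+ reversal, mV
    VL: float = -60.0     # leak reversal, mV
    tau_z: float = 75.0   # M-current gate time constant, ms

    def __post_init__(self) -> None:
        if self.C <= 0 or self.tau_z <= 0:
            raise ValueError("C and tau_z must be positive")
        if min(self.gNa, self.gKdr, self.gL) < 0:
            raise ValueError("conductances must be non-negative")


@dataclass
class NeuronState:
    """Dynamical variables of one cell: V (mV) and the gates h, n, z in [0,1]."""

    V: float
    h: float
    n: float
    z: float

    def __post_init__(self) -> None:
        for g in (self.h, self.n, self.z):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gates h, n, z must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h, self.n, self.z], dtype=float)


def _check_V(V):
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    return V


def steady_state_gates(V):
    """Voltage-dependent steady states (m_inf, h_inf, n_inf, z_inf).

    Half-(in)activation voltages: m at -30 mV (slope 9.5), h at -40.5 mV
    (slope 6), n at -30 mV (slope 10), z at -39 mV (slope 5).
    """
    V = _check_V(V)
    m_inf = 1.0 / (1.0 + np.exp((-V - 30.0) / 9.5))
    h_inf = 1.0 / (1.0 + np.exp((V + 40.5) / 6.0))
    n_inf = 1.0 / (1.0 + np.exp((-V - 30.0) / 10.0))
    z_inf = 1.0 / (1.0 + np.exp((-V - 39.0) / 5.0))
    return m_inf, h_inf, n_inf, z_inf


def gate_time_constants(V):
    """Relaxation times (tau_h, tau_n) in ms; both decrease with depolarization."""
    V = _check_V(V)
    tau_h = 0.37 + 2.78 / (1.0 + np.exp((V + 40.5) / 6.0))
    tau_n = 0.37 + 1.85 / (1.0 + np.exp((V + 27.0) / 15.0))
    return tau_h, tau_n


def membrane_currents(V, h, n, z, params: NeuronParams, gKs):
    """Ionic currents (INa, IKdr, IKs, IL) at the given state, uA/cm^2."""
    m_inf, _, _, _ = steady_state_gates(V)
    INa = params.gNa * m_inf**3 * h * (V - params.VNa)
    IKdr = params.gKdr * n**4 * (V - params.VK)
    IKs = gKs * z * (V - params.VK)
    IL = params.gL * (V - params.VL)
    return INa, IKdr, IKs, IL


def derivatives(state: NeuronState, params: NeuronParams, gKs: float,
                I_ext: float = 0.0):
    """Time derivatives (dV/dt, dh/dt, dn/dt, dz/dt) of one cell.

    ``gKs`` must lie in the modulation range [0, 1.5] mS/cm^2; ``I_ext`` is the
    total non-ionic current (drive minus synaptic plus noise).
    """
    if not 0.0 <= gKs <= GKS_MAX:
        raise ValueError(f"gKs must be in [0, {GKS_MAX}] mS/cm^2, got {gKs}")
    V, h, n, z = state.V, state.h, state.n, state.z
    INa, IKdr, IKs, IL = membrane_currents(V, h, n, z, params, gKs)
    dV = (-INa - IKdr - IKs - IL + I_ext) / params.C
    _, h_inf, n_inf, z_inf = steady_state_gates(V)
    tau_h, tau_n = gate_time_constants(V)
    dh = (h_inf - h) / tau_h
    dn = (n_inf - n) / tau_n
    dz = (z_inf - z) / params.tau_z
    return dV, dh, dn, dz


def resting_state(params: NeuronParams, gKs: float, I_ext: float = 0.0,
                  bracket: tuple[float, float] = (-90.0, -40.0)) -> NeuronState:
    """Find the fixed point of the dynamics by root-solving the V-nullcline
    with all gates at their steady state."""

    def f(V: float) -> float:
        h, n, z = steady_state_gates(V)[1:]
        INa, IKdr, IKs, IL = membrane_currents(V, h, n, z, params, gKs)
        return -INa - IKdr - IKs - IL + I_ext

    grid = np.linspace(bracket[0], bracket[1], 101)
    vals = np.array([f(v) for v in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError(
            f"no resting fixed point in {bracket} for gKs={gKs}, I={I_ext} "
            "(with the M-current blocked this cell is spontaneously active)")
    a, b = grid[sign_change[0]], grid[sign_change[0] + 1]
    V0 = brentq(f, a, b)
    _, h0, n0, z0 = steady_state_gates(V0)
    return NeuronState(V=V0, h=h0, n=n0, z=z0)


def _single_cell_spikes(params: NeuronParams, gKs: float, I_step: float,
                        duration: float, dt: float = 0.05,
                        state: NeuronState | None = None) -> np.ndarray:
    """Integrate one cell under constant drive and return its spike times (ms).

    The default initial condition is a standard hyperpolarized state (V = -65
    mV, gates at steady state) so that the adaptation gate z starts near its
    quiescent value regardless of whether a true resting fixed point exists
    (with gKs = 0 the cell is spontaneously active and none does).
    """
    from .simulator import integrate_single_cell

    if state is None:
        V0 = -65.0
        _, h0, n0, z0 = steady_state_gates(V0)
        state = NeuronState(V=V0, h=float(h0), n=float(n0), z=float(z0))
    return integrate_single_cell(state, params, gKs, I_step, duration, dt)


def f_I_curve(params: NeuronParams, gKs: float, I_values, duration: float = 3000.0,
              transient: float = 500.0, dt: float = 0.05) -> np.ndarray:
    """Steady firing frequency (Hz) for each drive current in ``I_values``.

    The first ``transient`` ms are discarded so adaptation (tau_z = 75 ms) has
    converged; frequency is the spike count over the remaining window.  Larger
    gKs shifts the curve rightward/downward (cholinergic blockade of the
    M-current raises excitability).
    """
    if duration <= transient:
        raise ValueError("duration must exceed the discarded transient")
    freqs = np.empty(len(I_values))
    for i, I in enumerate(I_values):
        spikes = _single_cell_spikes(params, gKs, float(I), duration, dt)
        spikes = spikes[spikes >= transient]
        freqs[i] = len(spikes) / ((duration - transient) / 1000.0)
    return freqs


def sfa_profile(params: NeuronParams, gKs: float, I_step: float = 1.5,
                duration: float = 2000.0, dt: float = 0.05) -> np.ndarray:
    """Inter-spike-interval sequence (ms) under a current step from rest.

    With gKs = 1.5 the M-current accumulates over successive spikes and the
    ISIs lengthen (spike-frequency adaptation); with gKs = 0 the ISIs are
    constant after the first interval.
    """
    spikes = _single_cell_spikes(params, gKs, I_step, duration, dt)
    if len(spikes) < 3:
        raise RuntimeError(
            f"insufficient data: {len(spikes)} spikes; I_step may be below rheobase")
    return np.diff(spikes)
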