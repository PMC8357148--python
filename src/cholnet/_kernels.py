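"""Numba-compiled inner loop of the network integrator.

The network state is integrated with fixed-step classical Runge-Kutta (RK4).
Synapses are conductance-based with single-exponential decay: each source j
carries a gate s_j(t) = sum_k exp(-(t - t_jk)/tau), incremented by 1 at every
presynaptic spike.  Rather than tracking s_j per source, the kernel maintains
the per-target weighted sums G_e[i] = sum_{j exc} w_ij s_j and G_i[i] (mathem-
atically identical, since all excitatory sources share tau_exc and inhibitory
sources tau_inh): both decay by exp(-dt/tau) per step and receive the source's
outgoing-weight column at each spike.  Within the RK4 stages the gates are
evaluated at the stage times via exact exponential factors.

Spikes are detected as upward crossings of 0 mV with a 2 ms lockout (spikes
in this model overshoot 0 mV robustly; the lockout only affects detection).
"""

import numpy as np
from numba import njit

SPIKE_THRESHOLD = 0.0   # mV
SPIKE_LOCKOUT = 2.0     # ms
BLOWUP_MV = 200.0       # |V| beyond this aborts as numerical blow-up

STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_OVERFLOW = 2


@njit(cache=True)
def _rhs(V, h, n, z, gks, I_const, ge, gi, E_exc, E_inh,
         C, gNa, gKdr, gL, VNa, VK, VL, tau_z):
    m_inf = 1.0 / (1.0 + np.exp((-V - 30.0) / 9.5))
    h_inf = 1.0 / (1.0 + np.exp((V + 40.5) / 6.0))
    n_inf = 1.0 / (1.0 + np.exp((-V - 30.0) / 10.0))
    z_inf = 1.0 / (1.0 + np.exp((-V - 39.0) / 5.0))
    tau_h = 0.37 + 2.78 / (1.0 + np.exp((V + 40.5) / 6.0))
    tau_n = 0.37 + 1.85 / (1.0 + np.exp((V + 27.0) / 15.0))
    Isyn = ge * (V - E_exc) + gi * (V - E_inh)
    dV = (-gNa * m_inf**3 * h * (V - VNa)
          - gKdr * n**4 * (V - VK)
          - gks * z * (V - VK)
          - gL * (V - VL)
          + I_const - Isyn) / C
    dh = (h_inf - h) / tau_h
    dn = (n_inf - n) / tau_n
    dz = (z_inf - z) / tau_z
    return dV, dh, dn, dz


@njit(cache=True)
def run_network(V, h, n, z, gks, WT, n_exc,
                tau_e, tau_i, E_exc, E_inh,
                drive, noise_on, noise_rate, noise_amp, noise_width, noise_seed,
                dt, n_steps,
                C, gNa, gKdr, gL, VNa, VK, VL, tau_z,
                rec_idx, rec_every, spike_cap):
    """Integrate the network for n_steps; mutates the state arrays in place.

    Returns (spike_times, spike_indices, V_record, status)."""
    N = V.shape[0]
    Ge = np.zeros(N)
    Gi = np.zeros(N)
    de_half = np.exp(-0.5 * dt / tau_e)
    de_full = np.exp(-dt / tau_e)
    di_half = np.exp(-0.5 * dt / tau_i)
    di_full = np.exp(-dt / tau_i)

    spike_t = np.empty(spike_cap)
    spike_i = np.empty(spike_cap, np.int64)
    nspk = 0
    last_spike = np.full(N, -1.0e9)
    step_spikes = np.empty(N, np.int64)

    pulse_end = np.full((N, 2), -1.0e9)
    if noise_on:
        np.random.seed(noise_seed)

    n_rec = rec_idx.shape[0]
    n_rec_steps = (n_steps // rec_every + 1) if n_rec > 0 else 0
    Vrec = np.zeros((n_rec, n_rec_steps))
    if n_rec > 0:
        for r in range(n_rec):
            Vrec[r, 0] = V[rec_idx[r]]

    status = STATUS_OK
    for step in range(n_steps):
        t = step * dt
        if noise_on:
            for i in range(N):
                if np.random.random() < noise_rate * dt:
                    if pulse_end[i, 0] <= t:
                        pulse_end[i, 0] = t + noise_width
                    else:
                        pulse_end[i, 1] = t + noise_width
        n_step_spk = 0
        for i in range(N):
            I_const = drive[i]
            if noise_on:
                if t < pulse_end[i, 0]:
                    I_const += noise_amp
                if t < pulse_end[i, 1]:
                    I_const += noise_amp
            ge0 = Ge[i]
            gi0 = Gi[i]
            k1V, k1h, k1n, k1z = _rhs(V[i], h[i], n[i], z[i], gks[i], I_const,
                                      ge0, gi0, E_exc, E_inh,
                                      C, gNa, gKdr, gL, VNa, VK, VL, tau_z)
            k2V, k2h, k2n, k2z = _rhs(V[i] + 0.5 * dt * k1V, h[i] + 0.5 * dt * k1h,
                                      n[i] + 0.5 * dt * k1n, z[i] + 0.5 * dt * k1z,
                                      gks[i], I_const,
                                      ge0 * de_half, gi0 * di_half, E_exc, E_inh,
                                      C, gNa, gKdr, gL, VNa, VK, VL, tau_z)
            k3V, k3h, k3n, k3z = _rhs(V[i] + 0.5 * dt * k2V, h[i] + 0.5 * dt * k2h,
                                      n[i] + 0.5 * dt * k2n, z[i] + 0.5 * dt * k2z,
                                      gks[i], I_const,
                                      ge0 * de_half, gi0 * di_half, E_exc, E_inh,
                                      C, gNa, gKdr, gL, VNa, VK, VL, tau_z)
            k4V, k4h, k4n, k4z = _rhs(V[i] + dt * k3V, h[i] + dt * k3h,
                                      n[i] + dt * k3n, z[i] + dt * k3z,
                                      gks[i], I_const,
                                      ge0 * de_full, gi0 * di_full, E_exc, E_inh,
                                      C, gNa, gKdr, gL, VNa, VK, VL, tau_z)
            V_new = V[i] + dt / 6.0 * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
            if np.abs(V_new) > BLOWUP_MV:
                status = STATUS_BLOWUP
                return spike_t[:nspk], spike_i[:nspk], Vrec, status
            t_new = t + dt
            if (V_new >= SPIKE_THRESHOLD and V[i] < SPIKE_THRESHOLD
                    and t_new - last_spike[i] > SPIKE_LOCKOUT):
                if nspk >= spike_cap:
                    status = STATUS_OVERFLOW
                    return spike_t[:nspk], spike_i[:nspk], Vrec, status
                spike_t[nspk] = t_new
                spike_i[nspk] = i
                nspk += 1
                last_spike[i] = t_new
                step_spikes[n_step_spk] = i
                n_step_spk += 1
            V[i] = V_new
            h[i] = min(max(h[i] + dt / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h), 0.0), 1.0)
            n[i] = min(max(n[i] + dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n), 0.0), 1.0)
            z[i] = min(max(z[i] + dt / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z), 0.0), 1.0)
        # advance synaptic gates to t+dt: decay, then add this step's spikes
        for i in range(N):
            Ge[i] *= de_full
            Gi[i] *= di_full
        for s in range(n_step_spk):
            j = step_spikes[s]
            if j < n_exc:
                for i in range(N):
                    Ge[i] += WT[j, i]
            else:
                for i in range(N):
                    Gi[i] += WT[j, i]
        if n_rec > 0 and (step + 1) % rec_every == 0:
            row = (step + 1) // rec_every
            if row < n_rec_steps:
                for r in range(n_rec):
                    Vrec[r, row] = V[rec_idx[r]]
    return spike_t[:nspk], spike_i[:nspk], Vrec, status
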