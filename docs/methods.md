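# Methods

## Neuron model

Single-compartment Hodgkin–Huxley dynamics with four currents: fast Na⁺
(instantaneous activation m∞(V) = {1+exp[(−V−30)/9.5]}⁻¹, inactivation h with
h∞ midpoint −40.5 mV and τ_h = 0.37 + 2.78·{1+exp[(V+40.5)/6]}⁻¹ ms),
delayed-rectifier K⁺ (gate n, midpoint −30 mV, τ_n = 0.37 +
1.85·{1+exp[(V+27)/15]}⁻¹ ms), the slow M-type K⁺ current (gate z, midpoint
−39 mV, slope 5, first-order relaxation with τ_z = 75 ms) and an ohmic leak.
Constants: C = 1 µF/cm², g_Na = 24, g_Kdr = 3, g_L = 0.02 mS/cm², V_Na = 55,
V_K = −90, V_L = −60 mV. The M-current conductance g_Ks is the cholinergic
variable: 1.5 mS/cm² means no modulation, 0 full muscarinic blockade. With
g_Ks = 0 the model has no subthreshold fixed point and is spontaneously
active; `resting_state` reports this explicitly.

Numerics: fixed-step classical RK4. Production step dt = 0.05 ms; halving the
step moves the spike times of a 1 s single-cell run by < 0.5 ms and the
population rate of a 2 s network run by < 3 % (both asserted in tests).
Spikes are detected as upward crossings of 0 mV with a 2 ms lockout (detection
only — the dynamics carry no explicit refractory mechanism). Single-cell
rate measurements discard a 500 ms transient (≈ 7 τ_z) so adaptation has
converged. Gate variables are clamped to [0, 1] after each step as a
numerical guard; the relaxation form keeps them inside the box to within
integration error anyway.

Reference values for the f–I curve and adaptation ratios were computed with
an independent adaptive integrator (scipy `solve_ivp`, RK45, rtol 1e-9,
event-based spike detection) and frozen into the test suite; the production
integrator matches within 2 %.

## Network

400 E cells on a periodic 20×20 lattice, 100 I cells on a nested 10×10
lattice, each I cell at the center of its 2×2 E block (position offset +0.5
lattice units). Cell IDs are column-major (index = y + x·L), 1-based in all
emitted rasters: E = 1..400, I = 401..500.

Connectivity is local-excitation / global-inhibition: each E cell projects to
its 40 nearest E cells and 10 nearest I cells under the periodic metric; each
I cell projects to all 400 E cells and the other 99 I cells (autapses
excluded). Exact-k neighborhoods on a lattice necessarily cut tied distance
shells (the 40-neighborhood cuts the 8-fold r² = 13 shell), so ties are
broken deterministically by (distance rounded to 9 decimals, angle of the
minimum-image offset from +x in [0, 2π), index). A brute-force pairwise
enumeration reproduces every target set in the tests. Weights: E-E 0.01,
E-I 0.05, I-I 0.04, I-E 0.04 mS/cm²; all synapses decay exponentially with
τ = 3 ms toward reversal 0 mV (excitatory) or −75 mV (inhibitory).

The integrator tracks per-target weighted gate sums (one for excitatory, one
for inhibitory sources) that decay by exp(−dt/τ) per step and receive the
presynaptic cell's outgoing-weight column at each spike; this is
algebraically identical to the per-spike exponential sum and is verified
against a direct evaluation of that sum on a 3-cell micro-network to 1e-6 mV
over 500 ms.

External drive I_drive (default 3.0 µA/cm²) is applied to E cells only.
Driving the I population tonically at the same level makes inhibition
E-independent, breaks the PING loop and drops network gamma to ~32 Hz; with
E-only drive gamma sits at 56–60 Hz and hotspot confinement holds, so E-only
is the default (I-cell drive is available as `DriveConfig.I_base_I`).

Poisson current-pulse noise (per-cell rate 1/150 ms⁻¹, amplitude 6 µA/cm²,
width 1 ms; overlapping pulses sum, tracked to two simultaneous pulses) is
off in the library default but enabled in every scenario configuration: the
two-hotspot competition without noise locks into a symmetric in-phase beat
(lobe-rate correlation +0.98) and no alternation develops; with noise the
lobes alternate anti-phase at theta timescale. Initial conditions: V uniform
in [−70, −55] mV, gates at steady state for the drawn V; everything is
deterministic given the seeds.

## ACh (g_Ks) maps

E-lattice field initialized at 1.5 mS/cm² and iterated with
g(n+1) = g(n) + D·Lap(g) − R + B·(1.5 − g), unit step and spacing, periodic
boundaries, R = R_amp at the release sites. Defaults D = 0.15, B = 0.05,
R_amp = 60 per step. The iteration runs unclamped — the release site
accumulates a deep negative deficit that acts as the reservoir feeding
hotspot growth — and the [0.2, 1.5] bounds are imposed when the map is
frozen. Clamping every step instead erases the released deficit at the
source as fast as it is produced and caps hotspots at an effective radius of
~1.7 lattice units regardless of (D, B, R_amp). Keep D ≤ 0.2: at the
explicit scheme's stability boundary D = 0.25 the checkerboard mode is
marginal and accumulates visibly from a point source.

The hotspot radius is operationalized as the area-equivalent radius of the
sub-0.6 mS/cm² region, r = √(count/π), matching the 0.6 contour drawn around
hotspots. `generate_map` freezes the iteration at the step at which an
isolated site first reaches the requested radius (calibrated once per
parameter set and cached); radii up to ~6.5 are reachable in under 100 steps
with the defaults while the decay term screens each site's tail, keeping the
background near 1.5 even under several superposed sites. I cells inherit the
mean of their 2×2 E block (optionally forced to 0 for the
unmodulated-I-population variant).

Known limitation — interior flatness. Any point-source release strong
enough to grow a 0.6-contour radius of 4–6 units saturates the hotspot
interior at the 0.2 bound well before freeze; we scanned per-step-clamped,
unclamped, shallow-transient and pinned-source regimes and found no
parameterization that yields both large radii and graded (bowl-shaped)
interiors with a high background. Since the theta alternation is paced by
spike-frequency adaptation inside the active hotspot, and adaptation strength
scales with the interior g_Ks level (clamping the same maps' interiors to
floors of 0.2/0.3/0.35/0.45 moves the cell-averaged theta peak from 3.9 to
4.6, 5.3 and 6.6 Hz), the flat 0.2 interiors slow the emergent theta rhythm
to ~3–5 Hz — at, and often below, the 5 Hz edge of the conventional theta
band. Downstream consequences: the nine-hotspot scenario's theta peak
frequency varies across map realizations (2.6–8.1 Hz for seeds 1/2/3/7 of
the acceptance protocol), and the single-hotspot radius scan does not
reproduce a decline of gamma-dominant cell counts beyond radius 5.5 (counts
64.5 → 100.5 → 158 for radii 4.2/5.5/6.5), because the weak interior
adaptation rarely interrupts central gamma firing. Gamma-band results
(peak ≈ 58 Hz, PING mechanism, confinement, trend directions) are robust to
all of this.

## Spectral analysis

Network spectra: pooled population spike counts binned at 1 ms over the
post-transient span (500 ms discarded; ≥ 2 s required), mean-subtracted,
autocorrelated, Hann-windowed, magnitude FFT (zero-padded to ≥ 4096 bins, so
the frequency grid is finer than 0.25 Hz). Theta is the band 2.5–20 Hz,
gamma 25–100 Hz. A second estimator, `cell_averaged_spectrum`, averages each
cell's own autocorrelation spectrum; unlike the pooled estimator it retains
slow per-cell on/off gating even when region alternation cancels in the
population sum, and it is the estimator used to center the LFP filter bands
(it locates the actual gamma-envelope modulation frequency).

Per-cell classification uses the same pipeline on the cell's train (< 5
spikes ⇒ "none"): a band flag is set when the band peak exceeds
`threshold_factor` × the mean power over 2.5–100 Hz; both flags ⇒ "mixed".
The default factor is 8: on synthetic pilot trains the max/mean statistic of
the windowed-ACF magnitude floor alone reaches ~6 over the 300-bin gamma
band, so a factor of 4 flags noise, while 8 cleanly separates genuine lines
(a jittered 8 Hz train scores 14.5 in theta against a 5.7 floor). Note that
a *zero-jitter* periodic train is genuinely broadband (its harmonic comb
lands in the gamma band at full power), so classifier tests use
physiologically jittered trains.

Replication convention: headline measurements average four replicates from
random initial conditions; replicate statistics are summarized as mean and
relative standard error (SE/|mean|).

## LFP and coupling

The LFP proxy at a lattice location sums the Gaussian-smoothed (σ = 1.5 ms,
grid 0.5 ms, unit-area kernels) spike trains of the 12 E cells nearest to the
location (voltage mode sums raw V traces of the same cells instead). The
trace is band-passed with zero-phase 4th-order Butterworth filters applied as
second-order sections — the theta band is ~0.3 % of Nyquist, where
transfer-function coefficients are numerically singular — with pass bands
centered on the measured peaks: theta peak ± 2 Hz, gamma peak ± 10 Hz.
Theta phase and gamma amplitude come from Hilbert transforms (200 ms trimmed
at each end); the modulation index is the normalized entropy deficit of the
mean amplitude in 18 phase bins, MI = (ln N − H(P))/ln N ∈ [0, 1].

## Experiments and problem sizes

`cholnet.experiments` holds declarative, hash-stable scenario specs (map
recipe, topology variant, drive/noise/synapse/simulation settings, seeds,
requested analyses) for the figure-style scenarios: the random 9-hotspot map
(r = 4.2), single-hotspot radius scans, double-hotspot (r, d) grids with the
r = 6.1 / d = 8 alternation case, random 6-hotspot variability pairs, the
MI-versus-distance line, stimulus gating (targeted drive 4.5 µA/cm² inside /
outside a hotspot versus a homogeneous control), the unmodulated-I variant
(I-I 0.06, I-E 0.035 mS/cm²), homogeneous-g_Ks controls, lower-bound × drive
grids, E-E rewiring (each E-E edge rewired with probability p to a uniform
random E cell, degree-preserving), τ_z scans, drive and inhibitory-τ scans
(holding w_inh·τ_I constant) and sparse inhibition (densities 0.8/0.6/0.4
with weights 0.045/0.048/0.075 mS/cm²).

Default scenario scale is 5.5 s per run with four replicates. The test suite
runs the same scenarios at 2.5–5.5 s with 1–3 replicates and coarse grids
(radii {4.2, 5.5, 6.5}, rewiring {0, 0.875}, τ_z {25, 75, 125} ms, distances
{5, 8}); these sizes are the package's chosen desk scale and are large enough
that every trend asserted in the tests reproduced consistently during
development, except the two items flagged above (theta-band peak location;
gamma-count reversal), which fail for the structural reason given, not for
lack of averaging.

What the generator does not emulate: time-varying ACh fields (maps are
frozen snapshots), receptor kinetics, multi-compartment neurons, synaptic
delays or plasticity. Passing tests therefore demonstrate the mechanism —
spatially structured M-current modulation producing localized PING gamma
gated at adaptation timescale — not a quantitative fit to any in vivo
recording.
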