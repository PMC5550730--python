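# Methods

## The model

`bgdbs` simulates four interconnected basal ganglia populations — thalamus
(TH), subthalamic nucleus (STN), external and internal globus pallidus
(GPe, GPi) — as single-compartment conductance-based neurons, and uses the
network to evaluate biphasic deep-brain-stimulation (DBS) waveforms with an
interphase delay.

Each neuron obeys

    C_m dV/dt = − Σ_ion I_ion + I_syn + I_ext + I_bias,
    I_ion     = g_ion · m^M · h^N · (V − E_ion),

with leak, Na, K, and low-threshold Ca (T) currents for all cells plus a
high-threshold Ca current for STN/GPe/GPi.  Conductances, reversal
potentials and bias currents are the network model's reference values
(`src/bgdbs/params/cells.yaml`); the full gating kinetics — Boltzmann
steady states, sigmoid/inverse-rate time constants, the thalamic
K-activation tied to Na inactivation (n = 0.75(1−h)) and the STN T-current
inactivation b(r) — follow the Rubin–Terman family of basal ganglia cell
models from which this network descends.  Two deliberate consequences:

* **Channel set is exactly {L, Na, K, Ca, T}.**  This network's membrane
  equations include no AHP current, so the RT-family AHP/calcium-pool
  machinery is omitted.  GPe/GPi therefore fire faster and more tonically
  than the RT originals (healthy ≈ 90 Hz here).
* **The healthy vs. Parkinsonian (PD) distinction is purely the bias
  current**: STN 29→20, GPe 20→8, GPi 22→12 µA/cm² (TH has no bias term).
  Reduced pallidal drive produces the PD signature: lower GPe rate and
  elevated GPi frame-count synchrony.

Synapses follow the same conductance form, `g_syn · Σ s_i · (V_post −
E_syn)`, with a first-order gate per presynaptic neuron (rise while the
presynaptic membrane exceeds −20 mV, exponential decay otherwise; fast
α=5, β=1 /ms for excitation, slower α=2, β=0.08 /ms for inhibition —
package choices, exposed in `params/synapses.yaml`).  Fan-in is fixed:
2 STN→GPe, 2 GPe→GPe, 2 STN→GPi, 2 GPe→GPi, 2 GPe→STN, 1 GPi→TH.  Partner
assignment is structured wrap-around (post *i* ← pre *i*, *i*+1; the
recurrent GPe→GPe uses *i*+1, *i*+2 so no neuron inhibits itself) or
seeded uniform-random.

External inputs: the thalamic population shares one stochastic
sensorimotor-cortex pulse train (3 µA/cm², 5 ms rectangles; Gaussian
inter-pulse intervals, mean 1000/14 ms, CV 0.2, redrawn below the pulse
width).  DBS is an identical additive current density to every neuron of
each targeted population (STN by default); there is no electrode geometry.

## Waveforms

A stimulus pulse is cathodic phase → interphase delay → anodic phase at
130 Hz.  The six presets pair three shapes (rectangular, half-sine,
truncated Gaussian) with delay 0 or 0.7 ms: Pulse/PDP, Sinusoid/SDS,
Gaussian/GDG.  All use a 200 µA/cm² × 0.3 ms cathodic and a −20 µA/cm² ×
1 ms anodic phase (1:3.3 width, 10:1 amplitude ratio).  Choices the source
material leaves open:

* Gaussian σ = width/6 (±3σ support, truncated at the phase edges), so
  "amplitude" always means peak current across shapes; σ is configurable.
* The nominal presets are *not* charge balanced (+60 vs −20 µA·ms/cm² per
  pulse); the library reports the imbalance and offers `rebalanced()`
  which rescales the anodic amplitude, off by default to keep the
  nominal presets.
* Trains start with a cathodic onset at t = 0; onsets are carried in
  `SampledWaveform` so miss counting is unambiguous.
* Cathodic current is stored positive (injected, depolarizing).

Sampling uses the midpoint convention (sample k is the value at
(k+½)·dt), so the discrete energy `Z·dt·ΣI²` is midpoint quadrature:
exact for grid-aligned rectangles (the 12 nJ single-phase closed form is
reproduced to 1e-12) and O(dt²) otherwise.

## Numerics

Fixed-step explicit integration of the fully coupled system (membrane
potentials, gating variables, synaptic gates): RK4 by default at
dt = 0.01 ms, forward Euler available.  External currents are held
constant within a step.  The production path is a numba kernel whose
right-hand sides are pinned to the reference Python layer by a 1e-12
agreement test; halving dt changes population rates by <5% and single-cell
spike counts by ≤1 over 1 s.  After every step gates are clamped to [0,1]
(clamping beyond 1e-6 is counted and reported; it does not occur in normal
operation) and |V| > 200 mV aborts with the time and neuron index.

Spikes are strict upward crossings of −20 mV (touching the threshold
exactly does not count) with a 2 ms refractory window — below the minimal
inter-spike interval these cells produce, configurable.

Initial conditions: per-neuron membrane voltages drawn uniformly from
[−75, −55] mV with gates at the corresponding steady state (symmetry
breaking; the structured network is otherwise perfectly symmetric), all
synaptic gates closed.  `init_resting_state` finds a deterministic
near-rest state by a 500 ms LSODA relaxation, falling back to the
algebraic fixed point (gates at steady state) for cells that fire
intrinsically under their bias.  All randomness (wiring in random mode,
initial jitter, SMC train) derives from one seed via `SeedSequence`
spawns; runs are bit-reproducible.

## Metrics

* **Cost**: `C = ∫_W I²Z dt + 3·M` nJ with Z = 1 kΩ; a *miss* is a DBS
  pulse with no spike of the assessed neuron in [onset, onset+period).
  M is evaluated per STN neuron over a common analysis window and
  averaged (the window and neuron set are not fixed by the source
  material; both are arguments).
* **Mutual information**: plug-in histogram estimator in nats, 8
  equal-width amplitude bins per signal by default.
* **PLV**: Hilbert phase of mean-removed signals; modulus of the mean
  unit phasor of the phase difference.  Spike trains are first smoothed
  into rate signals with a Gaussian kernel (σ = 10 ms for
  population-vs-population comparisons; σ = 2 ms at 0.5 ms resolution
  when locking to the 130 Hz DBS drive, which a 10 ms kernel would
  erase).
* **Synchronization Level**: per-neuron spike counts in non-overlapping
  15 ms frames; Pearson ρ over all pairs (upper triangle, diagonal
  excluded — self-pairs are trivially significant and would inflate SL by
  ~1/n); two-sided t-test with L−2 df; SL = significant fraction at
  α = 0.05.  Zero-variance count functions are excluded from numerator
  and denominator and the exclusion count is reported.  Under
  independence SL calibrates to the type-I error (~α); identical
  non-constant functions give SL = 1.
* **NET**: per (delay, frequency) cell, bisection on the cathodic
  amplitude (anodic held at 10:1) finds the minimal train energy
  achieving ≥50% pulse-to-spike success on an isolated STN neuron;
  the grid is min-max normalized per panel, unreachable cells are NaN
  and excluded.

## What the stated world does and does not reproduce

The synthetic world is fixed by the reference parameters above and was not
adjusted to the reported outcomes.  With RT-family kinetics:

* Most qualitative network signatures hold: GPe rate falls healthy→PD,
  every preset raises STN and GPi rates above PD (GPe rises under all but
  the Gaussian-shaped drives), DBS entrains STN, delay variants never
  miss more than their no-delay counterparts, and SL(PD) > SL(healthy)
  with SL(healthy) ≈ 0.2.  Stimulation does not push GPi synchrony below
  the healthy level here: the shared STN-targeted drive partially
  synchronizes GPi (SL(Pulse) ≈ 0.5), where the source network reports
  desynchronization below healthy.
* The 0.7 ms interphase delay barely changes miss counts at the 200 µA
  operating point: STN entrains 1:1 / 1:2 / 1:3 to rectangular /
  half-sine / Gaussian pulses with or without delay.  Cost reductions of
  delay variants over their no-delay counterparts are therefore near 0%
  (GDG vs PDP ≈ 54% comes from the shape's energy, not the delay).
* At equal peak amplitude the Gaussian delivers the least charge, so its
  eliciting threshold (~295 µA) exceeds the rectangular one (~145 µA),
  and the delay shifts thresholds by only a few µA.  The
  delay-threshold-at-200 µA experiment consequently has no crossing for
  SDS/GDG and a zero crossing for PDP.  Reproducing the reported strong
  delay dependence would require the source network's unpublished cell
  modifications in which the −20 µA anodic phase can abort a spike; in
  these cells it is an order of magnitude too weak against the Na
  current.  The sweep/bisection machinery itself is validated against a
  brute-force amplitude scan.

## Known limitations

Single compartments, no electrode/tissue geometry, no striatum or cortex
populations (the SMC drive is a signal), no plasticity or conduction
delays, frequency-independent 1 kΩ impedance, no AHP current (see above),
and gating constants reconstructed from the RT-model family rather than
from the (unpublished) modified cell definitions.
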