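# bgdbs — basal ganglia network simulation for interphase-delay DBS waveforms

Deep brain stimulation (DBS) of the subthalamic nucleus treats the motor
symptoms of Parkinson's disease, but the stimulator's battery life and
tissue safety depend on the waveform: a biphasic pulse with a short,
high-amplitude cathodic phase, an optional zero-current **interphase
delay**, and a long, low-amplitude anodic recovery phase.  `bgdbs` is a
simulator for studying that design space in a conductance-based network of
the four relevant populations — thalamus (TH), subthalamic nucleus (STN),
external and internal globus pallidus (GPe, GPi) — in healthy,
Parkinsonian (PD) and stimulated conditions.

It is aimed at computational neuroscientists who want a reproducible,
seeded, desk-scale version of the classic Rubin–Terman-family network with
a parametric DBS waveform layer and the standard evaluation statistics.

## The model in brief

Each neuron is a single compartment,

    C_m dV/dt = −Σ g_ion m^M h^N (V − E_ion) + I_syn + I_ext + I_bias,

with leak/Na/K/Ca/T currents (Rubin–Terman-family gating kinetics; see
`docs/methods.md` for all parameter values).  The healthy→PD switch
is a reduction of the bias currents to STN/GPe/GPi (29→20, 20→8,
22→12 µA/cm²), which lowers the GPe rate and raises GPi synchrony.
Populations are wired with fixed fan-in (2 STN→GPe, 2 GPe→GPe, 2 STN→GPi,
2 GPe→GPi, 2 GPe→STN, 1 GPi→TH); thalamus receives a stochastic 14 Hz
sensorimotor pulse train, and DBS is an additive current density on the
targeted populations (STN by default) at 130 Hz.

Six waveform presets pair three phase shapes (rectangular, half-sine,
Gaussian) with interphase delay 0 or 0.7 ms: `Pulse`/`PDP`,
`Sinusoid`/`SDS`, `Gaussian`/`GDG`; all use a 200 µA/cm² × 0.3 ms cathodic
and a −20 µA/cm² × 1 ms anodic phase.

Evaluation metrics (module `bgdbs.metrics`):

* **cost** `C = ∫_W I²Z dt + 3·M` nJ (Z = 1 kΩ; M = DBS pulses that fail
  to elicit a spike within their period),
* **mutual information** (plug-in histogram, nats),
* **phase-locking value** (Hilbert phase, |mean unit phasor|),
* **Synchronization Level** SL = fraction of neuron pairs whose 15 ms
  frame spike-count functions are significantly Pearson-correlated
  (α = 0.05),
* **normalized energy threshold** (NET) over a delay × frequency grid.

## Worked example

```python
from bgdbs.engine import SimulationConfig, run_simulation
from bgdbs.metrics import synchronization_level
from bgdbs.waveforms import make_preset, pulse_energy

for cond in ("healthy", "pd"):
    cfg = SimulationConfig(n_per_pop=100, condition=cond,
                           duration=1500.0, seed=1)
    res = run_simulation(cfg)
    sl = synchronization_level(res.spikes["GPi"], frame=15.0,
                               duration=1000.0, t0=500.0)
    print(f"{cond:8s}  GPe {res.mean_rate('GPe', 500, 1500):5.1f} Hz   "
          f"GPi {res.mean_rate('GPi', 500, 1500):5.1f} Hz   "
          f"SL(GPi) {sl.sl:.3f}")

w = make_preset("GDG")
print(f"GDG: cathodic {w.cathodic.amplitude:.0f} uA x {w.cathodic.width} ms, "
      f"delay {w.delay} ms, anodic {w.anodic.amplitude:.0f} uA x "
      f"{w.anodic.width} ms, {pulse_energy(w):.2f} nJ per pulse")
```

prints (≈100 s on one CPU):

```
healthy   GPe  83.3 Hz   GPi  83.2 Hz   SL(GPi) 0.231
pd        GPe  44.1 Hz   GPi  48.8 Hz   SL(GPi) 0.474
GDG: cathodic 200 uA x 0.3 ms, delay 0.7 ms, anodic -20 uA x 1.0 ms, 3.66 nJ per pulse
```

The PD bias reduction roughly halves the pallidal rates and doubles the
GPi Synchronization Level — the pathological signature DBS waveforms are
then scored against (energy + misses via `bgdbs.experiments.
energy_comparison`, SL via `sl_table`, delay thresholds via
`delay_threshold_curves`).

A CLI mirrors the experiment layer:

```sh
bgdbs simulate --preset GDG --condition pd --n 100 --seed 1 --out runs/gdg
bgdbs energy-compare --sizes 100 --seeds 1,2,3 --out runs/energy
bgdbs delay-thresholds --out runs/thresholds
bgdbs sl-table --n 100 --out runs/sl
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from fresh simulations: the seed-median percent cost reduction
of each delay variant over its no-delay counterpart (and GDG vs PDP) in
the PD network; the GPi Synchronization Level for the healthy, PD and
rectangular-pulse conditions; and the smallest interphase delay at which
each delayed waveform elicits spikes at the 200 µA/cm² reference amplitude
on an isolated STN neuron.  It writes one JSON object keyed by target id
and logs progress to stderr (~10 min on one CPU).

## Layout

```
src/bgdbs/
  cell_models.py   # TH/STN/GPe/GPi membrane + gating models (YAML-backed)
  network.py       # fan-in wiring, synaptic currents and gates
  waveforms.py     # phase shapes, presets, sampling, charge/energy
  engine.py        # SMC drive, network integration, spike detection
  _kernels.py      # numba fast path (pinned to the Python layer by tests)
  metrics.py       # cost, MI, PLV, SL, NET
  experiments.py   # seeded sweeps: energy, SL table, thresholds, PLV maps
  cli.py           # `bgdbs` command group
  params/          # cell and synapse parameter tables
docs/methods.md    # model, assumptions, numerical choices, limitations
```
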