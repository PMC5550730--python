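"""Network integration engine: stochastic cortical drive, full simulations,
spike detection and result packaging.

A simulation advances all four populations (TH, STN, GPe, GPi), their
synaptic gates and the external inputs with a fixed-step explicit scheme
(RK4 by default, dt = 0.01 ms).  Thalamic neurons receive a shared
sensorimotor-cortex (SMC) pulse train -- 3 uA/cm^2, 5 ms rectangles whose
inter-pulse intervals are Gaussian with mean 1000/14 ms and CV 0.2 -- and
the DBS waveform is added as an identical current density to every neuron
of each targeted population (STN by default).  Spikes are upward crossings
of -20 mV with a 2 ms refractory window, detected during integration.

Everything is reproducible bit-for-float given (config, seed): the seed
drives the SMC train, the initial-state jitter and (in random mode) the
wiring, through independent ``numpy`` SeedSequence spawns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .cell_models import CELL_TYPES, load_cell_params
from .network import Topology, build_topology, load_synapse_params
from .waveforms import SampledWaveform, WaveformSpec, sample

__all__ = [
    "SimulationError",
    "SMCSpec",
    "SimulationConfig",
    "SpikeTrain",
    "SimulationResult",
    "generate_smc_train",
    "run_simulation",
    "detect_spikes",
]

_POP_INDEX = {"TH": 0, "STN": 1, "GPe": 2, "GPi": 3}


class SimulationError(RuntimeError):
    """Raised when the integration blows up numerically."""


@dataclass(frozen=True)
class SMCSpec:
    """Sensorimotor-cortex pulse train: rectangular pulses with Gaussian
    inter-pulse intervals (mean 1000/rate, sd = cv * mean, redrawn while
    shorter than the pulse width so pulses never overlap)."""

    amplitude: float = 3.0   # uA/cm^2
    pulse_width: float = 5.0  # ms
    rate: float = 14.0        # Hz
    cv: float = 0.2
    seed: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    n_per_pop: int = 100
    condition: str = "healthy"          # "healthy" | "pd"
    dbs: WaveformSpec | None = None
    dbs_targets: tuple[str, ...] = ("STN",)
    dt: float = 0.01                    # ms
    duration: float = 1500.0            # ms
    seed: int = 0
    topology_mode: str = "structured"
    method: str = "rk4"                 # "rk4" | "euler"
    smc: SMCSpec = field(default_factory=SMCSpec)
    threshold: float = -20.0            # mV, spike detection
    refractory: float = 2.0             # ms
    record_voltages: int = 0            # neurons per population to trace
    record_stride: int = 10             # steps between trace samples

    def __post_init__(self):
        if self.condition.lower() not in ("healthy", "pd"):
            raise ValueError(f"unknown condition {self.condition!r}")
        bad = set(self.dbs_targets) - {"STN", "GPe", "GPi"}
        if bad:
            raise ValueError(
                f"invalid DBS targets {sorted(bad)}: only STN, GPe and GPi "
                "are subject to stimulation"
            )
        if self.n_per_pop < 3:
            raise ValueError("n_per_pop must be >= 3")
        if self.method not in ("rk4", "euler"):
            raise ValueError(f"unknown integration method {self.method!r}")

    def echo(self) -> dict:
        d = {
            "n_per_pop": self.n_per_pop,
            "condition": self.condition,
            "dbs": self.dbs.to_dict() if self.dbs else None,
            "dbs_targets": list(self.dbs_targets),
            "dt": self.dt,
            "duration": self.duration,
            "seed": self.seed,
            "topology_mode": self.topology_mode,
            "method": self.method,
            "smc": vars(self.smc).copy(),
            "threshold": self.threshold,
            "refractory": self.refractory,
        }
        return d


@dataclass
class SpikeTrain:
    """Ordered spike times of one neuron."""

    neuron_id: int
    times: np.ndarray  # ms, strictly increasing
    threshold: float = -20.0
    population: str = ""

    def rate(self, t0: float = 0.0, t1: float | None = None) -> float:
        """Mean firing rate in Hz over [t0, t1) ms."""
        if t1 is None:
            t1 = self.times[-1] if self.times.size else t0
        if t1 <= t0:
            return 0.0
        mask = (self.times >= t0) & (self.times < t1)
        return 1000.0 * mask.sum() / (t1 - t0)


@dataclass
class SimulationResult:
    spikes: dict[str, list[SpikeTrain]]
    dbs_onsets: np.ndarray
    config: SimulationConfig
    seed: int
    voltages: dict[str, np.ndarray] | None = None  # (n_rec, n_samples)
    trace_dt: float | None = None
    clamp_events: int = 0

    def mean_rate(self, pop: str, t0: float = 0.0, t1: float | None = None) -> float:
        if t1 is None:
            t1 = self.config.duration
        return float(np.mean([st.rate(t0, t1) for st in self.spikes[pop]]))

    def spikes_dataframe(self) -> pd.DataFrame:
        rows = []
        for pop, trains in self.spikes.items():
            for st in trains:
                for t in st.times:
                    rows.append((pop, st.neuron_id, t))
        return pd.DataFrame(rows, columns=["population", "neuron_id", "t_ms"])

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes_dataframe().to_csv(out / "spikes.csv", index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.echo(), fh)
        np.savetxt(out / "dbs_onsets.csv", self.dbs_onsets, delimiter=",")
        if self.voltages is not None:
            np.savez_compressed(
                out / "voltages.npz",
                trace_dt=self.trace_dt,
                **{p: v for p, v in self.voltages.items()},
            )


def generate_smc_train(
    spec: SMCSpec, duration: float, dt: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled SMC current (midpoint convention) and its pulse onset times.

    Deterministic given ``spec.seed``; cv = 0 degenerates to a perfectly
    periodic train.
    """
    if spec.cv < 0:
        raise ValueError("coefficient of variation must be >= 0")
    if duration <= spec.pulse_width:
        raise ValueError("duration must exceed the pulse width")
    rng = np.random.default_rng(spec.seed)
    mean_ipi = 1000.0 / spec.rate
    sd = spec.cv * mean_ipi

    def draw() -> float:
        if sd == 0.0:
            return mean_ipi
        while True:
            x = rng.normal(mean_ipi, sd)
            if x >= spec.pulse_width:
                return x

    onsets = []
    t = draw()
    while t < duration:
        onsets.append(t)
        t += draw()
    onsets = np.asarray(onsets)
    n = int(round(duration / dt))
    tmid = (np.arange(n) + 0.5) * dt
    current = np.zeros(n)
    for t0 in onsets:
        i0 = np.searchsorted(tmid, t0)
        i1 = np.searchsorted(tmid, t0 + spec.pulse_width)
        current[i0:i1] = spec.amplitude
    return current, onsets


def detect_spikes(
    trace: np.ndarray,
    dt: float,
    threshold: float = -20.0,
    refractory: float = 2.0,
    t0: float = 0.0,
    neuron_id: int = 0,
) -> SpikeTrain:
    """Spike times from a uniformly sampled voltage trace.

    A spike is a strict upward crossing of ``threshold`` (previous sample
    below, current sample strictly above); crossings within ``refractory`` ms
    of the previous accepted spike are suppressed.  A trace that only
    touches the threshold from below without crossing yields no spike.
    """
    v = np.asarray(trace, dtype=float)
    crossings = np.flatnonzero((v[:-1] < threshold) & (v[1:] > threshold)) + 1
    times = []
    last = -np.inf
    for k in crossings:
        t = t0 + k * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return SpikeTrain(neuron_id=neuron_id, times=np.asarray(times),
                      threshold=threshold)


def run_single_stn(
    drive: WaveformSpec | np.ndarray | None,
    duration: float,
    condition: str = "healthy",
    dt: float = 0.01,
    method: str = "rk4",
    threshold: float = -20.0,
    refractory: float = 2.0,
    record: bool = False,
    settle: float = 200.0,
) -> tuple[SpikeTrain, np.ndarray | None, np.ndarray]:
    """Integrate one isolated STN neuron under a DBS waveform (or a raw
    sampled current, or nothing).

    The neuron starts from its deterministic near-rest state and is settled
    for ``settle`` ms without stimulation before the drive begins, so the
    response to the first pulse is not an initial-condition artifact.
    Returns (spike train, voltage trace or None, pulse onset times); spike
    times are relative to the start of the drive (t = 0), the settle period
    contributes spikes at negative times.
    """
    from .cell_models import init_resting_state

    stn = load_cell_params("STN")
    cond = condition.lower()
    stn_p = _kernels.pack_stn(stn.raw, cond)
    rest = init_resting_state(stn, cond)
    y = np.array([rest.V, rest.gates["h"], rest.gates["n"], rest.gates["r"]])

    n_settle = int(round(settle / dt))
    n_drive = int(round(duration / dt))
    if drive is None:
        i_ext = np.zeros(n_drive)
        onsets = np.array([])
    elif isinstance(drive, WaveformSpec):
        sw = sample(drive, dt, duration)
        i_ext = sw.samples
        onsets = sw.pulse_onsets
    else:
        i_ext = np.asarray(drive, dtype=float)
        n_drive = i_ext.size
        onsets = np.array([])
    full = np.concatenate([np.zeros(n_settle), i_ext])
    n_steps = full.size
    max_spk = int(n_steps * dt / refractory) + 2
    spike_buf = np.zeros(max_spk)
    trace = np.empty(n_steps if record else 0)
    count = _kernels.run_single_stn(
        y, dt, n_steps, method == "rk4", stn_p, full,
        threshold, refractory, spike_buf, trace,
    )
    times = spike_buf[: min(count, max_spk)] - settle
    st = SpikeTrain(neuron_id=0, times=times, threshold=threshold,
                    population="STN")
    return st, (trace if record else None), onsets


def _initial_state(n: int, rng: np.random.Generator) -> np.ndarray:
    """Packed initial state: per-neuron voltages jittered uniformly in
    [-75, -55] mV (symmetry breaking), dynamic gates at steady state of the
    drawn voltage, synaptic gates closed."""
    Y = np.zeros((_kernels.NVAR, n))
    cells = {ct: load_cell_params(ct) for ct in CELL_TYPES}
    v0 = {ct: rng.uniform(-75.0, -55.0, size=n) for ct in CELL_TYPES}
    rows = {
        "TH": (0, ("h", "r")),
        "STN": (3, ("h", "n", "r")),
        "GPe": (7, ("h", "n", "r")),
        "GPi": (11, ("h", "n", "r")),
    }
    for ct, (vr, gates) in rows.items():
        Y[vr] = v0[ct]
        for j, gname in enumerate(gates):
            Y[vr + 1 + j] = cells[ct].gates[gname].steady_state(v0[ct])
    return Y


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Integrate the full network and return spike trains per population."""
    n = config.n_per_pop
    ss = np.random.SeedSequence(config.seed)
    seed_topo, seed_init, seed_smc = (s.generate_state(1)[0] % (2**31)
                                      for s in ss.spawn(3))
    topo = build_topology(n, seed=int(seed_topo), mode=config.topology_mode)

    cond = config.condition.lower()
    th_p = _kernels.pack_th(load_cell_params("TH").raw, cond)
    stn_p = _kernels.pack_stn(load_cell_params("STN").raw, cond)
    gpe_p = _kernels.pack_gp(load_cell_params("GPe").raw, cond)
    gpi_p = _kernels.pack_gp(load_cell_params("GPi").raw, cond)

    syn = load_synapse_params()
    order = ("GPi->TH", "GPe->STN", "STN->GPe", "GPe->GPe", "STN->GPi", "GPe->GPi")
    syn_g = np.array([syn[k].g_syn for k in order])
    syn_E = np.array([syn[k].E_syn for k in order])
    kin_exc = _kernels.pack_syn_kinetics(syn["STN->GPe"].kinetics)
    kin_inh = _kernels.pack_syn_kinetics(syn["GPe->STN"].kinetics)

    n_steps = int(round(config.duration / config.dt))
    smc_spec = replace(config.smc, seed=int(seed_smc))
    smc, _ = generate_smc_train(smc_spec, config.duration, config.dt)

    if config.dbs is not None:
        sw = sample(config.dbs, config.dt, config.duration)
        dbs = sw.samples
        dbs_onsets = sw.pulse_onsets
    else:
        dbs = np.zeros(n_steps)
        dbs_onsets = np.array([])
    targets = set(config.dbs_targets) if config.dbs is not None else set()

    rng = np.random.default_rng(int(seed_init))
    Y = _initial_state(n, rng)

    max_spk = int(config.duration / config.refractory) + 2
    spike_times = np.zeros((4, n, max_spk))
    spike_counts = np.zeros((4, n), dtype=np.int64)
    n_rec = min(config.record_voltages, n)
    if n_rec > 0:
        n_samples = n_steps // config.record_stride
        traces = np.zeros((4, n_rec, n_samples))
        stride = config.record_stride
    else:
        traces = np.zeros((4, 0, 0))
        stride = 0

    status, t_fail, pop_fail, neuron_fail, clamps = _kernels.run_network(
        Y, config.dt, n_steps, config.method == "rk4",
        th_p, stn_p, gpe_p, gpi_p,
        syn_g, syn_E, kin_exc, kin_inh,
        topo.afferents["GPi->TH"], topo.afferents["GPe->STN"],
        topo.afferents["STN->GPe"], topo.afferents["GPe->GPe"],
        topo.afferents["STN->GPi"], topo.afferents["GPe->GPi"],
        smc, dbs,
        "STN" in targets, "GPe" in targets, "GPi" in targets,
        config.threshold, config.refractory,
        spike_times, spike_counts,
        stride, traces,
    )
    if status != 0:
        pop = CELL_TYPES[pop_fail]
        raise SimulationError(
            f"|V| > 200 mV at t = {t_fail:.2f} ms "
            f"({pop} neuron {neuron_fail}); integration aborted"
        )

    spikes: dict[str, list[SpikeTrain]] = {}
    for pop, q in _POP_INDEX.items():
        spikes[pop] = [
            SpikeTrain(
                neuron_id=i,
                times=spike_times[q, i, : spike_counts[q, i]].copy(),
                threshold=config.threshold,
                population=pop,
            )
            for i in range(n)
        ]
    voltages = None
    trace_dt = None
    if n_rec > 0:
        voltages = {pop: traces[q] for pop, q in _POP_INDEX.items()}
        trace_dt = config.dt * config.record_stride
    return SimulationResult(
        spikes=spikes,
        dbs_onsets=dbs_onsets,
        config=config,
        seed=config.seed,
        voltages=voltages,
        trace_dt=trace_dt,
        clamp_events=int(clamps),
    )
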