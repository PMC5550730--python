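"""Parametric biphasic DBS waveforms and their charge/energy accounting.

A stimulus pulse is a cathodic (depolarizing) phase, an optional zero-current
interphase delay, and an anodic (charge-recovery) phase, repeated at the
stimulation frequency.  Three phase shapes are supported -- rectangular,
half-sine and (truncated) Gaussian -- giving the six named presets:

====================  ===========  ==========
name                  shape        delay (ms)
====================  ===========  ==========
Pulse                 rectangular  0
PDP  (pulse-delay-pulse)     rectangular  0.7
Sinusoid              half_sine    0
SDS  (sine-delay-sine)       half_sine    0.7
Gaussian              gaussian     0
GDG  (gaussian-delay-gaussian) gaussian   0.7
====================  ===========  ==========

All presets use a 200 uA/cm^2 x 0.3 ms cathodic phase, a -20 uA/cm^2 x 1 ms
anodic phase and 130 Hz.  Cathodic current is stored positive (it is the
depolarizing current injected into the unit-area compartment); the anodic
phase is negative.  Note the nominal presets are *not* exactly charge
balanced (60 vs -20 uA*ms/cm^2); ``rebalanced`` rescales the anodic
amplitude when exact balance is wanted.

Sampling uses midpoint convention: ``samples[k]`` is the current at
``t = (k + 1/2) * dt``, so the discrete energy ``Z * dt * sum(I^2)`` is the
midpoint quadrature of the energy integral (exact for grid-aligned
rectangles, O(dt^2) otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

__all__ = [
    "SHAPES",
    "PRESET_NAMES",
    "PhaseSpec",
    "WaveformSpec",
    "SampledWaveform",
    "make_preset",
    "sample",
    "phase_charge",
    "phase_energy",
    "pulse_energy",
    "waveform_energy",
    "charge_imbalance",
    "rebalanced",
]

SHAPES = ("rectangular", "half_sine", "gaussian")
PRESET_NAMES = ("Pulse", "PDP", "Sinusoid", "SDS", "Gaussian", "GDG")

# delay variant -> its zero-delay counterpart
DELAY_COUNTERPART = {"PDP": "Pulse", "SDS": "Sinusoid", "GDG": "Gaussian"}


@dataclass(frozen=True)
class PhaseSpec:
    """One phase of a biphasic pulse.

    ``amplitude`` is the peak current in uA/cm^2 (signed; cathodic positive).
    The Gaussian bell peaks at the phase midpoint with sigma =
    width / sigma_divisor and is truncated to [0, width].
    """

    shape: str
    amplitude: float
    width: float  # ms
    sigma_divisor: float = 6.0

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown phase shape {self.shape!r}")
        if self.width <= 0:
            raise ValueError("phase width must be positive")
        if self.sigma_divisor <= 0:
            raise ValueError("sigma_divisor must be positive")

    @property
    def sigma(self) -> float:
        return self.width / self.sigma_divisor

    def value(self, u):
        """Current at time u (ms) after phase onset; 0 outside [0, width)."""
        u = np.asarray(u, dtype=float)
        inside = (u >= 0.0) & (u < self.width)
        if self.shape == "rectangular":
            out = np.where(inside, self.amplitude, 0.0)
        elif self.shape == "half_sine":
            out = np.where(
                inside, self.amplitude * np.sin(np.pi * u / self.width), 0.0
            )
        else:
            out = np.where(
                inside,
                self.amplitude
                * np.exp(-((u - self.width / 2.0) ** 2) / (2.0 * self.sigma**2)),
                0.0,
            )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class WaveformSpec:
    """Cathodic phase -> interphase delay -> anodic phase, at ``frequency`` Hz."""

    cathodic: PhaseSpec
    delay: float
    anodic: PhaseSpec
    frequency: float
    name: str = ""

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("interphase delay must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.active_width >= self.period:
            raise ValueError(
                f"pulse ({self.active_width:.3f} ms) does not fit the "
                f"{self.period:.3f} ms period"
            )

    @property
    def period(self) -> float:
        return 1000.0 / self.frequency

    @property
    def active_width(self) -> float:
        return self.cathodic.width + self.delay + self.anodic.width

    def value(self, u):
        """Current at time u (ms) after pulse onset."""
        u = np.asarray(u, dtype=float)
        out = self.cathodic.value(u) + self.anodic.value(
            u - self.cathodic.width - self.delay
        )
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WaveformSpec":
        return cls(
            cathodic=PhaseSpec(**d["cathodic"]),
            delay=d["delay"],
            anodic=PhaseSpec(**d["anodic"]),
            frequency=d["frequency"],
            name=d.get("name", ""),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "WaveformSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SampledWaveform:
    """Discretized pulse train (midpoint samples) with its cathodic onsets."""

    dt: float
    samples: np.ndarray
    pulse_onsets: np.ndarray
    spec: WaveformSpec | None = None

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    def to_csv(self, path) -> None:
        t = (np.arange(self.samples.size) + 0.5) * self.dt
        np.savetxt(
            path,
            np.column_stack([t, self.samples]),
            delimiter=",",
            header="t_ms,I_uA_per_cm2",
            comments="",
        )


_PRESET_SHAPE = {
    "Pulse": "rectangular",
    "PDP": "rectangular",
    "Sinusoid": "half_sine",
    "SDS": "half_sine",
    "Gaussian": "gaussian",
    "GDG": "gaussian",
}


def make_preset(
    name: str,
    delay: float | None = None,
    cathodic_amplitude: float = 200.0,
    frequency: float = 130.0,
) -> WaveformSpec:
    """The six reference waveforms: 200 uA/cm^2 x 0.3 ms cathodic,
    -20 uA/cm^2 x 1 ms anodic (1:3.3 width, 10:1 amplitude ratio), 130 Hz;
    0.7 ms interphase delay for the delay variants (PDP/SDS/GDG).

    ``delay`` / ``cathodic_amplitude`` / ``frequency`` override the preset
    values for parameter sweeps; the anodic amplitude keeps the 10:1 ratio.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    shape = _PRESET_SHAPE[name]
    if delay is None:
        delay = 0.7 if name in DELAY_COUNTERPART else 0.0
    return WaveformSpec(
        cathodic=PhaseSpec(shape, cathodic_amplitude, 0.3),
        delay=delay,
        anodic=PhaseSpec(shape, -cathodic_amplitude / 10.0, 1.0),
        frequency=frequency,
        name=name,
    )


def sample(spec: WaveformSpec, dt: float, duration: float) -> SampledWaveform:
    """Discretize a pulse train over [0, duration) ms; first onset at t = 0."""
    if dt > spec.cathodic.width / 10.0 + 1e-12:
        raise ValueError(
            f"dt = {dt} ms too coarse: must be <= cathodic width / 10 "
            f"= {spec.cathodic.width / 10.0} ms"
        )
    n = int(round(duration / dt))
    t = (np.arange(n) + 0.5) * dt
    u = np.mod(t, spec.period)
    samples = spec.value(u)
    onsets = np.arange(0.0, duration, spec.period)
    return SampledWaveform(dt=dt, samples=samples, pulse_onsets=onsets, spec=spec)


def phase_charge(phase: PhaseSpec) -> float:
    """Analytic charge of one phase in uA*ms/cm^2 (signed)."""
    A, w = phase.amplitude, phase.width
    if phase.shape == "rectangular":
        return A * w
    if phase.shape == "half_sine":
        return 2.0 * A * w / math.pi
    s = phase.sigma
    return A * s * math.sqrt(2.0 * math.pi) * math.erf(w / (2.0 * s * math.sqrt(2.0)))


def phase_energy(phase: PhaseSpec, Z: float = 1.0) -> float:
    """Analytic single-phase energy integral Z * int I^2 dt, in nJ
    (uA^2 * kOhm * ms = 1e-3 nJ for the unit-area compartment)."""
    A, w = phase.amplitude, phase.width
    if phase.shape == "rectangular":
        e = A * A * w
    elif phase.shape == "half_sine":
        e = A * A * w / 2.0
    else:
        s = phase.sigma
        e = A * A * s * math.sqrt(math.pi) * math.erf(w / (2.0 * s))
    return e * Z * 1e-3


def pulse_energy(spec: WaveformSpec, Z: float = 1.0) -> float:
    """Analytic per-pulse energy (both phases; the delay contributes 0), nJ."""
    return phase_energy(spec.cathodic, Z) + phase_energy(spec.anodic, Z)


def waveform_energy(w: SampledWaveform, Z: float = 1.0, window: float | None = None) -> float:
    """Energy Z * int I(t)^2 dt over [0, window] ms of a sampled train, in nJ.

    Midpoint quadrature of the sampled trace; with uA, kOhm and ms inputs the
    scale factor to nJ is 1e-3.
    """
    if window is None:
        window = w.duration
    if window > w.duration + w.dt / 2.0:
        raise ValueError(f"window {window} ms exceeds sampled duration {w.duration} ms")
    n = min(int(round(window / w.dt)), w.samples.size)
    s = w.samples[:n]
    return float(Z * w.dt * np.sum(s * s) * 1e-3)


def charge_imbalance(spec: WaveformSpec) -> float:
    """Net injected charge per pulse, uA*ms/cm^2 (0 = charge balanced)."""
    return phase_charge(spec.cathodic) + phase_charge(spec.anodic)


def rebalanced(spec: WaveformSpec) -> WaveformSpec:
    """Rescale the anodic amplitude so each pulse carries zero net charge."""
    q_c = phase_charge(spec.cathodic)
    q_a = phase_charge(spec.anodic)
    if q_a == 0.0:
        raise ValueError("anodic phase has zero charge; cannot rebalance")
    scale = -q_c / q_a
    return replace(spec, anodic=replace(spec.anodic, amplitude=spec.anodic.amplitude * scale))
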