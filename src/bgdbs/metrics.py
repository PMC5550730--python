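"""Evaluation statistics for DBS waveforms and network firing patterns.

* **Cost**: energy of the stimulus train over a window, ``int I(t)^2 Z dt``
  at constant impedance Z = 1 kOhm, plus a 3 nJ penalty for every DBS pulse
  that fails to elicit an action potential (a *miss*).
* **Mutual information** between two equal-length firing signals, plug-in
  histogram estimator in nats.
* **Phase-locking value**: modulus of the mean unit phasor of the
  instantaneous (Hilbert) phase difference.
* **Synchronization Level (SL)**: spike counts in non-overlapping 15 ms
  frames per neuron; Pearson correlation of the per-neuron count functions
  over all pairs; SL is the fraction of pairs significantly correlated at
  alpha = 0.05.  Under independence SL calibrates to the test's type-I
  error rate (~alpha); fully synchronized populations give SL = 1.
* **Normalized energy threshold (NET)**: over a (interphase delay x
  stimulation frequency) grid, the minimal per-window stimulus energy that
  makes at least 50% of pulses elicit a spike on the model STN neuron,
  min-max normalized to [0, 1] per grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.stats import t as t_dist

from .waveforms import SampledWaveform, WaveformSpec, waveform_energy

__all__ = [
    "MISS_PENALTY_NJ",
    "CostReport",
    "MIEstimate",
    "PLVResult",
    "SLReport",
    "NETGrid",
    "count_misses",
    "cost",
    "mutual_information",
    "instantaneous_phase",
    "plv",
    "plv_from_phases",
    "smoothed_rate",
    "ap_count_functions",
    "synchronization_level",
    "net_grid",
]

MISS_PENALTY_NJ = 3.0


# ---------------------------------------------------------------------------
# cost function


@dataclass
class CostReport:
    energy: float           # nJ over the window
    misses: float           # M (may be a per-neuron average)
    penalty_per_miss: float  # nJ
    total: float            # C = energy + penalty * M
    window: float           # ms


def count_misses(pulse_onsets, spikes, period: float) -> int:
    """Number of DBS pulses with no spike in [onset, onset + period).

    ``spikes`` is a SpikeTrain or an array of spike times (ms).  Windows tile
    the inter-pulse interval, so each spike is credited to at most one pulse;
    onsets closer together than ``period`` are rejected as mis-configured.
    """
    onsets = np.asarray(pulse_onsets, dtype=float)
    times = np.asarray(getattr(spikes, "times", spikes), dtype=float)
    if onsets.size == 0:
        return 0
    if np.any(np.diff(onsets) < period - 1e-9):
        raise ValueError("pulse windows overlap: period exceeds onset spacing")
    hits = np.searchsorted(times, onsets + period) - np.searchsorted(times, onsets)
    return int(np.sum(hits == 0))


def cost(
    waveform: SampledWaveform,
    Z: float = 1.0,
    M: float = 0,
    window: float | None = None,
    penalty: float = MISS_PENALTY_NJ,
) -> CostReport:
    """Stimulation cost C = energy(window) + penalty * M, in nJ."""
    if M < 0:
        raise ValueError("miss count must be >= 0")
    if window is None:
        window = waveform.duration
    e = waveform_energy(waveform, Z=Z, window=window)
    return CostReport(
        energy=e, misses=M, penalty_per_miss=penalty,
        total=e + penalty * M, window=window,
    )


# ---------------------------------------------------------------------------
# mutual information


@dataclass
class MIEstimate:
    mi: float               # nats
    bins: int
    joint: np.ndarray       # joint histogram counts (bins x bins)


def mutual_information(y1, y2, bins: int = 8) -> MIEstimate:
    """Plug-in mutual information of two equal-length signals, in nats.

    Each signal is discretized into ``bins`` equal-width amplitude bins over
    its own range; zero-probability cells contribute nothing.  A constant
    signal occupies a single bin and yields MI = 0.
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    if y1.size != y2.size:
        raise ValueError("signals must have equal length")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    joint, _, _ = np.histogram2d(y1, y2, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    mi = float(np.nansum(terms))
    return MIEstimate(mi=max(mi, 0.0), bins=bins, joint=joint)


# ---------------------------------------------------------------------------
# phase locking


@dataclass
class PLVResult:
    plv: float
    length: int
    mode: str = "hilbert"


def instantaneous_phase(y) -> np.ndarray:
    """Four-quadrant instantaneous phase of the analytic signal, in (-pi, pi].

    The mean is removed first; an all-zero (or constant) signal has no
    defined phase and raises ValueError.  Scaling the signal leaves the
    phase unchanged.
    """
    y = np.asarray(y, dtype=float).ravel()
    y = y - y.mean()
    if not np.any(np.abs(y) > 0):
        raise ValueError("phase undefined for a constant signal")
    return np.angle(hilbert(y))


def plv_from_phases(phi_ref, phi_test) -> PLVResult:
    phi_ref = np.asarray(phi_ref, dtype=float).ravel()
    phi_test = np.asarray(phi_test, dtype=float).ravel()
    if phi_ref.size != phi_test.size:
        raise ValueError("phase series must have equal length")
    val = float(np.abs(np.mean(np.exp(1j * (phi_ref - phi_test)))))
    return PLVResult(plv=min(val, 1.0), length=phi_ref.size)


def plv(y_ref, y_test) -> PLVResult:
    """Phase-locking value of two equal-length continuous signals.

    1 for identical signals or a constant phase lag; -> 0 for independent
    phases as the series length grows.
    """
    return plv_from_phases(instantaneous_phase(y_ref), instantaneous_phase(y_test))


def smoothed_rate(
    trains, duration: float, dt: float = 1.0, sigma: float = 10.0
) -> np.ndarray:
    """Population firing-rate signal: spikes of all trains binned at ``dt``
    ms and convolved with a Gaussian kernel (sigma ms).  Used to turn spike
    trains into the continuous signals the Hilbert phase needs."""
    n_bins = int(round(duration / dt))
    counts = np.zeros(n_bins)
    trains = trains if isinstance(trains, (list, tuple)) else [trains]
    for st in trains:
        times = np.asarray(getattr(st, "times", st), dtype=float)
        idx = (times / dt).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1.0)
    half = int(4 * sigma / dt)
    x = np.arange(-half, half + 1) * dt
    kernel = np.exp(-(x**2) / (2.0 * sigma**2))
    kernel /= kernel.sum()
    return np.convolve(counts, kernel, mode="same") / (dt / 1000.0) / max(len(trains), 1)


# ---------------------------------------------------------------------------
# synchronization level


@dataclass
class SLReport:
    sl: float               # N_S / N_T
    n_significant: int      # N_S
    n_total: int            # N_T (evaluated pairs, upper triangle)
    frame: float            # ms
    alpha: float
    n_frames: int
    corr: np.ndarray        # full symmetric correlation matrix (nan = excluded)
    pvalues: np.ndarray
    n_excluded: int         # zero-variance count functions left out
    diagonal_excluded: bool = True


def ap_count_functions(trains, frame: float = 15.0, duration: float | None = None,
                       t0: float = 0.0) -> np.ndarray:
    """Per-neuron action-potential counts in consecutive non-overlapping
    frames of ``frame`` ms over [t0, t0 + duration); the partial trailing
    frame is discarded.  Returns an (n_neurons, n_frames) integer array."""
    if frame <= 0:
        raise ValueError("frame must be positive")
    if duration is None:
        duration = max(
            (np.asarray(getattr(st, "times", st)).max(initial=0.0) for st in trains),
            default=0.0,
        ) - t0
    n_frames = int(duration / frame)
    if n_frames < 2:
        raise ValueError("need at least 2 full frames")
    edges = t0 + np.arange(n_frames + 1) * frame
    F = np.empty((len(trains), n_frames), dtype=np.int64)
    for i, st in enumerate(trains):
        times = np.asarray(getattr(st, "times", st), dtype=float)
        F[i], _ = np.histogram(times, bins=edges)
    return F


def synchronization_level(
    trains_or_counts,
    frame: float = 15.0,
    alpha: float = 0.05,
    duration: float | None = None,
    t0: float = 0.0,
) -> SLReport:
    """Fraction of neuron pairs whose frame-count functions are significantly
    Pearson-correlated.

    Accepts spike trains (converted with :func:`ap_count_functions`) or an
    (n, L) count matrix.  Significance is a two-sided t-test on rho with
    L - 2 degrees of freedom at level ``alpha``.  Pairs are counted once
    (upper triangle, diagonal excluded); zero-variance count functions have
    undefined correlation and are excluded from both N_S and N_T.
    """
    F = np.asarray(trains_or_counts)
    if F.ndim != 2:
        F = ap_count_functions(trains_or_counts, frame=frame, duration=duration, t0=t0)
    F = F.astype(float)
    n, L = F.shape
    if n < 2:
        raise ValueError("need at least 2 neurons")
    sd = F.std(axis=1)
    valid = sd > 0
    n_excluded = int(np.sum(~valid))
    if valid.sum() < 2:
        raise ValueError("SL undefined: fewer than 2 non-constant count functions")
    Z = F - F.mean(axis=1, keepdims=True)
    norm = np.sqrt((Z**2).sum(axis=1))
    norm[~valid] = np.nan
    R = (Z @ Z.T) / np.outer(norm, norm)
    np.clip(R, -1.0, 1.0, out=R)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((L - 2) / (1.0 - R**2))
        P = 2.0 * t_dist.sf(np.abs(tstat), df=L - 2)
    P[np.isnan(R)] = np.nan
    # |rho| = 1 gives an infinite t statistic -> p = 0
    P[np.isclose(np.abs(R), 1.0)] = 0.0
    iu, ju = np.triu_indices(n, k=1)
    pair_ok = valid[iu] & valid[ju]
    n_total = int(pair_ok.sum())
    n_sig = int(np.sum(P[iu, ju][pair_ok] <= alpha))
    return SLReport(
        sl=n_sig / n_total,
        n_significant=n_sig,
        n_total=n_total,
        frame=frame,
        alpha=alpha,
        n_frames=L,
        corr=R,
        pvalues=P,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# normalized energy threshold


@dataclass
class NETGrid:
    delays: np.ndarray      # ms
    frequencies: np.ndarray  # Hz
    raw: np.ndarray         # minimal energy (nJ), nan = criterion unreachable
    net: np.ndarray         # min-max normalized to [0, 1]
    criterion: float = 0.5
    shape: str = "gaussian"


def net_grid(
    shape: str,
    delays,
    frequencies,
    criterion: float = 0.5,
    window: float = 200.0,
    amp_cap: float = 400.0,
    amp_resolution: float = 1.0,
    condition: str = "healthy",
    dt: float = 0.01,
) -> NETGrid:
    """Minimal stimulus energy reaching >= ``criterion`` pulse-to-spike
    success on the model STN neuron, over a delay x frequency grid.

    For each cell, the cathodic amplitude is bisected (anodic amplitude kept
    at the 10:1 ratio, widths at 0.3 / 1.0 ms); the achieved minimal
    amplitude's waveform energy over ``window`` ms is the raw threshold.
    Cells whose criterion is unreachable at ``amp_cap`` are flagged NaN and
    excluded from the per-grid min-max normalization.
    """
    from .experiments import minimal_cathodic_amplitude  # local: avoid cycle
    from .waveforms import make_preset, pulse_energy, sample as _sample

    delays = np.asarray(delays, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    if delays.size == 0 or frequencies.size == 0:
        raise ValueError("axes must be non-empty")
    preset = {"rectangular": "PDP", "half_sine": "SDS", "gaussian": "GDG"}[shape]
    raw = np.full((delays.size, frequencies.size), np.nan)
    for i, dl in enumerate(delays):
        for j, fs in enumerate(frequencies):
            amp = minimal_cathodic_amplitude(
                preset, delay=dl, frequency=fs, success_fraction=criterion,
                amp_cap=amp_cap, resolution=amp_resolution,
                condition=condition, dt=dt, window=window,
            )
            if np.isnan(amp):
                continue
            spec = make_preset(preset, delay=dl, cathodic_amplitude=amp,
                               frequency=fs)
            n_pulses = int(np.ceil(window / spec.period))
            raw[i, j] = pulse_energy(spec) * n_pulses
    finite = np.isfinite(raw)
    net = np.full_like(raw, np.nan)
    if finite.any():
        lo, hi = raw[finite].min(), raw[finite].max()
        net[finite] = 0.0 if hi == lo else (raw[finite] - lo) / (hi - lo)
    return NETGrid(delays=delays, frequencies=frequencies, raw=raw, net=net,
                   criterion=criterion, shape=shape)
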