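"""Population wiring and synaptic currents of the basal ganglia loop.

Six projections connect the four populations: each GPe neuron receives
2 STN (excitatory) and 2 GPe (inhibitory) afferents, each GPi receives
2 STN and 2 GPe, each STN receives 2 GPe, and each thalamic neuron
receives 1 GPi afferent.  Synaptic currents follow the same conductance
form as the ionic currents,

    I_pre->post = g_syn * sum_i s_i * (V_post - E_syn),

with a first-order gating variable s per presynaptic neuron that opens
while the presynaptic membrane is above threshold and decays otherwise.
Excitatory projections reverse at 0 mV, inhibitory ones at -85 mV.

Partner assignment is structured wrap-around by default (post ``i``
listens to pre ``i``, ``i+1`` mod n; recurrent GPe->GPe uses ``i+1``,
``i+2`` so a neuron never inhibits itself), or seeded uniform-random
without replacement in ``mode="random"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import yaml

__all__ = [
    "WiringError",
    "SynapseParams",
    "SynapseState",
    "Topology",
    "PROJECTIONS",
    "load_synapse_params",
    "build_topology",
    "synaptic_current",
    "update_synapse",
]

PROJECTIONS = ("GPi->TH", "GPe->STN", "STN->GPe", "GPe->GPe", "STN->GPi", "GPe->GPi")


class WiringError(ValueError):
    """Raised when wiring or fan-in constraints are violated."""


@dataclass(frozen=True)
class SynapseKinetics:
    """First-order synaptic gate: s' = alpha*T(V_pre)*(1-s) - beta*s."""

    alpha: float  # 1/ms, rise while presynaptic terminal is active
    beta: float   # 1/ms, decay
    theta: float  # mV, presynaptic activation threshold
    k: float      # mV, steepness of the activation sigmoid

    def activation(self, V_pre: float):
        return 1.0 / (1.0 + np.exp(-(V_pre - self.theta) / self.k))

    @property
    def s_max(self) -> float:
        """Saturation value under a sustained suprathreshold presynaptic V."""
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class SynapseParams:
    pre_pop: str
    post_pop: str
    g_syn: float
    E_syn: float
    sign: str          # "excitatory" | "inhibitory"
    fan_in: int
    kinetics: SynapseKinetics

    @property
    def name(self) -> str:
        return f"{self.pre_pop}->{self.post_pop}"


@dataclass
class SynapseState:
    """Gate value per presynaptic neuron of one projection."""

    s: np.ndarray

    def copy(self) -> "SynapseState":
        return SynapseState(self.s.copy())


_SYN_CACHE: dict[str, SynapseParams] = {}


def load_synapse_params(projection: str | None = None):
    """Load synapse parameter tables; one projection or all six as a dict."""
    if not _SYN_CACHE:
        raw = yaml.safe_load(
            (resources.files("bgdbs") / "params" / "synapses.yaml").read_text()
        )
        for name, p in raw["projections"].items():
            kin = raw["kinetics"][p["sign"]]
            _SYN_CACHE[name] = SynapseParams(
                pre_pop=p["pre"],
                post_pop=p["post"],
                g_syn=float(p["g_syn"]),
                E_syn=float(p["E_syn"]),
                sign=p["sign"],
                fan_in=int(p["fan_in"]),
                kinetics=SynapseKinetics(
                    alpha=float(kin["alpha"]),
                    beta=float(kin["beta"]),
                    theta=float(kin["theta"]),
                    k=float(kin["k"]),
                ),
            )
    if projection is None:
        return dict(_SYN_CACHE)
    if projection not in _SYN_CACHE:
        raise WiringError(f"unknown projection {projection!r}")
    return _SYN_CACHE[projection]


@dataclass
class Topology:
    """Afferent index lists of every projection for an n-per-population net."""

    n_per_pop: int
    seed: int
    mode: str
    afferents: dict[str, np.ndarray] = field(default_factory=dict)

    def edge_count(self) -> int:
        return sum(a.size for a in self.afferents.values())

    def validate(self) -> None:
        for name, idx in self.afferents.items():
            p = load_synapse_params(name)
            if idx.shape != (self.n_per_pop, p.fan_in):
                raise WiringError(
                    f"{name}: afferent table {idx.shape} != "
                    f"({self.n_per_pop}, {p.fan_in})"
                )
            for post in range(self.n_per_pop):
                row = idx[post]
                if len(set(row.tolist())) != len(row):
                    raise WiringError(f"{name}: repeated partner for post {post}")
                if name == "GPe->GPe" and post in row:
                    raise WiringError(f"GPe->GPe: neuron {post} is its own afferent")

    def to_json(self, path) -> None:
        payload = {
            "n_per_pop": self.n_per_pop,
            "seed": self.seed,
            "mode": self.mode,
            "afferents": {k: v.tolist() for k, v in self.afferents.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Topology":
        with open(path) as fh:
            payload = json.load(fh)
        topo = cls(
            n_per_pop=payload["n_per_pop"],
            seed=payload["seed"],
            mode=payload["mode"],
            afferents={
                k: np.asarray(v, dtype=np.int64)
                for k, v in payload["afferents"].items()
            },
        )
        topo.validate()
        return topo


def build_topology(n_per_pop: int, seed: int = 0, mode: str = "structured") -> Topology:
    """Wire the four populations with the fixed fan-in of each projection.

    Deterministic given (n_per_pop, seed, mode); ``seed`` only matters in
    random mode.
    """
    if n_per_pop < 3:
        raise WiringError("n_per_pop < 3 cannot host 2 distinct non-self partners")
    if mode not in ("structured", "random"):
        raise WiringError(f"unknown topology mode {mode!r}")
    rng = np.random.default_rng(seed)
    afferents: dict[str, np.ndarray] = {}
    for name in PROJECTIONS:
        p = load_synapse_params(name)
        n = n_per_pop
        if mode == "structured":
            post = np.arange(n)[:, None]
            if name == "GPe->GPe":
                offsets = np.arange(1, p.fan_in + 1)[None, :]
            else:
                offsets = np.arange(p.fan_in)[None, :]
            idx = (post + offsets) % n
        else:
            idx = np.empty((n, p.fan_in), dtype=np.int64)
            for post in range(n):
                pool = np.arange(n)
                if name == "GPe->GPe":
                    pool = np.delete(pool, post)
                idx[post] = rng.choice(pool, size=p.fan_in, replace=False)
        afferents[name] = idx.astype(np.int64)
    topo = Topology(n_per_pop=n_per_pop, seed=seed, mode=mode, afferents=afferents)
    topo.validate()
    return topo


def synaptic_current(params: SynapseParams, s_values, V_post: float) -> float:
    """g_syn * sum(s) * (V_post - E_syn) in uA/cm^2.

    The returned value is the conductance-form current; it enters dV/dt
    with a leading minus sign, so inhibition (E_syn = -85 mV) pulls a
    depolarized membrane down and excitation (E_syn = 0 mV) pulls a
    resting membrane up.
    """
    s = np.asarray(s_values, dtype=float)
    if s.size != params.fan_in:
        raise WiringError(
            f"{params.name}: got {s.size} afferents, fan-in is {params.fan_in}"
        )
    return float(params.g_syn * s.sum() * (V_post - params.E_syn))


def update_synapse(
    state: SynapseState, V_pre, dt: float, kinetics: SynapseKinetics
) -> SynapseState:
    """Advance the synaptic gates one Euler step of the first-order kinetics."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    T = kinetics.activation(np.asarray(V_pre, dtype=float))
    ds = kinetics.alpha * T * (1.0 - state.s) - kinetics.beta * state.s
    s_new = np.clip(state.s + dt * ds, 0.0, 1.0)
    return SynapseState(s_new)
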