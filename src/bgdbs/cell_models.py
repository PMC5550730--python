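"""Single-compartment conductance-based models of TH, STN, GPe and GPi neurons.

Each population is a Hodgkin-Huxley-style point neuron

    C_m dV/dt = -sum_ion I_ion + I_syn + I_ext + I_bias,
    I_ion     = g_ion * m^M * h^N * (V - E_ion),

with leak, sodium, potassium, and low-threshold calcium (T) currents, plus a
high-threshold calcium current for STN/GPe/GPi.  Activation gates are either
instantaneous (evaluated at their voltage-dependent steady state) or dynamic,
relaxing as x' = phi * (x_inf(V) - x) / tau(V).  Two gates are algebraic
functions of other gates: the thalamic K activation n = 0.75*(1 - h) and the
STN T-current inactivation b(r).

Channel conductances, reversal potentials and condition-dependent bias
currents live in ``params/cells.yaml``; the bias current is the only
parameter that differs between the healthy and the Parkinsonian (PD)
condition (STN 29 vs 20, GPe 20 vs 8, GPi 22 vs 12 uA/cm^2).  Thalamic
neurons carry no bias term.

Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ModelConfigError",
    "ContractError",
    "InitializationError",
    "GatingKinetics",
    "ChannelParams",
    "CellParams",
    "CellState",
    "CELL_TYPES",
    "CONDITIONS",
    "load_cell_params",
    "gate_value",
    "ionic_current",
    "membrane_derivative",
    "gate_derivative",
    "init_resting_state",
]

CELL_TYPES = ("TH", "STN", "GPe", "GPi")
CONDITIONS = ("healthy", "pd")


class ModelConfigError(ValueError):
    """Raised when a cell/channel configuration violates the model wiring."""


class ContractError(ValueError):
    """Raised when an operation is called outside its contract."""


class InitializationError(RuntimeError):
    """Raised when no resting state can be found for a cell."""


# ---------------------------------------------------------------------------
# kinetics functional forms


def _boltzmann(theta: float, k: float) -> Callable[[float], float]:
    def f(V):
        return 1.0 / (1.0 + np.exp(-(V - theta) / k))

    return f


def _tau_sigmoid(tau0, tau1, theta, k):
    def f(V):
        return tau0 + tau1 / (1.0 + np.exp(-(V - theta) / k))

    return f


def _tau_inv_rates(a0, a_theta, a_k, b0, b_theta, b_k):
    def f(V):
        a = a0 * np.exp(-(V - a_theta) / a_k)
        b = b0 / (1.0 + np.exp(-(V - b_theta) / b_k))
        return 1.0 / (a + b)

    return f


def _tau_exp_decay(tau0, tau1, theta, k):
    def f(V):
        return tau0 + tau1 * np.exp(-(V - theta) / k)

    return f


def _tau_const(tau0):
    def f(V):
        return tau0 * np.ones_like(np.asarray(V, dtype=float)) if np.ndim(V) else tau0

    return f


def _build_tau(spec: dict) -> Callable[[float], float]:
    form = spec["form"]
    if form == "sigmoid":
        return _tau_sigmoid(spec["tau0"], spec["tau1"], spec["theta"], spec["k"])
    if form == "inv_rates":
        return _tau_inv_rates(
            spec["a0"], spec["a_theta"], spec["a_k"],
            spec["b0"], spec["b_theta"], spec["b_k"],
        )
    if form == "exp_decay":
        return _tau_exp_decay(spec["tau0"], spec["tau1"], spec["theta"], spec["k"])
    if form == "const":
        return _tau_const(spec["tau0"])
    raise ModelConfigError(f"unknown tau form {form!r}")


def stn_b_inf(r: float) -> float:
    """STN T-current inactivation as a function of the slow gate r."""
    return 1.0 / (1.0 + np.exp((r - 0.4) / -0.1)) - 1.0 / (1.0 + np.exp(4.0))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GatingKinetics:
    """Voltage dependence of one gating variable."""

    mode: str  # "instantaneous" | "dynamic"
    steady_state: Callable[[float], float]
    time_constant: Callable[[float], float] | None = None
    phi: float = 1.0

    def __post_init__(self):
        if self.mode not in ("instantaneous", "dynamic"):
            raise ModelConfigError(f"unknown gating mode {self.mode!r}")
        if self.mode == "dynamic" and self.time_constant is None:
            raise ModelConfigError("dynamic gate needs a time constant")


@dataclass(frozen=True)
class ChannelParams:
    """One ionic conductance g * m^M * h^N * (V - E)."""

    name: str
    g_max: float
    E_rev: float
    m_exp: int
    h_exp: int
    activation: str | None = None  # gate or derived-gate name
    inactivation: str | None = None

    def __post_init__(self):
        if self.g_max < 0:
            raise ModelConfigError(f"channel {self.name}: g_max < 0")
        if self.m_exp < 0 or self.h_exp < 0:
            raise ModelConfigError(f"channel {self.name}: negative gate exponent")


@dataclass(frozen=True)
class CellParams:
    cell_type: str
    C_m: float
    channels: dict[str, ChannelParams]
    gates: dict[str, GatingKinetics]
    derived_gates: dict[str, dict]
    I_bias: dict[str, float]
    # raw YAML table this cell was built from (used to pack fast-path kernels)
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def dynamic_gate_names(self) -> tuple[str, ...]:
        return tuple(n for n, g in self.gates.items() if g.mode == "dynamic")

    def bias(self, condition: str) -> float:
        cond = condition.lower()
        if cond not in CONDITIONS:
            raise ModelConfigError(f"unknown condition {condition!r}")
        return self.I_bias[cond]


@dataclass
class CellState:
    """Membrane potential plus the values of the dynamic gating variables."""

    V: float
    gates: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "CellState":
        return CellState(self.V, dict(self.gates))


# ---------------------------------------------------------------------------
# parameter loading

_PARAM_CACHE: dict[str, CellParams] = {}


def _params_text(name: str) -> str:
    return (resources.files("bgdbs") / "params" / name).read_text()


def load_cell_params(cell_type: str, path: str | None = None) -> CellParams:
    """Load the parameter table for one cell type from the packaged YAML
    (or from ``path`` if given)."""
    if cell_type not in CELL_TYPES:
        raise ModelConfigError(f"unknown cell type {cell_type!r}")
    if path is None and cell_type in _PARAM_CACHE:
        return _PARAM_CACHE[cell_type]
    if path is None:
        raw = yaml.safe_load(_params_text("cells.yaml"))
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    spec = raw[cell_type]
    gates = {}
    for name, g in spec["gates"].items():
        inf = g["inf"]
        gates[name] = GatingKinetics(
            mode=g["mode"],
            steady_state=_boltzmann(inf["theta"], inf["k"]),
            time_constant=_build_tau(g["tau"]) if "tau" in g else None,
            phi=float(g.get("phi", 1.0)),
        )
    channels = {}
    for name, c in spec["channels"].items():
        channels[name] = ChannelParams(
            name=name,
            g_max=float(c["g_max"]),
            E_rev=float(c["E_rev"]),
            m_exp=int(c["m_exp"]),
            h_exp=int(c["h_exp"]),
            activation=c.get("activation"),
            inactivation=c.get("inactivation"),
        )
    cell = CellParams(
        cell_type=cell_type,
        C_m=float(spec["C_m"]),
        channels=channels,
        gates=gates,
        derived_gates=dict(spec.get("derived_gates", {})),
        I_bias={k.lower(): float(v) for k, v in spec["I_bias"].items()},
        raw=spec,
    )
    if path is None:
        _PARAM_CACHE[cell_type] = cell
    return cell


# ---------------------------------------------------------------------------
# operations


def gate_value(cell: CellParams, name: str | None, state: CellState) -> float:
    """Resolve a gate reference to its current value.

    Dynamic gates are read from the state, instantaneous gates evaluated at
    the present voltage, derived gates computed from their source gate.
    """
    if name is None:
        return 1.0
    if name in cell.derived_gates:
        d = cell.derived_gates[name]
        src = gate_value(cell, d["source"], state)
        if d["form"] == "th_k":
            return 0.75 * (1.0 - src)
        if d["form"] == "stn_b":
            return stn_b_inf(src)
        raise ModelConfigError(f"unknown derived gate form {d['form']!r}")
    if name not in cell.gates:
        raise ModelConfigError(f"{cell.cell_type}: unknown gate {name!r}")
    kin = cell.gates[name]
    if kin.mode == "instantaneous":
        return kin.steady_state(state.V)
    return state.gates[name]


def ionic_current(cell: CellParams, channel: str, state: CellState) -> float:
    """Current density g * m^M * h^N * (V - E_rev) in uA/cm^2.

    Positive values are outward; they enter the membrane equation with a
    leading minus sign.
    """
    if channel not in cell.channels:
        raise ModelConfigError(f"{cell.cell_type}: unknown channel {channel!r}")
    ch = cell.channels[channel]
    m = gate_value(cell, ch.activation, state) if ch.m_exp else 1.0
    h = gate_value(cell, ch.inactivation, state) if ch.h_exp else 1.0
    return ch.g_max * m**ch.m_exp * h**ch.h_exp * (state.V - ch.E_rev)


def membrane_derivative(
    cell: CellParams,
    state: CellState,
    I_syn: float = 0.0,
    I_ext: float = 0.0,
    condition: str = "healthy",
    ext_source: str | None = None,
) -> float:
    """dV/dt = (-sum I_ion + I_syn + I_ext + I_bias) / C_m  in mV/ms.

    ``I_syn`` is the signed sum of afferent synaptic currents (inhibition
    negative).  ``I_ext`` is the sensorimotor-cortex drive (TH only) or the
    DBS current (STN/GPe/GPi only); pass ``ext_source`` = "SMC" or "DBS" to
    have the wiring checked.
    """
    if ext_source is not None:
        if ext_source == "DBS" and cell.cell_type == "TH":
            raise ModelConfigError("thalamic neurons are not a DBS target")
        if ext_source == "SMC" and cell.cell_type != "TH":
            raise ModelConfigError("SMC drive reaches thalamic neurons only")
        if ext_source not in ("SMC", "DBS"):
            raise ModelConfigError(f"unknown external source {ext_source!r}")
    total_ionic = sum(ionic_current(cell, name, state) for name in cell.channels)
    return (-total_ionic + I_syn + I_ext + cell.bias(condition)) / cell.C_m


def gate_derivative(kinetics: GatingKinetics, gate: float, V: float) -> float:
    """First-order relaxation phi * (x_inf(V) - x) / tau(V), in 1/ms."""
    if kinetics.mode != "dynamic":
        raise ContractError("instantaneous gates are evaluated, not integrated")
    return kinetics.phi * (kinetics.steady_state(V) - gate) / kinetics.time_constant(V)


def _pack_derivs(cell: CellParams, condition: str):
    names = cell.dynamic_gate_names

    def rhs(t, y):
        state = CellState(y[0], dict(zip(names, y[1:])))
        dv = membrane_derivative(cell, state, 0.0, 0.0, condition)
        dg = [gate_derivative(cell.gates[n], state.gates[n], state.V) for n in names]
        return [dv] + dg

    return names, rhs


def init_resting_state(
    cell: CellParams,
    condition: str = "healthy",
    relax_ms: float = 500.0,
    v0: float = -65.0,
) -> CellState:
    """Deterministic initial state near the cell's zero-current fixed point.

    The cell is relaxed for ``relax_ms`` with no synaptic or stimulation
    input (the condition's bias current only).  If the trajectory has not
    settled (the cell fires intrinsically under its bias), the algebraic
    fixed point of dV/dt with all gates at steady state is located instead.
    """
    names, rhs = _pack_derivs(cell, condition)
    y0 = [v0] + [cell.gates[n].steady_state(v0) for n in names]
    sol = solve_ivp(rhs, (0.0, relax_ms), y0, method="LSODA",
                    rtol=1e-8, atol=1e-8)
    yf = sol.y[:, -1]
    state = CellState(float(yf[0]), dict(zip(names, map(float, yf[1:]))))
    if abs(membrane_derivative(cell, state, 0.0, 0.0, condition)) < 0.05:
        return state

    # intrinsically firing cell: fall back to the (possibly unstable)
    # stationary point with every gate at its steady state
    def f(V):
        st = CellState(V, {n: cell.gates[n].steady_state(V) for n in names})
        return membrane_derivative(cell, st, 0.0, 0.0, condition)

    grid = np.linspace(-100.0, 0.0, 201)
    vals = [f(v) for v in grid]
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if flo == 0.0 or flo * fhi < 0:
            v_star = brentq(f, lo, hi) if flo * fhi < 0 else lo
            return CellState(
                float(v_star),
                {n: float(cell.gates[n].steady_state(v_star)) for n in names},
            )
    raise InitializationError(
        f"{cell.cell_type} ({condition}): no resting point in [-100, 0] mV; "
        f"final V of relaxation run was {state.V:.2f} mV"
    )
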