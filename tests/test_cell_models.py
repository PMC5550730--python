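import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from bgdbs import _kernels
from bgdbs.cell_models import (
    CELL_TYPES,
    CellState,
    ContractError,
    GatingKinetics,
    ModelConfigError,
    gate_value,
    gate_derivative,
    init_resting_state,
    ionic_current,
    load_cell_params,
    membrane_derivative,
)


def _mid_state(cell, V):
    """State at voltage V with every dynamic gate at an arbitrary value."""
    return CellState(V, {g: 0.3 for g in cell.dynamic_gate_names})


class TestIonicCurrent:
    def test_nulls_at_reversal_potential(self, cells):
        # I = g m^M h^N (V - E) must vanish at V = E for every channel
        for cell in cells.values():
            for name, ch in cell.channels.items():
                state = _mid_state(cell, ch.E_rev)
                assert ionic_current(cell, name, state) == pytest.approx(0.0)

    def test_th_leak_value(self, cells):
        # leak g = 0.05 mS/cm^2, E = -70 mV: at -60 mV the driving force is
        # 10 mV, so I = 0.5 uA/cm^2
        state = _mid_state(cells["TH"], -60.0)
        assert ionic_current(cells["TH"], "L", state) == pytest.approx(0.5)

    def test_closed_activation_gate_blocks_current(self, cells):
        stn = cells["STN"]
        state = CellState(-40.0, {"h": 0.5, "n": 0.0, "r": 0.3})
        assert ionic_current(stn, "K", state) == pytest.approx(0.0)

    def test_unknown_channel_rejected(self, cells):
        with pytest.raises(ModelConfigError):
            ionic_current(cells["TH"], "Ca", _mid_state(cells["TH"], -60.0))


class TestMembraneDerivative:
    def test_zero_currents_zero_derivative(self, cells):
        stn = cells["STN"]
        silent = replace(
            stn,
            channels={k: replace(c, g_max=0.0) for k, c in stn.channels.items()},
            I_bias={"healthy": 0.0, "pd": 0.0},
        )
        dv = membrane_derivative(silent, _mid_state(stn, -60.0))
        assert dv == pytest.approx(0.0)

    @pytest.mark.parametrize("condition,bias", [("healthy", 29.0), ("pd", 20.0)])
    def test_stn_bias_drives_dvdt(self, cells, condition, bias):
        # with conductances silenced, dV/dt reduces to I_bias / C_m
        stn = cells["STN"]
        silent = replace(
            stn, channels={k: replace(c, g_max=0.0) for k, c in stn.channels.items()}
        )
        dv = membrane_derivative(silent, _mid_state(stn, -60.0), condition=condition)
        assert dv == pytest.approx(bias / stn.C_m)

    def test_th_has_no_bias_term(self, cells):
        assert cells["TH"].bias("healthy") == 0.0
        assert cells["TH"].bias("pd") == 0.0

    def test_wiring_violations_rejected(self, cells):
        th_state = _mid_state(cells["TH"], -60.0)
        stn_state = _mid_state(cells["STN"], -60.0)
        with pytest.raises(ModelConfigError):
            membrane_derivative(cells["TH"], th_state, I_ext=1.0, ext_source="DBS")
        with pytest.raises(ModelConfigError):
            membrane_derivative(cells["STN"], stn_state, I_ext=1.0, ext_source="SMC")
        # the legal wirings pass
        membrane_derivative(cells["TH"], th_state, I_ext=1.0, ext_source="SMC")
        membrane_derivative(cells["STN"], stn_state, I_ext=1.0, ext_source="DBS")


class TestGateDerivative:
    def test_fixed_point(self, cells):
        kin = cells["STN"].gates["h"]
        V = -55.0
        assert gate_derivative(kin, kin.steady_state(V), V) == pytest.approx(0.0)

    def test_linear_relaxation_rate(self):
        kin = GatingKinetics("dynamic", steady_state=lambda V: 1.0,
                             time_constant=lambda V: 2.0)
        assert gate_derivative(kin, 0.0, -60.0) == pytest.approx(0.5)

    def test_instantaneous_gate_rejected(self, cells):
        with pytest.raises(ContractError):
            gate_derivative(cells["STN"].gates["m"], 0.5, -60.0)

    def test_relaxation_matches_closed_form(self, cells):
        # x(t) = x_inf + (x0 - x_inf) exp(-phi t / tau) at clamped V;
        # after 20 tau/phi the gate sits on x_inf to < 1e-6
        kin = cells["GPe"].gates["r"]
        V = -60.0
        x_inf = kin.steady_state(V)
        tau_eff = kin.time_constant(V) / kin.phi
        T = 20.0 * tau_eff
        sol = solve_ivp(lambda t, y: gate_derivative(kin, y[0], V), (0, T), [0.0],
                        rtol=1e-10, atol=1e-12)
        x_end = sol.y[0, -1]
        closed = x_inf + (0.0 - x_inf) * math.exp(-T / tau_eff)
        assert x_end == pytest.approx(closed, abs=1e-7)
        assert abs(x_end - x_inf) < 1e-6


class TestSteadyStateBounds:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(V=st.floats(min_value=-120.0, max_value=60.0))
    def test_gates_bounded_and_taus_positive(self, V):
        for ct in CELL_TYPES:
            cell = load_cell_params(ct)
            for kin in cell.gates.values():
                x = kin.steady_state(V)
                assert 0.0 <= x <= 1.0
                if kin.mode == "dynamic":
                    assert kin.time_constant(V) > 0.0


class TestInitRestingState:
    def test_th_rests_subthreshold(self, cells):
        state = init_resting_state(cells["TH"], "healthy")
        assert -100.0 < state.V < -50.0
        # no spiking: dV/dt is essentially zero at the found point
        assert abs(membrane_derivative(cells["TH"], state)) < 0.05

    def test_relaxation_converged(self, cells):
        a = init_resting_state(cells["TH"], "healthy", relax_ms=500.0)
        b = init_resting_state(cells["TH"], "healthy", relax_ms=1000.0)
        assert abs(a.V - b.V) < 0.1

    def test_deterministic(self, cells):
        for ct in CELL_TYPES:
            a = init_resting_state(cells[ct], "pd")
            b = init_resting_state(cells[ct], "pd")
            assert a.V == b.V and a.gates == b.gates


class TestKernelConsistency:
    """The packed numba right-hand sides must equal the reference layer."""

    def _python_rhs(self, cell, state, I_syn, I_ext, condition):
        dv = membrane_derivative(cell, state, I_syn, I_ext, condition)
        dg = {
            g: gate_derivative(cell.gates[g], state.gates[g], state.V)
            for g in cell.dynamic_gate_names
        }
        return dv, dg

    @pytest.mark.parametrize("condition", ["healthy", "pd"])
    def test_rhs_agreement(self, cells, rng, condition):
        for _ in range(20):
            V = rng.uniform(-90.0, 20.0)
            gates = rng.uniform(0.0, 1.0, size=3)
            I_syn = rng.uniform(-20.0, 20.0)
            I_ext = rng.uniform(-50.0, 200.0)

            th = cells["TH"]
            st_th = CellState(V, {"h": gates[0], "r": gates[1]})
            dv, dg = self._python_rhs(th, st_th, I_syn, I_ext, condition)
            kv, kh, kr = _kernels.th_rhs(
                V, gates[0], gates[1], I_syn, I_ext,
                _kernels.pack_th(th.raw, condition))
            assert kv == pytest.approx(dv, rel=1e-12, abs=1e-12)
            assert kh == pytest.approx(dg["h"], rel=1e-12, abs=1e-12)
            assert kr == pytest.approx(dg["r"], rel=1e-12, abs=1e-12)

            stn = cells["STN"]
            st_stn = CellState(V, {"h": gates[0], "n": gates[1], "r": gates[2]})
            dv, dg = self._python_rhs(stn, st_stn, I_syn, I_ext, condition)
            kv, kh, kn, kr = _kernels.stn_rhs(
                V, gates[0], gates[1], gates[2], I_syn, I_ext,
                _kernels.pack_stn(stn.raw, condition))
            assert kv == pytest.approx(dv, rel=1e-12, abs=1e-12)
            assert (kh, kn, kr) == pytest.approx(
                (dg["h"], dg["n"], dg["r"]), rel=1e-12, abs=1e-12)

            for name in ("GPe", "GPi"):
                gp = cells[name]
                st_gp = CellState(V, {"h": gates[0], "n": gates[1], "r": gates[2]})
                dv, dg = self._python_rhs(gp, st_gp, I_syn, I_ext, condition)
                kv, kh, kn, kr = _kernels.gp_rhs(
                    V, gates[0], gates[1], gates[2], I_syn, I_ext,
                    _kernels.pack_gp(gp.raw, condition))
                assert kv == pytest.approx(dv, rel=1e-12, abs=1e-12)
                assert (kh, kn, kr) == pytest.approx(
                    (dg["h"], dg["n"], dg["r"]), rel=1e-12, abs=1e-12)


class TestDerivedGates:
    def test_th_potassium_tied_to_sodium_inactivation(self, cells):
        th = cells["TH"]
        state = CellState(-60.0, {"h": 0.4, "r": 0.1})
        assert gate_value(th, "k_from_h", state) == pytest.approx(0.75 * 0.6)

    def test_stn_b_gate_range(self, cells):
        stn = cells["STN"]
        for r in (0.0, 0.25, 0.5, 1.0):
            state = CellState(-60.0, {"h": 0.5, "n": 0.5, "r": r})
            b = gate_value(stn, "b_from_r", state)
            assert -0.02 < b <= 1.0
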