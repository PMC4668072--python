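"""Unit and property tests of the Beeler–Reuter cell model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from fraccable.cell_br import (
    BRParameters,
    CellState,
    GATE_NAMES,
    gate_rates,
    gate_steady_states,
    ionic_current,
    resting_state,
    simulate_cell,
    update_calcium,
    update_gates,
)

P = BRParameters()


class TestGateRates:
    def test_steady_states_at_rest_match_conventional_initial_gates(self):
        yinf = gate_steady_states(-85.0, P)
        expected = [0.0, 1.0, 1.0, 0.0, 1.0, 0.0]  # m, h, j, d, f, x1
        for name, y, e in zip(GATE_NAMES, yinf, expected):
            assert abs(y - e) < 0.1, f"gate {name}: {y} vs {e}"

    @pytest.mark.parametrize("v", [-120.0, -85.0, -47.0, -23.0, 0.0, 40.0, 60.0])
    def test_rates_nonnegative_finite_and_sum_positive(self, v):
        a, b = gate_rates(v, P)
        assert np.all(np.isfinite(a)) and np.all(np.isfinite(b))
        assert np.all(a >= 0) and np.all(b >= 0)
        assert np.all(a + b > 0)

    def test_sodium_activation_rate_analytic_limit_at_singularity(self):
        # alpha_m has a removable singularity at v = -47 mV
        a_sing = gate_rates(-47.0, P)[0][0]
        nearby = np.mean([gate_rates(-47.0 + e, P)[0][0]
                          for e in (1e-6, -1e-6)])
        assert a_sing == pytest.approx(10.0)  # C4/C6 = (-1)/(-0.1)
        assert a_sing == pytest.approx(nearby, abs=1e-6)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(FloatingPointError):
            gate_rates(np.nan, P)


class TestIonicCurrent:
    def test_resting_steady_state_has_negligible_current(self):
        rest = resting_state(P)
        assert abs(ionic_current(rest, P)) < 1e-3
        assert abs(rest.v + 85.0) < 1.0

    def test_depolarized_clamp_gives_net_repolarizing_current(self):
        s = CellState.resting_initial()
        s.v = 20.0
        assert ionic_current(s, P) > 0.0

    def test_current_continuous_in_voltage(self, rng):
        for _ in range(100):
            s = CellState(
                v=rng.uniform(-100, 60), m=rng.uniform(0, 1),
                h=rng.uniform(0, 1), j=rng.uniform(0, 1), d=rng.uniform(0, 1),
                f=rng.uniform(0, 1), x1=rng.uniform(0, 1),
                ca=rng.uniform(0.1, 30),
            )
            i0 = ionic_current(s, P)
            s_eps = s.copy()
            s_eps.v = s.v + 1e-7
            assert abs(ionic_current(s_eps, P) - i0) < 1e-4

    def test_potassium_singularity_at_minus_23_is_removable(self):
        s = CellState.resting_initial()
        vals = []
        for v in (-23.0, -23.0 + 1e-7, -23.0 - 1e-7):
            s.v = v
            vals.append(ionic_current(s, P))
        assert np.ptp(vals) < 1e-5


class TestGateUpdate:
    def test_steady_state_is_a_fixed_point(self):
        v = -40.0
        yinf = gate_steady_states(v, P)
        s = CellState(v=v, ca=1.0, **dict(zip(GATE_NAMES, yinf)))
        s2 = update_gates(s, v, dt=0.5, params=P)
        for name, y in zip(GATE_NAMES, yinf):
            assert getattr(s2, name) == pytest.approx(y, rel=1e-14)

    def test_infinite_dt_limit_is_steady_state(self):
        v = -30.0
        s = CellState.resting_initial()
        s2 = update_gates(s, v, dt=1e16, params=P)
        yinf = gate_steady_states(v, P)
        for name, y in zip(GATE_NAMES, yinf):
            assert getattr(s2, name) == pytest.approx(y, rel=1e-9)

    def test_single_step_matches_implicit_euler_root_find(self):
        # one step from y = 0.5 at v = -40: compare with a scalar root-find
        # on y - y0 - dt*(a*(1-y) - b*y) = 0
        v, dt = -40.0, 0.01
        a, b = gate_rates(v, P)
        s = CellState(v=v, m=0.5, h=0.5, j=0.5, d=0.5, f=0.5, x1=0.5, ca=1.0)
        s2 = update_gates(s, v, dt, P)
        for i, name in enumerate(GATE_NAMES):
            root = brentq(
                lambda y: y - 0.5 - dt * (a[i] * (1 - y) - b[i] * y),
                -1.0, 2.0, xtol=1e-15,
            )
            assert getattr(s2, name) == pytest.approx(root, abs=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        v=st.floats(-100, 60),
        dt=st.floats(1e-6, 1.0),
        ys=st.lists(st.floats(0, 1), min_size=6, max_size=6),
    )
    def test_gate_update_maps_unit_cube_into_itself(self, v, dt, ys):
        s = CellState(v=v, ca=1.0, **dict(zip(GATE_NAMES, ys)))
        s2 = update_gates(s, v, dt, P)
        for name in GATE_NAMES:
            assert 0.0 <= getattr(s2, name) <= 1.0


class TestCalciumUpdate:
    def _full_newton(self, c0, v, d, f, dt, tol=1e-14):
        """Oracle: implicit Euler root with the Jacobian recomputed every
        iteration (not frozen)."""
        c = c0
        for _ in range(200):
            e_s = P.es_offset + P.es_slope * np.log(P.ca_scale * c)
            i_s = P.g_s * d * f * (v - e_s)
            r = c - c0 - dt * (-i_s + P.ca_uptake * (1 - c))
            if abs(r) < tol:
                return c
            jac = 1.0 - dt * (P.es_slope * P.g_s * d * f / c - P.ca_uptake)
            c = max(c - r / jac, 1e-12)
        return c

    def test_matches_fully_converged_newton_on_random_states(self, rng):
        dt = 0.01
        for _ in range(1000):
            c0 = rng.uniform(0.05, 40.0)
            v = rng.uniform(-90, 50)
            d, f = rng.uniform(0, 1, 2)
            s = CellState(v=v, m=0, h=1, j=1, d=d, f=f, x1=0, ca=c0)
            got = update_calcium(s, v, dt, P)
            want = self._full_newton(c0, v, d, f, dt)
            assert got == pytest.approx(want, abs=1e-8)
            assert got > 0

    def test_zero_dt_is_identity(self):
        s = CellState.resting_initial()
        s.ca = 3.7
        assert update_calcium(s, -20.0, 0.0, P) == 3.7

    def test_resting_fixed_point_is_preserved(self):
        rest = resting_state(P)
        new = update_calcium(rest, rest.v, 0.1, P)
        assert new == pytest.approx(rest.ca, rel=1e-6)


class TestSingleCellAP:
    def test_morphology_of_stimulated_action_potential(self):
        t, v, _ = simulate_cell(P, t_final=500.0)
        rest = v[np.searchsorted(t, 10.0)]
        assert v.max() > 0.0                      # depolarization overshoot
        ipk = int(np.argmax(v))
        seg = v[ipk:]
        dmin = np.diff(seg)
        notch_idx = np.flatnonzero((dmin[:-1] < 0) & (dmin[1:] >= 0))
        assert notch_idx.size > 0                 # early-repolarization notch
        inotch = notch_idx[0] + 1
        assert seg[inotch:inotch + 20000].max() > seg[inotch]  # dome follows
        assert abs(v[-1] - rest) < 2.0            # near rest by 500 ms

    def test_unstimulated_cell_stays_quiescent_and_stationary(self):
        t, v, _ = simulate_cell(P, t_final=2000.0, stim_amplitude=0.0, dt=0.05)
        assert abs(v[-1] + 85.0) < 1.0
        # drift over the final millisecond below 1e-6 mV/ms
        assert abs(v[-1] - v[-21]) < 1e-6

    def test_deterministic(self):
        t1, v1, _ = simulate_cell(P, t_final=50.0)
        t2, v2, _ = simulate_cell(P, t_final=50.0)
        assert np.array_equal(v1, v2)


class TestParameters:
    def test_flat_dict_round_trip(self):
        d = P.to_dict()
        q = BRParameters.from_dict(d)
        assert np.array_equal(q.rate_table, P.rate_table)
        assert q.g_s == P.g_s and q.ca_newton_maxit == P.ca_newton_maxit

    def test_override_via_dict(self):
        q = BRParameters.from_dict({"g_na": 2.0, "rate_alpha_m_C4": -2.0})
        assert q.g_na == 2.0
        assert q.rate_table[0, 3] == -2.0
        assert q.e_na == P.e_na

    def test_bad_rate_table_shape_rejected(self):
        with pytest.raises(ValueError):
            BRParameters(rate_table=np.zeros((3, 3)))
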