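"""TP06 single-cell behavior and the fibrosis remodeling formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rotoranchor as ra
from rotoranchor import single_cell as sc
from rotoranchor.tp06 import IDX, N_STATE, ionic_total_current

from tp06_reference import (EPI, reference_resting_state, reference_run)


class TestRemodeling:
    @pytest.mark.parametrize("f,expected", [
        (40.0, (0.38, 0.30, 0.20)),   # 62 % / 70 % / 80 % reductions
        (0.0, (1.0, 1.0, 1.0)),
        (50.0, (0.225, 0.125, 0.0)),  # I_Ks formula clamps to zero here
    ])
    def test_scale_factors(self, f, expected):
        s = ra.remodeling_factors(f)
        assert s.as_tuple() == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("f", [-1.0, 100.5, 1e3])
    def test_rejects_out_of_range(self, f):
        with pytest.raises(ValueError):
            ra.remodeling_factors(f)

    def test_apply_remodeling_touches_only_three_conductances(self, epi):
        remodeled = ra.apply_remodeling(40.0, epi)
        assert remodeled.g_na == pytest.approx(0.38 * epi.g_na)
        assert remodeled.g_kr == pytest.approx(0.30 * epi.g_kr)
        assert remodeled.g_ks == pytest.approx(0.20 * epi.g_ks)
        for name, val in epi.to_dict().items():
            if name in ("g_na", "g_kr", "g_ks"):
                continue
            assert getattr(remodeled, name) == val

    @given(f1=st.floats(0, 100), f2=st.floats(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_factors_nonincreasing_and_nonnegative(self, f1, f2):
        lo, hi = sorted((f1, f2))
        s_lo, s_hi = ra.remodeling_factors(lo), ra.remodeling_factors(hi)
        for a, b in zip(s_lo.as_tuple(), s_hi.as_tuple()):
            assert b <= a + 1e-12
            assert 0.0 <= b <= 1.0


class TestSingleCell:
    def test_resting_state_is_stable(self, epi):
        t, v, _ = sc.integrate_cell(epi, 1000.0)
        assert abs(v[-1] - v[0]) < 1.0
        assert np.all(np.abs(v - v[0]) < 1.0)

    def test_suprathreshold_stimulus_elicits_action_potential(self, epi):
        t, v, _ = sc.integrate_cell(epi, 600.0, stim_times=[20.0])
        assert v.max() > 0.0          # overshoot
        assert v[-1] < -80.0          # back near rest

    def test_subthreshold_stimulus_does_not_fire(self, epi):
        t, v, _ = sc.integrate_cell(epi, 200.0, stim_times=[20.0],
                                    stim_amplitude=2.0)
        assert v.max() < -40.0

    def test_apd90_matches_independent_reference(self, epi):
        """Paced APD90 agrees with an independently coded TP06 integrated
        at dt = 0.001 ms (explicit Euler) to within 2 ms."""
        y0 = reference_resting_state()
        t, v, y1 = reference_run(y0, 0.001, 1000.0, 50.0, 1.0, 52.0, 0.5, EPI)
        t, v, _ = reference_run(y1, 0.001, 1000.0, 50.0, 1.0, 52.0, 0.5, EPI)
        apd_ref = sc.apd90(t, v, 50.0)

        tt, vv, yy = sc.integrate_cell(epi, 1000.0, stim_times=[50.0])
        tt, vv, _ = sc.integrate_cell(epi, 1000.0, y0=yy, stim_times=[50.0])
        apd = sc.apd90(tt, vv, 50.0)
        assert apd == pytest.approx(apd_ref, abs=2.0)

    def test_dt_refinement_changes_voltage_below_1mv(self, epi):
        """Halving-and-beyond time-step refinement: one paced beat at the
        production step agrees with dt = 0.002 ms within 1 mV throughout."""
        t1, v1, _ = sc.integrate_cell(epi, 600.0, dt=0.02,
                                      stim_times=[20.0], record_interval=1.0)
        t2, v2, _ = sc.integrate_cell(epi, 600.0, dt=0.002,
                                      stim_times=[20.0], record_interval=1.0)
        # compare away from the upstroke sample (steepest slope ~400 mV/ms
        # makes sub-sample timing differences dominate there)
        diff = np.abs(v1 - v2)
        mask = np.ones_like(diff, bool)
        up = int(np.argmax(np.diff(v1)))
        mask[max(0, up - 3):up + 4] = False
        assert diff[mask].max() < 1.0

    def test_remodeling_prolongs_apd(self, epi):
        remodeled = ra.apply_remodeling(40.0, epi)
        apds = {}
        for name, params in (("base", epi), ("remodeled", remodeled)):
            t, v, y1 = sc.integrate_cell(params, 1000.0, stim_times=[50.0])
            t, v, _ = sc.integrate_cell(params, 1000.0, y0=y1,
                                        stim_times=[50.0])
            apds[name] = sc.apd90(t, v, 50.0)
        assert apds["remodeled"] > apds["base"]

    def test_state_invariants_after_paced_beat(self, epi):
        _, _, y = sc.integrate_cell(epi, 1000.0, stim_times=[50.0])
        gates = y[1:13]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)
        concentrations = y[13:]
        assert np.all(concentrations > 0.0)
        assert np.all(np.isfinite(y))


class TestIonicTotalCurrent:
    def test_resting_current_is_small(self, epi):
        y = ra.resting_state(1)[:, 0]
        i_ion, derivs = ionic_total_current(y, epi)
        assert abs(i_ion) < 0.2
        assert set(derivs) == set(ra.STATE_NAMES) - {"V"}

    def test_nonfinite_state_identifies_variable(self, epi):
        y = ra.resting_state(1)[:, 0]
        y[IDX["cai"]] = np.nan
        with pytest.raises(FloatingPointError, match="cai"):
            ionic_total_current(y, epi)

    def test_derivatives_small_near_fixed_point(self, epi):
        """After relaxing 20 s without stimulus the state sits near the
        resting fixed point: every state variable moves by less than 1 %
        of its own magnitude per millisecond (the residual drift is the
        model's slow intracellular ion creep)."""
        _, _, y = sc.integrate_cell(epi, 20_000.0, record_interval=10.0)
        _, derivs = ionic_total_current(y[:, 0], epi)
        for name, d in derivs.items():
            scale = max(abs(y[IDX[name], 0]), 1e-3)
            assert abs(d) / scale < 1e-2, name


class TestParams:
    def test_validate_rejects_negative_conductance(self, epi):
        bad = ra.CellParams(g_na=-1.0)
        with pytest.raises(ValueError, match="g_na"):
            bad.validate()

    def test_variant_roundtrip(self):
        m = ra.CellParams.midmyocardial()
        again = ra.CellParams.from_dict(m.to_dict())
        assert again == m
        assert again.g_ks == pytest.approx(0.098)
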