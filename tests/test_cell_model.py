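"""Cell-model layer: I_K,ATP arithmetic, member scaling, ischemia hooks,
and physical invariants of the ODE backend."""

import numpy as np
import pytest

from ischempop import shannon
from ischempop.cell_model import (ConductanceSet, IschemiaState,
                                  CONTROL_MEMBER, CONTROL_ISCHEMIA,
                                  apply_ischemia, apply_member,
                                  baseline_parameters, ikatp_current, rhs)


class TestIkatp:
    def test_total_conductance_is_product_of_f_and_g(self):
        """f = 0.8% of g = 2.61 mS/uF gives 0.02088 mS/uF at control K_o
        (rectification factor r(5.4) = 1): slope of I vs driving force."""
        v, ko, ki = -20.0, 5.4, 135.0
        i = ikatp_current(v, ko, ki, f_katp=0.008, g_katp=2.61)
        e_k = (shannon._R * shannon._T / shannon._F) * np.log(ko / ki)
        assert i / (v - e_k) == pytest.approx(0.02088, abs=1e-12)

    def test_zero_activation_zero_current(self):
        for v in (-90.0, -20.0, 40.0):
            assert ikatp_current(v, 5.4, 135.0, f_katp=0.0) == 0.0

    def test_zero_at_reversal_potential(self):
        ko, ki = 8.0, 130.0
        e_k = (shannon._R * shannon._T / shannon._F) * np.log(ko / ki)
        assert ikatp_current(e_k, ko, ki, 0.008) == pytest.approx(0.0, abs=1e-12)

    def test_outward_positive_above_reversal(self):
        assert ikatp_current(0.0, 5.4, 135.0, 0.008) > 0

    def test_rejects_nonpositive_concentrations(self):
        with pytest.raises(ValueError):
            ikatp_current(-80.0, 0.0, 135.0, 0.008)
        with pytest.raises(ValueError):
            ikatp_current(-80.0, 5.4, -1.0, 0.008)


class TestApplyMember:
    def test_identity_member_keeps_baseline(self):
        base = baseline_parameters()
        scaled = apply_member(base, ConductanceSet())
        np.testing.assert_array_equal(scaled.vec, base.vec)

    def test_control_member_scales_the_six_conductances(self):
        """The control member is +30% g_to, -15% g_Ks, -30% g_K1,
        +15% g_NaK with g_CaL and g_Kr unchanged."""
        base = baseline_parameters()
        p = apply_member(base, CONTROL_MEMBER)
        assert p["g_tos"] == pytest.approx(1.30 * base["g_tos"])
        assert p["g_tof"] == pytest.approx(1.30 * base["g_tof"])
        assert p["p_ca"] == base["p_ca"]
        assert p["g_kr0"] == base["g_kr0"]
        assert p["g_ks_scale"] == pytest.approx(0.85)
        assert p["g_k10"] == pytest.approx(0.70 * base["g_k10"])
        assert p["ibar_nak"] == pytest.approx(1.15 * base["ibar_nak"])

    def test_zero_kr_silences_ikr_throughout(self, solver):
        """s_Kr = 0 must make I_Kr identically zero in any simulation:
        the K+ balance then never sees an x_kr-dependent term."""
        base = baseline_parameters()
        p = apply_member(base, ConductanceSet(s_kr=0.0))
        assert p["g_kr0"] == 0.0
        y = shannon.RESTING_STATE.copy()
        y[shannon.IDX["x_kr"]] = 1.0   # fully activated gate
        d1 = rhs(0.0, y, p)
        y[shannon.IDX["x_kr"]] = 0.0
        d2 = rhs(0.0, y, p)
        assert d1[shannon.IDX_V] == pytest.approx(d2[shannon.IDX_V], abs=1e-12)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            ConductanceSet(s_to=-0.1)


class TestApplyIschemia:
    def test_control_state_is_identity(self):
        base = baseline_parameters()
        p, y = apply_ischemia(base, shannon.RESTING_STATE, CONTROL_ISCHEMIA)
        np.testing.assert_array_equal(p.vec, base.vec)
        np.testing.assert_array_equal(y, shannon.RESTING_STATE)

    def test_inhibition_scales_ina_and_ical(self):
        base = baseline_parameters()
        p, _ = apply_ischemia(base, shannon.RESTING_STATE,
                              IschemiaState(f_inhib=0.25))
        assert p["g_na"] == pytest.approx(0.75 * base["g_na"])
        assert p["p_ca"] == pytest.approx(0.75 * base["p_ca"])

    def test_pump_reduction(self):
        base = baseline_parameters()
        p, _ = apply_ischemia(base, shannon.RESTING_STATE,
                              IschemiaState(f_nak=0.30))
        assert p["ibar_nak"] == pytest.approx(0.70 * base["ibar_nak"])

    def test_sodium_offset_moves_initial_state_only(self):
        base = baseline_parameters()
        p, y = apply_ischemia(base, shannon.RESTING_STATE,
                              IschemiaState(na_i_offset=3.0))
        for name in ("na_i", "na_sl", "na_j"):
            k = shannon.IDX[name]
            assert y[k] == pytest.approx(shannon.RESTING_STATE[k] + 3.0)
        np.testing.assert_array_equal(p.vec, base.vec)

    def test_katp_activation_sets_effective_conductance(self):
        base = baseline_parameters()
        p, _ = apply_ischemia(base, shannon.RESTING_STATE,
                              IschemiaState(f_katp=0.008))
        assert p["g_katp_eff"] == pytest.approx(0.008 * 2.61)

    @pytest.mark.parametrize("kw", [dict(f_inhib=1.0), dict(f_nak=1.0),
                                    dict(f_katp=1.5), dict(k_o=2.0),
                                    dict(na_i_offset=-1.0)])
    def test_invalid_states_rejected(self, kw):
        with pytest.raises(ValueError):
            IschemiaState(**kw)


class TestBackendPhysics:
    def test_resting_state_is_stationary(self):
        """At the stored resting state with no stimulus, all derivatives
        are at solver-tolerance level."""
        d = rhs(0.0, shannon.RESTING_STATE, baseline_parameters())
        assert np.max(np.abs(d)) < 1e-3

    def test_rhs_rejects_nonfinite_state(self):
        y = shannon.RESTING_STATE.copy()
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(0.0, y, baseline_parameters())

    def test_gates_and_concentrations_stay_physical(self, pacing, solver,
                                                    control_amplitude):
        """Over a full 10-beat control train the recorded gating product
        stays in [0, 1] and the end state has positive concentrations
        and in-range gates."""
        from ischempop.protocol import simulate_train
        tr = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pacing, solver,
                            control_amplitude, record="all", keep_states=True)
        assert np.all(tr.hj >= -1e-9) and np.all(tr.hj <= 1 + 1e-6)
        final = tr.states[-1]
        gate_idx = [shannon.IDX[n] for n in
                    ("m", "h", "j", "x_kr", "x_ks", "d", "fcab_j", "fcab_sl",
                     "ryr_r", "ryr_o", "ryr_i")]
        assert np.all(final[gate_idx] >= -1e-9)
        assert np.all(final[gate_idx] <= 1 + 1e-6)
        conc_idx = [shannon.IDX[n] for n in
                    ("na_i", "na_sl", "na_j", "k_i", "ca_sr", "ca_j",
                     "ca_sl", "ca_i")]
        assert np.all(final[conc_idx] > 0)

    def test_charge_conservation_over_one_cycle(self, control_amplitude):
        """With the stimulus book-kept as a K+ flux, the membrane
        potential tracks the total intracellular charge exactly:
        Cm*dV = -F*sum(z*d(amount)) over a 600 ms cycle to < 1e-6
        relative of the total intracellular charge. The identity is
        exact in the equations, so the solve runs at tight tolerances
        to keep integration error below the bound."""
        from ischempop.protocol import PacingConfig, SolverConfig, simulate_train
        pac1 = PacingConfig(n_beats=1)
        tight = SolverConfig(rtol=1e-9, atol=1e-11)
        tr = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac1, tight,
                            control_amplitude, record="all", keep_states=True)
        y0, y1 = tr.states[0], tr.states[-1]

        def charge(y):
            # mol of elementary charge from free + buffered ions (Cl- is
            # clamped in the backend and its currents enter only V)
            na = (y[shannon.IDX["na_i"]] * shannon._VMYO
                  + y[shannon.IDX["na_sl"]] * shannon._VSL
                  + y[shannon.IDX["na_j"]] * shannon._VJUNC
                  + y[shannon.IDX["nab_sl"]] * shannon._VSL
                  + y[shannon.IDX["nab_j"]] * shannon._VJUNC)
            k = y[shannon.IDX["k_i"]] * shannon._VMYO
            ca_free = (y[shannon.IDX["ca_i"]] * shannon._VMYO
                       + y[shannon.IDX["ca_sl"]] * shannon._VSL
                       + y[shannon.IDX["ca_j"]] * shannon._VJUNC
                       + y[shannon.IDX["ca_sr"]] * shannon._VSR)
            ca_buf = ((y[shannon.IDX["tncl"]] + y[shannon.IDX["tnchc"]]
                       + y[shannon.IDX["cam"]] + y[shannon.IDX["myoc"]]
                       + y[shannon.IDX["srb"]]) * shannon._VMYO
                      + (y[shannon.IDX["sllsl"]] + y[shannon.IDX["slhsl"]])
                      * shannon._VSL
                      + (y[shannon.IDX["sllj"]] + y[shannon.IDX["slhj"]])
                      * shannon._VJUNC
                      + y[shannon.IDX["csqn"]] * shannon._VSR)
            cl = y[shannon.IDX["cl_i"]] * shannon._VMYO
            return na + k + 2.0 * (ca_free + ca_buf) - cl   # mmol of charge

        dq = (charge(y1) - charge(y0)) * 1e-3 * shannon._F  # C
        dv = (y1[0] - y0[0]) * 1e-3                         # V
        residual = abs(shannon._CMEM * dv + dq)
        total = abs(charge(y0)) * 1e-3 * shannon._F
        assert residual / total < 1e-6

    def test_resting_potential_tracks_ek_under_hyperkalemia(
            self, pacing, solver, control_amplitude):
        """The hyperkalemic membrane is K+-dominated: end-diastolic
        V_rest rises monotonically with K_o through 5.4, 8, 12, 17 mM
        and stays within 0.5 mV of the K+ Nernst potential throughout
        (in this backend the control gap is already < 0.1 mV, so strict
        shrinkage of |V_rest - E_K| is below measurement noise)."""
        from ischempop.protocol import extract_last_beat, simulate_train
        v_rests, gaps = [], []
        for ko in (5.4, 8.0, 12.0, 17.0):
            tr = simulate_train(CONTROL_MEMBER, IschemiaState(k_o=ko),
                                pacing, solver, control_amplitude,
                                record="last", keep_states=True)
            beat = extract_last_beat(tr)
            v_rest = beat.vm[0]
            k_i = beat.states[0][shannon.IDX_KI]
            e_k = (shannon._R * shannon._T / shannon._F) * np.log(ko / k_i)
            v_rests.append(v_rest)
            gaps.append(abs(v_rest - e_k))
        assert v_rests[0] < v_rests[1] < v_rests[2] < v_rests[3]
        assert max(gaps) < 0.5

    def test_ikatp_monotonically_shortens_apd(self, pacing, solver,
                                              control_amplitude):
        """Increasing I_K,ATP activation at fixed member and control
        conditions monotonically decreases APD90."""
        from ischempop.protocol import extract_last_beat, simulate_train
        from ischempop.biomarkers import compute_biomarkers
        apds = []
        for f in (0.0, 0.004, 0.008):
            tr = simulate_train(CONTROL_MEMBER, IschemiaState(f_katp=f),
                                pacing, solver, control_amplitude)
            apds.append(compute_biomarkers(extract_last_beat(tr)).apd90)
        assert apds[0] > apds[1] > apds[2]
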