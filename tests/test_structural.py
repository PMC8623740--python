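"""Structural QSS model: algebraic root, ODE field, integration, half-lives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from dtmdd import (DoseEvent, StructuralParams, UnitSystem, qss_unbound, rhs,
                   simulate_profile, terminal_half_life)
from dtmdd.structural import linear_profile_conc
from dtmdd.units import convert_concentration
from dtmdd import _ode


def qss_fixed_point(ct, rt, kss, tol=1e-12):
    """Independent oracle: fixed-point iteration on C = CT - RT*C/(KSS+C)."""
    c = ct
    for _ in range(100000):
        c_new = ct - rt * c / (kss + c)
        c_new = max(c_new, 0.0)
        if abs(c_new - c) < tol:
            return c_new
        c = 0.5 * c + 0.5 * c_new   # damped to guarantee convergence
    return c


class TestQSSRoot:
    def test_no_target_returns_total(self):
        assert qss_unbound(10.0, 0.0, 1.0) == pytest.approx(10.0, rel=1e-12)

    def test_no_drug_returns_zero(self):
        assert qss_unbound(0.0, 5.0, 15.4) == 0.0

    def test_against_fixed_point_oracle(self):
        c = qss_unbound(50.0, 100.0, 15.4)
        oracle = qss_fixed_point(50.0, 100.0, 15.4)
        assert c == pytest.approx(oracle, abs=1e-10)
        assert c == pytest.approx(10.19, abs=0.01)
        # binding consistency: complex equals RT*C/(KSS+C)
        assert 50.0 - c == pytest.approx(100.0 * c / (15.4 + c), rel=1e-10)

    @settings(max_examples=200, deadline=None)
    @given(ct=st.floats(0, 1e4), rt=st.floats(0, 1e4),
           kss=st.floats(1e-3, 1e3))
    def test_root_properties(self, ct, rt, kss):
        c = qss_unbound(ct, rt, kss)
        assert 0.0 <= c <= ct
        # independent oracle: bisection on the binding quadratic over [0, CT]
        def h(x):
            return x * x + (rt + kss - ct) * x - kss * ct
        lo, hi = 0.0, max(ct, 1e-12)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if h(mid) <= 0.0:
                lo = mid
            else:
                hi = mid
        assert c == pytest.approx(0.5 * (lo + hi), rel=1e-8, abs=1e-8)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            qss_unbound(-1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            qss_unbound(1.0, 1.0, 0.0)


class TestRHS:
    def test_baseline_is_equilibrium(self, typical_ibd):
        state = typical_ibd.initial_state()
        dy = rhs(state, typical_ibd, infusion_rate=0.0)
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_linear_mode_conserves_concentration_sum(self, linear_params):
        # printed k12/k21 transfer form conserves CT + CPT when CL = 0
        p = linear_params.replace(CL=0.0)
        dy = rhs([40.0, 0.0, 15.0, 0.0], p, infusion_rate=0.0)
        assert dy[0] + dy[2] == pytest.approx(0.0, abs=1e-12)

    def test_full_double_tmdd_matches_printed_equations(self, typical_ibd):
        """Direct transcription oracle of the four printed equations."""
        p = typical_ibd
        ct, rtc, cpt, rtp = 100.0, 3.3, 20.0, 0.46
        c = qss_unbound(ct, rtc, p.KSSC)
        cp = qss_unbound(cpt, rtp, p.KSSP)
        expect = np.array([
            -(p.CL / p.V1) * c - (p.Q / p.V1) * c + (p.Q / p.V2) * cp
            - p.kintC * (ct - c),
            p.R0C * p.kout - p.kout * (rtc - (ct - c)) - p.kintC * (ct - c),
            (p.Q / p.V1) * c - (p.Q / p.V2) * cp - p.kintP * (cpt - cp),
            p.R0P * p.kout - p.kout * (rtp - (cpt - cp)) - p.kintP * (cpt - cp),
        ])
        got = rhs([ct, rtc, cpt, rtp], p, infusion_rate=0.0)
        assert np.all(np.isfinite(got))
        assert np.allclose(got, expect, rtol=1e-12)


class TestSimulateProfile:
    def test_baseline_stays_at_equilibrium(self, typical_ibd):
        traj = simulate_profile(typical_ibd, [], np.linspace(0, 300, 40))
        assert np.max(np.abs(traj["CT_nM"])) < 1e-9
        assert np.max(np.abs(traj["RTC_nM"] - typical_ibd.R0C)) < 1e-9
        assert np.max(np.abs(traj["RTP_nM"] - typical_ibd.R0P)) < 1e-9

    def test_peak_close_to_dose_over_v1_in_linear_mode(self, linear_params):
        # bolus-limit sanity bound: over a 1-h infusion the distribution and
        # elimination loss is (k10 + k12) * T / 2 ~ 1.3%, so the end-of-infusion
        # peak sits just below dose/V1
        dose = DoseEvent(0.0, 330.0, duration=1.0 / 24.0)
        traj = simulate_profile(linear_params, [dose], [dose.duration])
        peak_expect_mgl = 330.0 / linear_params.V1
        peak = traj["conc_mgL"].iloc[0]
        assert peak == pytest.approx(peak_expect_mgl, rel=0.02)
        assert peak < peak_expect_mgl

    def test_linearity_under_dose_doubling(self, linear_params):
        times = np.linspace(0.1, 60, 50)
        doses = [DoseEvent(0.0, 300.0), DoseEvent(14.0, 300.0)]
        doubled = [DoseEvent(d.time, 2 * d.amount_mg) for d in doses]
        c1 = simulate_profile(linear_params, doses, times)["conc_mgL"]
        c2 = simulate_profile(linear_params, doubled, times)["conc_mgL"]
        assert np.allclose(c2, 2 * c1, rtol=1e-7)

    def test_matches_independent_stiff_integration(self, typical_ibd,
                                                   standard_regimen):
        """Cross-check against scipy's LSODA at tight tolerance."""
        times = np.linspace(0.5, 180.0, 60)
        traj = simulate_profile(typical_ibd, standard_regimen, times,
                                rtol=1e-10, atol=1e-12)
        parr = typical_ibd.to_array()
        u = UnitSystem()

        def f(t, y):
            out = np.empty(4)
            r = 0.0
            for d in standard_regimen:
                if d.time <= t < d.time + d.duration:
                    r += u.to_nM(d.rate_mg_day) / typical_ibd.V1
            _ode.rhs(y, parr, r, out)
            return out

        sol = solve_ivp(f, (0.0, 180.5), typical_ibd.initial_state(),
                        method="LSODA", rtol=1e-10, atol=1e-12,
                        t_eval=times, max_step=0.05)
        ours = traj[["CT_nM", "RTC_nM", "CPT_nM", "RTP_nM"]].to_numpy()
        rel = np.abs(ours - sol.y.T) / (np.abs(sol.y.T) + 1e-8)
        assert rel.max() < 1e-6

    def test_qss_identity_along_trajectory(self, typical_ibd, standard_regimen):
        times = np.linspace(0.5, 200, 123)
        traj = simulate_profile(typical_ibd, standard_regimen, times)
        c = traj["C_nM"].to_numpy()
        complex_c = traj["CT_nM"].to_numpy() - c
        expect = traj["RTC_nM"].to_numpy() * c / (typical_ibd.KSSC + c)
        assert np.allclose(complex_c, expect, rtol=1e-8, atol=1e-10)
        # occupancy closed form
        ratio = traj["ratio_C"].to_numpy()
        assert np.allclose(ratio, typical_ibd.KSSC / (typical_ibd.KSSC + c),
                           rtol=1e-8)

    def test_linear_mode_matches_biexponential_closed_form(self, linear_params):
        times = np.linspace(0.05, 120, 97)
        doses = [DoseEvent(0.0, 400.0), DoseEvent(14.0, 400.0),
                 DoseEvent(42.0, 400.0)]
        ode = simulate_profile(linear_params, doses, times, rtol=1e-10,
                               atol=1e-12)["conc_mgL"].to_numpy()
        closed = linear_profile_conc(linear_params, doses, times)
        assert np.allclose(ode, closed, rtol=1e-6, atol=1e-9)

    def test_monotone_in_dose_and_target(self, typical_ibd, standard_regimen):
        times = np.linspace(0.5, 180, 60)
        base = simulate_profile(typical_ibd, standard_regimen, times)["C_nM"]
        bigger = [DoseEvent(d.time, 1.5 * d.amount_mg, d.duration)
                  for d in standard_regimen]
        up = simulate_profile(typical_ibd, bigger, times)["C_nM"]
        assert np.all(up >= base - 1e-9)
        more_target = typical_ibd.replace(R0C=3 * typical_ibd.R0C)
        down = simulate_profile(more_target, standard_regimen, times)["C_nM"]
        assert np.all(down <= base + 1e-9)

    def test_target_accumulation_under_regimen(self, typical_ibd,
                                               standard_regimen):
        times = np.arange(0.0, 210.0, 0.25)
        traj = simulate_profile(typical_ibd, standard_regimen, times)
        fold = traj["RTC_nM"].max() / typical_ibd.R0C
        assert fold > 1.0
        # analytic quasi-steady ceiling kin/kint = R0*kout/kint
        assert fold < typical_ibd.kout / typical_ibd.kintC


class TestSecondaryParams:
    def test_base_model_terminal_half_life_is_about_17_days(self):
        sec = terminal_half_life(V1=2.8, V2=1.9, CL=0.20, Q=1.5)
        assert sec.t_half_beta == pytest.approx(16.7, abs=0.4)
        assert sec.t_half_alpha < sec.t_half_beta

    def test_one_compartment_limit(self):
        sec = terminal_half_life(V1=2.8, V2=1.9, CL=0.20, Q=0.0)
        assert sec.t_half_beta == pytest.approx(math.log(2) * 2.8 / 0.20,
                                                rel=1e-12)

    def test_against_eigenvalue_oracle(self):
        V1, V2, CL, Q = 2.6, 1.9, 0.16, 1.8
        A = np.array([[-(CL + Q) / V1, Q / V2], [Q / V1, -Q / V2]])
        lam = np.sort(np.linalg.eigvals(A).real)   # [-alpha, -beta]
        sec = terminal_half_life(V1, V2, CL, Q)
        assert sec.t_half_beta == pytest.approx(math.log(2) / -lam[1], rel=1e-10)
        assert sec.t_half_alpha == pytest.approx(math.log(2) / -lam[0], rel=1e-10)
        assert sec.t_half_beta == pytest.approx(19.8, abs=0.1)

    def test_micro_constants(self):
        sec = terminal_half_life(2.8, 1.9, 0.2, 1.5)
        assert sec.k10 == pytest.approx(0.2 / 2.8)
        assert sec.k12 == pytest.approx(1.5 / 2.8)
        assert sec.k21 == pytest.approx(1.5 / 1.9)


class TestUnits:
    def test_round_trip(self):
        u = UnitSystem()
        x = np.array([0.0, 0.103, 5.0, 15.0, 400.0])
        assert np.allclose(u.to_mgL(u.to_nM(x)), x, rtol=1e-12)

    @pytest.mark.parametrize("mgl,expected", [(0.0, 0.0), (5.0, 33.557),
                                              (15.0, 100.67)])
    def test_known_conversions(self, mgl, expected):
        assert convert_concentration(mgl) == pytest.approx(expected, abs=0.01)

    def test_invalid(self):
        with pytest.raises(ValueError):
            UnitSystem(mw=-1.0)
        with pytest.raises(ValueError):
            convert_concentration(-5.0)


class TestValidation:
    def test_active_arm_requires_positive_parameters(self):
        with pytest.raises(ValueError):
            StructuralParams(V1=2.6, V2=1.9, CL=0.16, Q=1.8, tmdd_central=True)

    def test_disabled_arm_zeroes_r0(self):
        p = StructuralParams(V1=2.6, V2=1.9, CL=0.16, Q=1.8, R0C=3.3,
                             tmdd_central=False)
        assert p.R0C_eff == 0.0
        assert p.kinC == 0.0

    def test_kin_derived_from_r0_kout(self, typical_ibd):
        assert typical_ibd.kinC == pytest.approx(typical_ibd.R0C * typical_ibd.kout)

    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, 100.0, duration=0.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, -5.0)
        assert DoseEvent(0.0, 300.0, 0.125).rate_mg_day == pytest.approx(2400.0)


class TestRegimenConfig:
    def test_event_list_form(self, tmp_path):
        from dtmdd.structural import load_regimen
        import json

        path = tmp_path / "reg.json"
        path.write_text(json.dumps([
            {"time": 0.0, "amount_mg": 330.0, "duration": 0.1},
            {"time": 14.0, "amount_mg": 330.0},
        ]))
        reg = load_regimen(path)
        assert len(reg) == 2
        assert reg[0].duration == 0.1
        assert reg[1].amount_mg == 330.0

    def test_weight_based_form(self, tmp_path):
        from dtmdd.structural import load_regimen
        import json

        path = tmp_path / "reg.json"
        path.write_text(json.dumps({"mg_per_kg": 5,
                                    "times_weeks": [0, 2, 6, 14, 22]}))
        reg = load_regimen(path, bw=64.0)
        assert [d.time for d in reg] == [0.0, 14.0, 42.0, 98.0, 154.0]
        assert reg[0].amount_mg == 300.0     # vial-rounded 64 kg x 5 mg/kg
        with pytest.raises(ValueError):
            load_regimen(path)
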