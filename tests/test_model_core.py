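"""Structural-model tests: closed forms against an independent ODE oracle,
steady-state and mass-balance invariants of the turnover solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from gcdcas_pk.model_core import (
    BiomarkerParams,
    DoseEvent,
    ProbenecidParams,
    RifampicinParams,
    baseline_concentration,
    build_grid,
    clearance_multipliers,
    probenecid_conc,
    probenecid_conc_batch,
    rifampicin_conc,
    rifampicin_conc_batch,
    solve_biomarker,
)

RIF600 = (DoseEvent("rifampicin", 0.0, 600.0),)
PROB500 = (DoseEvent("probenecid", 0.0, 500.0),)


class TestInhibitorClosedForms:
    def test_zero_before_lag(self):
        p = RifampicinParams()
        assert rifampicin_conc(0.3, RIF600, p) == 0.0
        assert probenecid_conc(-0.1 + 0.1, PROB500, ProbenecidParams())[()] >= 0.0

    def test_end_of_zero_order_input(self):
        # (D/Tk0)/(kV) (1 - e^{-k Tk0}) at t = Tlag + Tk0
        p = RifampicinParams()
        c = rifampicin_conc(p.Tlag + p.Tk0, RIF600, p)
        assert c == pytest.approx(19.24, abs=0.005)

    def test_probenecid_peak(self):
        p = ProbenecidParams()
        k = p.CL / p.V
        tmax = np.log(p.ka / k) / (p.ka - k)
        assert tmax == pytest.approx(2.854, abs=1e-3)
        assert probenecid_conc(tmax, PROB500, p) == pytest.approx(87.9, abs=0.05)

    def test_superposition_linearity(self):
        p = ProbenecidParams()
        t = np.linspace(0, 30, 91)
        two = (DoseEvent("probenecid", 0.0, 500.0), DoseEvent("probenecid", 6.0, 500.0))
        c2 = probenecid_conc(t, two, p)
        c_a = probenecid_conc(t, PROB500, p)
        c_b = probenecid_conc(t, (DoseEvent("probenecid", 6.0, 500.0),), p)
        np.testing.assert_allclose(c2, c_a + c_b, rtol=1e-12)

    def test_rifampicin_against_ode_oracle(self):
        """Closed form vs numerical integration of the absorption ODE."""
        p = RifampicinParams()
        k = p.CL / p.V
        rate = 600.0 * 1000.0 / p.MW / p.Tk0

        def rhs(t, y):
            inp = rate if p.Tlag < t <= p.Tlag + p.Tk0 else 0.0
            return [inp / p.V - k * y[0]]

        # integrate piecewise so the integrator never steps across a kink
        times = np.linspace(0.0, 24.0, 101)
        c_num = np.zeros_like(times)
        y = 0.0
        segs = [0.0, p.Tlag, p.Tlag + p.Tk0, 24.0]
        vals = {0.0: 0.0}
        for a, b in zip(segs[:-1], segs[1:]):
            sol = solve_ivp(rhs, [a, b], [y], rtol=1e-12, atol=1e-14,
                            dense_output=True)
            y = sol.y[0, -1]
            sel = (times > a) & (times <= b)
            c_num[sel] = sol.sol(times[sel])[0]
        c_closed = rifampicin_conc(times, RIF600, p)
        mask = c_num > 1e-8
        np.testing.assert_allclose(c_closed[mask], c_num[mask], rtol=1e-6)

    def test_probenecid_against_ode_oracle(self):
        p = ProbenecidParams()
        k = p.CL / p.V
        dose = 500.0 * 1000.0 / p.MW

        def rhs(t, y):
            return [-p.ka * y[0], p.ka * y[0] / p.V - k * y[1]]

        sol = solve_ivp(rhs, [0, 48], [dose, 0.0], rtol=1e-12, atol=1e-14,
                        dense_output=True)
        times = np.linspace(0.05, 48, 100)
        np.testing.assert_allclose(
            probenecid_conc(times, PROB500, p), sol.sol(times)[1], rtol=1e-6)

    def test_degenerate_ka_equals_k_limit(self):
        # Bateman denominator vanishes; the t e^{-kt} limit must take over
        V, CL = 17.0, 0.95
        k = CL / V
        p_eq = ProbenecidParams(ka=k, V=V, CL=CL)
        p_near = ProbenecidParams(ka=k * (1 + 1e-7), V=V, CL=CL)
        t = np.linspace(0.1, 48, 50)
        c_eq = probenecid_conc(t, PROB500, p_eq)
        c_near = probenecid_conc(t, PROB500, p_near)
        assert np.all(np.isfinite(c_eq))
        np.testing.assert_allclose(c_eq, c_near, rtol=1e-5)

    def test_mass_balance_of_eliminated_amount(self):
        # cumulative eliminated amount approaches the dose in µmol
        p = RifampicinParams()
        t = np.linspace(0, 2000, 200001)
        c = rifampicin_conc(t, RIF600, p)
        eliminated = np.trapezoid(c * p.CL, t)
        assert eliminated == pytest.approx(600.0 * 1000.0 / p.MW, rel=1e-4)

    def test_wrong_drug_rejected(self):
        with pytest.raises(ValueError, match="rifampicin"):
            rifampicin_conc(1.0, PROB500, RifampicinParams())

    def test_batch_matches_scalar(self):
        p = RifampicinParams()
        t = np.linspace(0, 24, 97)
        batch = rifampicin_conc_batch(
            t, RIF600, [p.Tlag, 0.8], [p.Tk0, 1.2], [p.V, 30.0], [p.CL, 5.0], p.MW)
        np.testing.assert_allclose(batch[0], rifampicin_conc(t, RIF600, p), rtol=1e-12)
        p2 = RifampicinParams(Tlag=0.8, Tk0=1.2, V=30.0, CL=5.0)
        np.testing.assert_allclose(batch[1], rifampicin_conc(t, RIF600, p2), rtol=1e-12)
        pb = ProbenecidParams()
        bb = probenecid_conc_batch(t, PROB500, [pb.ka], [pb.V], [pb.CL], pb.MW)
        np.testing.assert_allclose(bb[0], probenecid_conc(t, PROB500, pb), rtol=1e-12)


class TestClearanceMultipliers:
    def test_no_inhibitor_is_identity(self):
        mh, mr = clearance_multipliers(0.0, 0.0, RifampicinParams(), ProbenecidParams())
        assert (mh, mr) == (1.0, 1.0)

    def test_renal_competitive_inhibition(self):
        prob = ProbenecidParams(Ki_u_OAT3=2.7)
        _, mr = clearance_multipliers(0.0, 10.0, RifampicinParams(), prob)
        assert mr == pytest.approx(1.0 / (1.0 + 10.0 / 2.7), rel=1e-12)

    def test_probenecid_occasion_fold_reduction(self):
        prob = ProbenecidParams(X=1.7)
        mh, _ = clearance_multipliers(0.0, 0.0, RifampicinParams(), prob,
                                      probenecid_occasion=True)
        assert mh == pytest.approx(1.0 / 1.7, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            clearance_multipliers(-1.0, 0.0, RifampicinParams(), ProbenecidParams())

    @settings(max_examples=50, deadline=None)
    @given(cu_r=st.floats(0, 1e3), cu_p=st.floats(0, 1e4),
           y1=st.floats(0, 10), y3=st.floats(0, 10),
           prob_occ=st.booleans())
    def test_multipliers_in_unit_interval(self, cu_r, cu_p, y1, y3, prob_occ):
        mh, mr = clearance_multipliers(cu_r, cu_p, RifampicinParams(),
                                       ProbenecidParams(), prob_occ, y1, y3)
        assert 0 < mh <= 1.0 and 0 < mr <= 1.0


class TestTurnoverSolver:
    def test_baseline_examples(self):
        bp = BiomarkerParams()
        assert baseline_concentration(bp) == pytest.approx(1.0 / 15.31, rel=1e-12)
        double = BiomarkerParams(ksyn=2.0)
        assert baseline_concentration(double) == pytest.approx(2.0 / 15.31, rel=1e-12)
        no_renal = BiomarkerParams(CLR=1e-9)
        assert baseline_concentration(no_renal) == pytest.approx(1.0 / 15.0, rel=1e-6)

    def test_steady_state_preserved_without_inhibitor(self):
        bp = BiomarkerParams()
        res = solve_biomarker(24.0, (), bp)
        b = baseline_concentration(bp)
        np.testing.assert_allclose(res.conc, b, rtol=1e-8)
        assert res.urine_cum[-1] == pytest.approx(b * bp.CLR * 24.0, rel=1e-8)

    def test_urine_cumulative_monotone_from_zero(self):
        res = solve_biomarker(24.0, RIF600, BiomarkerParams())
        assert res.urine_cum[0] == 0.0
        assert np.all(np.diff(res.urine_cum) >= 0)

    def test_mass_balance(self):
        """ksyn*T = Vc dC + hepatic + renal amounts, exactly, and the
        hepatic integral agrees with independent quadrature."""
        bp = BiomarkerParams()
        res = solve_biomarker(24.0, RIF600, bp, dt=0.005)
        lhs = bp.ksyn * 24.0
        rhs = bp.Vc * (res.conc[-1] - res.conc[0]) + res.hepatic_cum[-1] + res.urine_cum[-1]
        assert rhs == pytest.approx(lhs, rel=1e-12)
        # independent check of the renal split via trapezoid of C*CLR (mr=1)
        renal = np.trapezoid(res.conc * bp.CLR, res.t)
        assert res.urine_cum[-1] == pytest.approx(renal, rel=1e-6)

    def test_matches_adaptive_ode_oracle(self):
        bp, rif, prob = BiomarkerParams(), RifampicinParams(), ProbenecidParams()
        b = baseline_concentration(bp)

        def rhs(t, y):
            cu = rif.fu * rifampicin_conc(t, RIF600, rif)
            mh, mr = clearance_multipliers(cu, 0.0, rif, prob)
            return [(bp.ksyn - y[0] * (bp.CLh * mh + bp.CLR * mr)) / bp.Vc]

        sol = solve_ivp(rhs, [0, 24], [b], rtol=1e-10, atol=1e-13,
                        dense_output=True, max_step=0.1)
        res = solve_biomarker(24.0, RIF600, bp, dt=0.02)
        np.testing.assert_allclose(res.conc, sol.sol(res.t)[0], rtol=2e-3)

    def test_linear_in_synthesis_rate(self):
        res1 = solve_biomarker(24.0, RIF600, BiomarkerParams(ksyn=1.0))
        res2 = solve_biomarker(24.0, RIF600, BiomarkerParams(ksyn=2.0))
        np.testing.assert_allclose(res2.conc, 2.0 * res1.conc, rtol=1e-10)
        np.testing.assert_allclose(res2.urine_cum[1:], 2.0 * res1.urine_cum[1:], rtol=1e-10)

    def test_full_hepatic_inhibition_limit(self):
        # mh == 0 -> C tends to ksyn/CLR
        bp = BiomarkerParams()
        rif = RifampicinParams(Ki_u_OATP1B3=1e-12)  # effectively complete block
        doses = tuple(DoseEvent("rifampicin", t, 600.0) for t in np.arange(0, 2000, 12.0))
        res = solve_biomarker(2000.0, doses, bp, rif=rif, dt=0.1)
        assert res.conc[-1] == pytest.approx(bp.ksyn / bp.CLR, rel=0.01)

    def test_exposure_monotone_in_potency_scales(self):
        bp = BiomarkerParams()
        aucs, urines = [], []
        prob_doses = tuple(DoseEvent("probenecid", t, 500.0) for t in (0.0, 5.0, 13.0, 19.0))
        for y in (0.0, 0.5, 1.0, 2.0):
            r = solve_biomarker(24.0, RIF600, bp, scale_oatp1b3=y)
            aucs.append(np.trapezoid(r.conc, r.t))
            r = solve_biomarker(24.0, prob_doses, bp, scale_oat3=y)
            urines.append(r.urine_cum[-1] / np.trapezoid(r.conc, r.t))
        assert np.all(np.diff(aucs) > 0)          # OATP1B3 inhibition raises AUC
        assert np.all(np.diff(urines) < 0)        # OAT3 inhibition lowers CLR

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            solve_biomarker(-1.0, (), BiomarkerParams())

    def test_grid_contains_breakpoints(self):
        rif = RifampicinParams()
        grid = build_grid(24.0, RIF600, rif, extra=[7.7])
        for node in (0.0, rif.Tlag, rif.Tlag + rif.Tk0, 7.7, 24.0):
            assert np.min(np.abs(grid - node)) < 1e-12


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [
        {"Tk0": 0.0}, {"V": -1.0}, {"fu": 0.0}, {"fu": 1.5},
    ])
    def test_rifampicin_invariants(self, kwargs):
        with pytest.raises(ValueError):
            RifampicinParams(**kwargs)

    def test_probenecid_x_at_least_one(self):
        with pytest.raises(ValueError):
            ProbenecidParams(X=0.9)

    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent("aspirin", 0.0, 100.0)
        with pytest.raises(ValueError):
            DoseEvent("rifampicin", 0.0, -5.0)
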