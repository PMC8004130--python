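import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fdgflux import (CompartmentParams, FrameTiming, LC_MYOCARDIUM,
                     LC_SKELETAL_MUSCLE, ParametricInput, SampledInput,
                     SerumSeries, ValidationError, ki, metabolic_rate,
                     roi_signals, tissue_curves, tissue_curves_frame_avg,
                     window_average_glucose)
from _oracles import ode_tissue_curves


class TestTissueCurves:
    def test_step_input_closed_form(self, step_input):
        """Ce and Cm for a step input match the hand-derived closed form."""
        p = CompartmentParams(0.5, 0.4, 0.1)
        ce, cm = tissue_curves(p, step_input, np.array([10.0]))
        assert ce[0] == pytest.approx(9.9326, abs=1e-4)
        assert cm[0] == pytest.approx(8.0135, abs=1e-4)

    def test_no_uptake_and_no_trapping(self, step_input):
        t = np.linspace(0.0, 30.0, 7)
        ce, cm = tissue_curves(CompartmentParams(0.0, 0.4, 0.1), step_input, t)
        assert np.allclose(ce, 0) and np.allclose(cm, 0)
        ce, cm = tissue_curves(CompartmentParams(0.5, 0.4, 0.0), step_input, t)
        assert np.allclose(cm, 0) and np.all(ce[1:] > 0)

    @pytest.mark.parametrize("params", [
        CompartmentParams(0.6, 1.2, 0.1),
        CompartmentParams(0.3, 0.5, 0.05, 0.02),
        CompartmentParams(0.1, 0.3, 0.02, 0.005),
        CompartmentParams(0.05, 0.1, 0.3, 0.1),
    ])
    def test_agrees_with_ode_oracle(self, params, infusion_input):
        """Semi-analytic solution matches high-order ODE integration."""
        t = np.linspace(0.5, 60.0, 40)
        ce, cm = tissue_curves(params, infusion_input, t)
        ce_o, cm_o = ode_tissue_curves(params, infusion_input, t)
        assert np.allclose(ce, ce_o, rtol=1e-8, atol=1e-10)
        assert np.allclose(cm, cm_o, rtol=1e-8, atol=1e-10)

    def test_continuation_across_rate_switch(self, infusion_input):
        """Restarting at t0 with the saved state equals integrating through."""
        pn = CompartmentParams(0.6, 1.2, 0.0235)
        ph = pn.with_ki(0.6 * ki(pn))
        state = np.array(tissue_curves(pn, infusion_input, np.array([15.0]))).ravel()
        t = np.array([20.0, 40.0, 60.0])
        ce, cm = tissue_curves(ph, infusion_input, t, t0=15.0, initial_state=tuple(state))

        def rhs(tt, x):
            p = pn if tt < 15.0 else ph
            cp = float(infusion_input.conc(np.asarray(tt)))
            return [p.K1 * cp - (p.k2 + p.k3) * x[0], p.k3 * x[0]]
        from scipy.integrate import solve_ivp
        sol = solve_ivp(rhs, (0, 60), [0, 0], t_eval=t, method="DOP853",
                        rtol=1e-11, atol=1e-13, max_step=1.0)
        assert np.allclose(ce, sol.y[0], rtol=1e-7, atol=1e-8)
        assert np.allclose(cm, sol.y[1], rtol=1e-7, atol=1e-8)

    def test_linearity_in_input(self, myo_params, infusion_input):
        """Doubling the input doubles the tissue curves."""
        t = np.linspace(1, 60, 13)
        doubled = ParametricInput(2 * infusion_input.plateau, infusion_input.tau,
                                  2 * infusion_input.bolus_amp, infusion_input.bolus_tau)
        ce1, cm1 = tissue_curves(myo_params, infusion_input, t)
        ce2, cm2 = tissue_curves(myo_params, doubled, t)
        assert np.allclose(ce2, 2 * ce1, rtol=1e-10)
        assert np.allclose(cm2, 2 * cm1, rtol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(K1=st.floats(0.01, 1.5), k2=st.floats(0.05, 3.0),
           k3=st.floats(0.0, 0.5), k4=st.floats(0.0, 0.1))
    def test_nonnegative(self, K1, k2, k3, k4):
        p = CompartmentParams(K1, k2, k3, k4)
        inp = ParametricInput(50.0, 15.0, 20.0, 1.0)
        t = np.linspace(0, 60, 61)
        ce, cm = tissue_curves(p, inp, t)
        assert np.all(ce >= -1e-9) and np.all(cm >= -1e-9)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            CompartmentParams(-0.1, 0.4, 0.1)


class TestRoiSignals:
    def test_identity_mixing(self, myo_params, infusion_input, timing60):
        p0 = CompartmentParams(myo_params.K1, myo_params.k2, myo_params.k3)
        m, b = roi_signals(p0, infusion_input, timing60)
        ce, cm = tissue_curves_frame_avg(p0, infusion_input, timing60)
        cp = (infusion_input.cumint(timing60.frame_end)
              - infusion_input.cumint(timing60.frame_start)) / timing60.frame_duration
        assert np.allclose(m, ce + cm)
        assert np.allclose(b, cp)

    def test_pure_spillover_with_no_uptake(self, step_input, timing60):
        """alpha=0.3, Cp=10, K1=0 gives a constant tissue-ROI signal of 3."""
        p = CompartmentParams(0.0, 0.4, 0.1, sp_blood_to_tissue=0.3)
        m, _ = roi_signals(p, step_input, timing60)
        assert np.allclose(m, 3.0)

    def test_spillover_fraction_bound(self):
        with pytest.raises(ValidationError):
            CompartmentParams(0.5, 0.4, 0.1, sp_blood_to_tissue=1.0)

    def test_frame_average_converges_to_instantaneous(self, myo_params, infusion_input):
        """As frames shrink, frame averages approach point samples."""
        t_ref = 30.0
        inst_m = None
        errs = []
        ce, cm = tissue_curves(myo_params, infusion_input, np.array([t_ref + 0.0]))
        cp = infusion_input.conc(np.array([t_ref]))
        inst = (1 - myo_params.alpha) * (ce + cm) + myo_params.alpha * cp
        for dur in (2.0, 0.5, 0.05):
            timing = FrameTiming(np.array([t_ref - dur / 2]), np.array([dur]))
            m, _ = roi_signals(myo_params, infusion_input, timing)
            errs.append(abs(m[0] - inst[0]))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-4 * abs(inst[0])


class TestSampledInput:
    def test_matches_parametric_on_fine_grid(self, infusion_input):
        ts = np.arange(0.0, 60.0001, 0.01)
        si = SampledInput(ts, infusion_input.conc(ts))
        t = np.array([5.0, 20.0, 55.0])
        for lam in (0.1, 0.7, 1.5):
            a = si.expconv(lam, t)
            b = infusion_input.expconv(lam, t)
            assert np.allclose(a, b, rtol=1e-5)
        assert np.allclose(si.cumint(t), infusion_input.cumint(t), rtol=1e-5)

    def test_constant_extrapolation(self):
        si = SampledInput(np.array([1.0, 2.0]), np.array([4.0, 4.0]))
        assert si.conc(np.array([0.0]))[0] == 4.0
        assert si.conc(np.array([10.0]))[0] == 4.0

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValidationError):
            SampledInput(np.array([2.0, 1.0]), np.array([1.0, 1.0]))


class TestKi:
    def test_hand_value(self):
        assert ki(CompartmentParams(0.6, 1.2, 0.1)) == pytest.approx(0.046154, abs=1e-6)

    def test_limits(self):
        assert ki(CompartmentParams(0.6, 1.2, 0.0)) == 0.0
        assert ki(CompartmentParams(0.6, 0.0, 0.1)) == pytest.approx(0.6)

    def test_undefined_when_no_exchange(self):
        with pytest.raises(ValidationError):
            ki(CompartmentParams(0.0, 0.0, 0.0))

    def test_monotonicity(self):
        """Ki rises with K1 and k3, falls with k2, across a grid."""
        base = dict(K1=0.4, k2=0.8, k3=0.08)
        for K1 in (0.1, 0.4, 0.9):
            for k2 in (0.2, 0.8, 2.0):
                for k3 in (0.02, 0.08, 0.2):
                    v = ki(CompartmentParams(K1, k2, k3))
                    assert ki(CompartmentParams(K1 + 0.1, k2, k3)) > v
                    assert ki(CompartmentParams(K1, k2 + 0.1, k3)) < v
                    assert ki(CompartmentParams(K1, k2, k3 + 0.01)) > v


class TestMetabolicRate:
    def _serum(self, glc=90.0):
        t = np.arange(0.0, 61.0, 10.0)
        return SerumSeries(t, np.full(t.size, glc))

    def test_myocardial_rate_hand_value(self):
        # 0.046154 * (90 / 18.016) / 1.44 = 0.160112
        rate = metabolic_rate(0.046154, self._serum(), (0, 15), LC_MYOCARDIUM)
        assert rate == pytest.approx(0.046154 * (90 / 18.016) / 1.44, rel=1e-12)
        assert rate == pytest.approx(0.1601, abs=1e-4)

    def test_skeletal_rate_hand_value(self):
        # 0.046154 * (90 / 18.016) / 1.16 = 0.198759
        rate = metabolic_rate(0.046154, self._serum(), (0, 15), LC_SKELETAL_MUSCLE)
        assert rate == pytest.approx(0.046154 * (90 / 18.016) / 1.16, rel=1e-12)
        assert rate == pytest.approx(0.1988, abs=1e-4)

    def test_zero_ki(self):
        assert metabolic_rate(0.0, self._serum(), (0, 15), LC_MYOCARDIUM) == 0.0

    def test_linearity_in_glucose(self):
        r1 = metabolic_rate(0.01, self._serum(90), (0, 15), LC_MYOCARDIUM)
        r2 = metabolic_rate(0.01, self._serum(180), (0, 15), LC_MYOCARDIUM)
        assert r2 == pytest.approx(2 * r1)

    def test_window_average_interpolates_edges(self):
        """Ramp glucose: trapezoidal average over [0,15] with edge interpolation."""
        serum = SerumSeries(np.array([0.0, 10.0, 20.0]), np.array([90.0, 100.0, 110.0]))
        # linear ramp 90 + t: average over [0,15] = 90 + 7.5
        assert window_average_glucose(serum, (0, 15)) == pytest.approx(97.5)

    def test_no_samples_is_error(self):
        with pytest.raises(Exception):
            window_average_glucose(SerumSeries(np.array([]), np.array([])), (0, 15))
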