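import numpy as np
import pytest

from fdgflux import (AcquisitionProtocol, CompartmentParams, FitError,
                     FrameTiming, ParametricInput, SubjectSimSpec, ki,
                     simulate_subject_tacs)
from fdgflux.fitting import (FitOptions, fit_conditions_myocardium_blood,
                             fit_conditions_skeletal, fit_myocardium_blood,
                             fit_skeletal, fit_subject)
from fdgflux.kinetic_model import roi_signals
from fdgflux.tac_extraction import TimeActivityCurve


@pytest.fixture(scope="module")
def protocol():
    return AcquisitionProtocol()


def _subject(noise=0.0, seed=1, myo=CompartmentParams(0.6, 1.2, 0.1, 0.0, 0.2, 0.1),
             mult=1.0, protocol=None):
    spec = SubjectSimSpec("s", "preterm", myo_params=myo, noise_cv=noise,
                          seed=seed, myo_ki_multiplier=mult, sk_ki_multiplier=mult)
    return spec, simulate_subject_tacs(spec, protocol or AcquisitionProtocol())


class TestJointFitNoiseless:
    def test_exact_parameter_recovery(self, protocol):
        """Noiseless synthetic pair: all five parameters back within 1%."""
        spec, (tacs, _, truth) = _subject(noise=0.0, seed=1)
        fit = fit_myocardium_blood(tacs["myocardium"], tacs["blood_pool"],
                                   protocol.normoxia_fit_window)
        p, tp = fit.params, spec.myo_params
        for name in ("K1", "k2", "k3"):
            assert getattr(p, name) == pytest.approx(getattr(tp, name), rel=0.01)
        assert p.alpha == pytest.approx(0.2, rel=0.01)
        assert p.beta == pytest.approx(0.1, rel=0.01)
        norm = np.sum(tacs["myocardium"].activity ** 2) + np.sum(tacs["blood_pool"].activity ** 2)
        assert fit.sse < 1e-8 * norm

    def test_corrected_blood_matches_true_input(self, protocol):
        spec, (tacs, _, truth) = _subject(noise=0.0, seed=2)
        fit = fit_myocardium_blood(tacs["myocardium"], tacs["blood_pool"],
                                   protocol.normoxia_fit_window)
        cb = fit.corrected_blood
        ti = truth["input"]
        true_inp = ParametricInput(ti["plateau"], ti["tau"], ti["bolus_amp"], ti["bolus_tau"])
        expected = (true_inp.cumint(cb.frame_mid + cb.frame_duration / 2)
                    - true_inp.cumint(cb.frame_mid - cb.frame_duration / 2)) / cb.frame_duration
        assert np.allclose(cb.activity, expected, rtol=0.02)


class TestSkeletalFit:
    def test_noiseless_recovery_with_known_input(self, protocol):
        spec, (tacs, _, truth) = _subject(noise=0.0, seed=3)
        ti = truth["input"]
        inp = ParametricInput(ti["plateau"], ti["tau"], ti["bolus_amp"], ti["bolus_tau"])
        fit = fit_skeletal(tacs["skeletal_muscle"], inp, protocol.normoxia_fit_window)
        tp = spec.sk_params
        for name in ("K1", "k2", "k3"):
            assert getattr(fit.params, name) == pytest.approx(getattr(tp, name), rel=0.01)
        assert fit.params.alpha == pytest.approx(tp.alpha, rel=0.01)
        assert fit.params.beta == 0.0

    def test_zero_spillover_recovered_at_boundary(self, protocol):
        spec = SubjectSimSpec(
            "s", "preterm", noise_cv=0.0, seed=4,
            sk_params=CompartmentParams(0.1, 0.3, 0.02, 0.0, 0.0, 0.0))
        tacs, _, truth = simulate_subject_tacs(spec, protocol)
        ti = truth["input"]
        inp = ParametricInput(ti["plateau"], ti["tau"], ti["bolus_amp"], ti["bolus_tau"])
        fit = fit_skeletal(tacs["skeletal_muscle"], inp, protocol.normoxia_fit_window)
        assert fit.params.alpha < 0.02

    def test_missing_input_is_precondition_error(self, protocol):
        spec, (tacs, _, _) = _subject(noise=0.0, seed=5)
        with pytest.raises(FitError, match="corrected blood"):
            fit_skeletal(tacs["skeletal_muscle"], None, protocol.normoxia_fit_window)


class TestGuardsAndDeterminism:
    def _tacpair(self, n=12, value=1.0):
        t = FrameTiming.uniform(n, 1.0)
        mk = lambda label, v: TimeActivityCurve(label, t.frame_mid, t.frame_duration,
                                                np.full(n, v), 10)
        return mk("myocardium", value), mk("blood_pool", value)

    def test_zero_tac_is_degenerate(self):
        myo, blood = self._tacpair(value=0.0)
        with pytest.raises(FitError, match="zero"):
            fit_myocardium_blood(myo, blood)

    def test_refuses_five_frames(self):
        myo, blood = self._tacpair(n=5)
        with pytest.raises(FitError, match="[Ff]rames"):
            fit_myocardium_blood(myo, blood)

    def test_refuses_below_joint_minimum(self):
        myo, blood = self._tacpair(n=7)
        with pytest.raises(FitError):
            fit_myocardium_blood(myo, blood)

    def test_multistart_determinism(self, protocol):
        _, (tacs, _, _) = _subject(noise=0.05, seed=6)
        f1 = fit_myocardium_blood(tacs["myocardium"], tacs["blood_pool"],
                                  protocol.normoxia_fit_window)
        f2 = fit_myocardium_blood(tacs["myocardium"], tacs["blood_pool"],
                                  protocol.normoxia_fit_window)
        assert f1.params == f2.params
        assert f1.sse == f2.sse
        assert f1.best_start_index == f2.best_start_index

    def test_returned_sse_not_above_other_starts(self, protocol):
        _, (tacs, _, _) = _subject(noise=0.05, seed=7)
        fit = fit_myocardium_blood(tacs["myocardium"], tacs["blood_pool"],
                                   protocol.normoxia_fit_window)
        tried = fit.all_start_sse[np.isfinite(fit.all_start_sse)]
        assert tried.min() >= fit.sse - 1e-6 * max(fit.sse, 1.0)


class TestConditionFits:
    def test_noiseless_two_condition_recovery(self, protocol):
        _, (tacs, serum, truth) = _subject(noise=0.0, seed=8, mult=0.6)
        fn, fh = fit_conditions_myocardium_blood(tacs["myocardium"],
                                                 tacs["blood_pool"], protocol)
        assert ki(fn.params) == pytest.approx(truth["myocardium"]["normoxia"]["Ki"], rel=0.01)
        assert ki(fh.params) == pytest.approx(truth["myocardium"]["hypoxia"]["Ki"], rel=0.01)
        # shared transport, per-condition phosphorylation
        assert fn.params.K1 == fh.params.K1
        assert fn.params.k3 != fh.params.k3
        sn, sh = fit_conditions_skeletal(tacs["skeletal_muscle"], fn, protocol)
        assert ki(sn.params) == pytest.approx(truth["skeletal_muscle"]["normoxia"]["Ki"], rel=0.01)
        assert ki(sh.params) == pytest.approx(truth["skeletal_muscle"]["hypoxia"]["Ki"], rel=0.01)


class TestFitSubject:
    def test_four_results_and_rate_formula(self, protocol):
        _, (tacs, serum, truth) = _subject(noise=0.0, seed=9, mult=0.6)
        results = fit_subject(tacs, serum, protocol)
        assert len(results) == 4
        combos = {(r.tissue, r.condition) for r in results}
        assert combos == {("myocardium", "normoxia"), ("myocardium", "hypoxia"),
                          ("skeletal_muscle", "normoxia"), ("skeletal_muscle", "hypoxia")}
        for r in results:
            assert r.rate == pytest.approx(r.ki * r.glucose_umol_ml / r.lc.value, rel=1e-12)
            tr = truth[r.tissue][r.condition]
            assert r.rate == pytest.approx(tr["rate"], rel=0.02)

    def test_doubling_glucose_doubles_rates(self, protocol):
        _, (tacs, serum, _) = _subject(noise=0.0, seed=10)
        res1 = fit_subject(tacs, serum, protocol)
        from fdgflux import SerumSeries
        serum2 = SerumSeries(serum.sample_time, 2 * serum.glucose, serum.lactate)
        res2 = fit_subject(tacs, serum2, protocol)
        for a, b in zip(res1, res2):
            assert b.ki == pytest.approx(a.ki, rel=1e-12)
            assert b.rate == pytest.approx(2 * a.rate, rel=1e-12)

    def test_window_too_narrow_for_frames(self):
        proto = AcquisitionProtocol(hypoxia_fit_window=(15.0, 15.5))
        _, (tacs, serum, _) = _subject(noise=0.0, seed=11, protocol=proto)
        with pytest.raises(FitError):
            fit_subject(tacs, serum, proto)

    def test_missing_roi(self, protocol):
        _, (tacs, serum, _) = _subject(noise=0.0, seed=12)
        del tacs["blood_pool"]
        with pytest.raises(FitError, match="blood_pool"):
            fit_subject(tacs, serum, protocol)
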