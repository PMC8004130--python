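import numpy as np
import pytest
from scipy import ndimage

from fdgflux import (AcquisitionProtocol, CohortSimSpec, CompartmentParams,
                     FrameTiming, PhantomSpec, SubjectSimSpec, ValidationError,
                     build_phantom, extract_tac, ki, make_input_function,
                     roi_signals, simulate_cohort, simulate_subject_tacs)
from fdgflux.kinetic_model import LC_MYOCARDIUM
from fdgflux.synthetic_data import (HYPOXIA_KI_MULTIPLIERS,
                                    MYOCARDIUM_DEFAULTS, SKELETAL_DEFAULTS)


class TestInputFunction:
    def test_zero_at_start_and_plateau_limit(self, protocol):
        inp, truth = make_input_function(protocol)
        assert inp.conc(np.array([0.0]))[0] == 0.0
        assert inp.conc(np.array([1e4]))[0] == pytest.approx(truth["plateau"], rel=1e-6)

    def test_plateau_saturation_hand_value(self, protocol):
        # A(1 - e^{-t/tau}) at t = tau: 10 * (1 - e^-1) = 6.3212
        inp, _ = make_input_function(protocol, tau=20.0)
        from fdgflux.kinetic_model import ParametricInput
        pure = ParametricInput(10.0, 20.0, 0.0, 1.5)
        assert pure.conc(np.array([20.0]))[0] == pytest.approx(6.3212, abs=1e-4)

    def test_plateau_from_dose_and_volume(self, protocol):
        # 10 mCi = 370,000 kBq into 5 L
        inp, truth = make_input_function(protocol)
        assert truth["plateau"] == pytest.approx(74.0)
        # bolus peak is 25% of plateau at t = bolus_tau
        peak_t = truth["bolus_tau"]
        bolus_only = truth["bolus_amp"] * peak_t * np.exp(-1.0)
        assert bolus_only == pytest.approx(0.25 * 74.0, rel=1e-9)


class TestSubjectSimulation:
    def test_noiseless_tacs_equal_model_output(self, protocol):
        spec = SubjectSimSpec("s", "preterm", noise_cv=0.0, seed=0)
        tacs, _, truth = simulate_subject_tacs(spec, protocol)
        inp, _ = make_input_function(protocol)
        timing = FrameTiming.uniform(60, 1.0)
        pre = timing.frame_end <= 15.0 + 1e-9
        m, b = roi_signals(spec.myo_params, inp,
                           FrameTiming(timing.frame_start[pre], timing.frame_duration[pre]))
        assert np.allclose(tacs["myocardium"].activity[pre], m)
        assert np.allclose(tacs["blood_pool"].activity[pre], b)

    def test_unit_multiplier_keeps_ki(self, protocol):
        spec = SubjectSimSpec("s", "term", myo_ki_multiplier=1.0,
                              sk_ki_multiplier=1.0, noise_cv=0.0, seed=0)
        _, _, truth = simulate_subject_tacs(spec, protocol)
        assert truth["myocardium"]["normoxia"]["Ki"] == pytest.approx(
            truth["myocardium"]["hypoxia"]["Ki"])

    def test_determinism(self, protocol):
        for _ in range(2):
            spec = SubjectSimSpec("s", "preterm", seed=11)
            t1, s1, _ = simulate_subject_tacs(spec, protocol)
            t2, s2, _ = simulate_subject_tacs(spec, protocol)
            for k in t1:
                assert np.array_equal(t1[k].activity, t2[k].activity)
            assert np.array_equal(s1.glucose, s2.glucose)

    def test_programmed_ki_multiplier(self, protocol):
        spec = SubjectSimSpec("s", "preterm", noise_cv=0.0, seed=0)
        _, _, truth = simulate_subject_tacs(spec, protocol)
        r = truth["myocardium"]["hypoxia"]["Ki"] / truth["myocardium"]["normoxia"]["Ki"]
        assert r == pytest.approx(spec.myo_ki_multiplier)

    def test_default_mmrglc_scale(self, protocol):
        """Default myocardial parameters put resting MMRglc near 0.04 μmol/mL/min."""
        spec = SubjectSimSpec("s", "term", noise_cv=0.0, seed=0)
        _, _, truth = simulate_subject_tacs(spec, protocol)
        assert truth["myocardium"]["normoxia"]["rate"] == pytest.approx(0.04, abs=0.002)

    def test_glucose_rise_reaches_target_at_55(self, protocol):
        spec = SubjectSimSpec("s", "term", glucose_rise=0.05, noise_cv=0.0, seed=0)
        _, serum, _ = simulate_subject_tacs(spec, protocol)
        i55 = np.argmin(np.abs(serum.sample_time - 55.0))
        assert serum.glucose[i55] == pytest.approx(90.0 * 1.05)
        assert serum.glucose[0] == pytest.approx(90.0)

    def test_invalid_multiplier(self, protocol):
        with pytest.raises(ValidationError):
            SubjectSimSpec("s", "term", myo_ki_multiplier=-1.0)


class TestPhantom:
    def test_exact_region_curves_without_blur(self, protocol):
        spec = PhantomSpec(fwhm_mm=0.0, noise_cv=0.0, seed=0)
        image, masks, truth = build_phantom(spec, protocol)
        for mask in masks:
            tac = extract_tac(image, mask)
            expected = np.asarray(truth["region_curves"][mask.label])
            assert np.allclose(tac.activity, expected, rtol=1e-10)

    def test_masks_disjoint(self, protocol):
        _, masks, _ = build_phantom(PhantomSpec(), protocol)
        total = sum(m.voxels.astype(int) for m in masks)
        assert total.max() == 1

    def test_blur_mixes_adjacent_regions(self, protocol):
        """With 8 mm blur the blood-adjacent rim of the myocardial shell
        reads between the pure myocardial and blood curves at early frames
        (spill-in from the hotter cavity)."""
        from fdgflux import RoiMask
        spec = PhantomSpec(fwhm_mm=8.0, noise_cv=0.0, seed=0)
        image, masks, truth = build_phantom(spec, protocol)
        myo = next(m for m in masks if m.label == "myocardium").voxels
        blood = next(m for m in masks if m.label == "blood_pool").voxels
        rim = myo & ndimage.binary_dilation(blood, iterations=2)
        tac = extract_tac(image, RoiMask("myocardium", rim))
        myo_curve = np.asarray(truth["region_curves"]["myocardium"])
        blood_curve = np.asarray(truth["region_curves"]["blood_pool"])
        early = slice(2, 8)
        assert np.all(tac.activity[early] > myo_curve[early])
        assert np.all(tac.activity[early] < blood_curve[early])

    def test_blur_against_brute_force_convolution(self, protocol):
        """Package blur equals direct Gaussian convolution of the label image."""
        spec = PhantomSpec(fwhm_mm=6.0, noise_cv=0.0, seed=0)
        image, masks, truth = build_phantom(spec, protocol)
        frame = 10
        raw = np.zeros(spec.shape)
        for m in masks:
            raw[m.voxels] = truth["region_curves"][m.label][frame]
        sigma = [6.0 / 2.354820045 / v for v in spec.voxel_size_mm]
        expected = ndimage.gaussian_filter(raw, sigma)
        assert np.allclose(image.data[..., frame], expected, atol=1e-10)

    def test_erosion_improves_tac_fidelity(self, protocol):
        """On a blurred phantom, the eroded-mask TAC is closer to the true
        regional curve than the uneroded-mask TAC."""
        from fdgflux import erode_mask
        spec = PhantomSpec(fwhm_mm=8.0, noise_cv=0.0, seed=0)
        image, masks, truth = build_phantom(spec, protocol)
        myo_mask = next(m for m in masks if m.label == "myocardium")
        truth_curve = np.asarray(truth["region_curves"]["myocardium"])
        err_raw = np.max(np.abs(extract_tac(image, myo_mask).activity - truth_curve))
        eroded = erode_mask(myo_mask, 3)
        err_eroded = np.max(np.abs(extract_tac(image, eroded).activity - truth_curve))
        assert err_eroded < err_raw


class TestCohort:
    def test_counts_and_files(self, protocol, tmp_path):
        spec = CohortSimSpec(n_term=2, n_preterm=3, seed=1)
        subs, manifest = simulate_cohort(spec, protocol, out_dir=tmp_path)
        assert len(subs) == 5
        assert sum(s.group == "preterm" for s in subs) == 3
        assert sorted(p.name for p in tmp_path.iterdir() if p.is_dir()) == \
            [f"sub-{i:03d}" for i in range(1, 6)]
        assert (tmp_path / "truth_manifest.json").exists()

    def test_manifest_ki_consistent_with_params(self, protocol):
        spec = CohortSimSpec(n_term=1, n_preterm=2, seed=3)
        _, manifest = simulate_cohort(spec, protocol)
        for sub in manifest["subjects"]:
            for tissue in ("myocardium", "skeletal_muscle"):
                for cond in ("normoxia", "hypoxia"):
                    p = sub[tissue][cond]["params"]
                    expected = ki(CompartmentParams(p["K1"], p["k2"], p["k3"]))
                    assert sub[tissue][cond]["Ki"] == pytest.approx(expected, rel=1e-12)

    def test_determinism(self, protocol):
        s1, m1 = simulate_cohort(CohortSimSpec(n_term=1, n_preterm=1, seed=9), protocol)
        s2, m2 = simulate_cohort(CohortSimSpec(n_term=1, n_preterm=1, seed=9), protocol)
        for a, b in zip(s1, s2):
            for k in a.tacs:
                assert np.array_equal(a.tacs[k].activity, b.tacs[k].activity)
            assert a.spo2_hypoxia == b.spo2_hypoxia

    def test_group_multipliers_applied(self, protocol):
        spec = CohortSimSpec(n_term=1, n_preterm=1, seed=4)
        subs, _ = simulate_cohort(spec, protocol)
        for s in subs:
            m = s.truth["multipliers"]["myocardium"]
            assert m == HYPOXIA_KI_MULTIPLIERS[(s.group, "myocardium")]

    def test_default_spillover_values(self):
        assert MYOCARDIUM_DEFAULTS.alpha == 0.2 and MYOCARDIUM_DEFAULTS.beta == 0.1
        assert SKELETAL_DEFAULTS.beta == 0.0
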