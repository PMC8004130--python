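"""Synthetic constant-infusion FDG study generator.

Emulates everything the target acquisition would provide: a priming-bolus
plus constant-infusion plasma input, per-tissue TACs obeying the two-tissue
compartment model with ROI spillover and frame-averaged sampling, serum
glucose/lactate tables, 4-D digital phantoms with resolution blur, and
term/preterm cohorts in which hypoxia scales the net influx rate Ki by a
programmed per-group multiplier at the gas switch (compartment contents are
continuous across the switch; the lever is k3, the phosphorylation rate).

Every generated object carries a ground-truth record so recovery tests can
compare fitted quantities against what was programmed.

Default study conditions
------------------------
* 60 one-minute frames; 21% O2 for 15 min then 12% O2 for 45 min.
* Input plateau from 10 mCi distributed in a nominal 5 L blood volume;
  bolus peak 25% of plateau.
* Myocardium K1=0.6, k2=1.2, k3=0.0235 (Ki ≈ 0.0115 mL/mL/min, i.e.
  MMRglc ≈ 0.04 μmol/mL/min at 90 mg/dL glucose), spillover α=0.2, β=0.1.
* Skeletal muscle K1=0.1, k2=0.3, k3=0.02, α=0.05, β=0.
* Hypoxia Ki multipliers: myocardium 0.60 (preterm) / 0.75 (term);
  skeletal muscle 0.48 (preterm) / 0.36 (term).
* Glucose 90 mg/dL rising during hypoxia to +5% (term) / +2% (preterm) at
  55 min; lactate 1.0 mmol/L rising +4% / +11%.
* Frame noise: Gaussian, SD = noise_cv × frame activity × sqrt(1 min /
  frame duration), noise_cv = 0.05.
* Subject-level kinetic parameters log-normal around the defaults, CV 20%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .io_protocol import (AcquisitionProtocol, DynamicImage, FrameTiming,
                          RoiMask, SerumSeries, ValidationError, write_serum,
                          write_tacs)
from .kinetic_model import (CompartmentParams, ParametricInput, ki,
                            roi_signals, tissue_curves)
from .tac_extraction import TimeActivityCurve

__all__ = [
    "MYOCARDIUM_DEFAULTS",
    "SKELETAL_DEFAULTS",
    "HYPOXIA_KI_MULTIPLIERS",
    "CohortSimSpec",
    "SubjectSimSpec",
    "PhantomSpec",
    "make_input_function",
    "simulate_subject_tacs",
    "build_phantom",
    "simulate_cohort",
]

KBQ_PER_MCI = 37_000.0

MYOCARDIUM_DEFAULTS = CompartmentParams(
    K1=0.6, k2=1.2, k3=0.0235, k4=0.0,
    sp_blood_to_tissue=0.2, sp_tissue_to_blood=0.1)

SKELETAL_DEFAULTS = CompartmentParams(
    K1=0.1, k2=0.3, k3=0.02, k4=0.0,
    sp_blood_to_tissue=0.05, sp_tissue_to_blood=0.0)

#: programmed hypoxia effect: Ki under hypoxia = multiplier × Ki at rest
HYPOXIA_KI_MULTIPLIERS = {
    ("preterm", "myocardium"): 0.60,
    ("term", "myocardium"): 0.75,
    ("preterm", "skeletal_muscle"): 0.48,
    ("term", "skeletal_muscle"): 0.36,
}

GLUCOSE_RISE = {"term": 0.05, "preterm": 0.02}
LACTATE_RISE = {"term": 0.04, "preterm": 0.11}
SPO2_NORMOXIA = {"term": 98.0, "preterm": 98.0}
SPO2_HYPOXIA = {"term": 85.0, "preterm": 81.0}


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectSimSpec:
    """Exact ground-truth description of one simulated subject."""

    subject_id: str
    group: str                        # term | preterm
    myo_params: CompartmentParams = MYOCARDIUM_DEFAULTS
    sk_params: CompartmentParams = SKELETAL_DEFAULTS
    myo_ki_multiplier: float = 0.60
    sk_ki_multiplier: float = 0.48
    glucose_baseline: float = 90.0    # mg/dL
    glucose_rise: float = 0.02        # fractional rise by 55 min of hypoxia
    lactate_baseline: float = 1.0     # mmol/L
    lactate_rise: float = 0.11
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("term", "preterm"):
            raise ValidationError(f"group must be term|preterm, got {self.group!r}")
        for name in ("myo_ki_multiplier", "sk_ki_multiplier"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


@dataclass(frozen=True)
class CohortSimSpec:
    """Cohort-level simulation conditions (study defaults throughout)."""

    n_term: int = 18
    n_preterm: int = 28
    seed: int = 0
    myo_params: CompartmentParams = MYOCARDIUM_DEFAULTS
    sk_params: CompartmentParams = SKELETAL_DEFAULTS
    param_cv: float = 0.20            # log-normal CV of subject K1,k2,k3
    noise_cv: float = 0.05
    glucose_baseline: float = 90.0
    hypoxia_ki_multipliers: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(HYPOXIA_KI_MULTIPLIERS))
    spo2_normoxia: Dict[str, float] = field(default_factory=lambda: dict(SPO2_NORMOXIA))
    spo2_hypoxia: Dict[str, float] = field(default_factory=lambda: dict(SPO2_HYPOXIA))
    spo2_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_term < 0 or self.n_preterm < 0 or self.n_term + self.n_preterm < 1:
            raise ValidationError("cohort must contain at least one subject")
        for key, m in self.hypoxia_ki_multipliers.items():
            if m <= 0:
                raise ValidationError(f"hypoxia multiplier for {key} must be > 0")
        if self.param_cv < 0 or self.noise_cv < 0:
            raise ValidationError("variability parameters must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Digital-phantom geometry: LV blood cylinder, concentric myocardial
    shell and two paraspinal-muscle blocks on a regular grid."""

    shape: Tuple[int, int, int] = (48, 48, 24)
    voxel_size_mm: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    blood_radius_vox: float = 5.0
    myo_inner_vox: float = 5.0
    myo_outer_vox: float = 13.0
    fwhm_mm: float = 0.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.myo_inner_vox < self.blood_radius_vox:
            raise ValidationError("myocardial shell must not overlap the blood cylinder")
        if self.myo_outer_vox <= self.myo_inner_vox:
            raise ValidationError("myocardial shell outer radius must exceed inner")
        if self.fwhm_mm < 0 or self.noise_cv < 0:
            raise ValidationError("fwhm and noise_cv must be >= 0")


# ---------------------------------------------------------------------------
# Input function
# ---------------------------------------------------------------------------

def make_input_function(
    protocol: AcquisitionProtocol,
    tau: float = 20.0,
    bolus_tau: float = 1.5,
    bolus_peak_fraction: float = 0.25,
    distribution_volume_l: float = 5.0,
) -> Tuple[ParametricInput, dict]:
    """Build the constant-infusion plasma curve and its truth record.

    The plateau is the injected activity diluted into a nominal blood
    distribution volume; the priming bolus appears as a transient whose
    peak is ``bolus_peak_fraction`` of the plateau.
    """
    plateau = protocol.total_activity * KBQ_PER_MCI / (distribution_volume_l * 1000.0)
    if plateau <= 0:
        raise ValidationError("input plateau must be positive")
    # D t e^{-t/lam} peaks at t=lam with value D lam / e
    bolus_amp = bolus_peak_fraction * plateau * np.e / bolus_tau
    inp = ParametricInput(plateau, tau, bolus_amp, bolus_tau)
    truth = {"plateau": plateau, "tau": tau, "bolus_amp": bolus_amp,
             "bolus_tau": bolus_tau, "bolus_peak_fraction": bolus_peak_fraction,
             "distribution_volume_l": distribution_volume_l}
    return inp, truth


# ---------------------------------------------------------------------------
# Subject TACs
# ---------------------------------------------------------------------------

def _split_timing(timing: FrameTiming, t_switch: float):
    pre = timing.frame_end <= t_switch + 1e-9
    post = timing.frame_start >= t_switch - 1e-9
    if np.any(~pre & ~post):
        raise ValidationError("a frame straddles the gas switch; adjust frame timing")
    return pre, post


def _condition_signals(params_n, params_h, inp, timing, t_switch):
    """Noise-free frame-averaged ROI signals across the switch, plus truth."""
    pre, post = _split_timing(timing, t_switch)
    m = np.empty(len(timing))
    b = np.empty(len(timing))
    timing_pre = FrameTiming(timing.frame_start[pre], timing.frame_duration[pre])
    m[pre], b[pre] = roi_signals(params_n, inp, timing_pre)
    state = np.clip(np.array(
        tissue_curves(params_n, inp, np.asarray([t_switch]))).ravel(), 0.0, None)
    timing_post = FrameTiming(timing.frame_start[post], timing.frame_duration[post])
    m[post], b[post] = roi_signals(params_h, inp, timing_post,
                                   t0=t_switch, initial_state=tuple(state))
    return m, b, state


def _add_noise(values, durations, noise_cv, rng):
    if noise_cv == 0:
        return values.copy()
    sd = noise_cv * np.abs(values) * np.sqrt(1.0 / np.asarray(durations))
    return values + rng.normal(0.0, 1.0, size=values.shape) * sd


def _serum_series(spec: SubjectSimSpec, protocol: AcquisitionProtocol) -> SerumSeries:
    # draws every 10 min plus the 55-min draw the protocol reports as the
    # hypoxia measurement
    t = np.unique(np.append(np.arange(0.0, protocol.scan_duration + 1e-9, 10.0),
                            min(55.0, protocol.scan_duration)))
    # flat until the gas switch, then a linear climb reaching the programmed
    # rise at the 55-min draw
    ramp = np.clip((t - protocol.gas_switch_time) / (55.0 - protocol.gas_switch_time), 0.0, None)
    glucose = spec.glucose_baseline * (1.0 + spec.glucose_rise * ramp)
    lactate = spec.lactate_baseline * (1.0 + spec.lactate_rise * ramp)
    return SerumSeries(t, glucose, lactate)


def simulate_subject_tacs(
    spec: SubjectSimSpec,
    protocol: Optional[AcquisitionProtocol] = None,
    timing: Optional[FrameTiming] = None,
):
    """Generate one subject's (myocardium, blood, skeletal) TACs + serum.

    Returns ``(tacs, serum, truth)`` where ``tacs`` maps ROI label to
    TimeActivityCurve and ``truth`` records every generated parameter,
    per-condition Ki and metabolic rate.
    """
    from .kinetic_model import (LC_MYOCARDIUM, LC_SKELETAL_MUSCLE,
                                metabolic_rate)

    protocol = protocol or AcquisitionProtocol()
    timing = timing or FrameTiming.uniform(int(round(protocol.scan_duration)), 1.0)
    rng = np.random.default_rng(spec.seed)
    inp, inp_truth = make_input_function(protocol)
    t_switch = protocol.gas_switch_time

    myo_n = spec.myo_params
    sk_n = spec.sk_params
    myo_h = myo_n.with_ki(spec.myo_ki_multiplier * ki(myo_n))
    sk_h = sk_n.with_ki(spec.sk_ki_multiplier * ki(sk_n))

    m, b, myo_state = _condition_signals(myo_n, myo_h, inp, timing, t_switch)
    s, _, sk_state = _condition_signals(sk_n, sk_h, inp, timing, t_switch)

    durs = timing.frame_duration
    tacs = {
        "myocardium": TimeActivityCurve("myocardium", timing.frame_mid, durs,
                                        _add_noise(m, durs, spec.noise_cv, rng), 100),
        "blood_pool": TimeActivityCurve("blood_pool", timing.frame_mid, durs,
                                        _add_noise(b, durs, spec.noise_cv, rng), 100),
        "skeletal_muscle": TimeActivityCurve("skeletal_muscle", timing.frame_mid, durs,
                                             _add_noise(s, durs, spec.noise_cv, rng), 100),
    }
    serum = _serum_series(spec, protocol)

    def truth_rates(tissue, pn, ph, lc):
        out = {}
        for cond, p, window in (("normoxia", pn, protocol.normoxia_fit_window),
                                ("hypoxia", ph, protocol.hypoxia_fit_window)):
            k = ki(p)
            out[cond] = {
                "params": {"K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4,
                           "alpha": p.alpha, "beta": p.beta},
                "Ki": k,
                "rate": metabolic_rate(k, serum, window, lc),
            }
        return out

    truth = {
        "subject_id": spec.subject_id,
        "group": spec.group,
        "seed": spec.seed,
        "noise_cv": spec.noise_cv,
        "input": inp_truth,
        "multipliers": {"myocardium": spec.myo_ki_multiplier,
                        "skeletal_muscle": spec.sk_ki_multiplier},
        "myocardium": truth_rates("myocardium", myo_n, myo_h, LC_MYOCARDIUM),
        "skeletal_muscle": truth_rates("skeletal_muscle", sk_n, sk_h, LC_SKELETAL_MUSCLE),
        "state_at_switch": {"myocardium": list(map(float, myo_state)),
                            "skeletal_muscle": list(map(float, sk_state))},
    }
    return tacs, serum, truth


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

def _phantom_regions(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    z = np.arange(nz)
    zin = (z >= 2) & (z < nz - 2)
    blood = (r <= spec.blood_radius_vox)[:, :, None] & zin[None, None, :]
    myo = ((r > spec.myo_inner_vox) & (r <= spec.myo_outer_vox))[:, :, None] & zin[None, None, :]
    # paraspinal blocks in the posterior corners
    bw = max(nx // 6, 4)
    sk = np.zeros(spec.shape, dtype=bool)
    sk[2:2 + bw, 2:2 + bw, 2:nz - 2] = True
    sk[nx - 2 - bw:nx - 2, 2:2 + bw, 2:nz - 2] = True
    regions = {"blood_pool": blood, "myocardium": myo, "skeletal_muscle": sk}
    overlap = sum(m.astype(int) for m in regions.values())
    if overlap.max() > 1:
        raise ValidationError("phantom regions overlap")
    return regions


def build_phantom(
    spec: PhantomSpec,
    protocol: Optional[AcquisitionProtocol] = None,
    subject: Optional[SubjectSimSpec] = None,
    timing: Optional[FrameTiming] = None,
):
    """Rasterise pure region curves into a 4-D volume with optional blur/noise.

    Region curves are the spillover-free tissue curves (blood region carries
    the plasma curve itself); resolution blur of the stated FWHM is what
    mixes adjacent regions.  Returns ``(DynamicImage, masks, truth)`` where
    ``truth['region_curves']`` holds each region's noise-free frame-averaged
    curve.
    """
    protocol = protocol or AcquisitionProtocol()
    subject = subject or SubjectSimSpec("phantom", "term", noise_cv=0.0, seed=spec.seed)
    timing = timing or FrameTiming.uniform(int(round(protocol.scan_duration)), 1.0)
    rng = np.random.default_rng(spec.seed)
    inp, _ = make_input_function(protocol)
    t_switch = protocol.gas_switch_time

    myo_n = replace(subject.myo_params, sp_blood_to_tissue=0.0, sp_tissue_to_blood=0.0)
    sk_n = replace(subject.sk_params, sp_blood_to_tissue=0.0, sp_tissue_to_blood=0.0)
    myo_h = myo_n.with_ki(subject.myo_ki_multiplier * ki(myo_n))
    sk_h = sk_n.with_ki(subject.sk_ki_multiplier * ki(sk_n))

    m_curve, b_curve, _ = _condition_signals(myo_n, myo_h, inp, timing, t_switch)
    s_curve, _, _ = _condition_signals(sk_n, sk_h, inp, timing, t_switch)
    curves = {"myocardium": m_curve, "blood_pool": b_curve, "skeletal_muscle": s_curve}

    regions = _phantom_regions(spec)
    data = np.zeros(spec.shape + (len(timing),), dtype=float)
    for name, region in regions.items():
        data[region] = curves[name]

    if spec.fwhm_mm > 0:
        sigma_vox = [spec.fwhm_mm / 2.354820045 / v for v in spec.voxel_size_mm]
        for f in range(data.shape[3]):
            data[..., f] = ndimage.gaussian_filter(data[..., f], sigma=sigma_vox)
    if spec.noise_cv > 0:
        sd = spec.noise_cv * np.abs(data) / np.sqrt(timing.frame_duration)
        data = data + rng.normal(0.0, 1.0, size=data.shape) * sd

    image = DynamicImage(data, spec.voxel_size_mm, timing)
    masks = [RoiMask(name, region) for name, region in regions.items()]
    truth = {
        "region_curves": {k: v.tolist() for k, v in curves.items()},
        "params": {"myocardium": {"normoxia": myo_n, "hypoxia": myo_h},
                   "skeletal_muscle": {"normoxia": sk_n, "hypoxia": sk_h}},
        "input": inp,
        "fwhm_mm": spec.fwhm_mm,
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
    }
    return image, masks, truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _lognormal_around(rng, mean: float, cv: float) -> float:
    if cv == 0 or mean == 0:
        return mean
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2.0
    return float(rng.lognormal(mu, sigma))


def _draw_params(rng, base: CompartmentParams, cv: float) -> CompartmentParams:
    return replace(base,
                   K1=_lognormal_around(rng, base.K1, cv),
                   k2=_lognormal_around(rng, base.k2, cv),
                   k3=_lognormal_around(rng, base.k3, cv))


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    group: str
    tacs: dict
    serum: SerumSeries
    spo2_normoxia: float
    spo2_hypoxia: float
    truth: dict


def simulate_cohort(
    spec: CohortSimSpec,
    protocol: Optional[AcquisitionProtocol] = None,
    out_dir=None,
) -> Tuple[List[SimulatedSubject], dict]:
    """Simulate a term/preterm cohort with programmed hypoxia effects.

    Subject kinetic parameters are drawn log-normally (CV ``param_cv``)
    around the tissue defaults; the group's Ki multipliers, glucose/lactate
    drifts and SpO2 profile are applied per subject.  With ``out_dir`` set,
    per-subject TAC and serum CSVs plus a truth-manifest JSON are written.
    """
    protocol = protocol or AcquisitionProtocol()
    root_rng = np.random.default_rng(spec.seed)
    subjects: List[SimulatedSubject] = []
    manifest = {"seed": spec.seed, "n_term": spec.n_term, "n_preterm": spec.n_preterm,
                "param_cv": spec.param_cv, "noise_cv": spec.noise_cv,
                "hypoxia_ki_multipliers": {f"{g}/{t}": v for (g, t), v
                                           in spec.hypoxia_ki_multipliers.items()},
                "subjects": []}
    groups = ["preterm"] * spec.n_preterm + ["term"] * spec.n_term
    for i, group in enumerate(groups):
        sub_seed = int(root_rng.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        sspec = SubjectSimSpec(
            subject_id=f"sub-{i + 1:03d}",
            group=group,
            myo_params=_draw_params(rng, spec.myo_params, spec.param_cv),
            sk_params=_draw_params(rng, spec.sk_params, spec.param_cv),
            myo_ki_multiplier=spec.hypoxia_ki_multipliers[(group, "myocardium")],
            sk_ki_multiplier=spec.hypoxia_ki_multipliers[(group, "skeletal_muscle")],
            glucose_baseline=spec.glucose_baseline,
            glucose_rise=GLUCOSE_RISE[group],
            lactate_rise=LACTATE_RISE[group],
            noise_cv=spec.noise_cv,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        tacs, serum, truth = simulate_subject_tacs(sspec, protocol)
        spo2_n = float(rng.normal(spec.spo2_normoxia[group], spec.spo2_sd / 4.0))
        spo2_h = float(rng.normal(spec.spo2_hypoxia[group], spec.spo2_sd))
        truth["spo2_normoxia"] = spo2_n
        truth["spo2_hypoxia"] = spo2_h
        subjects.append(SimulatedSubject(sspec.subject_id, group, tacs, serum,
                                         spo2_n, spo2_h, truth))
        manifest["subjects"].append(truth)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sub in subjects:
            d = out_dir / sub.subject_id
            d.mkdir(exist_ok=True)
            write_tacs(sub.tacs.values(), d / "tacs.csv")
            write_serum(sub.serum, d / "serum.csv")
        with open(out_dir / "truth_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return subjects, manifest
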