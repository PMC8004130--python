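"""Nonlinear least-squares estimation of compartment parameters.

Two fits per condition window:

1. A joint myocardium + blood-pool fit.  Because the measured blood-pool
   TAC is itself contaminated by myocardial spillover, the true plasma
   curve is a latent quantity: it is parameterised as a
   bolus-plus-saturating-plateau form ``A (1 - e^{-t/tau}) + D t e^{-t/lam}``
   and fitted alongside the kinetic rates and the two spillover fractions,
   minimising the pooled squared residuals of both measured ROI signals.
   The fitted parametric curve is the spillover-corrected blood estimate.
2. A skeletal-muscle fit driven by that corrected input, with spillover
   allowed only from blood into the muscle ROI (beta fixed at 0).

Optimisation is bounded local least squares (``scipy.optimize.least_squares``,
trust-region reflective) from a deterministic multistart: one data-driven
start, structured variants covering the k3 condition split, and
scrambled-Sobol points to 16 starts total, all screened by initial SSE with
the most promising polished.  Residuals are inverse-activity weighted by
default (approximate maximum likelihood for activity-proportional frame
noise), and two weak noise-scaled penalties stabilise the weakly-identified
efflux rate k2 (see FitOptions).  Best SSE wins; ties break toward the
smaller parameter norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from . import kinetic_model as _km
from .io_protocol import (AcquisitionProtocol, FitError, SerumSeries,
                          ValidationError)
from .kinetic_model import (LC_MYOCARDIUM, LC_SKELETAL_MUSCLE, _frame_integrals,
                            CompartmentParams, InputFunction, LumpedConstant,
                            ParametricInput, ki, metabolic_rate, roi_signals,
                            tissue_curves, window_average_glucose)
from .tac_extraction import TimeActivityCurve, window_tac

__all__ = [
    "FitOptions",
    "FitResult",
    "MetabolicRateResult",
    "fit_myocardium_blood",
    "fit_skeletal",
    "fit_conditions_myocardium_blood",
    "fit_conditions_skeletal",
    "fit_subject",
]

#: hard floor on usable frames — below this the fit refuses to run
MIN_FRAMES_GUARD = 6
#: frames required for the joint myocardium/blood fit (free params + 2)
MIN_FRAMES_JOINT = 8


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings; all defaults are the pipeline's standard run."""

    n_starts: int = 16
    n_polish: int = 4    # starts polished by the local optimiser, chosen by initial SSE
    seed: int = 0
    k4_free: bool = False
    ftol: float = 1e-10
    blood_weight: float = 1.0        # blood-residual block weight vs myocardium
    # per-frame residual weighting: "uniform" or "inverse_activity"
    # (approximate maximum likelihood for activity-proportional noise;
    # weights 1/max(|y|, floor) with a 5%-of-peak floor, normalised to mean 1)
    residual_weighting: str = "inverse_activity"
    # how the two condition windows are handled by fit_subject:
    #   joint        — one fit spanning both windows, per-condition k3,
    #                  shared transport/spillover/input (default)
    #   continuation — sequential per-window fits; hypoxia starts from the
    #                  normoxia model state at the gas switch
    #   independent  — per-window fits with free initial amplitudes
    condition_mode: str = "joint"
    # one-sided efflux barrier: a penalty residual
    # ridge_k2 * sigma_hat * min(0, ln(k2 / k2_floor)) that activates only for
    # k2 below the physiological floor, with sigma_hat the frame-noise level
    # estimated from the data.  Suppresses the k2 -> 0 trapping alias (free
    # compartment mimicking irreversible uptake) that is otherwise
    # statistically indistinguishable at realistic noise; exerts no pull on
    # fits with k2 above the floor and vanishes as noise -> 0, so exact
    # noiseless recovery is untouched.
    ridge_k2: float = 1.0
    k2_floor: float = 0.05           # 1/min, lower end of physiological FDG efflux
    # weak symmetric efflux prior: adds k2_prior * sigma_hat * ln(k2/k2_prior_center)
    # to the penalty residual.  Centres the weakly-identified efflux rate on a
    # typical FDG value, countering the shrinkage the latent-input/spillover
    # scale ridge otherwise induces on Ki; like the barrier it scales with the
    # estimated noise level, so noiseless fits are unaffected (0 disables).
    k2_prior: float = 0.5
    k2_prior_center: float = 0.5     # 1/min
    # kinetic bounds
    k1_bounds: Tuple[float, float] = (0.0, 2.0)
    k2_bounds: Tuple[float, float] = (1e-3, 5.0)
    k3_bounds: Tuple[float, float] = (0.0, 2.0)
    k4_bounds: Tuple[float, float] = (0.0, 0.1)
    spill_bounds: Tuple[float, float] = (0.0, 0.8)
    # latent-input bounds (amplitudes are scaled by the data level at fit time)
    tau_bounds: Tuple[float, float] = (1.0, 200.0)
    bolus_tau_bounds: Tuple[float, float] = (0.2, 10.0)

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        if self.condition_mode not in ("joint", "continuation", "independent"):
            raise ValidationError(f"unknown condition_mode {self.condition_mode!r}")
        if self.residual_weighting not in ("uniform", "inverse_activity"):
            raise ValidationError(
                f"unknown residual_weighting {self.residual_weighting!r}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one bounded least-squares fit."""

    params: CompartmentParams
    input_fn: Optional[ParametricInput]
    sse: float
    converged: bool
    n_starts_tried: int
    best_start_index: int
    residuals: np.ndarray
    corrected_blood: Optional[TimeActivityCurve]
    window: Tuple[float, float]
    t0: float
    initial_state: Tuple[float, float]
    seed: int
    all_start_sse: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        p = self.params
        d = {
            "params": {"K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4,
                       "sp_blood_to_tissue": p.sp_blood_to_tissue,
                       "sp_tissue_to_blood": p.sp_tissue_to_blood},
            "sse": self.sse,
            "converged": bool(self.converged),
            "n_starts_tried": self.n_starts_tried,
            "best_start_index": self.best_start_index,
            "residuals": list(map(float, np.asarray(self.residuals))),
            "window": list(self.window),
            "t0": self.t0,
            "initial_state": list(map(float, self.initial_state)),
            "seed": self.seed,
        }
        if self.input_fn is not None:
            d["input"] = {"plateau": self.input_fn.plateau, "tau": self.input_fn.tau,
                          "bolus_amp": self.input_fn.bolus_amp,
                          "bolus_tau": self.input_fn.bolus_tau}
        if self.corrected_blood is not None:
            cb = self.corrected_blood
            d["corrected_blood"] = {
                "frame_mid": list(map(float, cb.frame_mid)),
                "frame_duration": list(map(float, cb.frame_duration)),
                "activity": list(map(float, cb.activity)),
            }
        return d


@dataclass(frozen=True)
class MetabolicRateResult:
    """Per-tissue, per-condition net influx and glucose metabolic rate."""

    tissue: str
    condition: str
    ki: float
    rate: float                 # μmol/mL/min
    lc: LumpedConstant
    glucose_umol_ml: float
    fit: FitResult

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "condition": self.condition,
            "Ki": self.ki,
            "rate": self.rate,
            "LC": self.lc.value,
            "glucose_umol_ml": self.glucose_umol_ml,
            "fit": self.fit.to_dict(),
        }


# ---------------------------------------------------------------------------
# Shared multistart machinery
# ---------------------------------------------------------------------------

def _check_tac(tac: TimeActivityCurve, name: str, min_frames: int) -> None:
    n = len(tac)
    if n <= 5:
        raise FitError(
            f"{name}: only {n} frames in window — too few for a stable fit (need > 5)")
    if n < min_frames:
        raise FitError(f"{name}: {n} frames in window; at least {min_frames} required")
    if np.allclose(tac.activity, 0.0):
        raise FitError(f"{name}: TAC is identically zero — degenerate data")
    if not np.all(np.isfinite(tac.activity)):
        raise FitError(f"{name}: TAC contains non-finite values")


def _frame_weights(activity: np.ndarray, mode: str) -> np.ndarray:
    """Per-frame residual weights; mean-1 normalised.

    Inverse-activity weights are computed from a smoothed copy of the TAC:
    weighting by the raw noisy values would correlate the weights with the
    noise itself and shrink the fit downward.
    """
    if mode == "uniform":
        return np.ones_like(activity)
    from scipy.ndimage import uniform_filter1d
    ref = uniform_filter1d(np.abs(activity), size=5, mode="nearest")
    w = 1.0 / np.maximum(ref, 0.05 * np.max(ref))
    return w / w.mean()


def _noise_level(*activities) -> float:
    """Robust per-frame noise SD from second differences of the TACs."""
    mads = []
    for a in activities:
        if a.size < 4:
            continue
        d2 = np.diff(a, n=2)
        mads.append(np.median(np.abs(d2 - np.median(d2))) / 0.6745 / np.sqrt(6.0))
    return float(np.sqrt(np.mean(np.square(mads)))) if mads else 0.0


def _multistart(residual_fn, lb, ub, starts, ftol, n_polish=None):
    """Screen the start points by initial SSE, polish the most promising
    with bounded least squares, return the best solution.

    Fully deterministic: starts are generated from the seed, screened by a
    single residual evaluation each, and the ``n_polish`` best are
    optimised in a fixed order.
    """
    order = np.arange(len(starts))
    if n_polish is not None and n_polish < len(starts):
        init_sse = np.array([float(np.sum(residual_fn(np.clip(x, lb, ub)) ** 2))
                             for x in starts])
        order = np.argsort(init_sse, kind="stable")[:n_polish]
    best = None
    sses = np.full(len(starts), np.inf)
    x_scale = np.maximum((np.asarray(ub) - np.asarray(lb)) / 2.0, 1e-6)
    for i in order:
        x0 = starts[i]
        x0c = np.clip(x0, lb, ub)
        try:
            sol = optimize.least_squares(
                residual_fn, x0c, bounds=(lb, ub), method="trf",
                x_scale=x_scale, ftol=ftol, xtol=1e-9, gtol=None,
                max_nfev=300 * len(x0c))
        except Exception:
            continue
        sse = 2.0 * sol.cost
        sses[i] = sse
        if best is None:
            best = (sse, i, sol)
            continue
        tie = np.isclose(sse, best[0], rtol=1e-12, atol=1e-300)
        if (not tie and sse < best[0]) or \
                (tie and np.linalg.norm(sol.x) < np.linalg.norm(best[2].x)):
            best = (sse, i, sol)
    if best is None:
        raise FitError("all optimiser starts failed; data may be degenerate")
    return best, sses


def _sobol_starts(lb, ub, n_starts, seed, heuristic=None):
    d = len(lb)
    n_sobol = n_starts - (1 if heuristic is not None else 0)
    starts = []
    if heuristic is not None:
        starts.append(np.asarray(heuristic, dtype=float))
    if n_sobol > 0:
        m = int(np.ceil(np.log2(max(n_sobol, 1))))
        sob = qmc.Sobol(d, scramble=True, seed=seed).random_base2(max(m, 0))[:n_sobol]
        starts.extend(lb + sob * (np.asarray(ub) - np.asarray(lb)))
    return starts


# ---------------------------------------------------------------------------
# Joint myocardium + blood-pool fit
# ---------------------------------------------------------------------------

def fit_myocardium_blood(
    myo_tac: TimeActivityCurve,
    blood_tac: TimeActivityCurve,
    window=None,
    options: Optional[FitOptions] = None,
    t0: float = 0.0,
    initial_state=(0.0, 0.0),
) -> FitResult:
    """Jointly fit myocardial kinetics, bidirectional spillover and the
    latent plasma input to the measured myocardium and blood-pool TACs.

    ``t0``/``initial_state`` continue the compartments from an earlier
    window (the tracer accumulated before a protocol change is carried
    forward rather than discarded).
    """
    opts = options or FitOptions()
    if window is not None:
        myo_tac = window_tac(myo_tac, window)
        blood_tac = window_tac(blood_tac, window)
    else:
        window = (float(myo_tac.frame_start[0]), float(myo_tac.frame_end[-1]))
    _check_tac(myo_tac, "myocardium TAC", MIN_FRAMES_JOINT)
    _check_tac(blood_tac, "blood-pool TAC", MIN_FRAMES_JOINT)
    if len(myo_tac) != len(blood_tac) or not np.allclose(myo_tac.frame_mid, blood_tac.frame_mid):
        raise FitError("myocardium and blood TACs must share frame timing")

    timing = myo_tac.timing()
    scale = float(np.max(blood_tac.activity))
    y = np.concatenate([myo_tac.activity, opts.blood_weight * blood_tac.activity])
    n_data = y.size
    w_m = _frame_weights(myo_tac.activity, opts.residual_weighting)
    w_b = _frame_weights(blood_tac.activity, opts.residual_weighting)
    sigma_hat = _noise_level(myo_tac.activity, blood_tac.activity)
    pen_w = opts.ridge_k2 * sigma_hat

    free_state = opts.condition_mode == "independent" and (t0 > 0 or np.any(np.asarray(initial_state) > 0))
    if free_state:
        # refit from the window start with free initial compartment contents
        t0 = float(window[0])

    k4f = opts.k4_free
    names = ["K1", "k2", "k3"] + (["k4"] if k4f else []) + \
        ["alpha", "beta", "A", "tau", "D", "lam_b"] + \
        (["ce0", "cm0"] if free_state else [])
    lb, ub = _joint_bounds(opts, scale, k4f, free_state)

    def unpack(x):
        i = 0
        K1, k2, k3 = x[0], x[1], x[2]
        i = 3
        k4 = x[i] if k4f else 0.0
        i += 1 if k4f else 0
        alpha, beta = x[i], x[i + 1]
        A, tau, D, lam_b = x[i + 2:i + 6]
        state = tuple(x[i + 6:i + 8]) if free_state else tuple(initial_state)
        return (CompartmentParams(K1, k2, k3, k4, alpha, beta),
                ParametricInput(A, tau, D, lam_b), state)

    starts_arr = timing.frame_start
    durs_arr = timing.frame_duration
    ends_arr = starts_arr + durs_arr
    i_sp = 4 if k4f else 3

    def residual(x):
        # bounds guarantee parameter validity; go straight to the kernel
        k4 = x[3] if k4f else 0.0
        alpha, beta = x[i_sp], x[i_sp + 1]
        inp = ParametricInput(x[i_sp + 2], x[i_sp + 3], x[i_sp + 4], x[i_sp + 5])
        state = tuple(x[i_sp + 6:i_sp + 8]) if free_state else tuple(initial_state)
        try:
            ce, cm, cp = _frame_integrals(x[0], x[1], x[2], k4, inp,
                                          starts_arr, ends_arr, durs_arr, t0, state)
        except (ValidationError, FloatingPointError):
            return np.full(n_data + 1, 1e6)
        ct = ce + cm
        m = (1.0 - alpha) * ct + alpha * cp
        b = (1.0 - beta) * cp + beta * ct
        r = np.concatenate([w_m * (m - myo_tac.activity),
                            opts.blood_weight * w_b * (b - blood_tac.activity),
                            [pen_w * min(0.0, np.log(x[1] / opts.k2_floor))
                             + opts.k2_prior * sigma_hat * np.log(x[1] / opts.k2_prior_center)]])
        return np.where(np.isfinite(r), r, 1e6)

    heuristic = _joint_heuristic(blood_tac, scale, k4f, free_state, lb, ub)
    starts = _sobol_starts(lb, ub, opts.n_starts, opts.seed, heuristic)
    (obj, best_i, sol), sses = _multistart(residual, lb, ub, starts, opts.ftol, opts.n_polish)
    params, inp, state = unpack(sol.x)
    sse = float(np.sum(sol.fun[:n_data] ** 2))

    # spillover-corrected blood estimate at the fitted frames
    starts_t = timing.frame_start
    ends_t = timing.frame_end
    cp_avg = (inp.cumint(ends_t) - inp.cumint(starts_t)) / timing.frame_duration
    corrected = TimeActivityCurve("blood_pool", timing.frame_mid,
                                  timing.frame_duration, cp_avg,
                                  blood_tac.n_voxels)
    return FitResult(
        params=params, input_fn=inp, sse=float(sse), converged=bool(sol.success),
        n_starts_tried=len(starts), best_start_index=int(best_i),
        residuals=sol.fun[:n_data].copy(), corrected_blood=corrected,
        window=(float(window[0]), float(window[1])), t0=float(t0),
        initial_state=tuple(map(float, state)), seed=opts.seed,
        all_start_sse=sses)


def _joint_bounds(opts: FitOptions, scale: float, k4f: bool, free_state: bool):
    lb = [opts.k1_bounds[0], opts.k2_bounds[0], opts.k3_bounds[0]]
    ub = [opts.k1_bounds[1], opts.k2_bounds[1], opts.k3_bounds[1]]
    if k4f:
        lb.append(opts.k4_bounds[0]); ub.append(opts.k4_bounds[1])
    lb += [opts.spill_bounds[0]] * 2
    ub += [opts.spill_bounds[1]] * 2
    lb += [1e-3 * scale, opts.tau_bounds[0], 0.0, opts.bolus_tau_bounds[0]]
    ub += [5.0 * scale, opts.tau_bounds[1], 10.0 * scale, opts.bolus_tau_bounds[1]]
    if free_state:
        lb += [0.0, 0.0]
        ub += [5.0 * scale, 5.0 * scale]
    return np.asarray(lb), np.asarray(ub)


def _joint_heuristic(blood_tac, scale, k4f, free_state, lb, ub):
    """Data-driven first start: plateau near the late blood level."""
    late = float(np.mean(blood_tac.activity[-max(3, len(blood_tac) // 4):]))
    x = [0.3, 0.6, 0.05] + ([0.01] if k4f else []) + \
        [0.15, 0.1, max(late, 1e-2 * scale), 20.0, 0.1 * scale, 1.5] + \
        ([0.0, 0.0] if free_state else [])
    return np.clip(np.asarray(x, dtype=float), lb, ub)


# ---------------------------------------------------------------------------
# Skeletal-muscle fit
# ---------------------------------------------------------------------------

def fit_skeletal(
    sk_tac: TimeActivityCurve,
    corrected_blood,
    window=None,
    options: Optional[FitOptions] = None,
    t0: float = 0.0,
    initial_state=(0.0, 0.0),
) -> FitResult:
    """Fit skeletal-muscle kinetics with the input fixed to the
    spillover-corrected blood curve from a converged myocardium fit.

    Spillover runs only from blood into the muscle ROI (``beta`` = 0).
    ``corrected_blood`` may be the myocardium FitResult (its fitted
    parametric input is used directly), an InputFunction, or a corrected
    blood TAC (interpolated piecewise-linearly).
    """
    opts = options or FitOptions()
    input_fn = _resolve_input(corrected_blood)
    if window is not None:
        sk_tac = window_tac(sk_tac, window)
    else:
        window = (float(sk_tac.frame_start[0]), float(sk_tac.frame_end[-1]))
    _check_tac(sk_tac, "skeletal-muscle TAC", MIN_FRAMES_GUARD)
    timing = sk_tac.timing()
    scale = max(float(np.max(sk_tac.activity)), 1e-12)
    n_data = len(sk_tac)
    w_s = _frame_weights(sk_tac.activity, opts.residual_weighting)
    sigma_hat = _noise_level(sk_tac.activity)
    pen_w = opts.ridge_k2 * sigma_hat

    free_state = opts.condition_mode == "independent" and (t0 > 0 or np.any(np.asarray(initial_state) > 0))
    if free_state:
        t0 = float(window[0])
    k4f = opts.k4_free
    lb = [opts.k1_bounds[0], opts.k2_bounds[0], opts.k3_bounds[0]]
    ub = [opts.k1_bounds[1], opts.k2_bounds[1], opts.k3_bounds[1]]
    if k4f:
        lb.append(opts.k4_bounds[0]); ub.append(opts.k4_bounds[1])
    lb.append(opts.spill_bounds[0]); ub.append(opts.spill_bounds[1])
    if free_state:
        lb += [0.0, 0.0]; ub += [5.0 * scale] * 2
    lb, ub = np.asarray(lb), np.asarray(ub)

    def unpack(x):
        k4 = x[3] if k4f else 0.0
        i = 4 if k4f else 3
        alpha = x[i]
        state = tuple(x[i + 1:i + 3]) if free_state else tuple(initial_state)
        return CompartmentParams(x[0], x[1], x[2], k4, alpha, 0.0), state

    starts_arr = timing.frame_start
    durs_arr = timing.frame_duration
    ends_arr = starts_arr + durs_arr
    i_sp = 4 if k4f else 3

    def residual(x):
        k4 = x[3] if k4f else 0.0
        state = tuple(x[i_sp + 1:i_sp + 3]) if free_state else tuple(initial_state)
        try:
            ce, cm, cp = _frame_integrals(x[0], x[1], x[2], k4, input_fn,
                                          starts_arr, ends_arr, durs_arr, t0, state)
        except (ValidationError, FloatingPointError):
            return np.full(n_data + 1, 1e6)
        m = (1.0 - x[i_sp]) * (ce + cm) + x[i_sp] * cp
        r = np.concatenate([w_s * (m - sk_tac.activity),
                            [pen_w * min(0.0, np.log(x[1] / opts.k2_floor))
                             + opts.k2_prior * sigma_hat * np.log(x[1] / opts.k2_prior_center)]])
        return np.where(np.isfinite(r), r, 1e6)

    heuristic = np.clip(np.asarray(
        [0.1, 0.3, 0.02] + ([0.005] if k4f else []) + [0.05] +
        ([0.0, 0.0] if free_state else []), dtype=float), lb, ub)
    starts = _sobol_starts(lb, ub, opts.n_starts, opts.seed, heuristic)
    (obj, best_i, sol), sses = _multistart(residual, lb, ub, starts, opts.ftol, opts.n_polish)
    params, state = unpack(sol.x)
    sse = float(np.sum(sol.fun[:n_data] ** 2))
    return FitResult(
        params=params, input_fn=input_fn if isinstance(input_fn, ParametricInput) else None,
        sse=float(sse), converged=bool(sol.success),
        n_starts_tried=len(starts), best_start_index=int(best_i),
        residuals=sol.fun[:n_data].copy(), corrected_blood=None,
        window=(float(window[0]), float(window[1])), t0=float(t0),
        initial_state=tuple(map(float, state)), seed=opts.seed,
        all_start_sse=sses)


def _resolve_input(corrected_blood) -> InputFunction:
    from .kinetic_model import SampledInput

    if corrected_blood is None:
        raise FitError(
            "corrected blood input missing: run the myocardium/blood joint fit first")
    if isinstance(corrected_blood, FitResult):
        if not corrected_blood.converged:
            raise FitError("myocardium fit did not converge; corrected blood input unusable")
        if corrected_blood.input_fn is None:
            raise FitError("myocardium fit carries no input-function estimate")
        return corrected_blood.input_fn
    if isinstance(corrected_blood, InputFunction):
        return corrected_blood
    if isinstance(corrected_blood, TimeActivityCurve):
        return SampledInput(corrected_blood.frame_mid, corrected_blood.activity)
    raise FitError(f"cannot use {type(corrected_blood).__name__} as a blood input")


# ---------------------------------------------------------------------------
# Two-condition joint fits (default subject-level strategy)
# ---------------------------------------------------------------------------

def _state_at_switch(K1, k2, k3, k4, input_fn, t_switch):
    """Instantaneous (Ce, Cm) at the gas switch for tracer started empty at 0."""
    a1, a2 = _km._eigenrates(k2, k3, k4)
    t = np.asarray([t_switch], dtype=float)
    E1 = input_fn.expconv(a1, t) if a1 > 0 else input_fn.cumint(t)
    E2 = input_fn.expconv(a2, t) if a2 > 0 else input_fn.cumint(t)
    denom = max(a1 - a2, 1e-12)
    ce = K1 * ((a1 - k4) * E1 + (k4 - a2) * E2) / denom
    cm = K1 * k3 * (E2 - E1) / denom
    return float(max(ce[0], 0.0)), float(max(cm[0], 0.0))


def fit_conditions_myocardium_blood(
    myo_tac: TimeActivityCurve,
    blood_tac: TimeActivityCurve,
    protocol: AcquisitionProtocol,
    options: Optional[FitOptions] = None,
) -> Tuple[FitResult, FitResult]:
    """Joint two-condition myocardium/blood fit over both protocol windows.

    One model spans the whole scan: transport (K1, k2), spillover (alpha,
    beta) and the latent input are shared across conditions, while the
    phosphorylation rate k3 takes a separate value before and after the gas
    switch; compartment contents are continuous across the switch.  Fitting
    both condition windows simultaneously anchors the shared parameters
    with the full curve, which the short pre-switch window alone cannot do
    at realistic noise.

    Returns ``(normoxia FitResult, hypoxia FitResult)``; both carry the
    shared input estimate.
    """
    opts = options or FitOptions()
    win_n = protocol.normoxia_fit_window
    win_h = protocol.hypoxia_fit_window
    t_switch = protocol.gas_switch_time
    seg_h = (t_switch, win_h[1])   # fit every frame from the switch on
    myo_n, myo_h = window_tac(myo_tac, win_n), window_tac(myo_tac, seg_h)
    blood_n, blood_h = window_tac(blood_tac, win_n), window_tac(blood_tac, seg_h)
    _check_tac(myo_n, "myocardium TAC (normoxia)", MIN_FRAMES_JOINT)
    _check_tac(myo_h, "myocardium TAC (hypoxia)", MIN_FRAMES_JOINT)
    _check_tac(blood_n, "blood-pool TAC (normoxia)", MIN_FRAMES_JOINT)
    _check_tac(blood_h, "blood-pool TAC (hypoxia)", MIN_FRAMES_JOINT)

    scale = float(max(np.max(blood_n.activity), np.max(blood_h.activity)))
    sigma_hat = _noise_level(myo_n.activity, myo_h.activity,
                             blood_n.activity, blood_h.activity)
    pen_w = opts.ridge_k2 * sigma_hat
    w = opts.blood_weight
    k4f = opts.k4_free

    # parameter vector: K1, k2, k3_normoxia, k3_hypoxia, [k4], alpha, beta,
    # plateau, tau, bolus_amp, bolus_tau
    lb = [opts.k1_bounds[0], opts.k2_bounds[0], opts.k3_bounds[0], opts.k3_bounds[0]]
    ub = [opts.k1_bounds[1], opts.k2_bounds[1], opts.k3_bounds[1], opts.k3_bounds[1]]
    if k4f:
        lb.append(opts.k4_bounds[0]); ub.append(opts.k4_bounds[1])
    lb += [opts.spill_bounds[0]] * 2 + [1e-3 * scale, opts.tau_bounds[0], 0.0,
                                        opts.bolus_tau_bounds[0]]
    ub += [opts.spill_bounds[1]] * 2 + [5.0 * scale, opts.tau_bounds[1],
                                        10.0 * scale, opts.bolus_tau_bounds[1]]
    lb, ub = np.asarray(lb), np.asarray(ub)
    i_sp = 5 if k4f else 4

    sn, dn = myo_n.frame_start, myo_n.frame_duration
    sh, dh = myo_h.frame_start, myo_h.frame_duration
    en, eh = sn + dn, sh + dh
    y = np.concatenate([myo_n.activity, myo_h.activity,
                        w * blood_n.activity, w * blood_h.activity])
    n_data = y.size
    w_mn = _frame_weights(myo_n.activity, opts.residual_weighting)
    w_mh = _frame_weights(myo_h.activity, opts.residual_weighting)
    w_bn = _frame_weights(blood_n.activity, opts.residual_weighting)
    w_bh = _frame_weights(blood_h.activity, opts.residual_weighting)

    def segments(x):
        K1, k2, k3n, k3h = x[0], x[1], x[2], x[3]
        k4 = x[4] if k4f else 0.0
        inp = ParametricInput(x[i_sp + 2], x[i_sp + 3], x[i_sp + 4], x[i_sp + 5])
        state = _state_at_switch(K1, k2, k3n, k4, inp, t_switch)
        ce_n, cm_n, cp_n = _frame_integrals(K1, k2, k3n, k4, inp, sn, en, dn,
                                            0.0, (0.0, 0.0))
        ce_h, cm_h, cp_h = _frame_integrals(K1, k2, k3h, k4, inp, sh, eh, dh,
                                            t_switch, state)
        return inp, state, (ce_n + cm_n, cp_n), (ce_h + cm_h, cp_h)

    def residual(x):
        alpha, beta = x[i_sp], x[i_sp + 1]
        try:
            _, _, (ct_n, cp_n), (ct_h, cp_h) = segments(x)
        except (ValidationError, FloatingPointError):
            return np.full(n_data + 1, 1e6)
        r = np.concatenate([
            w_mn * ((1 - alpha) * ct_n + alpha * cp_n - myo_n.activity),
            w_mh * ((1 - alpha) * ct_h + alpha * cp_h - myo_h.activity),
            w * w_bn * ((1 - beta) * cp_n + beta * ct_n - blood_n.activity),
            w * w_bh * ((1 - beta) * cp_h + beta * ct_h - blood_h.activity),
            [pen_w * min(0.0, np.log(x[1] / opts.k2_floor))
                             + opts.k2_prior * sigma_hat * np.log(x[1] / opts.k2_prior_center)]])
        return np.where(np.isfinite(r), r, 1e6)

    late = float(np.mean(blood_h.activity[-max(3, len(blood_h) // 4):]))
    heuristic = np.clip(np.asarray(
        [0.3, 0.6, 0.05, 0.05] + ([0.01] if k4f else []) +
        [0.15, 0.1, max(late, 1e-2 * scale), 20.0, 0.1 * scale, 1.5]), lb, ub)
    # structured variants covering the k3 normoxia/hypoxia split, so the
    # interior basin is always among the screened starts
    variants = []
    for k3n, k3h in ((0.005, 0.003), (0.02, 0.012), (0.1, 0.06)):
        v = heuristic.copy()
        v[2], v[3] = k3n, k3h
        variants.append(np.clip(v, lb, ub))
    n_sobol = max(opts.n_starts - 1 - len(variants), 0)
    starts = ([heuristic] + variants +
              _sobol_starts(lb, ub, n_sobol, opts.seed, None))
    (obj, best_i, sol), sses = _multistart(residual, lb, ub, starts, opts.ftol,
                                           opts.n_polish)
    x = sol.x
    k4 = x[4] if k4f else 0.0
    alpha, beta = x[i_sp], x[i_sp + 1]
    params_n = CompartmentParams(x[0], x[1], x[2], k4, alpha, beta)
    params_h = CompartmentParams(x[0], x[1], x[3], k4, alpha, beta)
    inp, state, _, _ = segments(x)

    nn, nh = len(myo_n), len(myo_h)
    res = sol.fun[:n_data]
    res_n = np.concatenate([res[:nn], res[nn + nh:nn + nh + nn]])
    res_h = np.concatenate([res[nn:nn + nh], res[nn + nh + nn:]])

    def corrected(tac):
        cp = (inp.cumint(tac.frame_end) - inp.cumint(tac.frame_start)) / tac.frame_duration
        return TimeActivityCurve("blood_pool", tac.frame_mid, tac.frame_duration,
                                 cp, tac.n_voxels)

    common = dict(input_fn=inp, converged=bool(sol.success),
                  n_starts_tried=len(starts), best_start_index=int(best_i),
                  seed=opts.seed, all_start_sse=sses)
    fit_n = FitResult(params=params_n, sse=float(np.sum(res_n**2)),
                      residuals=res_n, corrected_blood=corrected(blood_n),
                      window=(float(win_n[0]), float(win_n[1])), t0=0.0,
                      initial_state=(0.0, 0.0), **common)
    fit_h = FitResult(params=params_h, sse=float(np.sum(res_h**2)),
                      residuals=res_h, corrected_blood=corrected(blood_h),
                      window=(float(win_h[0]), float(win_h[1])), t0=float(t_switch),
                      initial_state=state, **common)
    return fit_n, fit_h


def fit_conditions_skeletal(
    sk_tac: TimeActivityCurve,
    corrected_blood,
    protocol: AcquisitionProtocol,
    options: Optional[FitOptions] = None,
) -> Tuple[FitResult, FitResult]:
    """Two-condition skeletal-muscle fit with the input fixed to the
    spillover-corrected blood curve; k3 is per-condition, the rest shared,
    compartments continuous across the gas switch."""
    opts = options or FitOptions()
    input_fn = _resolve_input(corrected_blood)
    win_n = protocol.normoxia_fit_window
    win_h = protocol.hypoxia_fit_window
    t_switch = protocol.gas_switch_time
    seg_h = (t_switch, win_h[1])
    sk_n, sk_h = window_tac(sk_tac, win_n), window_tac(sk_tac, seg_h)
    _check_tac(sk_n, "skeletal-muscle TAC (normoxia)", MIN_FRAMES_GUARD)
    _check_tac(sk_h, "skeletal-muscle TAC (hypoxia)", MIN_FRAMES_GUARD)
    sigma_hat = _noise_level(sk_n.activity, sk_h.activity)
    pen_w = opts.ridge_k2 * sigma_hat
    k4f = opts.k4_free

    lb = [opts.k1_bounds[0], opts.k2_bounds[0], opts.k3_bounds[0], opts.k3_bounds[0]]
    ub = [opts.k1_bounds[1], opts.k2_bounds[1], opts.k3_bounds[1], opts.k3_bounds[1]]
    if k4f:
        lb.append(opts.k4_bounds[0]); ub.append(opts.k4_bounds[1])
    lb.append(opts.spill_bounds[0]); ub.append(opts.spill_bounds[1])
    lb, ub = np.asarray(lb), np.asarray(ub)
    i_sp = 5 if k4f else 4

    sn, dn = sk_n.frame_start, sk_n.frame_duration
    sh, dh = sk_h.frame_start, sk_h.frame_duration
    en, eh = sn + dn, sh + dh
    n_data = len(sk_n) + len(sk_h)
    w_sn = _frame_weights(sk_n.activity, opts.residual_weighting)
    w_sh = _frame_weights(sk_h.activity, opts.residual_weighting)

    def residual(x):
        K1, k2, k3n, k3h = x[0], x[1], x[2], x[3]
        k4 = x[4] if k4f else 0.0
        alpha = x[i_sp]
        try:
            state = _state_at_switch(K1, k2, k3n, k4, input_fn, t_switch)
            ce_n, cm_n, cp_n = _frame_integrals(K1, k2, k3n, k4, input_fn,
                                                sn, en, dn, 0.0, (0.0, 0.0))
            ce_h, cm_h, cp_h = _frame_integrals(K1, k2, k3h, k4, input_fn,
                                                sh, eh, dh, t_switch, state)
        except (ValidationError, FloatingPointError):
            return np.full(n_data + 1, 1e6)
        r = np.concatenate([
            w_sn * ((1 - alpha) * (ce_n + cm_n) + alpha * cp_n - sk_n.activity),
            w_sh * ((1 - alpha) * (ce_h + cm_h) + alpha * cp_h - sk_h.activity),
            [pen_w * min(0.0, np.log(x[1] / opts.k2_floor))
                             + opts.k2_prior * sigma_hat * np.log(x[1] / opts.k2_prior_center)]])
        return np.where(np.isfinite(r), r, 1e6)

    heuristic = np.clip(np.asarray(
        [0.1, 0.3, 0.02, 0.02] + ([0.005] if k4f else []) + [0.05]), lb, ub)
    variants = []
    for k3n, k3h in ((0.004, 0.002), (0.01, 0.006), (0.06, 0.03)):
        v = heuristic.copy()
        v[2], v[3] = k3n, k3h
        variants.append(np.clip(v, lb, ub))
    n_sobol = max(opts.n_starts - 1 - len(variants), 0)
    starts = ([heuristic] + variants +
              _sobol_starts(lb, ub, n_sobol, opts.seed, None))
    (obj, best_i, sol), sses = _multistart(residual, lb, ub, starts, opts.ftol,
                                           opts.n_polish)
    x = sol.x
    k4 = x[4] if k4f else 0.0
    params_n = CompartmentParams(x[0], x[1], x[2], k4, x[i_sp], 0.0)
    params_h = CompartmentParams(x[0], x[1], x[3], k4, x[i_sp], 0.0)
    state = _state_at_switch(x[0], x[1], x[2], k4, input_fn, t_switch)
    nn = len(sk_n)
    res = sol.fun[:n_data]
    inp_store = input_fn if isinstance(input_fn, ParametricInput) else None
    common = dict(input_fn=inp_store, converged=bool(sol.success),
                  n_starts_tried=len(starts), best_start_index=int(best_i),
                  corrected_blood=None, seed=opts.seed, all_start_sse=sses)
    fit_n = FitResult(params=params_n, sse=float(np.sum(res[:nn]**2)),
                      residuals=res[:nn],
                      window=(float(win_n[0]), float(win_n[1])), t0=0.0,
                      initial_state=(0.0, 0.0), **common)
    fit_h = FitResult(params=params_h, sse=float(np.sum(res[nn:]**2)),
                      residuals=res[nn:],
                      window=(float(win_h[0]), float(win_h[1])), t0=float(t_switch),
                      initial_state=state, **common)
    return fit_n, fit_h


# ---------------------------------------------------------------------------
# Whole-subject orchestration
# ---------------------------------------------------------------------------

def fit_subject(
    tacs: Dict[str, TimeActivityCurve],
    serum: SerumSeries,
    protocol: AcquisitionProtocol,
    options: Optional[FitOptions] = None,
) -> List[MetabolicRateResult]:
    """Run the full per-subject analysis: joint myocardium/blood and
    skeletal fits in each condition window, then Ki → metabolic rate.

    Returns 4 results (myocardium/skeletal_muscle x normoxia/hypoxia).
    By default both condition windows are fitted jointly with shared
    transport, spillover and input and a per-condition phosphorylation
    rate (``options.condition_mode`` selects the sequential or independent
    per-window alternatives); in every mode the tracer accumulated before
    the gas switch is carried across it unless 'independent' is chosen.
    """
    opts = options or FitOptions()
    for roi in ("myocardium", "blood_pool", "skeletal_muscle"):
        if roi not in tacs:
            raise FitError(f"missing TAC for ROI {roi!r}")
    myo, blood, skel = tacs["myocardium"], tacs["blood_pool"], tacs["skeletal_muscle"]
    t_switch = protocol.gas_switch_time
    results: List[MetabolicRateResult] = []

    def rate_result(tissue, condition, fit, window, lc):
        from .kinetic_model import MG_DL_PER_UMOL_ML
        k = ki(fit.params)
        glc = window_average_glucose(serum, window) / MG_DL_PER_UMOL_ML
        rate = metabolic_rate(k, serum, window, lc)
        return MetabolicRateResult(tissue, condition, k, rate, lc, glc, fit)

    if opts.condition_mode == "joint":
        try:
            myo_n, myo_h = fit_conditions_myocardium_blood(myo, blood, protocol, opts)
        except (FitError, ValidationError) as e:
            raise FitError(f"myocardium: {e}") from e
        try:
            sk_n, sk_h = fit_conditions_skeletal(skel, myo_n, protocol, opts)
        except (FitError, ValidationError) as e:
            raise FitError(f"skeletal_muscle: {e}") from e
    else:
        try:
            myo_n = fit_myocardium_blood(myo, blood, protocol.normoxia_fit_window, opts)
        except FitError as e:
            raise FitError(f"myocardium/normoxia: {e}") from e
        state_myo = tuple(np.clip(
            np.array(tissue_curves(myo_n.params, myo_n.input_fn, np.asarray([t_switch]))).ravel(),
            0.0, None))
        try:
            myo_h = fit_myocardium_blood(myo, blood, protocol.hypoxia_fit_window, opts,
                                         t0=t_switch, initial_state=state_myo)
        except FitError as e:
            raise FitError(f"myocardium/hypoxia: {e}") from e

        try:
            sk_n = fit_skeletal(skel, myo_n, protocol.normoxia_fit_window, opts)
        except FitError as e:
            raise FitError(f"skeletal_muscle/normoxia: {e}") from e
        state_sk = tuple(np.clip(
            np.array(tissue_curves(sk_n.params, myo_n.input_fn, np.asarray([t_switch]))).ravel(),
            0.0, None))
        try:
            sk_h = fit_skeletal(skel, myo_h, protocol.hypoxia_fit_window, opts,
                                t0=t_switch, initial_state=state_sk)
        except FitError as e:
            raise FitError(f"skeletal_muscle/hypoxia: {e}") from e

    results.append(rate_result("myocardium", "normoxia", myo_n,
                               protocol.normoxia_fit_window, LC_MYOCARDIUM))
    results.append(rate_result("myocardium", "hypoxia", myo_h,
                               protocol.hypoxia_fit_window, LC_MYOCARDIUM))
    results.append(rate_result("skeletal_muscle", "normoxia", sk_n,
                               protocol.normoxia_fit_window, LC_SKELETAL_MUSCLE))
    results.append(rate_result("skeletal_muscle", "hypoxia", sk_h,
                               protocol.hypoxia_fit_window, LC_SKELETAL_MUSCLE))
    return results
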