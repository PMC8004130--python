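"""Irreversible/reversible two-tissue (3-compartment) FDG kinetics.

The model tracks tracer in plasma (``Cp``, the input function), free tissue
FDG (``Ce``) and phosphorylated FDG-6-P (``Cm``)::

    dCe/dt = K1*Cp(t) - (k2 + k3)*Ce + k4*Cm
    dCm/dt = k3*Ce - k4*Cm

All concentrations are kBq/mL and all times minutes.  The linear system is
solved semi-analytically: the matrix exponential is diagonalised in closed
form and the particular solution reduces to exponential convolutions of the
input, which both supported input representations (parametric
bolus-plus-plateau and piecewise-linear sampled curves) evaluate exactly.
This keeps a single forward-model evaluation cheap enough for
multistart nonlinear least squares while remaining accurate to machine
precision for the supported input families.

ROI-level signals add spillover mixing between the myocardium and blood-pool
regions: the myocardial ROI sees ``(1-alpha)*Ct + alpha*Cp`` and the blood
ROI sees ``(1-beta)*Cp + beta*Ct`` with ``Ct = Ce + Cm``.  Modeled ROI
signals are averaged over each frame interval to match the frame-integrating
measurement process of the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

from .io_protocol import FrameTiming, SerumSeries, ValidationError

__all__ = [
    "CompartmentParams",
    "InputFunction",
    "ParametricInput",
    "SampledInput",
    "LumpedConstant",
    "LC_MYOCARDIUM",
    "LC_SKELETAL_MUSCLE",
    "MG_DL_PER_UMOL_ML",
    "tissue_curves",
    "tissue_curves_frame_avg",
    "roi_signals",
    "ki",
    "metabolic_rate",
    "window_average_glucose",
]

#: mg/dL of glucose per μmol/mL (molar mass of glucose 180.16 g/mol).
MG_DL_PER_UMOL_ML = 18.016


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentParams:
    """Rate constants and ROI spillover fractions for one tissue.

    Parameters
    ----------
    K1 : float
        Plasma-to-tissue transport, mL/mL/min.
    k2 : float
        Tissue-to-plasma efflux, 1/min.
    k3 : float
        Phosphorylation (trapping), 1/min.
    k4 : float
        Dephosphorylation, 1/min; 0 (irreversible) by default.
    sp_blood_to_tissue : float
        Fraction ``alpha`` of the blood-pool signal contaminating the tissue
        ROI, in [0, 1).
    sp_tissue_to_blood : float
        Fraction ``beta`` of the tissue signal contaminating the blood-pool
        ROI, in [0, 1).  Fixed at 0 for skeletal muscle, whose ROI is remote
        from the LV cavity.
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    sp_blood_to_tissue: float = 0.0
    sp_tissue_to_blood: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"rate constant {name} must be finite and >= 0, got {v}")
        if self.K1 > 0 and self.k2 + self.k3 <= 0:
            raise ValidationError("k2 + k3 must be > 0 when K1 > 0")
        for name in ("sp_blood_to_tissue", "sp_tissue_to_blood"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(f"spillover fraction {name} must lie in [0, 1), got {v}")

    @property
    def alpha(self) -> float:
        return self.sp_blood_to_tissue

    @property
    def beta(self) -> float:
        return self.sp_tissue_to_blood

    def with_ki(self, target_ki: float) -> "CompartmentParams":
        """Return params with ``k3`` rescaled so that ``ki`` equals ``target_ki``.

        ``K1`` and ``k2`` are held fixed; requires ``0 <= target_ki < K1``.
        """
        if not (0 <= target_ki < self.K1):
            raise ValidationError(
                f"target Ki {target_ki} must lie in [0, K1={self.K1})")
        new_k3 = self.k2 * target_ki / (self.K1 - target_ki)
        return replace(self, k3=new_k3)


@dataclass(frozen=True)
class LumpedConstant:
    """Dimensionless factor relating FDG flux to glucose flux for a tissue."""

    value: float
    tissue: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError(f"lumped constant must be > 0, got {self.value}")


LC_MYOCARDIUM = LumpedConstant(1.44, "myocardium")
LC_SKELETAL_MUSCLE = LumpedConstant(1.16, "skeletal_muscle")


# ---------------------------------------------------------------------------
# Input functions
# ---------------------------------------------------------------------------

class InputFunction:
    """Plasma input curve ``Cp(t) >= 0`` on [0, scan end].

    Subclasses provide exact evaluations of ``Cp``, its exponential
    convolution ``E_lam(t) = ∫_0^t exp(-lam (t-s)) Cp(s) ds``, and the
    running integrals ``∫Cp`` and ``∫∫Cp`` — everything the compartment
    solution and its frame averages need.
    """

    def conc(self, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def expconv(self, lam: float, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def cumint(self, t: np.ndarray) -> np.ndarray:
        """∫_0^t Cp(s) ds."""
        raise NotImplementedError

    def cumint2(self, t: np.ndarray) -> np.ndarray:
        """∫_0^t ∫_0^u Cp(s) ds du."""
        raise NotImplementedError

    def expconv_cumint(self, lam: float, t: np.ndarray) -> np.ndarray:
        """∫_0^t E_lam(u) du; reduces to (∫Cp − E_lam)/lam for lam > 0."""
        if lam > 0:
            return (self.cumint(t) - self.expconv(lam, t)) / lam
        return self.cumint2(t)

    def __call__(self, t):
        return self.conc(np.asarray(t, dtype=float))


def _e_over(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x))/x with the x→0 limit, elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out


@dataclass(frozen=True)
class ParametricInput(InputFunction):
    """Priming-bolus-plus-saturating-plateau input for constant infusion.

    ``Cp(t) = A (1 - exp(-t/tau)) + D t exp(-t/lam_bolus)``: the first term
    is the slowly saturating plateau a constant-rate infusion produces, the
    second the small line-priming bolus washing through early.
    """

    plateau: float          # A, kBq/mL
    tau: float              # plateau saturation time constant, min
    bolus_amp: float = 0.0  # D, kBq/mL/min
    bolus_tau: float = 1.5  # lam_bolus, min

    def __post_init__(self) -> None:
        if self.plateau <= 0:
            raise ValidationError(f"input plateau must be > 0, got {self.plateau}")
        if self.tau <= 0 or self.bolus_tau <= 0:
            raise ValidationError("input time constants must be > 0")
        if self.bolus_amp < 0:
            raise ValidationError("bolus amplitude must be >= 0")

    def conc(self, t):
        t = np.asarray(t, dtype=float)
        return (-self.plateau * np.expm1(-t / self.tau)
                + self.bolus_amp * t * np.exp(-t / self.bolus_tau))

    def cumint(self, t):
        t = np.asarray(t, dtype=float)
        mu = 1.0 / self.bolus_tau
        a_term = self.plateau * (t + self.tau * np.expm1(-t / self.tau))
        d_term = self.bolus_amp * (1.0 - np.exp(-mu * t) * (1.0 + mu * t)) / mu**2
        return a_term + d_term

    def cumint2(self, t):
        t = np.asarray(t, dtype=float)
        tau, lb = self.tau, self.bolus_tau
        a_term = self.plateau * (t**2 / 2.0 - tau * (t - tau * (1.0 - np.exp(-t / tau))))
        em = np.exp(-t / lb)
        d_term = self.bolus_amp * lb**2 * (
            t - lb * (1.0 - em) - lb * (1.0 - em * (1.0 + t / lb)))
        return a_term + d_term

    def expconv(self, lam, t):
        t = np.asarray(t, dtype=float)
        if lam <= 0:
            return self.cumint(t)
        A, tau, D, lb = self.plateau, self.tau, self.bolus_amp, self.bolus_tau
        mu_a = 1.0 / tau
        mu_b = 1.0 / lb
        # constant plateau term
        out = A * t * _e_over(lam * t)
        # minus the decaying plateau complement: -A exp(-mu_a s)
        out -= A * _conv_exp(lam, mu_a, t)
        # bolus term: D s exp(-mu_b s)
        if D > 0:
            out += D * _conv_t_exp(lam, mu_b, t)
        return out


def _conv_exp(lam: float, mu: float, t: np.ndarray) -> np.ndarray:
    """∫_0^t exp(-lam (t-s)) exp(-mu s) ds."""
    g = lam - mu
    if abs(g) < 1e-10 * max(lam, mu, 1.0):
        return t * np.exp(-lam * t)
    return (np.exp(-mu * t) - np.exp(-lam * t)) / g


def _conv_t_exp(lam: float, mu: float, t: np.ndarray) -> np.ndarray:
    """∫_0^t exp(-lam (t-s)) s exp(-mu s) ds."""
    g = lam - mu
    if abs(g) < 1e-10 * max(lam, mu, 1.0):
        return 0.5 * t**2 * np.exp(-lam * t)
    e_mu, e_lam = np.exp(-mu * t), np.exp(-lam * t)
    return (t / g) * e_mu - (e_mu - e_lam) / g**2


class SampledInput(InputFunction):
    """Measured input curve: piecewise-linear between sample times.

    Before the first and after the last sample the curve is held constant at
    the respective end value.  The exponential convolutions and running
    integrals are evaluated with exact per-segment recursions, so the only
    approximation is the piecewise-linear representation itself.
    """

    def __init__(self, times: np.ndarray, values: np.ndarray):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape or times.size < 2:
            raise ValidationError("sampled input needs matching 1-D time/value arrays, n >= 2")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("sampled input times must be strictly increasing")
        if np.any(~np.isfinite(values)) or np.any(values < -1e-9):
            raise ValidationError("sampled input values must be finite and >= 0")
        # prepend the t=0 knot (constant extrapolation) if needed
        if times[0] > 0:
            times = np.concatenate([[0.0], times])
            values = np.concatenate([[values[0]], values])
        self.times = times
        self.values = np.clip(values, 0.0, None)

    def conc(self, t):
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.times, self.values)

    def _grid(self, t: np.ndarray):
        """Merged knot+eval grid and the indices of the eval points in it."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        grid = np.union1d(self.times[self.times <= t.max() + 1e-12], t)
        idx = np.searchsorted(grid, t)
        return grid, idx, t

    def cumint(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        grid, idx, t1 = self._grid(t)
        v = self.conc(grid)
        ci = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(grid))])
        out = ci[idx]
        return out[0] if scalar else out.reshape(t.shape)

    def cumint2(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        grid, idx, t1 = self._grid(t)
        v = self.conc(grid)
        h = np.diff(grid)
        ci = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * h)])
        # ∫ over segment of cumint: cumint(t0)*h + v0*h^2/2 + (v1-v0)*h^2/6
        seg = ci[:-1] * h + v[:-1] * h**2 / 2.0 + (v[1:] - v[:-1]) * h**2 / 6.0
        ci2 = np.concatenate([[0.0], np.cumsum(seg)])
        out = ci2[idx]
        return out[0] if scalar else out.reshape(t.shape)

    def expconv(self, lam, t):
        t = np.asarray(t, dtype=float)
        if lam <= 0:
            return self.cumint(t)
        scalar = t.ndim == 0
        grid, idx, t1 = self._grid(t)
        v = self.conc(grid)
        h = np.diff(grid)
        # E(t1) = E(t0) e^{-lam h} + a h q(lam h) + b h^2 r(lam h)
        # for Cp(s) = a + b (s - t0) on the segment, with
        # q(x) = (1 - e^{-x})/x and r(x) = (x - 1 + e^{-x})/x^2.
        x = lam * h
        q = _e_over(x)
        small = np.abs(x) <= 1e-12
        r = np.empty_like(x)
        r[~small] = (x[~small] - 1.0 + np.exp(-x[~small])) / x[~small] ** 2
        r[small] = 0.5
        a = v[:-1]
        b = np.zeros_like(h)
        nzh = h > 0
        b[nzh] = (v[1:][nzh] - v[:-1][nzh]) / h[nzh]
        decay = np.exp(-x)
        E = np.empty_like(grid)
        E[0] = 0.0
        inc = a * h * q + b * h**2 * r
        for i in range(h.size):
            E[i + 1] = E[i] * decay[i] + inc[i]
        out = E[idx]
        return out[0] if scalar else out.reshape(t.shape)


# ---------------------------------------------------------------------------
# Compartment solution
# ---------------------------------------------------------------------------

def _eigenrates(k2: float, k3: float, k4: float) -> Tuple[float, float]:
    """Macro rate constants a1 >= a2 >= 0 of the two-tissue system."""
    if k4 > 0 and abs(k2 - k4) < 1e-9 and k3 < 1e-9:
        # eigenvalue collision; nudge off the degenerate point
        k4 = k4 * (1.0 + 1e-7) + 1e-12
    theta = k2 + k3 + k4
    disc = np.sqrt(max(theta**2 - 4.0 * k2 * k4, 0.0))
    a1 = 0.5 * (theta + disc)
    a2 = 0.5 * (theta - disc)
    return a1, a2


def _check_state(initial_state) -> np.ndarray:
    x0 = np.asarray(initial_state, dtype=float)
    if x0.shape != (2,) or np.any(~np.isfinite(x0)) or np.any(x0 < -1e-9):
        raise ValidationError(f"initial compartment state must be 2 finite nonnegative values, got {initial_state}")
    return np.clip(x0, 0.0, None)


def _homog_coeffs(k2: float, k3: float, k4: float, a1: float, a2: float, x0: np.ndarray):
    """Decompose x0 over the eigenvectors of the rate matrix.

    Returns (w1, w2): 2-vectors so that x_h(t) = w1 e^{-a1 dt} + w2 e^{-a2 dt}.
    """
    lam12 = k2 + k3
    if a1 - a2 < 1e-12:
        # both macro rates ~0 (all micro rates ~0): state is constant
        return np.zeros(2), x0

    def eigvec(a: float) -> np.ndarray:
        # nullspace of (A + a I); rows of A are [-(k2+k3), k4], [k3, -k4]
        v = np.array([k4, lam12 - a])
        if np.abs(v).max() < 1e-12:
            v = np.array([a - k4, -k3])
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([1.0, 0.0])

    v1, v2 = eigvec(a1), eigvec(a2)
    V = np.column_stack([v1, v2])
    if abs(np.linalg.det(V)) < 1e-12:
        # pathological near-degeneracy: project on the single direction
        c = v1 @ x0
        return c * v1, np.zeros(2)
    c = np.linalg.solve(V, x0)
    return c[0] * v1, c[1] * v2


def tissue_curves(
    params: CompartmentParams,
    input_fn: InputFunction,
    times: np.ndarray,
    t0: float = 0.0,
    initial_state=(0.0, 0.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Instantaneous (Ce, Cm) at ``times`` for tracer started at ``t0``.

    ``initial_state = (Ce(t0), Cm(t0))`` allows continuing an earlier
    solution across a protocol change (e.g. the normoxia→hypoxia gas
    switch) with conserved compartment contents.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < t0 - 1e-9):
        raise ValidationError("evaluation times must not precede t0")
    x0 = _check_state(initial_state)
    a1, a2 = _eigenrates(params.k2, params.k3, params.k4)
    K1, k3, k4 = params.K1, params.k3, params.k4

    # particular solution: exponential convolutions started at t0
    def P(lam):
        if t0 == 0.0:
            return input_fn.expconv(lam, t)
        base = input_fn.expconv(lam, t)
        at0 = input_fn.expconv(lam, np.asarray(t0))
        if lam > 0:
            return base - np.exp(-lam * (t - t0)) * at0
        return base - at0

    denom = a1 - a2
    if denom < 1e-12:
        denom = 1e-12
    E1, E2 = P(a1), P(a2)
    ce = K1 * ((a1 - k4) * E1 + (k4 - a2) * E2) / denom
    cm = K1 * k3 * (E2 - E1) / denom

    if np.any(x0 > 0):
        w1, w2 = _homog_coeffs(params.k2, params.k3, params.k4, a1, a2, x0)
        d1 = np.exp(-a1 * (t - t0))
        d2 = np.exp(-a2 * (t - t0))
        ce = ce + w1[0] * d1 + w2[0] * d2
        cm = cm + w1[1] * d1 + w2[1] * d2
    return ce, cm


def _frame_integrals(K1: float, k2: float, k3: float, k4: float,
                     input_fn: InputFunction,
                     starts: np.ndarray, ends: np.ndarray, durs: np.ndarray,
                     t0: float, x0) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fused kernel: frame-averaged (Ce, Cm, Cp) in one batched pass.

    Evaluates every input-curve primitive on the concatenated
    [starts, ends] array once — this is the hot path of the fitter.
    """
    a1, a2 = _eigenrates(k2, k3, k4)
    n = starts.size
    tcat = np.concatenate([starts, ends])

    ci = input_fn.cumint(tcat)

    def eint(lam):
        """∫_0^T E_lam for the t0-started convolution, on tcat."""
        if lam > 0:
            base = (ci - input_fn.expconv(lam, tcat)) / lam
        else:
            base = input_fn.cumint2(tcat)
        if t0 != 0.0:
            st0 = np.asarray(t0)
            at0 = float(input_fn.expconv(lam, st0)) if lam > 0 else float(input_fn.cumint(st0))
            if lam > 0:
                base0 = (float(input_fn.cumint(st0)) - at0) / lam
                base = base - base0 - at0 * (1.0 - np.exp(-lam * (tcat - t0))) / lam
            else:
                base = base - float(input_fn.cumint2(st0)) - at0 * (tcat - t0)
        return base

    denom = max(a1 - a2, 1e-12)
    e1, e2 = eint(a1), eint(a2)
    I1 = e1[n:] - e1[:n]
    I2 = e2[n:] - e2[:n]
    ce = K1 * ((a1 - k4) * I1 + (k4 - a2) * I2) / denom
    cm = K1 * k3 * (I2 - I1) / denom

    if x0[0] > 0 or x0[1] > 0:
        w1, w2 = _homog_coeffs(k2, k3, k4, a1, a2, np.asarray(x0, dtype=float))

        def hint(a):
            if a <= 1e-12:
                return durs
            return (np.exp(-a * (starts - t0)) - np.exp(-a * (ends - t0))) / a

        h1, h2 = hint(a1), hint(a2)
        ce = ce + w1[0] * h1 + w2[0] * h2
        cm = cm + w1[1] * h1 + w2[1] * h2
    cp = (ci[n:] - ci[:n]) / durs
    return ce / durs, cm / durs, cp


def tissue_curves_frame_avg(
    params: CompartmentParams,
    input_fn: InputFunction,
    timing: FrameTiming,
    t0: float = 0.0,
    initial_state=(0.0, 0.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Frame-averaged (Ce, Cm): each frame's time-integral over its duration."""
    starts = np.asarray(timing.frame_start, dtype=float)
    durs = np.asarray(timing.frame_duration, dtype=float)
    if np.any(starts < t0 - 1e-9):
        raise ValidationError("frames must not start before t0")
    x0 = _check_state(initial_state)
    ce, cm, _ = _frame_integrals(params.K1, params.k2, params.k3, params.k4,
                                 input_fn, starts, starts + durs, durs, t0, x0)
    return ce, cm


def roi_signals(
    params: CompartmentParams,
    input_fn: InputFunction,
    timing: FrameTiming,
    t0: float = 0.0,
    initial_state=(0.0, 0.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Frame-averaged modeled tissue-ROI and blood-ROI signals.

    Tissue ROI: ``M = (1-alpha) (Ce+Cm) + alpha Cp``;
    blood ROI:  ``B = (1-beta) Cp + beta (Ce+Cm)``; both averaged over each
    frame interval.
    """
    starts = np.asarray(timing.frame_start, dtype=float)
    durs = np.asarray(timing.frame_duration, dtype=float)
    if np.any(starts < t0 - 1e-9):
        raise ValidationError("frames must not start before t0")
    x0 = _check_state(initial_state)
    ce, cm, cp = _frame_integrals(params.K1, params.k2, params.k3, params.k4,
                                  input_fn, starts, starts + durs, durs, t0, x0)
    ct = ce + cm
    alpha, beta = params.alpha, params.beta
    m = (1.0 - alpha) * ct + alpha * cp
    b = (1.0 - beta) * cp + beta * ct
    return m, b


def ki(params: CompartmentParams) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3), mL/mL/min."""
    if params.k2 + params.k3 <= 0:
        raise ValidationError("Ki undefined: k2 + k3 = 0")
    return params.K1 * params.k3 / (params.k2 + params.k3)


# ---------------------------------------------------------------------------
# Metabolic rate
# ---------------------------------------------------------------------------

def window_average_glucose(serum: SerumSeries, window) -> float:
    """Trapezoidal time-average of serum glucose over ``window`` (minutes), mg/dL.

    Sample values at the window edges are linearly interpolated from the
    bounding samples; a window not overlapped by any pair of samples (and
    containing no sample) is an error.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValidationError(f"glucose window must have t1 > t0, got {window}")
    times = np.asarray(serum.sample_time, dtype=float)
    glc = np.asarray(serum.glucose, dtype=float)
    if times.size == 0:
        raise ValidationError("serum series has no glucose samples")
    if times.size == 1:
        # single sample: the only available estimate
        return float(glc[0])
    lo, hi = times.min(), times.max()
    if t1 < lo or t0 > hi:
        # window entirely outside sampled range: nearest constant value
        return float(glc[0] if t1 < lo else glc[-1])
    tt0, tt1 = max(t0, lo), min(t1, hi)
    inside = times[(times > tt0) & (times < tt1)]
    grid = np.concatenate([[tt0], inside, [tt1]])
    vals = np.interp(grid, times, glc)
    return float(np.trapezoid(vals, grid) / (tt1 - tt0))


def metabolic_rate(
    ki_value: float,
    serum: SerumSeries,
    window,
    lc: LumpedConstant,
) -> float:
    """Glucose metabolic rate MRglc = Ki * [glc] / LC, μmol/mL/min.

    ``[glc]`` is the time-averaged serum glucose over the condition window
    converted from mg/dL to μmol/mL.
    """
    if ki_value < 0:
        raise ValidationError(f"Ki must be >= 0, got {ki_value}")
    glc_mg_dl = window_average_glucose(serum, window)
    glc_umol_ml = glc_mg_dl / MG_DL_PER_UMOL_ML
    return ki_value * glc_umol_ml / lc.value
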