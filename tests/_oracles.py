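"""Independent oracles used by the unit and acceptance tests.

Everything here deliberately avoids the package's semi-analytic solution
machinery: compartment curves come from a high-order adaptive ODE
integrator, erosion from brute-force set arithmetic, and the net influx
rate from a graphical Patlak analysis.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_tissue_curves(params, input_fn, t_eval, rtol=1e-11, atol=1e-13,
                      t0=0.0, initial_state=(0.0, 0.0), max_step=np.inf):
    """Reference (Ce, Cm) by DOP853 integration of the rate equations."""

    def rhs(t, x):
        cp = float(input_fn.conc(np.asarray(t)))
        return [params.K1 * cp - (params.k2 + params.k3) * x[0] + params.k4 * x[1],
                params.k3 * x[0] - params.k4 * x[1]]

    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (t0, float(t_eval.max())), list(initial_state),
                    t_eval=t_eval, method="DOP853", rtol=rtol, atol=atol,
                    max_step=max_step)
    assert sol.success
    return sol.y[0], sol.y[1]


def brute_force_erode(voxels: np.ndarray, iterations: int) -> np.ndarray:
    """6-connected erosion by explicit set arithmetic over all voxels."""
    out = voxels.astype(bool).copy()
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for _ in range(iterations):
        nxt = np.zeros_like(out)
        idx = np.argwhere(out)
        shape = out.shape
        for i, j, k in idx:
            keep = True
            for di, dj, dk in offsets:
                ii, jj, kk = i + di, j + dj, k + dk
                if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]) \
                        or not out[ii, jj, kk]:
                    keep = False
                    break
            nxt[i, j, k] = keep
        out = nxt
    return out


def patlak_slope(ct, cp, cumint_cp, late_mask):
    """Graphical Patlak estimate of the net influx rate.

    Regresses Ct/Cp on (∫Cp)/Cp over the late, quasi-steady-state points.
    """
    x = cumint_cp[late_mask] / cp[late_mask]
    y = ct[late_mask] / cp[late_mask]
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
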