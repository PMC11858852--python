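"""Independent brute-force oracles used to verify landmark extraction.

These deliberately avoid the package's trigonometric-interpolation code path:
extrema are located by a dense grid scan over one period of an *analytic*
curve, refined by bounded scalar minimization of the analytic function
itself.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def brute_force_extrema(func, n_grid: int = 200_000):
    """All local (minima, maxima) of a periodic analytic function on [0, 1)."""
    ug = np.arange(n_grid) / n_grid
    vg = func(ug)
    mins, maxs = [], []
    step = 1.0 / n_grid
    for i in range(n_grid):
        prev_v, next_v = vg[i - 1], vg[(i + 1) % n_grid]
        if vg[i] < prev_v and vg[i] < next_v:
            mins.append(_refine(func, ug[i], step, 1.0))
        elif vg[i] > prev_v and vg[i] > next_v:
            maxs.append(_refine(func, ug[i], step, -1.0))
    return mins, maxs


def _refine(func, u0, step, sign):
    res = minimize_scalar(
        lambda u: sign * func(u),
        bounds=(u0 - 2 * step, u0 + 2 * step),
        method="bounded",
        options={"xatol": 1e-14},
    )
    return float(res.x % 1.0), float(sign * res.fun)


def brute_force_landmarks(func, phase_R: float, phase_L: float) -> dict[str, float]:
    """Landmark values of an analytic stride curve by dense scanning.

    Assumes the trot pattern (two minima, two maxima per period) and the same
    half-stride convention as the package: side X spans from that limb's
    stance-onset phase to the contralateral one.
    """
    mins, maxs = brute_force_extrema(func)
    assert len(mins) == 2 and len(maxs) == 2, "oracle expects a trot-shaped curve"
    half_len = (phase_L - phase_R) % 1.0

    def in_R(u):
        return (u - phase_R) % 1.0 < half_len

    min_pt = {"R": next(m for m in mins if in_R(m[0])),
              "L": next(m for m in mins if not in_R(m[0]))}
    max_pt = {"R": next(m for m in maxs if in_R(m[0])),
              "L": next(m for m in maxs if not in_R(m[0]))}

    def next_max(u0):
        return min(maxs, key=lambda p: (p[0] - u0) % 1.0)[1]

    def prev_max(u0):
        return min(maxs, key=lambda p: (u0 - p[0]) % 1.0)[1]

    gmin = min(m[1] for m in mins)
    gmax = max(m[1] for m in maxs)
    out = {"ROM": gmax - gmin}
    for side in ("R", "L"):
        u_min, v_min = min_pt[side]
        out[f"min_{side}"] = v_min
        out[f"max_{side}"] = max_pt[side][1]
        out[f"up_{side}"] = next_max(u_min) - v_min
        out[f"down_{side}"] = prev_max(u_min) - v_min
        out[f"diffTmax_{side}"] = max_pt[side][1] - gmin
    return out
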