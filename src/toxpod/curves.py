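"""Dose-response mean-curve families.

All curves map dose (µM, natural scale) to a response on the log2 scale.
Parameter conventions:

====== =====================  =========================================
family parameters             f(d)
====== =====================  =========================================
null   (a,)                   a
linear (a, b)                 a + b·d
poly2  (a, b, c)              a + b·d + c·d²
poly3  (a, b, c, e)           a + b·d + c·d² + e·d³
power  (a, b, p)              a + b·d^p           (p ≥ 1 by default)
hill   (v0, v, k, n)          v0 + v·d^n/(k^n + d^n)
exp    (a, b, c)              a + b·(1 − exp(−c·d))   (alias: exp3)
====== =====================  =========================================

The same functions serve the synthetic generator (as ground truth means)
and the fitting engine (as model predictions).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = ["CURVE_FAMILIES", "evaluate_curve", "bmd_from_curve"]


def _null(params, d):
    (a,) = params
    return np.full_like(np.asarray(d, dtype=float), a)


def _linear(params, d):
    a, b = params
    return a + b * np.asarray(d, dtype=float)


def _poly2(params, d):
    d = np.asarray(d, dtype=float)
    a, b, c = params
    return a + b * d + c * d**2


def _poly3(params, d):
    d = np.asarray(d, dtype=float)
    a, b, c, e = params
    return a + b * d + c * d**2 + e * d**3


def _power(params, d):
    d = np.asarray(d, dtype=float)
    a, b, p = params
    return a + b * np.power(d, p)


def _hill(params, d):
    d = np.asarray(d, dtype=float)
    v0, v, k, n = params
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, d**n / (k**n + d**n), 0.0)
    return v0 + v * frac


def _exp3(params, d):
    d = np.asarray(d, dtype=float)
    a, b, c = params
    return a + b * (1.0 - np.exp(-c * d))


CURVE_FAMILIES = {
    "null": _null,
    "linear": _linear,
    "poly2": _poly2,
    "poly3": _poly3,
    "power": _power,
    "hill": _hill,
    "exp": _exp3,
    "exp3": _exp3,
}


def evaluate_curve(family: str, params, dose):
    """Evaluate the named curve family at `dose` (scalar or array)."""
    try:
        fn = CURVE_FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown curve family {family!r}") from None
    return fn(np.asarray(params, dtype=float), dose)


def bmd_from_curve(
    family: str,
    params,
    bmr: float,
    max_dose: float,
    n_grid: int = 1024,
    rtol: float = 1e-12,
) -> float | None:
    """Smallest dose d in (0, max_dose] with |f(d) − f(0)| = bmr.

    Bracketing on a dense grid (log-spaced plus linear to catch both
    low-dose and mid-range crossings) followed by Brent refinement.
    Returns None when the curve never departs from control by `bmr`
    within the tested range.
    """
    if bmr <= 0:
        raise ValueError("bmr must be positive")
    f0 = float(evaluate_curve(family, params, 0.0))

    def g(d):
        return abs(float(evaluate_curve(family, params, d)) - f0) - bmr

    lo = max_dose * 1e-9
    grid = np.unique(
        np.concatenate(
            [
                np.geomspace(lo, max_dose, n_grid // 2),
                np.linspace(lo, max_dose, n_grid // 2),
            ]
        )
    )
    vals = np.abs(np.asarray(evaluate_curve(family, params, grid)) - f0) - bmr
    if vals[0] >= 0:  # crossing below the grid floor; treat floor as the bracket
        return float(brentq(g, 0.0, grid[0], rtol=max(rtol, 4e-16)))
    idx = np.nonzero(vals >= 0)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    return float(brentq(g, grid[i - 1], grid[i], rtol=max(rtol, 4e-16)))
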