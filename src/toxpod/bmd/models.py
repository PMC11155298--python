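"""Continuous dose-response model suite for benchmark-dose fitting.

Six families: linear, poly2, poly3 (nested polynomials), power, hill and
exp3 (3-parameter saturating exponential). All are mean curves on the
log2 response scale as functions of dose in µM (natural scale), fitted
under a normal likelihood with one residual SD shared across dose
groups. Each spec knows its parameter boxes and data-driven starting
points for the multi-start optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..curves import evaluate_curve

__all__ = ["ModelSpec", "MODEL_SPECS", "make_spec"]

POLY_FAMILIES = ("linear", "poly2", "poly3")


@dataclass(frozen=True)
class ModelSpec:
    """One model family: name, parameterization and optimizer metadata."""

    family: str
    param_names: tuple[str, ...]
    power_min_exponent: float = 1.0
    hill_n_min: float = 1.0

    @property
    def n_mean_params(self) -> int:
        return len(self.param_names)

    @property
    def n_params(self) -> int:
        """Mean parameters plus the residual-SD parameter."""
        return self.n_mean_params + 1

    @property
    def is_polynomial(self) -> bool:
        return self.family in POLY_FAMILIES

    @property
    def poly_degree(self) -> int:
        return {"linear": 1, "poly2": 2, "poly3": 3}[self.family]

    def predict(self, params, dose):
        return evaluate_curve(self.family, params, dose)

    # -- optimizer metadata ------------------------------------------------
    def bounds(self, dose: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Box constraints sized to the data/dose range."""
        d_max = float(dose.max())
        d_min_pos = float(dose[dose > 0].min())
        y_lo, y_hi = float(y.min()), float(y.max())
        span = max(y_hi - y_lo, 1.0)
        a_lo, a_hi = y_lo - 2 * span, y_hi + 2 * span
        eff = 10 * span
        if self.family == "power":
            return (
                np.array([a_lo, -eff / d_max**self.power_min_exponent, self.power_min_exponent]),
                np.array([a_hi, eff / d_max**self.power_min_exponent, 8.0]),
            )
        if self.family == "hill":
            return (
                np.array([a_lo, -eff, d_max * 1e-6, self.hill_n_min]),
                np.array([a_hi, eff, d_max * 30.0, 18.0]),
            )
        if self.family == "exp3":
            return (
                np.array([a_lo, -eff, 1.0 / (d_max * 100.0)]),
                np.array([a_hi, eff, 10.0 / d_min_pos]),
            )
        raise ValueError(f"{self.family} is fitted in closed form; no bounds needed")

    def starts(self, dose: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        """Data-driven starting points (supplemented by seeded LHS draws)."""
        d_max = float(dose.max())
        d_min_pos = float(dose[dose > 0].min())
        y0 = float(y[dose == 0].mean()) if (dose == 0).any() else float(y.mean())
        y_top = float(y[dose == d_max].mean())
        eff = y_top - y0 if y_top != y0 else 0.1
        d_mid = float(np.sqrt(d_min_pos * d_max))
        if self.family == "power":
            return [
                np.array([y0, eff / d_max**p, p])
                for p in (max(1.0, self.power_min_exponent), 2.0)
            ]
        if self.family == "hill":
            return [
                np.array([y0, eff * (k**n + d_max**n) / d_max**n, k, n])
                for k in (d_mid, d_min_pos * 3, d_max / 3)
                for n in (1.0, 2.0)
                if self.hill_n_min <= n
            ]
        if self.family == "exp3":
            return [np.array([y0, eff, 1.0 / k]) for k in (d_mid, d_min_pos * 3, d_max)]
        raise ValueError(f"{self.family} is fitted in closed form; no starts needed")


def make_spec(
    family: str, power_min_exponent: float = 1.0, hill_n_min: float = 1.0
) -> ModelSpec:
    names = {
        "linear": ("a", "b"),
        "poly2": ("a", "b1", "b2"),
        "poly3": ("a", "b1", "b2", "b3"),
        "power": ("a", "b", "p"),
        "hill": ("v0", "v", "k", "n"),
        "exp3": ("a", "b", "c"),
    }
    if family not in names:
        raise ValueError(f"unknown model family {family!r}")
    return ModelSpec(family, names[family], power_min_exponent, hill_n_min)


MODEL_SPECS = {f: make_spec(f) for f in ("linear", "poly2", "poly3", "power", "hill", "exp3")}
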