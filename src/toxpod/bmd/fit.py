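"""Maximum-likelihood dose-response fitting, model selection and BMD/BMDL/BMDU.

Likelihood: y_ij ~ Normal(f(d_i; θ), σ²) with one σ across all dose
groups (constant variance on the log2 scale). The reported log
likelihood is the exact profile over σ (σ̂² = RSS/n).

Model selection follows the benchmark-dose convention for continuous
data: the best polynomial is chosen by nested likelihood-ratio
chi-square tests (adjacent degrees, p < 0.05 to accept the extra term),
then compared against the non-polynomial families by AIC. A winning
Hill model whose half-max dose k falls below one third of the lowest
positive dose is flagged and replaced by the lowest-AIC unflagged model
with goodness-of-fit p > 0.05 when one exists.

The benchmark response is one residual SD: BMD is the smallest positive
dose at which the fitted mean departs from the fitted control mean by
σ̂. BMDL/BMDU are profile-likelihood bounds at one-sided 95% per side
(likelihood-ratio cutoff χ²₁(0.90)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from ..curves import bmd_from_curve
from ..design import DoseDesign
from ..preprocess import ExpressionMatrix
from .models import MODEL_SPECS, ModelSpec, make_spec

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "BmdConfig",
    "fit_model",
    "goodness_of_fit",
    "select_best_model",
    "compute_bmd",
    "profile_interval",
    "apply_result_filters",
    "run_bmd",
]

# per-observation RSS floor guards log(0) on noiseless data while keeping
# σ̂ far below any meaningful response (σ̂ >= 1e-12)
_RSS_FLOOR_PER_OBS = 1e-24

FILTER_PASS = "pass"
FILTER_FAIL_RANGE = "fail_range"
FILTER_FAIL_FIT_P = "fail_fit_p"
FILTER_FAIL_RATIO = "fail_ratio"
FILTER_FAIL_NO_BMD = "fail_no_bmd"


@dataclass(frozen=True)
class ModelFit:
    """One fitted dose-response model (σ profiled out)."""

    feature_id: str
    spec: ModelSpec
    theta_hat: tuple[float, ...]
    sigma_hat: float
    loglik: float
    n_obs: int
    converged: bool = True

    @property
    def family(self) -> str:
        return self.spec.family

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def predict(self, dose):
        return self.spec.predict(np.asarray(self.theta_hat), dose)


def _loglik_from_rss(rss: float, n: int) -> tuple[float, float]:
    """(loglik, sigma_hat) for the σ-profiled normal likelihood."""
    rss = max(float(rss), n * _RSS_FLOOR_PER_OBS)
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return ll, float(np.sqrt(sigma2))


def _align(responses, design: DoseDesign) -> tuple[np.ndarray, np.ndarray]:
    """(dose, y) arrays in design sample order."""
    ids = design.sample_ids
    if isinstance(responses, pd.Series):
        y = responses.reindex(ids).to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("responses missing for some design samples")
    else:
        y = np.asarray(responses, dtype=float)
        if y.shape != (len(ids),):
            raise ValueError("responses must align with the design's samples")
    dose = design.sample_table["dose_uM"].to_numpy(dtype=float)
    return dose, y


def _fit_polynomial(feature_id, spec, dose, y) -> ModelFit:
    # scale doses to [0, 1] for conditioning, then map coefficients back
    d_max = dose.max()
    u = dose / d_max
    deg = spec.poly_degree
    X = np.vander(u, deg + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    theta = tuple(float(c) / d_max**k for k, c in enumerate(coef))
    ll, sigma = _loglik_from_rss(rss, len(y))
    return ModelFit(feature_id, spec, theta, sigma, ll, len(y))


def fit_model(
    responses,
    design: DoseDesign,
    spec: ModelSpec,
    n_starts: int = 10,
    seed: int = 0,
) -> ModelFit:
    """Fit one model family by multi-start bounded least squares.

    Polynomial families are solved in closed form; the nonlinear
    families run trust-region-reflective least squares from data-driven
    starts plus seeded Latin-hypercube draws over the parameter boxes.
    Deterministic for a given seed.
    """
    dose, y = _align(responses, design)
    if len(y) < spec.n_params + 1:
        raise ValueError(
            f"{spec.family}: needs at least {spec.n_params + 1} observations, got {len(y)}"
        )
    if spec.is_polynomial:
        return _fit_polynomial(getattr(responses, "name", "") or "", spec, dose, y)

    lb, ub = spec.bounds(dose, y)
    starts = spec.starts(dose, y)
    n_lhs = max(0, n_starts - len(starts))
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(lb), seed=seed)
        # sample positive-scale parameters (dose constants) on log scale
        unit = sampler.random(n_lhs)
        log_scale = lb > 0
        lo, hi = lb.copy(), ub.copy()
        lo[log_scale] = np.log(lb[log_scale])
        hi[log_scale] = np.log(ub[log_scale])
        draws = lo + unit * (hi - lo)
        draws[:, log_scale] = np.exp(draws[:, log_scale])
        starts = starts + [d for d in draws]

    def resid(theta):
        return y - np.asarray(spec.predict(theta, dose), dtype=float)

    best_rss, best_theta, ok = np.inf, None, False
    for x0 in starts[: max(n_starts, len(spec.starts(dose, y)))]:
        x0 = np.clip(np.asarray(x0, dtype=float), lb, ub)
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        if not np.isfinite(sol.cost):
            continue
        ok = True
        rss = 2.0 * sol.cost
        if rss < best_rss:
            best_rss, best_theta = rss, sol.x
    fid = getattr(responses, "name", "") or ""
    if not ok:
        return ModelFit(fid, spec, tuple(np.clip(starts[0], lb, ub)), 1.0,
                        -np.inf, len(y), converged=False)
    ll, sigma = _loglik_from_rss(best_rss, len(y))
    return ModelFit(fid, spec, tuple(float(t) for t in best_theta), sigma, ll, len(y))


def goodness_of_fit(fit: ModelFit, responses, design: DoseDesign) -> float:
    """Likelihood-ratio lack-of-fit p-value against the saturated means model.

    The saturated model has one mean per dose group and the same common
    σ; the statistic 2·(ll_full − ll_model) is referred to chi-square
    with df = (number of dose groups − number of mean parameters).
    df ≤ 0 yields p = 1 by convention.
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    dose, y = _align(responses, design)
    rss_full = 0.0
    for d in design.doses:
        g = y[dose == d]
        rss_full += float(np.sum((g - g.mean()) ** 2))
    ll_full, _ = _loglik_from_rss(rss_full, len(y))
    df = len(design.doses) - fit.spec.n_mean_params
    if df <= 0:
        return 1.0
    stat = max(0.0, 2.0 * (ll_full - fit.loglik))
    return float(stats.chi2.sf(stat, df))


def select_best_model(
    fits: list[ModelFit],
    responses,
    design: DoseDesign,
    lowest_positive_dose: float | None = None,
    poly_lrt_alpha: float = 0.05,
    flag_gof_alpha: float = 0.05,
) -> tuple[ModelFit | None, bool]:
    """Nested-chi-square polynomial selection, AIC comparison, Hill-k flag.

    Returns (winner, hill_flagged). hill_flagged is True when the AIC
    winner was a Hill model with k below one third of the lowest
    positive dose; in that case the returned fit is the lowest-AIC
    non-Hill model with goodness-of-fit p > `flag_gof_alpha`, or the
    flagged Hill itself when no such fallback exists.
    """
    if lowest_positive_dose is None:
        lowest_positive_dose = design.min_positive_dose
    conv = [f for f in fits if f.converged]
    if not conv:
        return None, False

    polys = sorted((f for f in conv if f.spec.is_polynomial), key=lambda f: f.spec.poly_degree)
    candidates: list[ModelFit] = [f for f in conv if not f.spec.is_polynomial]
    if polys:
        winner = polys[0]
        for nxt in polys[1:]:
            df = nxt.spec.n_mean_params - winner.spec.n_mean_params
            stat = max(0.0, 2.0 * (nxt.loglik - winner.loglik))
            if stats.chi2.sf(stat, df) < poly_lrt_alpha:
                winner = nxt
        candidates.append(winner)

    def order(f: ModelFit):
        return (f.aic, f.n_params)

    best = min(candidates, key=order)
    hill_flagged = False
    if best.family == "hill":
        k = best.theta_hat[2]
        if k < lowest_positive_dose / 3.0:
            hill_flagged = True
            fallbacks = [
                f
                for f in candidates
                if f.family != "hill"
                and goodness_of_fit(f, responses, design) > flag_gof_alpha
            ]
            if fallbacks:
                best = min(fallbacks, key=order)
    return best, hill_flagged


def compute_bmd(fit: ModelFit, design: DoseDesign) -> tuple[float | None, str]:
    """(BMD, adverse direction) at the one-SD benchmark response.

    The adverse direction is the sign of f(max dose) − f(0); BMD is the
    smallest positive dose where |f(d) − f(0)| reaches σ̂, located by
    bracketing plus Brent refinement. None when the fitted curve never
    departs from control by σ̂ within the tested range.
    """
    if fit.sigma_hat <= 0:
        raise ValueError("compute_bmd requires sigma_hat > 0")
    f0 = float(fit.predict(0.0))
    f_top = float(fit.predict(design.max_dose))
    direction = "up" if f_top >= f0 else "down"
    bmd = bmd_from_curve(
        fit.family, fit.theta_hat, fit.sigma_hat, design.max_dose, rtol=1e-10
    )
    return bmd, direction


# ---------------------------------------------------------------------------
# profile-likelihood interval
# ---------------------------------------------------------------------------

def _nll(x, spec, dose, y):
    theta, log_sigma = x[:-1], x[-1]
    sigma2 = np.exp(2.0 * log_sigma)
    r = y - np.asarray(spec.predict(theta, dose), dtype=float)
    n = len(y)
    return 0.5 * n * np.log(2.0 * np.pi * sigma2) + float(r @ r) / (2.0 * sigma2)


def _profile_nll_at(b, spec, dose, y, sign, x0, box):
    """min NLL subject to sign·(f(b) − f(0)) = σ (BMD pinned at b)."""

    def constraint(x):
        theta = x[:-1]
        f = spec.predict
        return sign * (float(f(theta, b)) - float(f(theta, 0.0))) - np.exp(x[-1])

    res = optimize.minimize(
        _nll,
        x0,
        args=(spec, dose, y),
        method="SLSQP",
        bounds=box,
        constraints=[{"type": "eq", "fun": constraint}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if not np.isfinite(res.fun):
        return np.inf, x0
    return float(res.fun), res.x


def profile_interval(
    fit: ModelFit,
    responses,
    design: DoseDesign,
    confidence: float = 0.95,
    rtol: float = 1e-3,
) -> tuple[float | None, float | None]:
    """Profile-likelihood BMDL/BMDU for a fitted model.

    The BMD is made an explicit parameter through the equality
    constraint sign·(f(b) − f(0)) = σ; each bound is the dose where the
    profiled likelihood-ratio statistic reaches the χ²₁ quantile at
    2·confidence − 1 (one-sided `confidence` per side). The upward
    search is clamped to 10× the top dose; a side on which the profile
    never closes is returned as None (treated downstream as an infinite
    BMDU/BMDL ratio).
    """
    bmd, direction = compute_bmd(fit, design)
    if bmd is None:
        raise ValueError("profile_interval requires a defined BMD")
    sign = 1.0 if direction == "up" else -1.0
    dose, y = _align(responses, design)
    spec = fit.spec
    cutoff = stats.chi2.ppf(2.0 * confidence - 1.0, 1)

    if spec.is_polynomial:
        box = [(None, None)] * spec.n_mean_params
    else:
        lb, ub = spec.bounds(dose, y)
        box = list(zip(lb, ub))
    box = box + [(np.log(1e-12), np.log(1e6))]

    x_hat = np.array([*fit.theta_hat, np.log(max(fit.sigma_hat, 1e-12))])
    nll_hat = _nll(x_hat, spec, dose, y)

    cache = {"x": x_hat.copy()}

    def lr(b):
        val, x = _profile_nll_at(b, spec, dose, y, sign, cache["x"], box)
        retry, x_alt = _profile_nll_at(b, spec, dose, y, sign, x_hat, box)
        if retry < val:
            val, x = retry, x_alt
        cache["x"] = x
        return max(0.0, 2.0 * (val - nll_hat))

    def find_bound(direction_up: bool) -> float | None:
        cache["x"] = x_hat.copy()
        factor = 1.5 if direction_up else 1 / 1.5
        limit = 10.0 * design.max_dose if direction_up else bmd * 1e-6
        b_in, b_out = bmd, bmd * factor
        lr_out = lr(b_out)
        while lr_out < cutoff:
            b_in, b_out = b_out, b_out * factor
            past_limit = b_out > limit if direction_up else b_out < limit
            if past_limit:
                b_out = limit
                if lr(b_out) < cutoff:
                    return None  # profile does not close on this side
                break
            lr_out = lr(b_out)
        lo, hi = (b_in, b_out) if direction_up else (b_out, b_in)
        try:
            return float(
                optimize.brentq(lambda b: lr(b) - cutoff, lo, hi, rtol=rtol, xtol=1e-12)
            )
        except ValueError:
            logger.debug("profile bracket failed for %s", fit.feature_id)
            return None

    bmdl = find_bound(direction_up=False)
    bmdu = find_bound(direction_up=True)
    if bmdl is not None:
        bmdl = min(bmdl, bmd)
    if bmdu is not None:
        bmdu = max(bmdu, bmd)
    return bmdl, bmdu


# ---------------------------------------------------------------------------
# filters and batch driver
# ---------------------------------------------------------------------------

def apply_result_filters(
    results: pd.DataFrame,
    design: DoseDesign,
    fit_p_min: float = 0.1,
    ratio_max: float = 40.0,
) -> pd.DataFrame:
    """Label each BMD result with its filter status.

    Pass requires, in rejection order: BMD defined and inside
    [lowest positive dose, highest dose]; goodness-of-fit p ≥ `fit_p_min`;
    BMDU/BMDL ratio ≤ `ratio_max` (an undefined bound counts as an
    infinite ratio).
    """
    out = results.copy()
    lo, hi = design.min_positive_dose, design.max_dose
    status = []
    for _, row in out.iterrows():
        bmd = row["bmd"]
        if pd.isna(bmd):
            status.append(FILTER_FAIL_NO_BMD)
        elif not (lo <= bmd <= hi):
            status.append(FILTER_FAIL_RANGE)
        elif row["fit_p"] < fit_p_min:
            status.append(FILTER_FAIL_FIT_P)
        else:
            bmdl, bmdu = row["bmdl"], row["bmdu"]
            ratio = np.inf if (pd.isna(bmdl) or pd.isna(bmdu) or bmdl <= 0) else bmdu / bmdl
            status.append(FILTER_PASS if ratio <= ratio_max else FILTER_FAIL_RATIO)
    out["filter_status"] = status
    return out


@dataclass
class BmdConfig:
    """Settings for the per-feature BMD pipeline (defaults = study values)."""

    families: tuple[str, ...] = ("linear", "poly2", "poly3", "power", "hill", "exp3")
    n_starts: int = 10
    seed: int = 0
    confidence: float = 0.95
    poly_lrt_alpha: float = 0.05
    hill_flag_gof_alpha: float = 0.05
    fit_p_min: float = 0.1
    ratio_max: float = 40.0
    power_min_exponent: float = 1.0
    hill_n_min: float = 1.0

    def specs(self) -> list[ModelSpec]:
        return [
            make_spec(f, self.power_min_exponent, self.hill_n_min) for f in self.families
        ]


def _feature_seed(seed: int, feature_id: str) -> int:
    import zlib

    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(feature_id.encode())])
        .generate_state(1)[0] % (2**31 - 1)
    )


def run_bmd(
    matrix: ExpressionMatrix,
    design: DoseDesign,
    config: BmdConfig | None = None,
) -> pd.DataFrame:
    """Fit, select, test and filter every feature of a normalized matrix.

    The same driver serves gene expression and intron read-count
    matrices (both enter on the normalized log2 scale). Per-feature
    failures are logged and yield `fail_no_bmd` rows; the batch never
    aborts.
    """
    config = config or BmdConfig()
    specs = config.specs()
    rows = []
    for fid in matrix.feature_ids:
        y = matrix.values.loc[fid]
        y.name = fid
        fseed = _feature_seed(config.seed, fid)
        try:
            fits = [
                fit_model(y, design, spec, n_starts=config.n_starts, seed=fseed)
                for spec in specs
            ]
            best, flagged = select_best_model(
                fits, y, design,
                poly_lrt_alpha=config.poly_lrt_alpha,
                flag_gof_alpha=config.hill_flag_gof_alpha,
            )
            if best is None:
                raise RuntimeError("no model converged")
            fit_p = goodness_of_fit(best, y, design)
            bmd, direction = compute_bmd(best, design)
            bmdl = bmdu = None
            if bmd is not None:
                bmdl, bmdu = profile_interval(best, y, design, config.confidence)
            rows.append(
                {
                    "feature_id": fid,
                    "best_model": best.family,
                    "bmd": np.nan if bmd is None else bmd,
                    "bmdl": np.nan if bmdl is None else bmdl,
                    "bmdu": np.nan if bmdu is None else bmdu,
                    "fit_p": fit_p,
                    "aic": best.aic,
                    "hill_flagged": flagged,
                    "adverse_direction": direction,
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-feature isolation
            logger.debug("feature %s failed: %s", fid, exc)
            rows.append(
                {
                    "feature_id": fid,
                    "best_model": "none",
                    "bmd": np.nan,
                    "bmdl": np.nan,
                    "bmdu": np.nan,
                    "fit_p": np.nan,
                    "aic": np.nan,
                    "hill_flagged": False,
                    "adverse_direction": "up",
                }
            )
    if not rows:
        results = pd.DataFrame(
            columns=[
                "feature_id", "best_model", "bmd", "bmdl", "bmdu",
                "fit_p", "aic", "hill_flagged", "adverse_direction",
            ]
        )
    else:
        results = pd.DataFrame(rows)
    results = apply_result_filters(results, design, config.fit_p_min, config.ratio_max)
    return results
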