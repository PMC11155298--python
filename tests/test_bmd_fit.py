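"""Model fitting, lack-of-fit testing and best-model selection."""

import numpy as np
import pandas as pd
import pytest

from conftest import hill_responses
from toxpod import build_design
from toxpod.bmd import ModelFit, fit_model, goodness_of_fit, make_spec, select_best_model
from toxpod.curves import evaluate_curve


def _series(design, y):
    return pd.Series(np.asarray(y, dtype=float), index=design.sample_ids, name="f")


class TestFitModel:
    def test_noiseless_linear_exact(self):
        design = build_design(2, 2, 2, "x")  # doses 0, 1, 2 (sqrt10 -> no; use explicit)
        from toxpod.design import DoseDesign
        design = DoseDesign("x", (0.0, 1.0, 2.0), 2)
        dose = design.sample_table["dose_uM"].to_numpy()
        fit = fit_model(_series(design, 2 + 3 * dose), design, make_spec("linear"))
        assert fit.theta_hat[0] == pytest.approx(2.0, abs=1e-9)
        assert fit.theta_hat[1] == pytest.approx(3.0, abs=1e-9)
        assert fit.sigma_hat <= 1e-6

    def test_noiseless_hill_recovery(self, design9):
        dose = design9.sample_table["dose_uM"].to_numpy()
        y = _series(design9, evaluate_curve("hill", [1, 4, 10, 1], dose))
        fit = fit_model(y, design9, make_spec("hill"), n_starts=10, seed=1)
        assert np.allclose(fit.theta_hat, [1, 4, 10, 1], rtol=1e-3)

    def test_constant_responses_match_mean_only_loglik(self, design_small):
        y = _series(design_small, np.full(15, 5.0))
        fit = fit_model(y, design_small, make_spec("linear"))
        # mean-only model: rss = 0 as well -> identical profiled loglik
        from toxpod.bmd.fit import _loglik_from_rss
        ll_mean, _ = _loglik_from_rss(0.0, 15)
        assert fit.loglik == pytest.approx(ll_mean, abs=1e-6)

    def test_too_few_observations(self):
        from toxpod.design import DoseDesign
        design = DoseDesign("x", (0.0, 1.0), 1)
        with pytest.raises(ValueError, match="observations"):
            fit_model(_series(design, [1.0, 2.0]), design, make_spec("hill"))

    def test_determinism_under_seed(self, design9):
        rng = np.random.default_rng(3)
        y = hill_responses(design9, [2, 2, 30, 2], 0.25, rng)
        a = fit_model(y, design9, make_spec("hill"), seed=7)
        b = fit_model(y, design9, make_spec("hill"), seed=7)
        assert a.theta_hat == b.theta_hat


class TestGoodnessOfFit:
    def test_noiseless_on_curve_p_is_one(self, design_small):
        dose = design_small.sample_table["dose_uM"].to_numpy()
        y = _series(design_small, 1 + 0.05 * dose)
        fit = fit_model(y, design_small, make_spec("linear"))
        assert goodness_of_fit(fit, y, design_small) == pytest.approx(1.0)

    def test_v_shape_rejected_and_matches_chi2_oracle(self):
        from scipy.stats import chi2
        from toxpod.design import DoseDesign
        design = DoseDesign("x", (0.0, 1.0, 2.0), 4)
        means = {0.0: 0.0, 1.0: 5.0, 2.0: 0.0}
        rng = np.random.default_rng(4)
        dose = design.sample_table["dose_uM"].to_numpy()
        y = np.array([means[d] for d in dose]) + rng.normal(0, 0.1, len(dose))
        ys = _series(design, y)
        fit = fit_model(ys, design, make_spec("linear"))
        p = goodness_of_fit(fit, ys, design)
        # oracle: 2*(ll_full - ll_model) = n*log(rss_model/rss_full), df = 3 - 2
        rss_m = float(np.sum((y - fit.predict(dose)) ** 2))
        rss_f = sum(
            float(np.sum((y[dose == d] - y[dose == d].mean()) ** 2)) for d in design.doses
        )
        stat = len(y) * np.log(rss_m / rss_f)
        assert p == pytest.approx(float(chi2.sf(stat, 1)), rel=1e-9)
        assert p < 0.1

    def test_df_zero_or_negative_gives_one(self):
        from toxpod.design import DoseDesign
        design = DoseDesign("x", (0.0, 1.0, 2.0), 3)
        dose = design.sample_table["dose_uM"].to_numpy()
        rng = np.random.default_rng(5)
        y = _series(design, 1 + dose + rng.normal(0, 0.1, len(dose)))
        fit = fit_model(y, design, make_spec("poly3"))  # 4 mean params, 3 groups
        assert goodness_of_fit(fit, y, design) == 1.0


class TestSelectBestModel:
    def test_equal_loglik_fewer_params_wins(self, design_small):
        rng = np.random.default_rng(6)
        y = _series(design_small, rng.normal(0, 1, 15))
        lin = ModelFit("f", make_spec("linear"), (0.0, 0.1), 1.0, -10.0, 15)
        hill = ModelFit("f", make_spec("hill"), (0.0, 1.0, 1.0, 1.0), 1.0, -10.0, 15)
        best, flagged = select_best_model([lin, hill], y, design_small)
        assert best.family == "linear" and not flagged

    def test_hill_k_flag_triggers_fallback(self):
        # k = 0.02 < lowest positive dose 0.1 / 3; linear fallback fits well
        design = build_design(10, 3, 4, "x")  # positive doses 0.1*... actually 1,3.16,10
        from toxpod.design import DoseDesign
        design = DoseDesign("x", (0.0, 0.1, 1.0, 10.0), 4)
        dose = design.sample_table["dose_uM"].to_numpy()
        rng = np.random.default_rng(7)
        y = _series(design, 1 + 0.05 * dose + rng.normal(0, 0.05, len(dose)))
        lin = fit_model(y, design, make_spec("linear"))
        hill = ModelFit(
            "f", make_spec("hill", hill_n_min=1.0), (1.0, 0.5, 0.02, 1.0),
            lin.sigma_hat, lin.loglik + 50, len(dose),
        )  # artificially dominant AIC, flagged k
        best, flagged = select_best_model([lin, hill], y, design)
        assert flagged
        assert best.family == "linear"

    def test_hill_flag_no_fallback_returns_flagged_hill(self):
        from toxpod.design import DoseDesign
        design = DoseDesign("x", (0.0, 0.1, 1.0, 10.0), 4)
        dose = design.sample_table["dose_uM"].to_numpy()
        rng = np.random.default_rng(8)
        # step response at the lowest dose: polynomials fail lack-of-fit,
        # so no unflagged fallback with GOF p > 0.05 exists
        y = _series(design, np.where(dose > 0, 3.0, 0.0) + rng.normal(0, 0.05, len(dose)))
        lin = fit_model(y, design, make_spec("linear"))
        hill = ModelFit("f", make_spec("hill"), (0.0, 3.0, 0.02, 2.0),
                        0.05, lin.loglik + 50, len(dose))
        best, flagged = select_best_model([lin, hill], y, design)
        assert flagged
        assert best.family == "hill"

    def test_nested_lrt_prefers_quadratic_on_quadratic_truth(self, design_small):
        dose = design_small.sample_table["dose_uM"].to_numpy()
        wins = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            y = _series(design_small, 1 + 0.001 * dose**2 * 0 + 5e-4 * dose**2
                        + rng.normal(0, 0.2, len(dose)))
            fits = [fit_model(y, design_small, make_spec(f))
                    for f in ("linear", "poly2", "poly3")]
            best, _ = select_best_model(fits, y, design_small)
            wins += best.family in ("poly2", "poly3")
        assert wins >= 95

    def test_no_converged_fits(self, design_small):
        rng = np.random.default_rng(9)
        y = _series(design_small, rng.normal(0, 1, 15))
        bad = ModelFit("f", make_spec("hill"), (0, 1, 1, 1), 1.0, -np.inf, 15, converged=False)
        best, flagged = select_best_model([bad], y, design_small)
        assert best is None and not flagged


def test_aic_selection_recovers_hill_curve(design9):
    """With 64 replicates the selected model's curve tracks the Hill truth."""
    import dataclasses
    big = build_design(1000.0, 9, 64, "big")
    dose = big.sample_table["dose_uM"].to_numpy()
    params = [2.0, 2.0, 30.0, 2.0]
    truth = evaluate_curve("hill", params, np.asarray(big.doses))
    hits = 0
    n_seeds = 100
    for s in range(n_seeds):
        rng = np.random.default_rng(5000 + s)
        y = pd.Series(
            evaluate_curve("hill", params, dose) + rng.normal(0, 0.25, len(dose)),
            index=big.sample_ids,
        )
        fits = [fit_model(y, big, make_spec(f), n_starts=6, seed=s)
                for f in ("linear", "poly2", "poly3", "power", "hill", "exp3")]
        best, _ = select_best_model(fits, y, big)
        curve = np.asarray(best.predict(np.asarray(big.doses)), dtype=float)
        if best.family == "hill" or np.max(np.abs(curve - truth)) < 0.25:
            hits += 1
    assert hits >= 90
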