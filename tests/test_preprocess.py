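"""Preprocessing: low-count filter, normalization, prefilter, DE calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxpod import build_design
from toxpod.preprocess import (
    anova_prefilter,
    deg_counts,
    differential_expression,
    filter_low_counts,
    median_center,
    normalize_matrix,
)


def _counts(design, rows, feature_ids=None):
    rows = np.atleast_2d(rows)
    ids = feature_ids or [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=pd.Index(ids, name="feature_id"),
                        columns=design.sample_ids)


class TestLowCountFilter:
    def test_less_than_ten_removed(self):
        design = build_design(10, 1, 5, "x")
        counts = _counts(design, [[1]*9 + [0], [1]*10, [2]*5 + [1]*5])
        kept = filter_low_counts(counts)  # totals 9, 10, 11
        assert list(kept.index) == ["g1", "g2"]

    def test_all_zero_matrix_warns_empty(self):
        design = build_design(10, 1, 2, "x")
        counts = _counts(design, np.zeros((3, 4), dtype=int))
        with pytest.warns(UserWarning):
            kept = filter_low_counts(counts)
        assert kept.empty

    def test_survivors_match_brute_force(self, design_small):
        rng = np.random.default_rng(0)
        counts = _counts(design_small, rng.integers(0, 3, size=(200, 15)))
        kept = filter_low_counts(counts, min_total=10)
        expected = {fid for fid, row in counts.iterrows() if row.sum() >= 10}
        assert set(kept.index) == expected


class TestNormalize:
    def test_log2_of_zero_count(self):
        design = build_design(10, 1, 2, "x")
        m = normalize_matrix(_counts(design, [[0, 0, 0, 0]]))
        assert (m.values.to_numpy() == 0).all()  # single feature: no centering

    def test_sample_offset_removed(self, design_small):
        rng = np.random.default_rng(1)
        counts = _counts(design_small, rng.poisson(200, size=(50, 15)))
        shifted = counts.astype(float).copy()
        j = shifted.columns[3]
        shifted[j] = (shifted[j] + 1) * 4 - 1  # +2 in log2(count+1) space
        a = normalize_matrix(counts).values
        b = normalize_matrix(shifted).values
        pd.testing.assert_frame_equal(a, b, atol=1e-12, rtol=0)

    def test_median_centering_idempotent(self, design_small):
        rng = np.random.default_rng(2)
        log2 = pd.DataFrame(rng.normal(8, 1, size=(40, 15)), columns=design_small.sample_ids)
        once = median_center(log2)
        twice = median_center(once)
        pd.testing.assert_frame_equal(once, twice, atol=1e-12, rtol=0)
        medians = once.median(axis=0)
        assert np.allclose(medians, np.median(medians), atol=1e-9)

    def test_negative_counts_rejected(self, design_small):
        counts = _counts(design_small, -np.ones((2, 15)))
        with pytest.raises(ValueError):
            normalize_matrix(counts)


class TestAnovaPrefilter:
    def test_constant_feature_fails(self, design_small):
        m = normalize_matrix(_counts(design_small, [[100] * 15, [100] * 15]))
        res = anova_prefilter(m, design_small)
        assert not res["passes"].any()
        assert (res["anova_p"] == 1.0).all()  # degenerate convention

    def test_strong_shift_passes_and_matches_f_test(self, design_small):
        rng = np.random.default_rng(3)
        vals = rng.normal(8, 0.1, size=(1, 15))
        vals[0, -3:] += 1.0  # top-dose mean shifted +10 SD
        from toxpod.preprocess import ExpressionMatrix
        m = ExpressionMatrix(pd.DataFrame(vals, index=["g0"], columns=design_small.sample_ids))
        res = anova_prefilter(m, design_small)
        groups = [vals[0, 3*i:3*(i+1)] for i in range(5)]
        _, p_oracle = stats.f_oneway(*groups)
        assert res.loc["g0", "anova_p"] == pytest.approx(p_oracle, rel=1e-9)
        assert bool(res.loc["g0", "passes"])

    def test_significant_but_small_fc_fails(self, design_small):
        rng = np.random.default_rng(4)
        vals = rng.normal(8, 0.01, size=(1, 15))
        vals[0, -3:] += np.log2(1.4)  # p tiny, |FC| = 1.4 < 1.5
        from toxpod.preprocess import ExpressionMatrix
        m = ExpressionMatrix(pd.DataFrame(vals, index=["g0"], columns=design_small.sample_ids))
        res = anova_prefilter(m, design_small)
        assert res.loc["g0", "anova_p"] < 0.01
        assert not bool(res.loc["g0", "passes"])

    def test_pass_set_invariant_to_sample_median_shifts(self, design_small):
        rng = np.random.default_rng(5)
        counts = _counts(design_small, rng.poisson(150, size=(100, 15)))
        m1 = normalize_matrix(counts)
        scaled = (counts.astype(float) + 1) * 2 ** rng.uniform(-1, 1, 15) - 1
        m2 = normalize_matrix(scaled)
        r1 = anova_prefilter(m1, design_small)
        r2 = anova_prefilter(m2, design_small)
        assert (r1["passes"] == r2["passes"]).all()


class TestDifferentialExpression:
    def test_null_groups_no_degs_uniform_p(self, design_small):
        rng = np.random.default_rng(6)
        vals = rng.normal(8, 0.25, size=(2000, 15))
        from toxpod.preprocess import ExpressionMatrix
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(2000)], columns=design_small.sample_ids
        ))
        de = differential_expression(m, design_small, design_small.max_dose)
        assert int(de["is_deg"].sum()) == 0
        ks = stats.kstest(de["raw_p"], "uniform")
        assert ks.pvalue > 0.01

    def test_forced_effect_detected_with_sign(self, design_small):
        rng = np.random.default_rng(7)
        vals = rng.normal(8, 0.01, size=(50, 15))
        vals[0, -3:] += 2.0
        from toxpod.preprocess import ExpressionMatrix
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(50)], columns=design_small.sample_ids
        ))
        de = differential_expression(m, design_small, design_small.max_dose)
        assert bool(de.loc["g0", "is_deg"])
        assert de.loc["g0", "log2_fold_change"] > 0

    def test_fc_149_never_deg(self, design_small):
        rng = np.random.default_rng(8)
        vals = rng.normal(8, 1e-4, size=(20, 15))
        vals[0, -3:] += np.log2(1.49)
        from toxpod.preprocess import ExpressionMatrix
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(20)], columns=design_small.sample_ids
        ))
        de = differential_expression(m, design_small, design_small.max_dose)
        assert de.loc["g0", "fdr"] < 0.05  # overwhelmingly significant...
        assert not bool(de.loc["g0", "is_deg"])  # ...but below the FC threshold

    def test_fdr_monotone_and_geq_raw(self, design_small):
        rng = np.random.default_rng(9)
        vals = rng.normal(8, 0.3, size=(300, 15))
        vals[:30, -3:] += rng.uniform(0.5, 2, size=(30, 1))
        from toxpod.preprocess import ExpressionMatrix
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(300)], columns=design_small.sample_ids
        ))
        de = differential_expression(m, design_small, design_small.max_dose)
        assert (de["fdr"] >= de["raw_p"] - 1e-12).all()
        s = de.sort_values("raw_p")
        assert (np.diff(s["fdr"]) >= -1e-12).all()
        # DEG set is a subset of the |FC| > 1.5 set
        deg = de[de["is_deg"]]
        assert (np.abs(deg["log2_fold_change"]) > np.log2(1.5)).all()

    def test_too_few_replicates_named_error(self):
        design = build_design(10, 2, 1, "x")
        from toxpod.preprocess import ExpressionMatrix
        m = ExpressionMatrix(pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["g0"], columns=design.sample_ids
        ))
        with pytest.raises(ValueError, match="control"):
            differential_expression(m, design, 10.0)

    def test_deg_counts_layout(self, design_small):
        rng = np.random.default_rng(10)
        counts = _counts(design_small, rng.poisson(200, size=(40, 15)))
        tab = deg_counts(normalize_matrix(counts), design_small)
        assert list(tab.columns) == ["chemical", "dose_uM", "n_up", "n_down"]
        assert len(tab) == len(design_small.positive_doses)
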