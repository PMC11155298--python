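"""Count preprocessing, ANOVA prefilter and differential expression.

The normalization convention is log2(count + 1) followed by per-sample
median centering to the grand median of sample medians — the same
transform is applied to gene counts and to intron read counts before
dose-response modeling.

Differential expression is a per-dose-vs-control Welch t-test on the
normalized log2 values with Benjamini–Hochberg correction across
features within each contrast; a feature is called differentially
expressed when FDR < 0.05 and the linear fold change exceeds 1.5 in
magnitude. (This is a documented stand-in for a negative-binomial GLM:
the stages under study sit downstream of the DE caller, which only has
to be distribution-honest on the normalized scale.)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import DoseDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "filter_low_counts",
    "median_center",
    "normalize_matrix",
    "anova_prefilter",
    "differential_expression",
    "deg_counts",
]


@dataclass
class ExpressionMatrix:
    """Normalized feature × sample matrix on the log2(count+1) scale."""

    values: pd.DataFrame
    normalization_record: list[str] = field(default_factory=list)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def filter_low_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop features whose total count across all samples is below `min_total`.

    "Below" is strict: a feature summing to exactly `min_total` is kept.
    """
    totals = counts.sum(axis=1)
    kept = counts.loc[totals >= min_total]
    if kept.empty:
        warnings.warn("all features removed by the low-count filter", stacklevel=2)
    return kept


def median_center(log2_values: pd.DataFrame) -> pd.DataFrame:
    """Shift each sample so its median equals the grand median of sample medians.

    Idempotent: re-centering an already centered matrix is a no-op.
    """
    medians = log2_values.median(axis=0)
    grand = float(np.median(medians))
    return log2_values - medians + grand


def normalize_matrix(counts: pd.DataFrame) -> ExpressionMatrix:
    """log2(count+1) transform, then per-sample median centering.

    Each sample is shifted so its median equals the grand median of the
    per-sample medians; the operation is idempotent. Single-feature
    matrices skip the median step (a per-feature shift would erase the
    signal).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    log2 = np.log2(counts.astype(float) + 1.0)
    record = ["log2(count+1)"]
    if len(log2) < 2:
        warnings.warn("single-feature matrix: median normalization skipped", stacklevel=2)
        return ExpressionMatrix(log2, record)
    log2 = median_center(log2)
    record.append("per-sample median centering")
    return ExpressionMatrix(log2, record)


def _group_values(matrix: ExpressionMatrix, design: DoseDesign) -> list[tuple[float, np.ndarray]]:
    """Per-dose sub-matrices (features × replicates), ascending dose."""
    return [
        (d, matrix.values[ids].to_numpy()) for d, ids in design.groups()
    ]


def anova_prefilter(
    matrix: ExpressionMatrix,
    design: DoseDesign,
    p_max: float = 0.05,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """One-way ANOVA across dose groups plus a max-fold-change screen.

    A feature passes when the ANOVA p-value is ≤ `p_max` AND the largest
    absolute linear fold change of any positive-dose group mean versus
    the control mean is ≥ `fc_min`. Fold change is computed on group
    means in log2 space and back-transformed; magnitude means
    max(FC, 1/FC).

    Degenerate features with zero within-group variance everywhere get
    p = 0 if any group mean differs from another, else p = 1.
    """
    groups = _group_values(matrix, design)
    if len(groups) < 2 or any(g.shape[1] < 2 for _, g in groups):
        raise ValueError("prefilter needs >= 2 dose groups with >= 2 replicates each")
    arrays = [g for _, g in groups]
    means = np.column_stack([g.mean(axis=1) for g in arrays])  # features × groups
    within_var = np.column_stack([g.var(axis=1, ddof=1) for g in arrays])

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.f_oneway(*arrays, axis=1)
    pvals = np.asarray(pvals, dtype=float)
    degenerate = (within_var == 0).all(axis=1)
    if degenerate.any():
        spread = means.max(axis=1) - means.min(axis=1)
        pvals[degenerate] = np.where(spread[degenerate] > 0, 0.0, 1.0)
    pvals = np.nan_to_num(pvals, nan=1.0)

    log2fc = means[:, 1:] - means[:, [0]]  # positive doses vs control
    max_abs_log2fc = np.abs(log2fc).max(axis=1)
    max_abs_fc = np.exp2(max_abs_log2fc)  # |FC| as max(FC, 1/FC)
    passes = (pvals <= p_max) & (max_abs_fc >= fc_min)
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "anova_p": pvals,
            "max_abs_fold_change": max_abs_fc,
            "passes": passes,
        }
    ).set_index("feature_id")


def differential_expression(
    matrix: ExpressionMatrix,
    design: DoseDesign,
    dose: float,
    fdr_max: float = 0.05,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Welch t-test of one positive dose group against the vehicle control.

    Returns per-feature log2 fold change, raw p, BH-adjusted FDR and the
    differential-expression call (FDR < `fdr_max` and |FC| > `fc_min`).
    """
    if dose not in design.positive_doses:
        raise ValueError(f"dose {dose} is not a positive dose of the design")
    ctrl_ids = design.samples_at(0.0)
    trt_ids = design.samples_at(dose)
    for name, ids in (("control", ctrl_ids), (f"dose {dose}", trt_ids)):
        if len(ids) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    ctrl = matrix.values[ctrl_ids].to_numpy()
    trt = matrix.values[trt_ids].to_numpy()
    lfc = trt.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    # zero-variance, zero-difference features are exactly null
    pvals[np.isnan(pvals)] = np.where(lfc[np.isnan(pvals)] == 0, 1.0, 0.0)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    is_deg = (fdr < fdr_max) & (np.abs(lfc) > np.log2(fc_min))
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "dose_uM": dose,
            "log2_fold_change": lfc,
            "raw_p": pvals,
            "fdr": fdr,
            "is_deg": is_deg,
        }
    ).set_index("feature_id")


def deg_counts(
    matrix: ExpressionMatrix,
    design: DoseDesign,
    fdr_max: float = 0.05,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Up/down differentially-expressed feature counts per positive dose."""
    rows = []
    for dose in design.positive_doses:
        de = differential_expression(matrix, design, dose, fdr_max, fc_min)
        deg = de[de["is_deg"]]
        rows.append(
            {
                "chemical": design.chemical,
                "dose_uM": dose,
                "n_up": int((deg["log2_fold_change"] > 0).sum()),
                "n_down": int((deg["log2_fold_change"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows)
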