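"""PSI quantification and differential-splicing calls.

PSI (percent spliced in) is 100 · inclusion / (inclusion + exclusion)
junction reads, reported per event per sample when coverage reaches a
minimum read count. Differential splicing between a treated group and
the vehicle control combines two criteria:

* a point-estimate threshold |ΔPSI| > 5 percentage points, where ΔPSI
  is the difference of group means of per-replicate PSI; and
* a credible-interval criterion MV_ΔPSI > 0: each group's inclusion
  ratio gets a replicate-aware posterior — an equal-weight mixture of
  the per-replicate Beta(inc+1, exc+1) posteriors, sampled by drawing a
  covered replicate uniformly and then from its Beta — so biological
  spread between replicates widens the interval. MV is the distance
  from zero to the nearer endpoint of the central 95% credible interval
  of treated − control ΔPSI draws when that interval excludes zero
  (0 otherwise). MV > 0 removes events whose apparent shift is not
  supported at the 95% credible level given both read-sampling and
  replicate variability.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import DoseDesign

logger = logging.getLogger(__name__)

__all__ = [
    "compute_psi_table",
    "diff_splicing",
    "diff_splicing_by_dose",
    "tally_event_changes",
]

EVENT_TYPES = ("EX", "IR", "ALT3", "ALT5")


def _group_rng(seed: int, sample_ids: list[str]) -> np.random.Generator:
    """Generator keyed to (seed, sample set) — role-independent."""
    import zlib

    key = zlib.crc32(",".join(sorted(sample_ids)).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def compute_psi_table(events: pd.DataFrame, min_coverage: int = 10) -> pd.DataFrame:
    """Attach per-sample PSI to a long-format event table.

    PSI is left missing (NaN) where inclusion + exclusion reads fall
    below `min_coverage`.
    """
    ev = events.copy()
    inc = ev["inc_reads"].to_numpy(dtype=float)
    exc = ev["exc_reads"].to_numpy(dtype=float)
    if (inc < 0).any() or (exc < 0).any():
        raise ValueError("negative junction read counts")
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total >= min_coverage, 100.0 * inc / total, np.nan)
    ev["psi"] = psi
    return ev


def diff_splicing(
    events: pd.DataFrame,
    control_samples: list[str],
    treated_samples: list[str],
    min_coverage: int = 10,
    dpsi_min: float = 5.0,
    cred_level: float = 0.95,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Call differential splicing for one treated group versus control.

    Per event: ΔPSI point estimate = mean of covered treated replicate
    PSIs − mean of covered control replicate PSIs; each group's
    posterior is the equal-weight mixture of its covered replicates'
    Beta(inc + 1, exc + 1) posteriors, and mv_dpsi_95 summarizes the
    central `cred_level` interval of treated − control posterior draws.
    Significant ⇔ |ΔPSI| > `dpsi_min` and mv_dpsi_95 > 0.

    Events with no covered replicate in either group are skipped.
    """
    if seed is None:
        raise ValueError("seed is required (Monte-Carlo credible intervals)")
    # One stream per group, keyed to the group's sample set rather than its
    # role, so exchanging the control/treated labels exactly negates the
    # posterior ΔPSI draws (label-swap antisymmetry).
    rng_ctrl = _group_rng(seed, control_samples)
    rng_trt = _group_rng(seed, treated_samples)
    psi_tab = compute_psi_table(events, min_coverage=min_coverage)
    covered = psi_tab[psi_tab["psi"].notna()]
    ctrl = covered[covered["sample_id"].isin(control_samples)]
    trt = covered[covered["sample_id"].isin(treated_samples)]

    def _group_stats(sub: pd.DataFrame) -> pd.DataFrame:
        g = sub.groupby("event_id")
        return pd.DataFrame(
            {
                "mean_psi": g["psi"].mean(),
                "n_rep": g["psi"].size(),
            }
        )

    cs, ts = _group_stats(ctrl), _group_stats(trt)
    all_events = covered[["event_id", "gene_id", "event_type"]].drop_duplicates("event_id")
    shared = cs.index.intersection(ts.index)
    skipped = set(all_events["event_id"]) - set(shared)
    for ev_id in sorted(skipped):
        logger.info("event %s skipped: no covered replicates in one group", ev_id)
    cs, ts = cs.loc[shared], ts.loc[shared]

    dpsi_point = (ts["mean_psi"] - cs["mean_psi"]).to_numpy()

    def _mixture_draws(sub: pd.DataFrame, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Per event: draws from the replicate-mixture posterior (as PSI fraction)."""
        out = {}
        for ev_id, grp in sub.groupby("event_id", sort=True):
            a = grp["inc_reads"].to_numpy(dtype=float) + 1.0
            b = grp["exc_reads"].to_numpy(dtype=float) + 1.0
            idx = rng.integers(len(a), size=n_draws) if len(a) > 1 else np.zeros(n_draws, int)
            out[ev_id] = rng.beta(a[idx], b[idx])
        return out

    draws_c = _mixture_draws(ctrl[ctrl["event_id"].isin(shared)], rng_ctrl)
    draws_t = _mixture_draws(trt[trt["event_id"].isin(shared)], rng_trt)

    lo_q, hi_q = (1 - cred_level) / 2, 1 - (1 - cred_level) / 2
    q_lo = np.empty(len(shared))
    q_hi = np.empty(len(shared))
    for i, ev_id in enumerate(shared):
        delta = 100.0 * (draws_t[ev_id] - draws_c[ev_id])
        q_lo[i], q_hi[i] = np.quantile(delta, [lo_q, hi_q])

    excludes_zero = (q_lo > 0) | (q_hi < 0)
    mv = np.where(excludes_zero, np.minimum(np.abs(q_lo), np.abs(q_hi)), 0.0)
    significant = (np.abs(dpsi_point) > dpsi_min) & (mv > 0)

    meta = all_events.set_index("event_id").loc[shared]
    return pd.DataFrame(
        {
            "event_id": shared,
            "gene_id": meta["gene_id"].to_numpy(),
            "event_type": meta["event_type"].to_numpy(),
            "dpsi_point": dpsi_point,
            "mv_dpsi_95": mv,
            "significant": significant,
            "direction": np.where(dpsi_point >= 0, "up", "down"),
            "n_rep_control": cs["n_rep"].to_numpy(),
            "n_rep_treated": ts["n_rep"].to_numpy(),
        }
    ).reset_index(drop=True)


def diff_splicing_by_dose(
    events: pd.DataFrame,
    design: DoseDesign,
    seed: int,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`diff_splicing` for every positive dose against control."""
    ctrl = design.samples_at(0.0)
    out = []
    rng = np.random.default_rng(seed)
    for dose in design.positive_doses:
        res = diff_splicing(
            events,
            control_samples=ctrl,
            treated_samples=design.samples_at(dose),
            seed=int(rng.integers(0, 2**31 - 1)),
            **kwargs,
        )
        res.insert(1, "dose_uM", dose)
        out.append(res)
    return pd.concat(out, ignore_index=True)


def tally_event_changes(results_by_dose: pd.DataFrame) -> pd.DataFrame:
    """Count significant events per dose × event type × direction.

    The output carries the full dose × type × direction index, with
    zeros where nothing was called.
    """
    doses = sorted(results_by_dose["dose_uM"].unique())
    idx = pd.MultiIndex.from_product(
        [doses, EVENT_TYPES, ["up", "down"]], names=["dose_uM", "event_type", "direction"]
    )
    sig = results_by_dose[results_by_dose["significant"]]
    counts = (
        sig.groupby(["dose_uM", "event_type", "direction"]).size()
        .reindex(idx, fill_value=0)
        .rename("n_events")
        .reset_index()
    )
    return counts
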