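"""Synthetic dose-response experiments with recorded ground truth.

Emulates the statistical substrate of an in-vitro concentration-response
RNA-seq study: a vehicle control plus a half-log dilution series (the
study layout is 9 positive concentrations × 4 biological replicates),
negative-binomially dispersed gene/intron counts whose log2 means follow
known dose-response curves, and binomial junction reads whose
percent-spliced-in (PSI) follows known ΔPSI trajectories.

Every simulated feature/event carries its generating truth, including
the dose at which the noiseless mean curve departs from control by one
generating residual SD — the same benchmark-response definition the
fitting engine uses — so parameter recovery is directly testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import bmd_from_curve, evaluate_curve
from .design import DoseDesign, build_design

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTruth",
    "EventTruth",
    "make_feature_truths",
    "make_event_truths",
    "make_gene_sets",
    "lognormal_size_factors",
    "simulate_counts",
    "simulate_splicing",
    "simulate_study",
    "StudyScenario",
    "write_fixtures",
]

EVENT_TYPES = ("EX", "IR", "ALT3", "ALT5")


@dataclass(frozen=True)
class FeatureTruth:
    """Generating truth for one count feature (gene or intron).

    curve_params are on the log2 scale; true_bmd is the dose where the
    noiseless mean departs from the control mean by residual_sd (None
    for null features or curves that never reach that departure).
    """

    feature_id: str
    curve_family: str
    curve_params: tuple[float, ...]
    residual_sd: float
    direction: str  # "up" | "down"
    true_bmd: float | None = None

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.curve_family == "null" and self.true_bmd is not None:
            raise ValueError("null features carry no true_bmd")

    def mean_log2(self, dose):
        return evaluate_curve(self.curve_family, self.curve_params, dose)


@dataclass(frozen=True)
class EventTruth:
    """Generating truth for one alternative-splicing event.

    dpsi_params parameterize a saturating ΔPSI trajectory
    ΔPSI(d) = amplitude · d^n / (k^n + d^n) in percentage points;
    the PSI trajectory baseline_psi + ΔPSI(d) is clipped to [0, 100].
    """

    event_id: str
    gene_id: str
    event_type: str
    baseline_psi: float
    dpsi_params: tuple[float, float, float]  # (amplitude, k, n); amplitude 0 => null
    read_depth: float

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"event_type must be one of {EVENT_TYPES}")
        if not 0 <= self.baseline_psi <= 100:
            raise ValueError("baseline_psi must lie in [0, 100]")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")

    def psi_at(self, dose, warn: bool = True) -> np.ndarray:
        amp, k, n = self.dpsi_params
        d = np.asarray(dose, dtype=float)
        if amp == 0 or k <= 0:
            traj = np.full_like(d, self.baseline_psi)
        else:
            traj = self.baseline_psi + amp * d**n / (k**n + d**n)
        clipped = np.clip(traj, 0.0, 100.0)
        if warn and np.any(clipped != traj):
            logger.warning("event %s: PSI trajectory clipped to [0, 100]", self.event_id)
        return clipped


# ---------------------------------------------------------------------------
# truth builders
# ---------------------------------------------------------------------------

def _true_bmd(family, params, residual_sd, max_dose):
    if family == "null":
        return None
    return bmd_from_curve(family, params, residual_sd, max_dose)


def make_feature_truths(
    design: DoseDesign,
    n_features: int,
    responsive_fraction: float = 0.3,
    residual_sd: float = 0.25,
    effect_range: tuple[float, float] = (1.0, 3.0),
    baseline_log2_range: tuple[float, float] = (4.0, 10.0),
    k_quantile_range: tuple[float, float] = (0.1, 0.9),
    families: tuple[str, ...] = ("hill", "linear", "exp", "power"),
    seed: int = 0,
    prefix: str = "G",
) -> list[FeatureTruth]:
    """Draw a mixed panel of null and dose-responsive feature truths.

    Responsive features get a random family, direction, a top-of-range
    effect magnitude in ``effect_range`` (log2 units), and — for
    saturating families — a half-max dose placed log-uniformly between
    the ``k_quantile_range`` quantiles of the positive dose range.
    """
    rng = np.random.default_rng(seed)
    d_lo, d_hi = design.min_positive_dose, design.max_dose
    lk_lo = np.log10(d_lo) + k_quantile_range[0] * (np.log10(d_hi) - np.log10(d_lo))
    lk_hi = np.log10(d_lo) + k_quantile_range[1] * (np.log10(d_hi) - np.log10(d_lo))
    truths: list[FeatureTruth] = []
    n_resp = int(round(n_features * responsive_fraction))
    width = len(str(max(n_features, 1)))
    for i in range(n_features):
        fid = f"{prefix}{i:0{width}d}"
        a = rng.uniform(*baseline_log2_range)
        if i >= n_resp:
            truths.append(
                FeatureTruth(fid, "null", (a,), residual_sd, "up", None)
            )
            continue
        fam = families[rng.integers(len(families))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        eff = sign * rng.uniform(*effect_range)
        k = 10 ** rng.uniform(lk_lo, lk_hi)
        if fam == "linear":
            params = (a, eff / d_hi)
        elif fam == "power":
            p = rng.uniform(1.0, 2.0)
            params = (a, eff / d_hi**p, p)
        elif fam == "exp":
            c = 1.0 / k
            params = (a, eff / (1.0 - np.exp(-c * d_hi)), c)
        elif fam == "hill":
            n_hill = rng.uniform(1.0, 3.0)
            v = eff * (k**n_hill + d_hi**n_hill) / d_hi**n_hill
            params = (a, v, k, n_hill)
        else:
            raise ValueError(f"unsupported generating family {fam!r}")
        bmd = _true_bmd(fam, params, residual_sd, d_hi)
        truths.append(
            FeatureTruth(
                fid, fam, tuple(float(p) for p in params), residual_sd,
                "up" if eff > 0 else "down", bmd,
            )
        )
    return truths


def make_event_truths(
    design: DoseDesign,
    n_events: int,
    responsive_fraction: float = 0.4,
    dpsi_range: tuple[float, float] = (10.0, 40.0),
    read_depth: float = 100.0,
    k_quantile_range: tuple[float, float] = (0.1, 0.9),
    gene_ids: list[str] | None = None,
    type_weights: dict[str, float] | None = None,
    seed: int = 0,
    prefix: str = "EV",
) -> list[EventTruth]:
    """Draw splicing-event truths (null and responsive, four event types).

    Event-type frequencies default to the empirical pattern that intron
    retention and exon skipping dominate chemically induced splicing
    responses, with alternative splice-site usage rarer.
    """
    rng = np.random.default_rng(seed)
    weights = type_weights or {"IR": 0.4, "EX": 0.35, "ALT3": 0.125, "ALT5": 0.125}
    types = list(weights)
    p = np.array([weights[t] for t in types], dtype=float)
    p /= p.sum()
    d_lo, d_hi = design.min_positive_dose, design.max_dose
    lk_lo = np.log10(d_lo) + k_quantile_range[0] * (np.log10(d_hi) - np.log10(d_lo))
    lk_hi = np.log10(d_lo) + k_quantile_range[1] * (np.log10(d_hi) - np.log10(d_lo))
    n_resp = int(round(n_events * responsive_fraction))
    width = len(str(max(n_events, 1)))
    truths = []
    for i in range(n_events):
        etype = types[rng.choice(len(types), p=p)]
        gid = (
            gene_ids[rng.integers(len(gene_ids))]
            if gene_ids
            else f"G{i:0{width}d}"
        )
        base = rng.uniform(15.0, 85.0)
        if i < n_resp:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            amp = sign * rng.uniform(*dpsi_range)
            # keep the trajectory inside [0, 100]
            amp = float(np.clip(amp, -base, 100.0 - base))
            k = 10 ** rng.uniform(lk_lo, lk_hi)
            n_hill = rng.uniform(1.0, 3.0)
            params = (amp, k, n_hill)
        else:
            params = (0.0, 1.0, 1.0)
        truths.append(
            EventTruth(f"{prefix}{i:0{width}d}", gid, etype, base, params, read_depth)
        )
    return truths


def make_gene_sets(
    gene_ids: list[str],
    responsive_genes: list[str],
    n_enriched: int = 25,
    n_background: int = 35,
    set_size: tuple[int, int] = (15, 40),
    enriched_fraction: float = 0.7,
    seed: int = 0,
) -> dict[str, tuple[str, list[str]]]:
    """Synthetic GMT-style gene sets: name -> (description, genes).

    Enriched sets draw ``enriched_fraction`` of members from the
    responsive genes, background sets draw uniformly from the universe.
    """
    rng = np.random.default_rng(seed)
    resp = list(responsive_genes)
    other = [g for g in gene_ids if g not in set(resp)]
    sets: dict[str, tuple[str, list[str]]] = {}
    for i in range(n_enriched):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        n_r = min(len(resp), int(round(size * enriched_fraction)))
        members = list(rng.choice(resp, size=n_r, replace=False))
        pool = [g for g in other if g not in members]
        n_o = min(len(pool), size - n_r)
        members += list(rng.choice(pool, size=n_o, replace=False))
        sets[f"SET_ENR_{i:03d}"] = ("synthetic responsive-biased set", sorted(members))
    for i in range(n_background):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        members = list(rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False))
        sets[f"SET_BG_{i:03d}"] = ("synthetic background set", sorted(set(members)))
    return sets


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def lognormal_size_factors(
    design: DoseDesign, sigma: float = 0.1, seed: int | None = None
) -> np.ndarray:
    """Per-sample log-normal library-size factors (median 1).

    Intended to exercise the median-normalization step; pass the result
    to :func:`simulate_counts`.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(0.0, sigma, size=len(design.sample_ids)))


def simulate_counts(
    design: DoseDesign,
    feature_truths: list[FeatureTruth],
    nb_dispersion: float = 0.05,
    library_size_factors: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a feature × sample count matrix around the truth curves.

    The count for feature i in sample j is negative-binomial with mean
    ``m = sf_j · 2^(μ_i(dose_j))`` and variance ``m + dispersion·m²``
    (size parameter 1/dispersion). Returns (counts, truth_table);
    identical seeds give identical output.
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    if seed is None:
        raise ValueError("seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    samples = design.sample_table
    doses = samples["dose_uM"].to_numpy()
    sf = (
        np.ones(len(samples))
        if library_size_factors is None
        else np.asarray(library_size_factors, dtype=float)
    )
    if sf.shape != (len(samples),):
        raise ValueError("library_size_factors must have one entry per sample")
    n_nb = 1.0 / nb_dispersion  # NB size: var = m + m^2/n
    rows = np.empty((len(feature_truths), len(samples)), dtype=np.int64)
    for i, ft in enumerate(feature_truths):
        mu = np.asarray(ft.mean_log2(doses), dtype=float)
        m = sf * np.exp2(mu)
        p = n_nb / (n_nb + m)
        rows[i] = rng.negative_binomial(n_nb, p)
    counts = pd.DataFrame(
        rows,
        index=pd.Index([ft.feature_id for ft in feature_truths], name="feature_id"),
        columns=list(samples["sample_id"]),
    )
    return counts, truth_table(feature_truths)


def truth_table(feature_truths: list[FeatureTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [ft.feature_id for ft in feature_truths],
            "curve_family": [ft.curve_family for ft in feature_truths],
            "curve_params": [";".join(f"{p:.10g}" for p in ft.curve_params) for ft in feature_truths],
            "residual_sd": [ft.residual_sd for ft in feature_truths],
            "direction": [ft.direction for ft in feature_truths],
            "true_bmd": [ft.true_bmd if ft.true_bmd is not None else np.nan for ft in feature_truths],
        }
    )


def event_truth_table(event_truths: list[EventTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in event_truths],
            "gene_id": [e.gene_id for e in event_truths],
            "event_type": [e.event_type for e in event_truths],
            "baseline_psi": [e.baseline_psi for e in event_truths],
            "dpsi_amplitude": [e.dpsi_params[0] for e in event_truths],
            "dpsi_k": [e.dpsi_params[1] for e in event_truths],
            "dpsi_n": [e.dpsi_params[2] for e in event_truths],
            "read_depth": [e.read_depth for e in event_truths],
        }
    )


def simulate_splicing(
    design: DoseDesign,
    event_truths: list[EventTruth],
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample junction reads for each event × sample (long format).

    Per sample: total reads T ~ Poisson(read_depth), inclusion reads
    ~ Binomial(T, PSI(dose)/100), exclusion = T − inclusion.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    samples = design.sample_table
    doses = samples["dose_uM"].to_numpy()
    recs = []
    for ev in event_truths:
        psi = ev.psi_at(doses) / 100.0
        total = rng.poisson(ev.read_depth, size=len(samples))
        inc = rng.binomial(total, psi)
        for j, sid in enumerate(samples["sample_id"]):
            recs.append(
                (ev.event_id, ev.gene_id, ev.event_type, sid, int(inc[j]), int(total[j] - inc[j]))
            )
    return pd.DataFrame(
        recs,
        columns=["event_id", "gene_id", "event_type", "sample_id", "inc_reads", "exc_reads"],
    )


# ---------------------------------------------------------------------------
# full-study scenario
# ---------------------------------------------------------------------------

@dataclass
class StudyScenario:
    """One chemical's complete synthetic dataset with ground truth."""

    design: DoseDesign
    gene_counts: pd.DataFrame
    intron_counts: pd.DataFrame
    events: pd.DataFrame
    gene_sets: dict[str, tuple[str, list[str]]]
    gene_truths: list[FeatureTruth] = field(repr=False)
    intron_truths: list[FeatureTruth] = field(repr=False)
    event_truths: list[EventTruth] = field(repr=False)
    intron_to_gene: dict[str, str] = field(repr=False)


def simulate_study(
    seed: int,
    chemical: str = "chemX",
    top_dose_uM: float = 1000.0,
    n_positive_doses: int = 9,
    n_replicates: int = 4,
    n_genes: int = 500,
    n_introns: int = 200,
    n_events: int = 200,
    gene_responsive_fraction: float = 0.3,
    residual_sd: float = 0.25,
    nb_dispersion: float = 0.05,
    gene_k_quantiles: tuple[float, float] = (0.55, 0.9),
    intron_k_quantiles: tuple[float, float] = (0.25, 0.55),
    event_k_quantiles: tuple[float, float] = (0.05, 0.4),
    event_read_depth: float = 100.0,
    count_families: tuple[str, ...] = ("hill", "exp"),
) -> StudyScenario:
    """Generate the full synthetic study for one chemical.

    The scenario encodes the qualitative structure under test: gene
    expression responds mostly in the upper dose range while intron
    (retention) counts and splicing events respond from lower doses, so
    splicing-derived benchmark doses fall below expression-derived ones.
    Responsive count features use saturating families (hill/exp), whose
    half-max dose placement controls where the benchmark dose lands;
    the default quantile windows keep both modalities' true BMDs inside
    the tested dose range. Intron features attach to responsive genes
    so pathway enrichment can be compared across modalities on the same
    gene sets.
    """
    rng = np.random.default_rng(seed)
    design = build_design(top_dose_uM, n_positive_doses, n_replicates, chemical)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    gene_truths = make_feature_truths(
        design, n_genes,
        responsive_fraction=gene_responsive_fraction,
        residual_sd=residual_sd,
        k_quantile_range=gene_k_quantiles,
        families=count_families,
        seed=sub(), prefix="G",
    )
    gene_counts, _ = simulate_counts(design, gene_truths, nb_dispersion, seed=sub())

    # introns attach to responsive genes first, then fill with nulls on random genes
    resp_genes = [t.feature_id for t in gene_truths if t.curve_family != "null"]
    all_genes = [t.feature_id for t in gene_truths]
    intron_truths_raw = make_feature_truths(
        design, n_introns,
        responsive_fraction=0.5,
        residual_sd=residual_sd,
        k_quantile_range=intron_k_quantiles,
        baseline_log2_range=(3.0, 8.0),
        families=count_families,
        seed=sub(), prefix="I",
    )
    intron_to_gene: dict[str, str] = {}
    intron_truths = []
    host_resp = list(rng.permutation(resp_genes)) if resp_genes else []
    for idx, t in enumerate(intron_truths_raw):
        if t.curve_family != "null" and host_resp:
            host = host_resp[idx % len(host_resp)]
        else:
            host = all_genes[rng.integers(len(all_genes))]
        iid = f"{host}:intron{idx}"
        intron_truths.append(
            FeatureTruth(iid, t.curve_family, t.curve_params, t.residual_sd,
                         t.direction, t.true_bmd)
        )
        intron_to_gene[iid] = host
    intron_counts, _ = simulate_counts(design, intron_truths, nb_dispersion, seed=sub())

    event_truths = make_event_truths(
        design, n_events,
        responsive_fraction=0.4,
        k_quantile_range=event_k_quantiles,
        read_depth=event_read_depth,
        gene_ids=all_genes,
        seed=sub(),
    )
    events = simulate_splicing(design, event_truths, seed=sub())

    gene_sets = make_gene_sets(all_genes, resp_genes, seed=sub())
    return StudyScenario(
        design=design,
        gene_counts=gene_counts,
        intron_counts=intron_counts,
        events=events,
        gene_sets=gene_sets,
        gene_truths=gene_truths,
        intron_truths=intron_truths,
        event_truths=event_truths,
        intron_to_gene=intron_to_gene,
    )


def write_fixtures(
    outdir: str | Path,
    scenario: StudyScenario | None = None,
    seed: int = 0,
    **scenario_kwargs,
) -> dict[str, Path]:
    """Write a complete synthetic study to TSV/GMT files.

    Emits counts.tsv (genes), intron_counts.tsv, metadata.tsv,
    events.tsv, gene_sets.gmt, feature_truth.tsv and event_truth.tsv;
    all round-trip through :mod:`toxpod.io`.
    """
    from . import io as tio

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        if scenario is None:
            scenario = simulate_study(seed=seed, **scenario_kwargs)
        paths = {
            "counts": outdir / "counts.tsv",
            "intron_counts": outdir / "intron_counts.tsv",
            "metadata": outdir / "metadata.tsv",
            "events": outdir / "events.tsv",
            "gene_sets": outdir / "gene_sets.gmt",
            "feature_truth": outdir / "feature_truth.tsv",
            "event_truth": outdir / "event_truth.tsv",
        }
        tio.write_counts(scenario.gene_counts, paths["counts"])
        tio.write_counts(scenario.intron_counts, paths["intron_counts"])
        scenario.design.to_frame().to_csv(paths["metadata"], sep="\t", index=False)
        scenario.events.to_csv(paths["events"], sep="\t", index=False)
        tio.write_gmt(scenario.gene_sets, paths["gene_sets"])
        truth_table(scenario.gene_truths + scenario.intron_truths).to_csv(
            paths["feature_truth"], sep="\t", index=False
        )
        event_truth_table(scenario.event_truths).to_csv(
            paths["event_truth"], sep="\t", index=False
        )
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {outdir}: {exc}") from exc
    return paths
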