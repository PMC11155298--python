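"""Gene-set over-representation, pathway BMD aggregation and POD derivation.

Gene-level BMD/BMDL/BMDU values (medians over a gene's features) feed a
two-tailed Fisher exact over-representation test of the BMD-passing
query genes against each gene set. A pathway is significant when it
holds at least 5 query genes and Fisher p < 0.05 (raw, matching common
benchmark-dose practice; a BH column is emitted for reference). The
point of departure (POD) is the mean of the median-BMDL values over the
20 most sensitive significant pathways (ranked by median BMD), falling
back to the median over all significant pathways when fewer than 20
exist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "PodSummary",
    "aggregate_to_genes",
    "enrich_pathways",
    "derive_pod",
    "accumulation_curve",
    "upset_counts",
    "modality_pairs",
    "network_edges",
    "compare_modalities_and_overlaps",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe for enrichment."""

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str]

    def __post_init__(self):
        if not self.universe:
            raise ValueError("universe must be non-empty")
        self.sets = {
            name: (desc, sorted(set(genes))) for name, (desc, genes) in self.sets.items()
        }


def aggregate_to_genes(
    bmd_results: pd.DataFrame,
    feature_to_gene: dict[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Collapse passing feature-level BMD results to gene level (medians).

    With no mapping, features are taken to be genes (expression
    modality). Features without a mapping entry are dropped with a log
    message. Genes with a single feature keep its values unchanged.
    """
    passing = bmd_results[bmd_results["filter_status"] == "pass"].copy()
    if feature_to_gene is None:
        passing["gene_id"] = passing["feature_id"]
    else:
        mapping = pd.Series(feature_to_gene)
        genes = passing["feature_id"].map(mapping)
        unmapped = passing.loc[genes.isna(), "feature_id"]
        for fid in unmapped:
            logger.info("feature %s has no gene mapping; dropped", fid)
        passing = passing.loc[genes.notna()].copy()
        passing["gene_id"] = genes.dropna().to_numpy()
    agg = (
        passing.groupby("gene_id")[["bmd", "bmdl", "bmdu"]].median().reset_index()
    )
    n_feat = passing.groupby("gene_id").size().rename("n_features").reset_index()
    return agg.merge(n_feat, on="gene_id")


def enrich_pathways(
    gene_bmds: pd.DataFrame,
    collection: GeneSetCollection,
    p_max: float = 0.05,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Two-tailed Fisher over-representation of query genes in each set.

    The query is the gene list of `gene_bmds` (BMD-passing genes); query
    genes absent from the universe are dropped with a warning. Each
    pathway row carries the Fisher p, the median BMD/BMDL/BMDU over the
    query genes in the set, and the significance call (p < `p_max` and
    at least `min_genes` query genes in the set).
    """
    universe = set(collection.universe)
    query = set(gene_bmds["gene_id"])
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query genes not in the universe were dropped", stacklevel=2
        )
        query &= universe
    n_u, n_q = len(universe), len(query)
    values = gene_bmds.set_index("gene_id")[["bmd", "bmdl", "bmdu"]]

    rows = []
    for name, (desc, genes) in collection.sets.items():
        members = set(genes) & universe
        overlap = sorted(query & members)
        a = len(overlap)
        b = n_q - a
        c = len(members) - a
        d = n_u - n_q - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        med = values.loc[overlap].median() if overlap else pd.Series(
            {"bmd": np.nan, "bmdl": np.nan, "bmdu": np.nan}
        )
        rows.append(
            {
                "set_name": name,
                "description": desc,
                "n_set": len(members),
                "n_query_in_set": a,
                "fisher_p": float(p),
                "median_bmd": med["bmd"],
                "median_bmdl": med["bmdl"],
                "median_bmdu": med["bmdu"],
                "significant": (p < p_max) and (a >= min_genes),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        _, bh, _, _ = multipletests(out["fisher_p"], method="fdr_bh")
        out["fisher_p_bh"] = bh
    else:
        out["fisher_p_bh"] = pd.Series(dtype=float)
    return out


@dataclass
class PodSummary:
    """Pathway-derived point of departure for one chemical × modality."""

    chemical: str
    modality: str
    n_significant_pathways: int
    pod_bmdl: float | None
    rule_used: str  # "mean_of_20_lowest" | "median_all" | "undefined"
    mean_bmdl_top20: float | None = None
    mean_bmdl_all: float | None = None
    median_bmdl_all: float | None = None

    def to_frame(self) -> pd.DataFrame:
        row = {k: (np.nan if v is None else v) for k, v in self.__dict__.items()}
        return pd.DataFrame([row])


def derive_pod(
    pathways: pd.DataFrame,
    chemical: str = "",
    modality: str = "",
    top_k: int = 20,
) -> PodSummary:
    """POD from significant pathways ranked by sensitivity (median BMD).

    With at least `top_k` significant pathways the POD is the mean of
    the `top_k` lowest pathways' median BMDLs; with fewer it falls back
    to the median BMDL over all significant pathways. Both the top-k and
    all-pathway means are reported alongside.
    """
    sig = pathways[pathways["significant"]].copy()
    n = len(sig)
    if n == 0:
        return PodSummary(chemical, modality, 0, None, "undefined")
    sig = sig.sort_values("median_bmd", kind="mergesort")
    mean_all = float(sig["median_bmdl"].mean())
    median_all = float(sig["median_bmdl"].median())
    if n >= top_k:
        top = sig.head(top_k)
        mean_top = float(top["median_bmdl"].mean())
        return PodSummary(
            chemical, modality, n, mean_top, "mean_of_20_lowest",
            mean_bmdl_top20=mean_top, mean_bmdl_all=mean_all, median_bmdl_all=median_all,
        )
    return PodSummary(
        chemical, modality, n, median_all, "median_all",
        mean_bmdl_top20=None, mean_bmdl_all=mean_all, median_bmdl_all=median_all,
    )


def accumulation_curve(bmd_values, grid=None) -> pd.DataFrame:
    """Accumulation plot table: count of BMD values at or below each dose.

    The grid defaults to the sorted unique BMD values; the curve is
    non-decreasing and right-continuous on its grid.
    """
    values = np.asarray(bmd_values, dtype=float)
    values = values[np.isfinite(values)]
    if (values <= 0).any():
        raise ValueError("BMD values must be positive")
    if grid is None:
        grid = np.unique(values)
    grid = np.asarray(grid, dtype=float)
    counts = np.searchsorted(np.sort(values), grid, side="right")
    return pd.DataFrame({"dose_uM": grid, "n_at_or_below": counts.astype(int)})


def upset_counts(sets_by_name: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection cardinalities for every non-empty combination.

    Upset-plot semantics: each element is counted once, in the row for
    the exact combination of sets containing it.
    """
    names = list(sets_by_name)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(sets_by_name[n]) for n in combo))
            outside = set.union(
                set(), *(set(sets_by_name[n]) for n in names if n not in combo)
            )
            exclusive = inside - outside
            if exclusive:
                rows.append({"combination": "&".join(combo), "degree": r, "count": len(exclusive)})
    return pd.DataFrame(rows, columns=["combination", "degree", "count"])


def modality_pairs(
    expression_pathways: pd.DataFrame,
    intron_pathways: pd.DataFrame,
    expression_gene_bmds: pd.DataFrame | None = None,
    intron_gene_bmds: pd.DataFrame | None = None,
    collection: GeneSetCollection | None = None,
) -> pd.DataFrame:
    """Paired pathway BMDs for pathways significant in both modalities.

    Each row holds the pathway's mean gene BMD per modality (mean over
    the modality's query genes in the set) when gene tables are given,
    plus the median BMDs carried by the pathway tables.
    """
    e = expression_pathways[expression_pathways["significant"]].set_index("set_name")
    i = intron_pathways[intron_pathways["significant"]].set_index("set_name")
    shared = e.index.intersection(i.index)
    rows = []
    for name in shared:
        row = {
            "set_name": name,
            "expression_median_bmd": e.loc[name, "median_bmd"],
            "intron_median_bmd": i.loc[name, "median_bmd"],
        }
        if (
            expression_gene_bmds is not None
            and intron_gene_bmds is not None
            and collection is not None
        ):
            genes = set(collection.sets[name][1])
            for label, tab in (
                ("expression_mean_bmd", expression_gene_bmds),
                ("intron_mean_bmd", intron_gene_bmds),
            ):
                in_set = tab[tab["gene_id"].isin(genes)]
                row[label] = float(in_set["bmd"].mean()) if len(in_set) else np.nan
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "set_name", "expression_median_bmd", "intron_median_bmd",
            "expression_mean_bmd", "intron_mean_bmd",
        ][: 5 if rows and "expression_mean_bmd" in rows[0] else 3],
    )


def network_edges(pathway_tables_by_condition: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pathway—condition edge list (weight = pathway median BMD).

    Emitted as a table for external network rendering; only significant
    pathways contribute edges.
    """
    rows = []
    for condition, tab in pathway_tables_by_condition.items():
        for _, r in tab[tab["significant"]].iterrows():
            rows.append(
                {
                    "pathway": r["set_name"],
                    "condition": condition,
                    "median_bmd": r["median_bmd"],
                }
            )
    return pd.DataFrame(rows, columns=["pathway", "condition", "median_bmd"])


def compare_modalities_and_overlaps(
    pathway_tables_by_condition: dict[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Overlap counts, modality pairs and the network edge list in one call.

    Conditions named `<chemical>:expression` and `<chemical>:intron`
    are paired per chemical for the modality table.
    """
    if len(pathway_tables_by_condition) < 2:
        raise ValueError("need at least two named pathway tables")
    sig_sets = {
        name: set(tab.loc[tab["significant"], "set_name"])
        for name, tab in pathway_tables_by_condition.items()
    }
    pairs = []
    chems = {
        n.split(":")[0]
        for n in pathway_tables_by_condition
        if ":" in n
    }
    for chem in sorted(chems):
        e_key, i_key = f"{chem}:expression", f"{chem}:intron"
        if e_key in pathway_tables_by_condition and i_key in pathway_tables_by_condition:
            p = modality_pairs(
                pathway_tables_by_condition[e_key], pathway_tables_by_condition[i_key]
            )
            p.insert(0, "chemical", chem)
            pairs.append(p)
    return {
        "upset": upset_counts(sig_sets),
        "modality_pairs": (
            pd.concat(pairs, ignore_index=True)
            if pairs
            else pd.DataFrame(
                columns=["chemical", "set_name", "expression_median_bmd", "intron_median_bmd"]
            )
        ),
        "edges": network_edges(pathway_tables_by_condition),
    }
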