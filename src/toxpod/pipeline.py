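"""End-to-end per-chemical analysis: counts → DE/prefilter → splicing →
BMD (expression + intron) → pathways → POD → report tables.

Every stage writes a TSV into the run directory; a manifest records the
effective configuration, the seed, input hashes and output hashes so a
rerun with identical inputs reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .bmd import BmdConfig, run_bmd
from .design import DoseDesign
from .pathways import (
    GeneSetCollection,
    accumulation_curve,
    aggregate_to_genes,
    compare_modalities_and_overlaps,
    derive_pod,
    enrich_pathways,
    modality_pairs,
)
from .preprocess import anova_prefilter, deg_counts, filter_low_counts, normalize_matrix
from .splicing import diff_splicing_by_dose, tally_event_changes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_report", "compare_runs"]


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds (defaults are the study values)."""

    counts: str | None = None
    intron_counts: str | None = None
    metadata: str | None = None
    events: str | None = None
    gene_sets: str | None = None
    chemical: str | None = None
    out_dir: str = "toxpod_run"
    seed: int = 0
    # preprocessing / DE
    min_total_counts: int = 10
    deg_fdr_max: float = 0.05
    deg_fc_min: float = 1.5
    anova_p_max: float = 0.05
    anova_fc_min: float = 1.5
    # splicing
    min_coverage: int = 10
    dpsi_min: float = 5.0
    splicing_cred_level: float = 0.95
    splicing_n_draws: int = 10_000
    # BMD engine
    bmd_families: list[str] = field(
        default_factory=lambda: ["linear", "poly2", "poly3", "power", "hill", "exp3"]
    )
    bmd_n_starts: int = 10
    bmd_confidence: float = 0.95
    fit_p_min: float = 0.1
    ratio_max: float = 40.0
    # pathways / POD
    pathway_p_max: float = 0.05
    pathway_min_genes: int = 5
    pod_top_k: int = 20

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def bmd_config(self) -> BmdConfig:
        return BmdConfig(
            families=tuple(self.bmd_families),
            n_starts=self.bmd_n_starts,
            seed=self.seed,
            confidence=self.bmd_confidence,
            fit_p_min=self.fit_p_min,
            ratio_max=self.ratio_max,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
    manifest["outputs"][path.name] = _sha256(path)


def _bmd_modality(counts, design, cfg, prefilter_out, results_out, out, manifest):
    """Shared expression/intron path: filter → normalize → prefilter → BMD."""
    filtered = filter_low_counts(counts, cfg.min_total_counts)
    matrix = normalize_matrix(filtered)
    pre = anova_prefilter(matrix, design, cfg.anova_p_max, cfg.anova_fc_min)
    _write(pre.reset_index(), out / prefilter_out, manifest)
    keep = pre.index[pre["passes"]]
    sub = dataclasses.replace(matrix, values=matrix.values.loc[keep])
    results = run_bmd(sub, design, cfg.bmd_config())
    _write(results, out / results_out, manifest)
    return matrix, results


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages for one chemical; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "inputs": {}, "outputs": {}, "seed": config.seed}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        if config.metadata is None:
            raise FileNotFoundError("no metadata file configured")
        if config.counts is None:
            raise FileNotFoundError("no counts file configured")
        for key in ("counts", "intron_counts", "metadata", "events", "gene_sets"):
            p = getattr(config, key)
            if p is not None:
                p = Path(p)
                if not p.exists():
                    raise FileNotFoundError(f"input {key!r} not found: {p}")
                manifest["inputs"][key] = _sha256(p)
        meta = tio.read_metadata(config.metadata)
        design = DoseDesign.from_frame(meta, chemical=config.chemical)
        gene_counts = tio.read_counts(config.counts)

        stage("differential_expression")
        gene_matrix_all = normalize_matrix(
            filter_low_counts(gene_counts, config.min_total_counts)
        )
        degs = deg_counts(gene_matrix_all, design, config.deg_fdr_max, config.deg_fc_min)
        _write(degs, out / "deg_counts.tsv", manifest)

        stage("bmd_expression")
        _, expr_results = _bmd_modality(
            gene_counts, design, config, "prefilter_expression.tsv",
            "bmd_results_expression.tsv", out, manifest,
        )
        expr_results.insert(1, "modality", "expression")

        splicing_results = None
        if config.events is not None:
            stage("differential_splicing")
            events = tio.read_events(config.events)
            splicing_results = diff_splicing_by_dose(
                events, design, seed=config.seed,
                min_coverage=config.min_coverage, dpsi_min=config.dpsi_min,
                cred_level=config.splicing_cred_level,
                n_draws=config.splicing_n_draws,
            )
            _write(splicing_results, out / "diff_splicing.tsv", manifest)
            _write(tally_event_changes(splicing_results), out / "event_counts.tsv", manifest)

        intron_results = intron_matrix = None
        if config.intron_counts is not None:
            stage("bmd_intron")
            intron_counts = tio.read_counts(config.intron_counts)
            intron_matrix, intron_results = _bmd_modality(
                intron_counts, design, config, "prefilter_intron.tsv",
                "bmd_results_intron.tsv", out, manifest,
            )
            intron_results.insert(1, "modality", "intron")

        stage("pathways")
        pathway_tables: dict[str, pd.DataFrame] = {}
        pods = []
        gene_tables: dict[str, pd.DataFrame] = {}
        collection = None
        if config.gene_sets is not None:
            sets = tio.read_gmt(config.gene_sets)
            for modality, results, matrix in (
                ("expression", expr_results, gene_matrix_all),
                ("intron", intron_results, intron_matrix),
            ):
                if results is None:
                    continue
                # background = all genes whose features entered the analysis
                # for this modality (the low-count-filtered matrix)
                if modality == "intron":
                    fmap = {fid: fid.split(":")[0] for fid in matrix.feature_ids}
                    universe = list(dict.fromkeys(fmap.values()))
                else:
                    fmap = None
                    universe = list(matrix.feature_ids)
                gene_bmds = aggregate_to_genes(results, fmap)
                coll = GeneSetCollection(sets=dict(sets), universe=universe)
                pathways = enrich_pathways(
                    gene_bmds, coll, config.pathway_p_max, config.pathway_min_genes
                )
                pathways.insert(0, "modality", modality)
                pathway_tables[f"{design.chemical}:{modality}"] = pathways
                gene_tables[modality] = gene_bmds
                collection = coll
                pods.append(
                    derive_pod(pathways, design.chemical, modality, config.pod_top_k).to_frame()
                )
                passing = results[results["filter_status"] == "pass"]
                _write(
                    accumulation_curve(passing["bmd"]),
                    out / f"accumulation_{modality}.tsv", manifest,
                )
            _write(
                pd.concat(pathway_tables.values(), ignore_index=True)
                if pathway_tables else pd.DataFrame(),
                out / "pathways.tsv", manifest,
            )
            _write(
                pd.concat(pods, ignore_index=True) if pods else pd.DataFrame(),
                out / "pod_summary.tsv", manifest,
            )
            if len(pathway_tables) >= 2:
                comp = compare_modalities_and_overlaps(pathway_tables)
                pairs = modality_pairs(
                    pathway_tables[f"{design.chemical}:expression"],
                    pathway_tables[f"{design.chemical}:intron"],
                    gene_tables.get("expression"),
                    gene_tables.get("intron"),
                    collection,
                )
                _write(comp["upset"], out / "upset_counts.tsv", manifest)
                _write(pairs, out / "modality_pairs.tsv", manifest)
                _write(comp["edges"], out / "network_edges.tsv", manifest)

        stage("done")
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "init"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(
            f"pipeline failed at stage {manifest['failed_stage']!r}: {exc}"
        ) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_report(run_dir: str | Path) -> pd.DataFrame:
    """Consolidated per-chemical summary from a completed run directory.

    Stacks the DEG counts per dose, significant splicing-event counts
    per dose × type, and the POD summary per modality into one long
    table (section, key columns, value); missing sections are marked.
    """
    run_dir = Path(run_dir)
    if not run_dir.exists() or not (run_dir / "manifest.json").exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run directory")
    rows = []

    def section(name, path, handler):
        p = run_dir / path
        if not p.exists():
            rows.append({"section": name, "key": "status", "value": "missing"})
            return
        handler(pd.read_csv(p, sep="\t"))

    def degs(df):
        for _, r in df.iterrows():
            rows.append(
                {"section": "deg_counts", "key": f"dose={r['dose_uM']}",
                 "value": f"up={int(r['n_up'])};down={int(r['n_down'])}"}
            )

    def events(df):
        sig = df[df["n_events"] > 0]
        for _, r in sig.iterrows():
            rows.append(
                {"section": "splicing_events",
                 "key": f"dose={r['dose_uM']};type={r['event_type']};dir={r['direction']}",
                 "value": str(int(r["n_events"]))}
            )
        if sig.empty:
            rows.append({"section": "splicing_events", "key": "status", "value": "none"})

    def pods(df):
        for _, r in df.iterrows():
            rows.append(
                {"section": "pod_summary", "key": f"modality={r['modality']}",
                 "value": f"pod_bmdl={r['pod_bmdl']};rule={r['rule_used']};"
                          f"n_pathways={int(r['n_significant_pathways'])}"}
            )

    def pairs(df):
        for _, r in df.iterrows():
            rows.append(
                {"section": "modality_comparison", "key": r["set_name"],
                 "value": f"expression_bmd={r['expression_median_bmd']:.4g};"
                          f"intron_bmd={r['intron_median_bmd']:.4g}"}
            )

    section("deg_counts", "deg_counts.tsv", degs)
    section("splicing_events", "event_counts.tsv", events)
    section("pod_summary", "pod_summary.tsv", pods)
    section("modality_comparison", "modality_pairs.tsv", pairs)
    report = pd.DataFrame(rows, columns=["section", "key", "value"])
    report.to_csv(run_dir / "report.tsv", sep="\t", index=False)
    return report


def compare_runs(run_dirs: list[str | Path], out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Cross-run pathway overlap (upset counts) and pooled edge list."""
    tables = {}
    for rd in run_dirs:
        rd = Path(rd)
        p = rd / "pathways.tsv"
        if not p.exists():
            raise FileNotFoundError(f"{rd} has no pathways.tsv")
        tab = pd.read_csv(p, sep="\t")
        cfg = RunConfig.from_yaml(rd / "config.yaml")
        for modality, sub in tab.groupby("modality"):
            tables[f"{cfg.chemical or rd.name}:{modality}"] = sub
    comp = compare_modalities_and_overlaps(tables)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comp["upset"].to_csv(out / "upset_counts.tsv", sep="\t", index=False)
    comp["edges"].to_csv(out / "network_edges.tsv", sep="\t", index=False)
    comp["modality_pairs"].to_csv(out / "modality_pairs.tsv", sep="\t", index=False)
    return comp
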