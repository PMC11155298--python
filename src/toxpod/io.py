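"""Readers/writers for the pipeline's plain-text interchange formats.

Counts are feature × sample TSVs with a `feature_id` index column;
splicing events are long-format TSVs; gene sets use the standard GMT
dialect (set name, description, then one gene per tab-separated field).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "read_events",
    "read_gmt",
    "write_gmt",
]

EVENT_COLUMNS = ["event_id", "gene_id", "event_type", "sample_id", "inc_reads", "exc_reads"]


def _open_err(path: Path, exc: Exception) -> OSError:
    return OSError(f"cannot read {path}: {exc}")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read an integer feature × sample count matrix."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
    except (OSError, ValueError) as exc:
        raise _open_err(path, exc) from exc
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts = counts.copy()
    counts.index.name = "feature_id"
    counts.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id, chemical, dose_uM, replicate)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "chemical", "dose_uM", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return meta


def read_events(path: str | Path) -> pd.DataFrame:
    """Read the long-format splicing-event read-count table."""
    path = Path(path)
    try:
        events = pd.read_csv(path, sep="\t")
    except (OSError, ValueError) as exc:
        raise _open_err(path, exc) from exc
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"{path}: events table missing columns {sorted(missing)}")
    return events


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into {set_name: (description, genes)}."""
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    try:
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                name, desc, *genes = fields
                sets[name] = (desc, [g for g in genes if g])
    except OSError as exc:
        raise _open_err(path, exc) from exc
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")
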