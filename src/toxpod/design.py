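"""Dose-response experimental designs.

A design is a set of concentrations (vehicle control at dose 0 plus a
geometric series of positive doses) crossed with biological replicates.
The canonical layout in concentration-response transcriptomics is a
half-log series: successive doses differ by a factor of sqrt(10), i.e.
0.5 units in log10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["DoseDesign", "build_design", "sig3"]

_HALF_LOG = math.sqrt(10.0)


def sig3(x: float) -> str:
    """Format a concentration to 3 significant figures for display/IDs.

    Produces the conventional style of published dose tables:
    0.316, 3.16, 31.6, 100, 316, 1000 (no exponent notation, no
    trailing zeros after the decimal point).
    """
    if x == 0:
        return "0"
    s = f"{x:.3g}"
    if "e" in s or "E" in s:
        # expand scientific notation for very small/large doses
        v = float(s)
        if v >= 1:
            s = f"{v:.0f}"
        else:
            s = f"{v:.{max(0, 2 - int(math.floor(math.log10(abs(v)))))}f}".rstrip("0")
    return s


@dataclass(frozen=True)
class DoseDesign:
    """Layout of one chemical's dose-response experiment.

    Parameters
    ----------
    chemical
        Chemical label, used to derive sample ids.
    doses
        Strictly increasing concentrations in µM; ``doses[0]`` must be 0
        (vehicle control). Stored unrounded; rounding to 3 significant
        figures is applied only when formatting labels.
    n_replicates
        Biological replicates per dose group.
    """

    chemical: str
    doses: tuple[float, ...]
    n_replicates: int
    sample_table: pd.DataFrame = field(compare=False, repr=False, default=None)

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        if len(doses) < 2:
            raise ValueError("design needs a control plus at least one positive dose")
        if doses[0] != 0.0:
            raise ValueError("first dose must be the vehicle control (0)")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        object.__setattr__(self, "doses", doses)
        if self.sample_table is None:
            rows = [
                {
                    "sample_id": f"{self.chemical}_d{sig3(d)}_r{r}",
                    "chemical": self.chemical,
                    "dose_uM": d,
                    "replicate": r,
                }
                for d in doses
                for r in range(1, self.n_replicates + 1)
            ]
            object.__setattr__(self, "sample_table", pd.DataFrame(rows))

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_table["sample_id"])

    @property
    def positive_doses(self) -> tuple[float, ...]:
        return self.doses[1:]

    @property
    def max_dose(self) -> float:
        return self.doses[-1]

    @property
    def min_positive_dose(self) -> float:
        return self.doses[1]

    def samples_at(self, dose: float) -> list[str]:
        t = self.sample_table
        return list(t.loc[t["dose_uM"] == dose, "sample_id"])

    def dose_of(self) -> pd.Series:
        """Series mapping sample_id -> dose (µM)."""
        return self.sample_table.set_index("sample_id")["dose_uM"]

    def groups(self) -> list[tuple[float, list[str]]]:
        """(dose, sample ids) pairs in ascending dose order."""
        return [(d, self.samples_at(d)) for d in self.doses]

    def to_frame(self) -> pd.DataFrame:
        """Sample metadata table (columns sample_id, chemical, dose_uM, replicate)."""
        return self.sample_table.copy()

    @staticmethod
    def from_frame(meta: pd.DataFrame, chemical: str | None = None) -> "DoseDesign":
        """Rebuild a design from a metadata table written by :meth:`to_frame`."""
        required = {"sample_id", "chemical", "dose_uM", "replicate"}
        missing = required - set(meta.columns)
        if missing:
            raise ValueError(f"metadata table missing columns: {sorted(missing)}")
        if chemical is None:
            chems = meta["chemical"].unique()
            if len(chems) != 1:
                raise ValueError(
                    f"metadata holds {len(chems)} chemicals; pass `chemical=` to select one"
                )
            chemical = chems[0]
        sub = meta[meta["chemical"] == chemical].copy()
        if sub.empty:
            raise ValueError(f"no samples for chemical {chemical!r}")
        doses = tuple(sorted(sub["dose_uM"].unique()))
        n_rep = int(sub.groupby("dose_uM")["sample_id"].count().iloc[0])
        counts = sub.groupby("dose_uM")["sample_id"].count()
        if not (counts == n_rep).all():
            raise ValueError("unbalanced designs are not supported")
        sub = sub.sort_values(["dose_uM", "replicate"]).reset_index(drop=True)
        return DoseDesign(chemical=chemical, doses=doses, n_replicates=n_rep, sample_table=sub)


def build_design(
    top_dose_uM: float,
    n_positive_doses: int,
    n_replicates: int,
    chemical: str,
) -> DoseDesign:
    """Build a half-log dilution series descending from the top dose.

    Positive doses are ``top / sqrt(10)**k`` for k = 0..n_positive_doses-1,
    stored ascending after dose 0 (vehicle). Doses are kept unrounded;
    sample ids use the 3-significant-figure display form.
    """
    if top_dose_uM <= 0:
        raise ValueError("top_dose_uM must be positive")
    if n_positive_doses < 1:
        raise ValueError("n_positive_doses must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be a positive integer")
    pos = [top_dose_uM / _HALF_LOG**k for k in range(n_positive_doses)]
    doses = (0.0, *sorted(pos))
    return DoseDesign(chemical=chemical, doses=doses, n_replicates=n_replicates)
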