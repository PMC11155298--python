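import numpy as np
import pandas as pd
import pytest

from toxpod import build_design
from toxpod.curves import evaluate_curve


@pytest.fixture(scope="session")
def design9():
    """The study layout: 9 half-log doses descending from 1000 µM + vehicle, 4 reps."""
    return build_design(1000.0, 9, 4, "chemX")


@pytest.fixture(scope="session")
def design_small():
    """A compact layout for cheap fitting tests: 4 positive doses, 3 reps."""
    return build_design(100.0, 4, 3, "mini")


def hill_responses(design, params, sigma, rng):
    """Noisy responses from a Hill mean curve, aligned to the design."""
    dose = design.sample_table["dose_uM"].to_numpy()
    y = evaluate_curve("hill", params, dose) + rng.normal(0.0, sigma, len(dose))
    return pd.Series(y, index=design.sample_ids)


def make_events_frame(groups):
    """Long event table from {sample_id: (inc, exc)} per event.

    `groups` is a list of (event_id, event_type, {sample: (inc, exc)}).
    """
    rows = []
    for event_id, event_type, per_sample in groups:
        for sample_id, (inc, exc) in per_sample.items():
            rows.append((event_id, "G1", event_type, sample_id, inc, exc))
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene_id", "event_type", "sample_id", "inc_reads", "exc_reads"],
    )
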