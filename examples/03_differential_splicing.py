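"""Differential splicing from junction reads: ΔPSI plus a credible bound.

Simulates intron-retention events whose percent-spliced-in rises with
dose, then calls each dose against vehicle using the two-criterion rule:
|ΔPSI| > 5 percentage points AND a central 95% credible interval of the
posterior ΔPSI excluding zero (MV_ΔPSI > 0).
"""

from toxpod import build_design, simulate_splicing, tally_event_changes
from toxpod.simulate import EventTruth
from toxpod.splicing import diff_splicing_by_dose

design = build_design(100, 4, 4, "demo")
events = [
    EventTruth(f"IR_{i}", f"G{i}", "IR", baseline_psi=30.0,
               dpsi_params=(25.0, 3.16, 2.0),  # +25 points, half-max at 3.16 µM
               read_depth=150.0)
    for i in range(10)
] + [
    EventTruth(f"EX_{i}", f"G{i+10}", "EX", baseline_psi=60.0,
               dpsi_params=(0.0, 1.0, 1.0), read_depth=150.0)
    for i in range(10)
]
table = simulate_splicing(design, events, seed=5)
results = diff_splicing_by_dose(table, design, seed=6)

print(results[results["significant"]][
    ["event_id", "dose_uM", "dpsi_point", "mv_dpsi_95"]
].head(10).to_string(index=False))
print("\nper-dose event tally (significant only):")
tally = tally_event_changes(results)
print(tally[tally["n_events"] > 0].to_string(index=False))
# dpsi_point: treated-minus-control PSI difference in percentage points;
# mv_dpsi_95: how far the 95% credible interval stays from zero. The
# planted IR events emerge around their 3.16 µM half-max dose; the flat
# EX events stay silent.
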