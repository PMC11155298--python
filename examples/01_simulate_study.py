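"""Generate a synthetic concentration-response study and inspect its truth.

Builds the canonical layout (9 half-log doses descending from 1000 µM
plus vehicle, 4 replicates), simulates negative-binomial gene counts
around known dose-response curves, and prints a few recorded true
benchmark doses — the dose at which each feature's noiseless mean
departs from control by one residual SD.
"""

from toxpod import build_design, make_feature_truths, simulate_counts

design = build_design(top_dose_uM=1000, n_positive_doses=9, n_replicates=4,
                      chemical="demo")
print(f"doses (µM): {[round(d, 3) for d in design.doses]}")
print(f"samples: {len(design.sample_ids)}")

truths = make_feature_truths(design, n_features=20, responsive_fraction=0.5, seed=1)
counts, truth_table = simulate_counts(design, truths, nb_dispersion=0.05, seed=2)
print(f"\ncount matrix: {counts.shape[0]} features x {counts.shape[1]} samples")
responsive = truth_table.dropna(subset=["true_bmd"])
print("\nrecorded ground truth (first 5 responsive features):")
print(responsive[["feature_id", "curve_family", "direction", "true_bmd"]]
      .head().to_string(index=False))
# true_bmd is in µM: a fitted BMD for these features should land near it.
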