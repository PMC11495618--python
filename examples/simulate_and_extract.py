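"""Simulate a small synthetic cohort and extract per-trial features.

Generates 2 congruent + 2 incongruent virtual participants over five daily
sessions (reduced block sizes), runs every raw-EMG trial through the
interface chain and feature extraction, and prints session-wise summaries
of the three performance measures.
"""

from myolearn import pipeline, synthetic_participant as sp

config = sp.CohortConfig(
    n_per_group=2, n_sessions=5, rounds=1, train_reps=3, test_reps=1
)
cohort = sp.simulate_cohort(config, master_seed=5)
features = pipeline.extract_cohort_features(cohort)
print(f"{len(features)} trials from {features['participant'].nunique()} "
      "participants\n")

valid = features[features["valid"] & ~features["feedback"]]
summary = valid.groupby("session")[
    ["epsilon", "hit_pct", "traj_peak_time"]
].mean().round(3)
print("No-feedback trial means by session")
print(summary)
print("""
epsilon        : peak-aligned RMS error vs the target path (px) - shape
hit_pct        : share of the 25 targets intersected after alignment (%)
traj_peak_time : pre-alignment trajectory peak time (s); the ideal is 1.21 s,
                 so the decline towards it across sessions is the simulated
                 timing learning
""")
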