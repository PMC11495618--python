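"""Were session-5 muscle outputs already producible in session 1?

Computes, per participant and channel, the 99th percentile of per-trial
minimum amplitude differences between session-5 trained-condition trials
and all session-1 trials, and a three-component functional-PCA feature
space of the hand-channel profiles.
"""

import numpy as np

from myolearn import (
    generalisation as gen,
    pipeline,
    synthetic_participant as sp,
    trajectory_features as tf,
)
from myolearn.emg_interface import control_signal, smooth

config = sp.CohortConfig(
    n_per_group=2, n_sessions=5, rounds=1, train_reps=3, test_reps=1
)
cohort = sp.simulate_cohort(config, master_seed=5)
features = pipeline.extract_cohort_features(cohort)
valid = features[features["valid"].astype(bool)]

table = gen.similarity_table(
    valid,
    {"hand": "hand_peak_amplitude", "shin": "shin_peak_amplitude"},
    session5_conditions=["R1", "R3"],
)
print("99th-percentile minimum amplitude difference, session 5 vs session 1")
print(table.to_string(index=False))
print("\nValues near zero mean almost every session-5 output had a close"
      "\nsession-1 counterpart - the repertoire-fixity signature.\n")

# fPCA of peak-aligned hand profiles around the alignment reference
sub = valid[valid["participant"] == "C1"].head(40)
profiles = []
for _, row in sub.iterrows():
    trial = cohort.render(row)
    prof = control_signal(
        smooth(trial.hand_raw), cohort.calibrations["C1"]["hand"], "hand")
    peak = tf.find_channel_peak(prof)
    shifted = np.interp(
        np.arange(prof.values.size) / prof.fs - (1.21 - peak.peak_time),
        np.arange(prof.values.size) / prof.fs, prof.values,
    )
    window = slice(int(0.9 * prof.fs), int(1.6 * prof.fs))
    profiles.append(shifted[window])
profiles = np.array(profiles)
grid = np.arange(profiles.shape[1]) / 2048 + 0.9
basis = gen.fit_fpca(profiles, grid, k=3)
ev = 100 * basis.explained_variance
print(f"hand-profile fPCA: components explain {ev[0]:.1f}% / {ev[1]:.1f}% / "
      f"{ev[2]:.1f}% (cumulative {ev.sum():.1f}%)")
scores = gen.project_fpca(profiles[0], basis)
print(f"first trial's 3-D score vector: ({scores[0]:+.3f}, {scores[1]:+.3f}, "
      f"{scores[2]:+.3f})")
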