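"""Hierarchical Bayesian evidence for session-1-to-5 learning.

Fits the hierarchical normal model to log-standardised peak-aligned RMS
errors of order-correct no-feedback trials from a small synthetic cohort,
then computes the sampling-based Bayes factor for a reduction in the
across-participant marginal mean from session 1 to session 5.
"""

import numpy as np

from myolearn import inference as inf, pipeline, synthetic_participant as sp

config = sp.CohortConfig(
    n_per_group=2, n_sessions=5, rounds=1, train_reps=3, test_reps=2
)
cohort = sp.simulate_cohort(config, master_seed=11)
features = pipeline.extract_cohort_features(cohort)
test_rows = features[features["block_type"] == "test"]

post = inf.fit_hierarchical_model(
    test_rows, "epsilon", inf.SamplerConfig(seed=1)
)
print(f"fitted {post.mu.shape[1]} participant x scale x day cells, "
      f"max R-hat {post.diagnostics.rhat_max:.3f}\n")

groups = {g: i for i, g in enumerate(post.groups)}
p2g = test_rows.drop_duplicates("participant").set_index("participant")[
    "congruence"]
group_of_cell = np.array([groups[p2g[p]] for p in post.cells["participant"]])
prior = inf.sample_prior_hierarchical(
    post.cells, post.groups, group_of_cell,
    n_draws=post.mu.shape[0], seed=2,
)

for scale in (1, 3):
    post_a = post.marginal_mean(scale=scale, day=1)
    post_b = post.marginal_mean(scale=scale, day=5)
    bf = inf.bayes_factor(
        post_a, post_b,
        prior.marginal_mean(scale=scale, day=1),
        prior.marginal_mean(scale=scale, day=5),
    )
    verdict = inf.classify_improver(bf.bf10)
    print(f"scale {scale}: marginal mean log-RMS {post_a.mean():+.2f} -> "
          f"{post_b.mean():+.2f}, BF10(reduction) = {bf.bf10:.2f} "
          f"[{verdict} at the BF > 3 rule]")
print("\nBF10 > 1 favours a session-1-to-5 reduction in mean shape error;"
      "\nthe synthetic cohort's amplitude-jitter decay produces exactly"
      "\nsuch a reduction, so large BFs are expected here.")
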