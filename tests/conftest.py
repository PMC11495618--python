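import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from myolearn import pipeline, synthetic_participant as sp  # noqa: E402


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort: 2+2 participants, 5 sessions, 1 round with 3
    training / 1 test repetition per condition."""
    config = sp.CohortConfig(
        n_per_group=2, n_sessions=5, rounds=1, train_reps=3, test_reps=1
    )
    return sp.simulate_cohort(config, master_seed=5)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return pipeline.extract_cohort_features(small_cohort)


@pytest.fixture(scope="session")
def ideal_setup():
    """Noise-free participant tuned to the canonical path, with its
    session-1 calibration."""
    participant = sp.ideal_participant("congruent")
    calib = sp.calibrate_participant(participant, seed=1)
    return participant, calib


def model_feature_frame(
    rng,
    groups=(("congruent", ("C1", "C2")), ("incongruent", ("I1", "I2"))),
    scales=(1, 3),
    days=(1, 5),
    trials_per_cell=50,
    mu_sd=0.5,
):
    """Tidy feature table drawn from a known per-cell log-normal process.

    Returns the frame and the dict of true (mu, sigma) per cell on the log
    scale.
    """
    rows, true = [], {}
    for g, pids in groups:
        for p in pids:
            for s in scales:
                for d in days:
                    mu = rng.normal(0.0, mu_sd)
                    sd = abs(rng.normal(0.5, 0.2)) + 0.2
                    true[(p, s, d)] = (mu, sd)
                    for v in np.exp(rng.normal(mu, sd, trials_per_cell)):
                        rows.append(dict(
                            participant=p, congruence=g, scale=s, day=d,
                            order_correct=True, feedback=False, epsilon=v,
                        ))
    return pd.DataFrame(rows), true
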