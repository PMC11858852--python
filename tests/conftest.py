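"""Shared fixtures: noise-free simulation parameters, a small noisy cohort,
and the full-size default cohort with its fitted classifier (session-scoped,
reused by the acceptance tests)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import equigait as eg
from equigait.features import FEATURE_NAMES


@pytest.fixture()
def zero_noise_params() -> eg.SimParams:
    """Deterministic, noise-free single-trial parameters."""
    return eg.SimParams(
        noise_sd=0.0, angle_noise_sd=0.0, amplitude_cv=0.0, stride_frequency_sd=0.0, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort() -> list[eg.GaitTrial]:
    """A 25-trial cohort with default noise levels (5 per class)."""
    counts = {lab: 5 for lab in eg.CLASS_ORDER}
    return eg.simulate_cohort(counts, params=eg.SimParams(seed=11))


@pytest.fixture(scope="session")
def default_cohort_run():
    """The full default study: 287 trials, feature table, tuned model and
    400-repetition bootstrap validation."""
    trials = eg.simulate_cohort(params=eg.SimParams(seed=42))
    table = eg.cohort_feature_table(trials)
    X, y = table[list(FEATURE_NAMES)], table["label"]
    config = eg.SVMConfig(seed=1)
    model = eg.train_svm(X, y, config)
    validation = eg.bootstrap_validate(X, y, config, cost=model.cost)
    return {
        "trials": trials,
        "table": table,
        "X": X,
        "y": y,
        "config": config,
        "model": model,
        "validation": validation,
    }
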