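"""Shared fixtures: small simulated datasets and predicted curves, built
once per session (everything is seeded, so fixtures are deterministic)."""

import numpy as np
import pytest

from tripletask.pipeline import PredictedCurves, predict_condition_curves
from tripletask.synth import EffectSpec
from tripletask.trial_sim import TASK_CONDITIONS, TrialParams, gen_stimuli, simulate_trial


@pytest.fixture(scope="session")
def predicted_small() -> PredictedCurves:
    """Predicted ROI curves for all nine conditions (2 trials averaged)."""
    return predict_condition_curves(seed=123, n_rep=2)


@pytest.fixture(scope="session")
def effects_small(predicted_small) -> EffectSpec:
    return EffectSpec.from_predictions(predicted_small.curves)


@pytest.fixture(scope="session")
def task_trials():
    """One simulated trial per task condition (no listening):
    {(sub, te): (TrialResult, DemandTrace, TrialTimeline)}."""
    out = {}
    for cond in TASK_CONDITIONS:
        stim = gen_stimuli(cond, 11)
        out[(cond.subtraction, cond.text_entry)] = simulate_trial(cond, stim, TrialParams(), 12)
    return out
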