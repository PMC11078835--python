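import numpy as np
import pandas as pd
import pytest

from handover.pipeline import PipelineSettings, features_to_frame, process_trial
from handover.preprocessing import preprocess_recording
from handover.schedule import Size, TrialCondition, Weight
from handover.simulate import SimulatorConfig, simulate_experiment, simulate_trial


def make_condition(weight=Weight.MEDIUM, size=Size.SMALL, **kw) -> TrialCondition:
    defaults = dict(
        dyad_id="D01",
        block=1,
        trial_in_block=1,
        giver_id="D01-a",
        receiver_id="D01-b",
        size=size,
        weight=weight,
    )
    defaults.update(kw)
    return TrialCondition(**defaults)


@pytest.fixture(scope="session")
def noise_free_config() -> SimulatorConfig:
    return SimulatorConfig().noise_free()


@pytest.fixture(scope="session")
def noise_free_trials(noise_free_config):
    """One noise-free trial per weight: (condition, raw, filtered, ground truth)."""
    out = {}
    for w in Weight:
        cond = make_condition(weight=w)
        rec, gt = simulate_trial(cond, noise_free_config, rng=0)
        out[w] = (cond, rec, preprocess_recording(rec), gt)
    return out


@pytest.fixture(scope="session")
def experiment_20_dyads():
    """Full default-noise 20-dyad experiment processed end to end.

    Returns (features_df, ground_truths) — shared across tests because the
    simulation is the expensive part.
    """
    settings = PipelineSettings(n_dyads=20)
    rows, gts = [], []
    for rec, gt in simulate_experiment(20, settings.simulator, seed=2024):
        rows.append(process_trial(rec, settings))
        gts.append((rec.meta.condition, gt))
    return features_to_frame(rows), gts


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
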