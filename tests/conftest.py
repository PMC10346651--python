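import numpy as np
import pytest

import spinesense as ss
from spinesense import curvenet


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort: 6 participants x 2 sessions, ~58k
    mocap frames, accelerometer noise 0.02 g."""
    return ss.default_cohort(6, base_seed=42)


@pytest.fixture(scope="session")
def experiment(cohort):
    """Full pipeline run with the published training recipe (RMSprop,
    lr 1e-4, rho 0.9, momentum 0, 250 epochs, batch 512), one male and one
    female participant held out.  Shared across tests — training runs once.
    """
    sex = {s.participant_id: s.metadata["sex"] for s in cohort}
    holdout = ss.choose_holdout(sex, seed=7)
    return ss.run_experiment(
        cohort,
        holdout,
        model_config=ss.ModelConfig(init_seed=3),
        training_config=ss.TrainingConfig(shuffle_seed=3),
        split_spec=ss.SplitSpec(split_seed=3),
    )


@pytest.fixture()
def short_script():
    """A fast two-pose script for stream-level unit tests."""
    return ss.MotionScript(
        (ss.PoseParams(), ss.PoseParams(flexion_deg=60.0, lateral_deg=20.0)),
        dwell_s=2.0,
        transition_s=1.0,
    )


@pytest.fixture()
def trained_toy_model():
    """A deterministic untrained-but-valid TrainedModel wrapper for
    structural prediction tests."""
    net = curvenet.build_model(ss.ModelConfig(init_seed=0))
    return curvenet.TrainedModel(
        net=net,
        model_config=ss.ModelConfig(init_seed=0),
        training_config=ss.TrainingConfig(),
        norm_spec=ss.NormalizationSpec(),
    )
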