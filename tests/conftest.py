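"""Shared fixtures: one synthetic cohort and the three trained tiny models.

The expensive fixtures are session-scoped so training happens once for the
whole run; unit tests and the end-to-end checks share the same cohort.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from echomvp.diagnosis import SegTrainConfig, train_segmenter
from echomvp.heatmap import HeatmapTrainConfig, train_heatmap
from echomvp.phase import PhaseTrainConfig, train_phase_classifier
from echomvp.synthetic import (
    EchoPhantomConfig,
    collect_systolic_frames,
    generate_case,
    generate_dataset,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """60 synthetic cine loops (30 control / 30 MVP) with a 3:2:3 split."""
    return generate_dataset(30, 30, seed=101)


@pytest.fixture(scope="session")
def cohort_train(cohort):
    return [c for c in cohort if c.split == "train"]


@pytest.fixture(scope="session")
def cohort_test(cohort):
    return [c for c in cohort if c.split == "test"]


@pytest.fixture(scope="session")
def mvp_case():
    """A single deterministic prolapse case used across unit tests."""
    return generate_case(
        EchoPhantomConfig(
            mvp_case=True, prolapse_amplitude=7.0, prolapse_zone="P2",
            n_cycles=2, frames_per_cycle=12, systole_fraction=0.5, seed=5,
        ),
        case_id="mvp_fixture",
    )


@pytest.fixture(scope="session")
def control_case():
    return generate_case(
        EchoPhantomConfig(n_cycles=3, frames_per_cycle=10, seed=6), case_id="control_fixture"
    )


@pytest.fixture(scope="session")
def phase_models(cohort_train):
    """Main and secondary phase classifiers, 5 epochs on the train split."""
    main, _ = train_phase_classifier(cohort_train, "main", PhaseTrainConfig(epochs=5, seed=0))
    secondary, _ = train_phase_classifier(
        cohort_train, "secondary", PhaseTrainConfig(epochs=5, seed=0)
    )
    return main, secondary


@pytest.fixture(scope="session")
def seg_model(cohort_train):
    """Segmenter trained for 10 epochs on up to 300 systolic train frames."""
    frames, masks = collect_systolic_frames(cohort_train, cap=300)
    model, _ = train_segmenter(frames, masks, SegTrainConfig(epochs=10, seed=0))
    return model


@pytest.fixture(scope="session")
def heatmap_model(cohort_train):
    """Saliency model trained for 15 epochs on up to 200 prolapse frames."""
    frames, masks = collect_systolic_frames(cohort_train, mvp_only=True, cap=200)
    model, _ = train_heatmap(frames, masks, HeatmapTrainConfig(epochs=15, seed=0))
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
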