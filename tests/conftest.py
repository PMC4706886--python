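import numpy as np
import pytest

from eegmem import (
    EEGRecording,
    ElectrodeLayout,
    EventTable,
    SyntheticStudyConfig,
    Topomap,
    TopomapSequence,
    generate_layout,
    generate_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def layout16():
    return generate_layout(16)


@pytest.fixture(scope="session")
def tiny_study():
    """8 channels, 0.5-s epochs, 10 questions: fast but structurally complete."""
    cfg = SyntheticStudyConfig(
        n_channels=8, epoch_seconds=0.5, n_questions_per_class=5, seed=11
    )
    return generate_study(cfg)


def make_topomap(pixels, mask=None, time_index=0):
    pixels = np.asarray(pixels, dtype=float)
    if mask is None:
        mask = np.ones_like(pixels, dtype=bool)
    return Topomap(pixels, mask, time_index=time_index)


def random_sequence(rng, n_maps, side=8, question_id="q"):
    """Random full-mask topomap sequence for oracle comparisons."""
    maps = tuple(
        make_topomap(rng.normal(size=(side, side)), time_index=t)
        for t in range(n_maps)
    )
    return TopomapSequence(question_id=question_id, maps=maps)


@pytest.fixture
def simple_recording():
    t = np.arange(1000)
    pot = np.vstack([np.sin(0.05 * t), np.cos(0.05 * t), 0.001 * t])
    return EEGRecording(pot, 250.0, ("c1", "c2", "c3"), subject_id="s1")


@pytest.fixture
def simple_events():
    return EventTable(
        ("q1", "q2"), np.array([0, 250]), np.array([250, 1000]), np.array([1, 0])
    )
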