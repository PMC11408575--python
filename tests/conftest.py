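import numpy as np
import pytest

from erpconsensus.datamodel import Labeling, PipelineConfig

from erpconsensus.simulate import (ComponentSpec, StudySpec, electrode_layout,
                                   simulate_study)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def layout():
    return electrode_layout(32)


@pytest.fixture
def cfg():
    return PipelineConfig(seed=7)


def planted_epoch(n_per_phase=40, n_chan=16, n_phases=3, noise=0.05, seed=0):
    """Epoch whose time axis alternates between well-separated topographies.

    Returns (data, truth_labels): each phase is a distinct random map with a
    small amount of noise, so any reasonable clustering recovers the phases.
    """
    r = np.random.default_rng(seed)
    maps = r.normal(size=(n_phases, n_chan))
    maps *= 5.0 / np.linalg.norm(maps, axis=1, keepdims=True)
    data = np.repeat(maps, n_per_phase, axis=0)
    data += r.normal(0.0, noise, size=data.shape)
    truth = np.repeat(np.arange(1, n_phases + 1), n_per_phase)
    return data, truth


@pytest.fixture
def planted():
    return planted_epoch()


@pytest.fixture(scope="session")
def tiny_study():
    """Small but complete simulated study (2 subjects, 2 conditions, 6 trials)."""
    spec = StudySpec(n_subjects=2, n_trials=6, seed=42)
    epochsets, truth = simulate_study(spec)
    return spec, epochsets, truth


def make_labeling(labels):
    labels = np.asarray(labels, dtype=int)
    return Labeling(labels=labels, K=int(labels.max()))


@pytest.fixture
def single_component_spec():
    """Noiseless, jitter-free study with only the P3-like component."""
    comp = ComponentSpec("P3", "Pz", 0.6, +1, (300, 300), (200, 200),
                         (5.0, 5.0), (0, 0, 0))
    return StudySpec(n_subjects=1, n_conditions=1, n_trials=3, noise_sd=0.0,
                     components=[comp], condition_scale={}, seed=3)
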