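"""Shared fixtures: scaled-down simulated sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from p300speller.classify import classify_phase, selection_accuracy, train_lda
from p300speller.design import Condition
from p300speller.pipeline import StudyConfig, run_session_phase


def simulate_phase(scale=1.0, seed=0, reps=8, symbols=3, speed="fast",
                   phase="training", stim="CH", color="white", noise=None):
    """One scaled session phase -> (epochs, features, targets)."""
    kwargs = {} if noise is None else {"noise": noise}
    cfg = StudyConfig(master_seed=seed, n_repetitions=reps,
                      n_symbols_per_phase=symbols, amplitude_scale=scale,
                      **kwargs)
    condition = Condition(stim=stim, color=color, speed=speed, phase=phase)
    return run_session_phase(cfg, condition, subject=0, session=0)


def session_accuracy(scale, seed, reps=8, symbols=3, speed="fast"):
    """Train on a training phase, classify the matched performance phase."""
    _, train_fm, _ = simulate_phase(scale, seed, reps, symbols, speed, "training")
    _, perf_fm, _ = simulate_phase(scale, seed, reps, symbols, speed, "performance")
    model = train_lda(train_fm)
    return selection_accuracy(classify_phase(model, perf_fm))


@pytest.fixture(scope="session")
def fast_session():
    """A scaled fast-timing session: training + performance, default noise."""
    train_ep, train_fm, _ = simulate_phase(phase="training")
    perf_ep, perf_fm, _ = simulate_phase(phase="performance")
    return {"train_epochs": train_ep, "train_features": train_fm,
            "perf_epochs": perf_ep, "perf_features": perf_fm}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
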