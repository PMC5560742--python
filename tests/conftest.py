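"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import wmreplay as w


@pytest.fixture(scope="session")
def small_params() -> w.SimulationParams:
    """Reduced sensor array for fast tests; the physics is scale-free."""
    return w.SimulationParams(n_channels=24, seed=7)


@pytest.fixture(scope="session")
def small_design(small_params):
    return w.assign_predominant(w.enumerate_design(3)[:40], small_params)


@pytest.fixture(scope="session")
def clf_bundle():
    """High-SNR encoding sim with trained selected-bin classifiers.

    Session-scoped: several delay/replay tests reuse the same trained
    pipeline.  Returns (params, design, grid, curve, best_center,
    classifiers).
    """
    params = w.SimulationParams(n_channels=24, seed=11, snr_encoding=5.0)
    design = w.assign_predominant(w.enumerate_design(11)[:30], params)
    epochs = w.simulate_encoding_epochs(design, params)
    grid = w.make_time_bins(fs=params.fs)
    curve = w.crossvalidate_bins(epochs, grid, folds=10, seed=0)
    center, classifiers = w.select_best_bin(curve, epochs, grid, seed=0)
    return params, design, grid, curve, center, classifiers


def noise_epochs(
    n_epochs=4, n_channels=3, n_samples=601, fs=600.0, seed=0, scale=1.0
) -> w.SensorEpochs:
    """Plain white-noise epochs for preprocessing tests."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_epochs, n_channels, n_samples)) * scale
    t = -100 + np.arange(n_samples) * (1000.0 / fs)
    return w.SensorEpochs(
        data=data,
        time_ms=t,
        fs=fs,
        alignment="stimulus_onset",
        events=pd.DataFrame({"trial_id": np.arange(n_epochs)}),
    )
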