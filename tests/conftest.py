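"""Shared fixtures: small, seeded synthetic sessions.

Test sessions run at reduced sampling rates (128-256 Hz, still well
above twice the highest analysis band) to keep the suite fast; the
paradigm structure is unchanged.
"""

import numpy as np
import pytest

import lmbci


@pytest.fixture(scope="session")
def default_session():
    """Full-size paradigm (12 runs, 192 trials) at 160 Hz, default ERD depths."""
    cfg = lmbci.SimConfig(n_runs=12, fs=160.0, rng_seed=11)
    return cfg, lmbci.synthesize_session(cfg)


@pytest.fixture(scope="session")
def default_epochs(default_session):
    """Clean 40-trial-per-condition epochs from the default session."""
    _, session = default_session
    epochs = lmbci.reject_artifacts(lmbci.extract_epochs(session))
    return lmbci.subsample_trials(epochs, 40, rng_seed=11)


@pytest.fixture()
def tiny_cfg():
    """Two-run session config for structural tests."""
    return lmbci.SimConfig(n_runs=2, fs=160.0, rng_seed=5)


@pytest.fixture(scope="session")
def narrowband_epochs_factory():
    """Builds EpochSet objects directly from channel processes (fast path)."""

    def build(task, baseline=None, fs=160.0, labels=None, montage=None):
        task = np.asarray(task, dtype=float)
        n_trials, n_ch, _ = task.shape
        if baseline is None:
            baseline = task[:, :, : int(fs)].copy()
        if labels is None:
            labels = np.array(["no-LMI"] * n_trials, dtype="U8")
        if montage is None:
            montage = tuple(lmbci.DEFAULT_MONTAGE[:n_ch])
        return lmbci.EpochSet(
            baseline=np.asarray(baseline, dtype=float),
            task=task,
            labels=labels,
            artifact_flags=np.zeros(n_trials, dtype=bool),
            fs=fs,
            montage=montage,
        )

    return build
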