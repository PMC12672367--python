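"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from somnifold.features.registry import FeatureExtractor
from somnifold.synthetic import NightSpec, simulate_cohort, simulate_eeg_night

FS = 256.0
EPOCH_N = int(6 * FS)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_night():
    """One compact night: 8 min wake, 3 min N1, 12 min N2, with ECG."""
    spec = NightSpec(stage_plan=[("W", 480.0), ("N1", 180.0), ("N2", 720.0)],
                     seed=42, ecg_rate=60.0)
    return simulate_eeg_night(spec)


@pytest.fixture(scope="session")
def cohort():
    """4 subjects x 4 nights with subject-consistent sleep centroids and
    short latencies (desk-scale)."""
    return simulate_cohort(n_subjects=4, nights_per_subject=4, seed=2024,
                           latency_range=(5.0, 11.0), post_onset_minutes=12.0)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    """47-feature matrices for every cohort night (shared across tests)."""
    ext = FeatureExtractor(feature_set=47)
    return {(sid, nid): ext.transform(rec)
            for sid, nid, rec, hyp in cohort}


def phase_randomized(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier phase-randomised surrogate (amplitude spectrum preserved)."""
    X = np.fft.rfft(x)
    ph = rng.uniform(0, 2 * np.pi, len(X))
    ph[0] = 0.0
    return np.fft.irfft(np.abs(X) * np.exp(1j * ph), len(x))
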