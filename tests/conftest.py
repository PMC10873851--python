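"""Shared fixtures: montages, ground truths and a small simulated cohort.

Everything is generated programmatically and seeded, so the suite needs
no stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import mstates as ms


@pytest.fixture(scope="session")
def montage32() -> ms.Montage:
    return ms.spherical_montage(32)


@pytest.fixture(scope="session")
def montage16() -> ms.Montage:
    return ms.spherical_montage(16)


@pytest.fixture(scope="session")
def gt4(montage32) -> ms.GroundTruth:
    """Four-class ground truth at the calibrated signal-to-noise ratio."""
    return ms.default_ground_truth(montage32, k=4, seed=7)


@pytest.fixture(scope="session")
def noiseless_gt4(montage32) -> ms.GroundTruth:
    ts = ms.make_templates(montage32, 4, seed=7)
    return ms.GroundTruth(
        templates=ts,
        mean_durations_ms=np.full(4, 75.0),
        coverages=np.full(4, 0.25),
        snr=np.inf,
    )


@pytest.fixture(scope="session")
def small_cohort(montage32, gt4):
    """6-subject cohort with the default condition and trait effects."""
    spec = ms.CohortSpec(
        n_subjects=6, n_epochs_per_condition=2, epoch_s=10.0, seed=11
    )
    recs, truth = ms.simulate_cohort(spec, gt4, montage32)
    return recs, truth
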