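"""Shared fixtures: a small synthetic cohort reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from maldi_tma import (
    CohortConfig,
    FeaturePanel,
    NoiseModel,
    align_masses,
    filter_annotated,
    generate_cohort,
    patient_mean_spectra,
    tic_normalize,
)

SMALL_CONFIG = CohortConfig(
    n_patients_treated=24,
    n_patients_untreated=30,
    cores_per_patient=2,
    tma_layout=(20, 20, 20, 20, 20, 20, 10),
    muscle_cores_per_tma=2,
    spectra_per_core=4,
    seed=42,
)

SMALL_NOISE = NoiseModel(n_background_peaks=80, n_muscle_peaks=15)


@pytest.fixture(scope="session")
def small_cohort():
    """A 54-patient cohort small enough for every test to reuse."""
    return generate_cohort(SMALL_CONFIG, FeaturePanel.default(), SMALL_NOISE)


@pytest.fixture(scope="session")
def small_fm(small_cohort):
    """Spectrum-level feature matrix (TIC-normalized, 0.5 Da bins)."""
    sset, _ = small_cohort
    return align_masses(tic_normalize(sset), 0.5)


@pytest.fixture(scope="session")
def small_fm_syn(small_cohort, small_fm):
    _, meta = small_cohort
    return filter_annotated(small_fm, meta)


@pytest.fixture(scope="session")
def small_fm_pat(small_cohort, small_fm_syn):
    _, meta = small_cohort
    return patient_mean_spectra(small_fm_syn, meta)


@pytest.fixture(scope="session")
def small_labels(small_cohort, small_fm_pat):
    _, meta = small_cohort
    return meta.labels_for(small_fm_pat.unit_ids).to_numpy()
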