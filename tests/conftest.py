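"""Shared fixtures: small synthetic cohorts reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from lbnpdet import EffectConfig, extract_cohort, synth_cohort, synth_subject
from lbnpdet.metrics import extract_subject


@pytest.fixture(scope="session")
def calib_config() -> EffectConfig:
    """The calibrated study-condition configuration (generator defaults)."""
    return EffectConfig()


@pytest.fixture(scope="session")
def subject_rec(calib_config):
    """One calibrated subject stopping at 60 mmHg."""
    return synth_subject(calib_config, "S01", seed=101, tolerance=60)


@pytest.fixture(scope="session")
def subject_metrics(subject_rec):
    return extract_subject(subject_rec)


@pytest.fixture(scope="session")
def small_cohort(calib_config):
    """Four-subject cohort for plumbing tests."""
    return synth_cohort(calib_config, 4, seed=23)


@pytest.fixture(scope="session")
def small_metrics(small_cohort):
    return extract_cohort(small_cohort)


@pytest.fixture(scope="session")
def cohort16(calib_config):
    """Study-scale 16-subject calibrated cohort."""
    return synth_cohort(calib_config, 16, seed=7)


@pytest.fixture(scope="session")
def metrics16(cohort16):
    return extract_cohort(cohort16)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
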