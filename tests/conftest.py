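"""Shared fixtures: montage, projections, and reduced-scale synthetic
cohorts (generated at test time; nothing is read from disk)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from skillstate import workflows as wf
from skillstate.io import default_montage
from skillstate.preprocess import PreprocessConfig
from skillstate.synth import SimulationSpec, make_prototype_bank, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def bank(montage):
    return make_prototype_bank(montage, 6, seed=0)


# reduced-scale trial timing shared by end-to-end tests: long enough for a
# 10-s task-onset epoch and a 30-s ASR calibration tail
SHORT = dict(task_s=12.0, rest_s=35.0, pre_trigger_s=3.0)
PP_CFG = PreprocessConfig(calibration_s=30.0)


def make_cohort_entries(seed: int, montage, **spec_kw):
    """Simulate + fully preprocess a reduced-duration cohort in memory."""
    spec = SimulationSpec(seed=seed, **{**SHORT, **spec_kw})
    manifest = simulate_cohort(spec)
    cohort = wf.load_cohort(manifest)
    entries, qc = wf.preprocess_cohort(cohort, montage, PP_CFG)
    return spec, entries, qc


@pytest.fixture(scope="session")
def highsnr_cohort(montage):
    """Disjoint group prototype weights at high SNR (seed 0)."""
    return make_cohort_entries(0, montage, snr_db=6.0, dominance=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
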