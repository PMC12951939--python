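"""Shared fixtures: digital phantoms and the (expensive) cohort studies.

The two end-to-end study fixtures are session-scoped so the pipeline
tests and the acceptance checks share one simulation + extraction run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from habitatomics.pipeline import StudyConfig, build_feature_table, run_prognosis_study, run_response_study
from habitatomics.synth import (
    effectful_cohort_spec,
    null_cohort_spec,
    simulate_cohort_tables,
    study_phantom_spec,
)


def digital_sphere(radius_mm: float = 10.0, spacing: float = 1.0, pad: int = 6):
    """Binary sphere mask: voxel centers within radius of a central voxel."""
    n = int(2 * (radius_mm / spacing + pad)) + 1
    c = (n - 1) / 2
    g = np.indices((n, n, n))
    dist = np.sqrt((((g - c) * spacing) ** 2).sum(axis=0))
    return dist <= radius_mm


@pytest.fixture(scope="session")
def sphere_mask():
    return digital_sphere(10.0, 1.0)


@pytest.fixture(scope="session")
def effectful_response_study():
    """Planted-signal cohort (n=300) run through the full response pipeline."""
    pspec = study_phantom_spec(seed=0)
    cspec = effectful_cohort_spec(n_subjects=300, seed=1)
    subjects, clinical, outcomes = simulate_cohort_tables(pspec, cspec)
    config = StudyConfig(seed=0, n_boot=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = build_feature_table(subjects, config, timepoints=("pre",))
        report = run_response_study(
            subjects, clinical, outcomes, config, feature_table=table
        )
    return {
        "subjects": subjects,
        "clinical": clinical,
        "outcomes": outcomes,
        "table": table,
        "config": config,
        "report": report,
    }


@pytest.fixture(scope="session")
def effectful_prognosis_study():
    """Planted temporal-signal cohort (n=160) through the prognosis pipeline."""
    pspec = study_phantom_spec(seed=0)
    cspec = effectful_cohort_spec(n_subjects=160, seed=1)
    subjects, clinical, outcomes = simulate_cohort_tables(pspec, cspec)
    config = StudyConfig(seed=0, n_boot=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_prognosis_study(subjects, clinical, outcomes, config)
    return {
        "subjects": subjects,
        "clinical": clinical,
        "outcomes": outcomes,
        "config": config,
        "report": report,
    }


@pytest.fixture(scope="session")
def null_response_study():
    """No-effect cohort (n=150) through the response pipeline (calibration)."""
    pspec = study_phantom_spec(seed=0)
    cspec = null_cohort_spec(n_subjects=150, seed=2)
    subjects, clinical, outcomes = simulate_cohort_tables(pspec, cspec)
    config = StudyConfig(seed=0, n_boot=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_response_study(subjects, clinical, outcomes, config)
    return {"outcomes": outcomes, "report": report}
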