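"""Shared fixtures: the exemplary day, a small synthetic cohort, and one
session-scoped scaled-down SVI fit reused by every analytics test."""

from __future__ import annotations

import numpy as np
import pytest

from glucotwin import (
    CohortConfig,
    FitConfig,
    HierModel,
    build_dataset,
    build_priors,
    exemplary_day,
    fit_svi,
    generate_cohort,
)

# Scaled-down study conditions for the recovery cohort: 2 patients x 4
# samples, CGM noise sd 10 mg/dL, 5-min likelihood grid, a posterior-mode
# warm start, then 2000 SVI iterations with 2 antithetic ELBO particles.
RECOVERY_SEED = 20260920
RECOVERY_COHORT = dict(n_patients=2, samples_per_patient=4, sigma_range=(10.0, 10.0), seed=42)
RECOVERY_FIT = dict(n_particles=2, n_iterations=2000, seed=RECOVERY_SEED, lr=0.01, lr_min=1e-3)


@pytest.fixture(scope="session")
def priors():
    return build_priors()


@pytest.fixture(scope="session")
def day():
    return exemplary_day()


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort with ground truth (no fit)."""
    truth, raw = generate_cohort(CohortConfig(n_patients=3, samples_per_patient=6,
                                              sigma_range=(8.0, 12.0), seed=5))
    return truth, raw


@pytest.fixture(scope="session")
def recovery_cohort():
    truth, raw = generate_cohort(CohortConfig(**RECOVERY_COHORT))
    dataset, report = build_dataset(raw, min_stride=1440.0)
    return truth, raw, dataset, report


@pytest.fixture(scope="session")
def scaled_fit(recovery_cohort):
    """The scaled-down SVI fit of the recovery cohort (runs once per session)."""
    from glucotwin.svi import map_init

    truth, raw, dataset, _ = recovery_cohort
    model = HierModel(dataset, dt=5.0)
    z0 = map_init(model, maxiter=400)
    fit = fit_svi(model, FitConfig(**RECOVERY_FIT), init_loc=z0)
    return truth, model, fit
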