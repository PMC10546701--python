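"""Shared fixtures: small synthetic cohorts and cached model fits.

Expensive MCMC fits are session-scoped so several tests can interrogate
the same posterior.
"""

from __future__ import annotations

import numpy as np
import pytest

from esmvar import TrueParams, default_missingness, default_true_params
from esmvar.dsem import McmcConfig, fit_dsem
from esmvar.simulate import generate_dataset


def one_group_params(n_persons: int = 20, **overrides) -> TrueParams:
    """BPD-regime single-group cohort parameters."""
    tp = default_true_params("study")
    kwargs = dict(
        group_labels=("BPD",),
        group_means=tp.group_means[:1].copy(),
        omega=tp.omega.copy(),
        n_per_group=(n_persons,),
        n_occasions=52,
    )
    kwargs.update(overrides)
    return TrueParams(**kwargs)


@pytest.fixture(scope="session")
def study_params() -> TrueParams:
    return default_true_params("study")


@pytest.fixture(scope="session")
def bpd_params() -> TrueParams:
    return one_group_params(20)


@pytest.fixture(scope="session")
def bpd_complete_dataset(bpd_params):
    """20 BPD-regime persons, complete 52-slot grids."""
    return generate_dataset(bpd_params, None, seed=1)


@pytest.fixture(scope="session")
def bpd_missing_dataset(bpd_params):
    """Same cohort with the default time-of-day missingness applied."""
    return generate_dataset(bpd_params, default_missingness(52, 0.5), seed=1)


@pytest.fixture(scope="session")
def small_fit(bpd_complete_dataset):
    """Two-chain fit of the small complete cohort (shared across tests)."""
    cfg = McmcConfig(n_chains=2, n_iterations=400, seed=3)
    return fit_dsem(bpd_complete_dataset["grids"], config=cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
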