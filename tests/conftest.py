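"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import pytest

from famvar.config import SimulationConfig, Thresholds
from famvar.simulate import SyntheticCohort, simulate


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def sim_small() -> SyntheticCohort:
    """Small cohort with planted recessive/X-linked events and an MZ twin
    pair; quality-failing de novos included."""
    cfg = SimulationConfig(
        n_families=12, seed=7, n_biallelic_events=2, n_xlinked_events=2,
        mz_twin_families=1, fraction_multiplex=0.4,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_cohort() -> SyntheticCohort:
    """Cohort with no quality-failing planted de novos and no CNV caller
    dropout: every planted event should be recoverable exactly."""
    cfg = SimulationConfig(
        n_families=60, seed=11, quality_fail_fraction=0.0, cnv_dropout=0.0,
        n_biallelic_events=3, n_xlinked_events=3,
    )
    return simulate(cfg)
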