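"""Shared fixtures: synthetic cohorts with known mechanisms, fitted once.

The Stage-2 cohort fits are expensive, so they are computed once per session
and shared between the recovery, null-behaviour, and nested-dominance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazeddm.fit import MCMCConfig, fit_cohort
from gazeddm.selection import selection_table
from gazeddm.synth import GenerativeProfile, generate_cohort


def make_cohort(
    mechanism: str,
    n_participants: int,
    trials_per_condition: int,
    seed: int,
    dt0_ms: float = 50.0,
    z_c: float = 0.60,
    dv: float = 0.40,
):
    """Single-mechanism cohort with the effect size pinned (negligible spread)."""
    profile = GenerativeProfile(
        n_participants=n_participants,
        trials_per_condition=trials_per_condition,
        mixture={mechanism: 1.0},
        dt0_ms=(dt0_ms, 1e-9),
        z_c=(z_c, 1e-9),
        dv=(dv, 1e-9),
        seed=seed,
    )
    return generate_cohort(profile)


def fit_stage2(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    cfg = MCMCConfig.reduced(seed=seed)
    fits = fit_cohort(table, cfg=cfg)
    return selection_table(fits)


@pytest.fixture(scope="session")
def t0_cohort():
    """20 participants x 250 trials/condition generated from the t0 mechanism
    with a 60 ms orienting gap."""
    table, truth = make_cohort("t0", 20, 250, seed=101, dt0_ms=60.0)
    return table, truth


@pytest.fixture(scope="session")
def t0_cohort_selection(t0_cohort):
    table, _ = t0_cohort
    return fit_stage2(table, seed=11)


@pytest.fixture(scope="session")
def z_cohort():
    """20 x 250/condition from the starting-point mechanism, z_c = 0.65."""
    table, truth = make_cohort("z", 20, 250, seed=102, z_c=0.65)
    return table, truth


@pytest.fixture(scope="session")
def z_cohort_selection(z_cohort):
    table, _ = z_cohort
    return fit_stage2(table, seed=12)


@pytest.fixture(scope="session")
def null_cohort():
    """20 x 250/condition with no condition differences (simple mechanism)."""
    table, truth = make_cohort("simple", 20, 250, seed=103)
    return table, truth


@pytest.fixture(scope="session")
def null_cohort_selection(null_cohort):
    table, _ = null_cohort
    return fit_stage2(table, seed=13)
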