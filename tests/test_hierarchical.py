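"""Hierarchical model construction, log-posterior, sampler, and differences."""

import math

import numpy as np
import pytest

from gazeddm.ddm import DDMParams
from gazeddm.hierarchical import (
    DifferenceSummary,
    HierChains,
    HierMCMCConfig,
    _data_loglik,
    _hyper_logpdf,
    _tn_logpdf,
    build_hierarchical_model,
    group_difference,
    hierarchical_log_posterior,
    sample_hierarchical,
)
from gazeddm.synth import GenerativeProfile, generate_cohort, generate_participant

BASE = DDMParams(v=3.0, a=1.2, z=0.5, t0=0.3)


def _cohort(mechanism, n_participants, n_per_cond, seed, **pins):
    profile = GenerativeProfile(
        n_participants=n_participants,
        trials_per_condition=n_per_cond,
        mixture={mechanism: 1.0},
        dt0_ms=(pins.get("dt0_ms", 50.0), 1e-9),
        z_c=(pins.get("z_c", 0.6), 1e-9),
        dv=(pins.get("dv", 0.4), 1e-9),
        seed=seed,
    )
    return generate_cohort(profile)


@pytest.fixture(scope="module")
def small_cohort():
    table, _ = _cohort("t0", 4, 100, seed=9)
    return table


def test_layouts_free_the_target_and_constrain_the_rest(small_cohort):
    spec_t0 = build_hierarchical_model("t0", small_cohort)
    assert {"t0_c", "t0_m"} <= set(spec_t0.param_names)
    assert "dv" in spec_t0.param_names and "z_c" in spec_t0.param_names

    spec_z = build_hierarchical_model("z", small_cohort)
    assert {"z_cued", "z_miscued"} <= set(spec_z.param_names)
    # the target starting points are each free on (0, 1), not reflected
    for name in ("z_cued", "z_miscued"):
        j = spec_z.param_names.index(name)
        assert spec_z.lo[j] < 0.5 < spec_z.hi[j]
    assert {"dt0", "dv"} <= set(spec_z.param_names)

    spec_v = build_hierarchical_model("v", small_cohort)
    assert {"v_cued", "v_miscued"} <= set(spec_v.param_names)
    jc = spec_v.param_names.index("v_cued")
    assert spec_v.lo[jc] < 0  # condition drifts unconstrained in sign


def test_unknown_target_and_single_participant_rejected(small_cohort):
    with pytest.raises(ValueError, match="unknown target"):
        build_hierarchical_model("a", small_cohort)
    solo = small_cohort[small_cohort["participant"] == small_cohort["participant"].iloc[0]]
    with pytest.raises(ValueError, match="2 participants"):
        build_hierarchical_model("t0", solo)


def _state(spec, theta, mu, sigma):
    P = spec.n_participants
    return {
        "individual": np.tile(theta, (P, 1)),
        "group_mu": mu,
        "group_sigma": sigma,
    }


def test_log_posterior_doubles_data_and_population_terms():
    """A duplicated participant exactly doubles the data + population terms."""
    table, _ = generate_participant("t0", BASE, {"dt0_ms": 50.0}, 60, seed=3, participant="a")
    dup = table.assign(participant="b")
    import pandas as pd

    spec = build_hierarchical_model("t0", pd.concat([table, dup], ignore_index=True))
    theta = np.array([1.2, 3.0, 0.1, 0.55, 0.30, 0.35])
    mu = np.array([1.2, 3.0, 0.2, 0.55, 0.3, 0.34])
    sigma = np.full(spec.dim, 0.2)
    total = hierarchical_log_posterior(spec, _state(spec, theta, mu, sigma))
    hyper = _hyper_logpdf(spec, mu, sigma)
    per_part = _data_loglik(spec, 0, theta) + float(
        _tn_logpdf(theta, mu, sigma, spec.lo, spec.hi).sum()
    )
    assert total == pytest.approx(hyper + 2.0 * per_part, rel=1e-12)


def test_log_posterior_rejects_out_of_domain_states(small_cohort):
    spec = build_hierarchical_model("t0", small_cohort)
    theta = np.array([1.2, 3.0, 0.1, 0.55, 0.30, 0.35])
    mu = theta.copy()
    sigma = np.full(spec.dim, 0.2)
    bad_theta = theta.copy()
    bad_theta[0] = 99.0  # boundary separation outside its domain
    assert hierarchical_log_posterior(spec, _state(spec, bad_theta, mu, sigma)) == -math.inf
    assert (
        hierarchical_log_posterior(
            spec, {"individual": np.tile(theta, (spec.n_participants, 1)),
                   "group_mu": mu, "group_sigma": -sigma}
        )
        == -math.inf
    )


def test_population_term_dominates_far_values(small_cohort):
    """With a tight group SD, values near the group mean are far more probable
    than distant ones."""
    spec = build_hierarchical_model("t0", small_cohort)
    j = spec.param_names.index("t0_c")
    near = float(_tn_logpdf(0.30, 0.30, 0.01, spec.lo[j], spec.hi[j]))
    far = float(_tn_logpdf(0.60, 0.30, 0.01, spec.lo[j], spec.hi[j]))
    assert near - far > 100


def test_wide_population_approaches_flat_prior_limit():
    """As the group SD grows, log-posterior differences between states reduce
    to data log-likelihood differences (monotonically)."""
    table, _ = generate_participant("t0", BASE, {"dt0_ms": 50.0}, 60, seed=5, participant="a")
    import pandas as pd

    both = pd.concat([table, table.assign(participant="b")], ignore_index=True)
    spec = build_hierarchical_model("t0", both)
    th1 = np.array([1.2, 3.0, 0.1, 0.55, 0.30, 0.35])
    th2 = np.array([1.0, 2.5, 0.2, 0.60, 0.25, 0.30])
    mu = th1.copy()  # population centred on one state penalises the other
    ll_gap = 2 * (_data_loglik(spec, 0, th1) - _data_loglik(spec, 0, th2))
    errs = []
    for sd in (0.05, 0.2, 1.0):
        sigma = np.full(spec.dim, sd)
        lp1 = hierarchical_log_posterior(spec, _state(spec, th1, mu, sigma))
        lp2 = hierarchical_log_posterior(spec, _state(spec, th2, mu, sigma))
        errs.append(abs((lp1 - lp2) - ll_gap))
    assert errs[0] > errs[1] > errs[2]


def test_sampler_deterministic_under_seed(small_cohort):
    spec = build_hierarchical_model("t0", small_cohort)
    cfg = HierMCMCConfig(n_chains=8, iterations=60, burn_in=30, seed=17)
    a = sample_hierarchical(spec, cfg=cfg)
    b = sample_hierarchical(spec, cfg=cfg)
    np.testing.assert_array_equal(a.group_mu, b.group_mu)
    np.testing.assert_array_equal(a.individual, b.individual)


def test_hier_config_validation():
    with pytest.raises(ValueError):
        HierMCMCConfig(iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        HierMCMCConfig(n_chains=4)


def _degenerate_chains(value_c=0.3, value_m=0.3):
    mu = np.zeros((2, 10, 6))
    mu[:, :, 4] = value_c  # t0_c
    mu[:, :, 5] = value_m  # t0_m
    return HierChains(
        target="t0",
        param_names=("a", "v", "dv", "z_c", "t0_c", "t0_m"),
        participants=["a", "b"],
        group_mu=mu,
        group_sigma=np.full_like(mu, 0.1),
        individual=np.zeros((2, 10, 2, 6)),
        acceptance_rate=0.3,
    )


def test_group_difference_degenerate_point_mass():
    diff = group_difference(_degenerate_chains())
    assert diff.mean == 0.0
    assert (diff.ci_low, diff.ci_high) == (0.0, 0.0)
    assert not diff.excludes_zero()


def test_group_difference_is_linear_in_shifts():
    base = group_difference(_degenerate_chains(0.30, 0.32))
    shifted = group_difference(_degenerate_chains(0.40, 0.32))
    assert shifted.mean - base.mean == pytest.approx(0.1)
    assert base.plausible_direction == "negative"
    assert base.plausible_mass == 1.0  # all draws negative


def test_group_difference_missing_parameter_raises():
    chains = _degenerate_chains()
    with pytest.raises(KeyError):
        group_difference(chains, target="z")


def test_small_cohort_orienting_gap_recovery():
    """6 participants x 200 trials/condition with a 50 ms orienting gap: the
    posterior difference is clearly negative."""
    table, _ = _cohort("t0", 6, 200, seed=31, dt0_ms=50.0)
    spec = build_hierarchical_model("t0", table)
    cfg = HierMCMCConfig.reduced(seed=8, iterations=500, burn_in=250)
    diff = group_difference(sample_hierarchical(spec, cfg=cfg))
    assert diff.mean < -0.015
    assert abs(diff.mean - (-0.050)) < 0.030
    assert diff.plausible_mass > 0.8
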