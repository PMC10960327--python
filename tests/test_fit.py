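"""Likelihood assembly, DE-MCMC behaviour, and parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from gazeddm.ddm import DDMParams, trial_log_density
from gazeddm.fit import (
    Chains,
    MCMCConfig,
    PriorSpec,
    de_mcmc,
    extract_max_likelihood,
    fit_participant,
    participant_log_likelihood,
)
from gazeddm.models import expand_parameters, get_model
from gazeddm.synth import generate_participant

BASE = DDMParams(v=3.0, a=1.2, z=0.5, t0=0.3)


def _participant(mechanism="t0", effects=None, n=250, seed=1):
    table, _ = generate_participant(
        mechanism, BASE, effects if effects is not None else {"dt0_ms": 60.0}, n, seed=seed
    )
    return table


def test_loglik_equals_sum_of_trial_log_densities():
    table = _participant(n=40)
    spec = get_model("t0")
    fv = {"v": 3.0, "a": 1.2, "t0": 0.29, "dt0": 0.05}
    cued_p, miscued_p = expand_parameters(spec, fv)
    expected = 0.0
    for _, row in table.iterrows():
        p = cued_p if row["condition"] == "cued" else miscued_p
        boundary = "upper" if row["correct"] else "lower"
        expected += trial_log_density(row["rt_ms"] / 1000.0, boundary, p)
    got = participant_log_likelihood(table, spec, fv)
    assert got == pytest.approx(expected, rel=1e-10)


def test_loglik_invariant_to_trial_order():
    table = _participant(n=100)
    spec = get_model("simple")
    fv = {"v": 3.0, "a": 1.2, "t0": 0.28}
    shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
    assert participant_log_likelihood(table, spec, fv) == pytest.approx(
        participant_log_likelihood(shuffled, spec, fv)
    )


def test_loglik_out_of_prior_support_is_minus_inf():
    table = _participant(n=30)
    spec = get_model("simple")
    assert participant_log_likelihood(table, spec, {"v": -1.0, "a": 1.2, "t0": 0.3}) == -math.inf
    assert participant_log_likelihood(table, spec, {"v": 3.0, "a": 1.2, "t0": 2.0}) == -math.inf


def test_truth_beats_distorted_drift_in_most_replications():
    """At the generating parameters the likelihood exceeds the value at
    doubled drift in nearly every 200-trial replication."""
    spec = get_model("simple")
    truth = {"v": 3.0, "a": 1.2, "t0": 0.3}
    distorted = {"v": 6.0, "a": 1.2, "t0": 0.3}
    wins = 0
    n_rep = 100
    for rep in range(n_rep):
        table, _ = generate_participant("simple", BASE, {}, 100, seed=1000 + rep)
        if participant_log_likelihood(table, spec, truth) > participant_log_likelihood(
            table, spec, distorted
        ):
            wins += 1
    assert wins >= 95


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        MCMCConfig(iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        MCMCConfig(iterations=100, burn_in=200)
    cfg = MCMCConfig.reduced()
    assert cfg.n_chains(6) == 12  # capped
    assert cfg.n_chains(3) == 9
    assert MCMCConfig().n_chains(1) == 4  # never fewer than 4 chains
    assert MCMCConfig().gamma(4) == pytest.approx(2.38 / math.sqrt(8))


def test_de_mcmc_is_deterministic_under_seed():
    table = _participant(n=80)
    spec = get_model("simple")
    cfg = MCMCConfig(iterations=120, burn_in=60, seed=9, min_trials=10)
    a = de_mcmc(spec, table, cfg=cfg)
    b = de_mcmc(spec, table, cfg=cfg)
    np.testing.assert_array_equal(a.samples, b.samples)
    np.testing.assert_array_equal(a.loglik, b.loglik)
    assert a.acceptance_rate == b.acceptance_rate


def test_de_mcmc_warns_on_few_trials():
    table = _participant(n=15)
    cfg = MCMCConfig(iterations=60, burn_in=30, seed=2)
    with pytest.warns(UserWarning, match="unreliable"):
        de_mcmc(get_model("simple"), table, cfg=cfg)


def _hand_chains(logliks):
    arr = np.array(logliks, dtype=float).reshape(1, -1)
    k = 2
    samples = np.arange(arr.size * k, dtype=float).reshape(1, arr.size, k)
    return Chains(
        param_names=("v", "a"),
        samples=samples,
        loglik=arr,
        logprior=np.zeros_like(arr),
        acceptance_rate=0.5,
    )


def test_extract_max_likelihood_singleton_and_argmax():
    single = _hand_chains([-3.0])
    params, ll = extract_max_likelihood(single)
    assert ll == -3.0 and params == {"v": 0.0, "a": 1.0}

    chains = _hand_chains([-10.0, -5.0, -8.0])
    params, ll = extract_max_likelihood(chains)
    assert ll == -5.0
    assert params == {"v": 2.0, "a": 3.0}  # the second sample


def test_extract_max_likelihood_tie_breaks_chain_major():
    arr = np.array([[-5.0, -7.0], [-5.0, -5.0]])
    chains = Chains(
        param_names=("v",),
        samples=np.arange(4, dtype=float).reshape(2, 2, 1),
        loglik=arr,
        logprior=np.zeros_like(arr),
        acceptance_rate=0.5,
    )
    params, ll = extract_max_likelihood(chains)
    assert ll == -5.0
    assert params["v"] == 0.0  # chain 0, iteration 0 comes first


def test_max_likelihood_dominates_posterior_mean_value():
    table = _participant(n=150, mechanism="simple", effects={})
    spec = get_model("simple")
    cfg = MCMCConfig(iterations=400, burn_in=200, seed=4)
    chains = de_mcmc(spec, table, cfg=cfg)
    _, max_ll = extract_max_likelihood(chains)
    post_mean = chains.samples.reshape(-1, chains.samples.shape[-1]).mean(axis=0)
    ll_at_mean = participant_log_likelihood(
        table, spec, dict(zip(chains.param_names, post_mean))
    )
    assert max_ll >= ll_at_mean


def test_t0_gap_recovery_within_20ms():
    """1,000 trials from the t0 variant with a 60 ms gap: the posterior mean
    of the gap lands within +-20 ms of truth."""
    table = _participant(n=500, seed=77)  # 500 per condition
    spec = get_model("t0")
    cfg = MCMCConfig.reduced(seed=21)
    fr = fit_participant(table, spec, cfg=cfg)
    j = fr.param_names.index("dt0")
    post_mean_gap = fr.chains.samples[:, :, j].mean()
    assert abs(post_mean_gap - 0.060) < 0.020
    assert all(v < 1.1 for k, v in fr.diagnostics.items() if k.startswith("rhat_"))


def test_posterior_contracts_with_more_trials():
    """Doubling the trial count shrinks the posterior SD of the drift."""
    spec = get_model("simple")
    ratios = []
    for seed in range(3):
        small, _ = generate_participant("simple", BASE, {}, 125, seed=300 + seed)
        large, _ = generate_participant("simple", BASE, {}, 250, seed=600 + seed)
        cfg = MCMCConfig(iterations=500, burn_in=250, seed=40 + seed)
        sd_small = de_mcmc(spec, small, cfg=cfg).samples[:, :, 0].std()
        sd_large = de_mcmc(spec, large, cfg=cfg).samples[:, :, 0].std()
        ratios.append(sd_large / sd_small)
    assert np.median(ratios) < 1.0


def test_prior_spec_support_and_sampling():
    spec = get_model("complex")
    priors = PriorSpec.for_model(spec)
    rng = np.random.default_rng(0)
    for _ in range(50):
        x = priors.sample(rng)
        assert math.isfinite(priors.logpdf(x))
    bad = priors.sample(rng)
    bad[0] = -1.0  # drift below its lower prior bound
    assert priors.logpdf(bad) == -math.inf
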