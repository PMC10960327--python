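"""Hierarchical Bayesian estimation of group-level cued-miscued differences.

For each target parameter (non-decision time t0, starting point z, or drift
rate v) one hierarchical model is fitted in which the target is estimated
separately per condition with *unconstrained* group-level means, while the
remaining parameters keep their directional individual-level constraints via
nonnegative gap parameters whose population distributions are truncated at
zero.  Boundary separation is shared across conditions with a single group
distribution.  Every individual-level parameter follows a truncated-normal
group distribution whose truncation equals the parameter's domain.

Inference targets the posterior of Delta = mu_target(cued) - mu_target(miscued).
A positive cueing effect predicts Delta < 0 for t0 and Delta > 0 for z and v;
the fraction of posterior mass in that plausible direction is reported with
the equal-tailed 95% credible interval.

Sampling is blocked DE-MCMC: differential-evolution proposals on each
participant's parameter block conditional on the group level, then on the
group-level block conditional on the individuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .ddm import DEFAULT_LOG_FLOOR, loglik_trials

__all__ = [
    "HierarchicalSpec",
    "HierMCMCConfig",
    "HierChains",
    "DifferenceSummary",
    "build_hierarchical_model",
    "hierarchical_log_posterior",
    "sample_hierarchical",
    "group_difference",
]

TARGETS = ("t0", "z", "v")

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)

# per-parameter (domain lo, domain hi, mu-hyperprior loc, mu-hyperprior scale,
# sigma half-normal scale)
_PARAM_TABLE: Dict[str, Tuple[float, float, float, float, float]] = {
    "a": (0.1, 5.0, 1.5, 2.0, 1.0),
    "v": (0.0, 10.0, 2.0, 4.0, 2.0),
    "dv": (0.0, 10.0, 0.0, 2.0, 1.0),
    "t0": (0.03, 1.0, 0.3, 0.3, 0.2),
    "dt0": (0.0, 1.0, 0.0, 0.2, 0.1),
    "z_c": (0.5, 0.99, 0.6, 0.3, 0.2),
    "t0_c": (0.03, 1.0, 0.3, 0.3, 0.2),
    "t0_m": (0.03, 1.0, 0.3, 0.3, 0.2),
    "z_cued": (0.01, 0.99, 0.5, 0.3, 0.2),
    "z_miscued": (0.01, 0.99, 0.5, 0.3, 0.2),
    "v_cued": (-10.0, 10.0, 2.0, 4.0, 2.0),
    "v_miscued": (-10.0, 10.0, 2.0, 4.0, 2.0),
}

# individual-level parameter layout per target; the last two entries are the
# condition-specific target parameters whose group means define Delta
_LAYOUTS: Dict[str, Tuple[str, ...]] = {
    "t0": ("a", "v", "dv", "z_c", "t0_c", "t0_m"),
    "z": ("a", "v", "dv", "t0", "dt0", "z_cued", "z_miscued"),
    "v": ("a", "t0", "dt0", "z_c", "v_cued", "v_miscued"),
}

_PLAUSIBLE_SIGN = {"t0": -1.0, "z": 1.0, "v": 1.0}


@dataclass
class HierarchicalSpec:
    """One target parameter's hierarchical model bound to a cohort."""

    target: str
    param_names: Tuple[str, ...]
    participants: List
    # per participant: (rt_s, is_upper, is_cued) arrays
    trial_arrays: List[Tuple[np.ndarray, np.ndarray, np.ndarray]]
    lo: np.ndarray
    hi: np.ndarray
    mu_loc: np.ndarray
    mu_scale: np.ndarray
    sigma_scale: np.ndarray
    s: float = 1.0
    floor: float = DEFAULT_LOG_FLOOR

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def dim(self) -> int:
        return len(self.param_names)

    def expand(self, theta: np.ndarray) -> Tuple[float, ...]:
        """(v_c, v_m, a, z_c, z_m, t0_c, t0_m) from one individual's vector."""
        p = dict(zip(self.param_names, theta))
        if self.target == "t0":
            return (
                p["v"] + p["dv"], p["v"], p["a"],
                p["z_c"], 1.0 - p["z_c"], p["t0_c"], p["t0_m"],
            )
        if self.target == "z":
            return (
                p["v"] + p["dv"], p["v"], p["a"],
                p["z_cued"], p["z_miscued"], p["t0"], p["t0"] + p["dt0"],
            )
        return (
            p["v_cued"], p["v_miscued"], p["a"],
            p["z_c"], 1.0 - p["z_c"], p["t0"], p["t0"] + p["dt0"],
        )

    def delta_names(self) -> Tuple[str, str]:
        """Group-mean names whose difference (cued - miscued) is Delta."""
        return {
            "t0": ("t0_c", "t0_m"),
            "z": ("z_cued", "z_miscued"),
            "v": ("v_cued", "v_miscued"),
        }[self.target]


def build_hierarchical_model(
    target: str, data: pd.DataFrame, s: float = 1.0
) -> HierarchicalSpec:
    """Bind the target parameter's hierarchical model to a cohort table."""
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    participants = list(pd.unique(data["participant"]))
    if len(participants) < 2:
        raise ValueError("hierarchical estimation needs at least 2 participants")
    names = _LAYOUTS[target]
    arrays = []
    for pid in participants:
        sub = data[data["participant"] == pid]
        arrays.append(
            (
                sub["rt_ms"].to_numpy(dtype=float) / 1000.0,
                sub["correct"].to_numpy(dtype=bool),
                (sub["condition"] == "cued").to_numpy(dtype=bool),
            )
        )
    rows = np.array([_PARAM_TABLE[n] for n in names])
    return HierarchicalSpec(
        target=target,
        param_names=tuple(names),
        participants=participants,
        trial_arrays=arrays,
        lo=rows[:, 0].copy(),
        hi=rows[:, 1].copy(),
        mu_loc=rows[:, 2].copy(),
        mu_scale=rows[:, 3].copy(),
        sigma_scale=rows[:, 4].copy(),
        s=s,
    )


def _tn_logpdf(x, mu, sigma, lo, hi):
    """Truncated-normal log-density; broadcasts; -inf outside [lo, hi]."""
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    alpha = (lo - mu) / sigma
    beta = (hi - mu) / sigma
    mass = ndtr(beta) - ndtr(alpha)
    with np.errstate(divide="ignore"):
        out = -0.5 * z**2 - np.log(sigma) - _HALF_LOG_2PI - np.log(mass)
    return np.where((x >= lo) & (x <= hi), out, -np.inf)


def _halfnormal_logpdf(sigma, scale):
    sigma = np.asarray(sigma, dtype=float)
    out = (
        math.log(2.0)
        - np.log(scale)
        - _HALF_LOG_2PI
        - 0.5 * (sigma / scale) ** 2
    )
    return np.where(sigma > 0, out, -np.inf)


def _data_loglik(spec: HierarchicalSpec, i: int, theta: np.ndarray) -> float:
    rt_s, upper, cued = spec.trial_arrays[i]
    vc, vm, a, zc, zm, t0c, t0m = spec.expand(theta)
    return float(
        loglik_trials(rt_s, upper, cued, vc, vm, a, zc, zm, t0c, t0m, spec.s, spec.floor)
    )


def _population_terms(spec, individuals, mu, sigma):
    """(P,) array: per-participant summed population log-density."""
    lp = _tn_logpdf(individuals, mu[None, :], sigma[None, :], spec.lo[None, :], spec.hi[None, :])
    return lp.sum(axis=1)


def _hyper_logpdf(spec, mu, sigma) -> float:
    lp_mu = _tn_logpdf(mu, spec.mu_loc, spec.mu_scale, spec.lo, spec.hi)
    lp_sig = _halfnormal_logpdf(sigma, spec.sigma_scale)
    total = lp_mu.sum() + lp_sig.sum()
    return float(total)


def hierarchical_log_posterior(spec: HierarchicalSpec, state: Mapping) -> float:
    """Full log-posterior of a complete state.

    ``state`` holds "individual" (P x d), "group_mu" (d,), "group_sigma" (d,).
    Sum of per-participant trial log-likelihoods, truncated-normal population
    terms, and group-level hyperprior terms; -inf outside any domain.
    """
    individuals = np.asarray(state["individual"], dtype=float)
    mu = np.asarray(state["group_mu"], dtype=float)
    sigma = np.asarray(state["group_sigma"], dtype=float)
    if individuals.shape != (spec.n_participants, spec.dim):
        raise ValueError("individual block has wrong shape")
    if np.any(sigma <= 0):
        return -math.inf
    if np.any(individuals < spec.lo) or np.any(individuals > spec.hi):
        return -math.inf
    lp = _hyper_logpdf(spec, mu, sigma)
    if not math.isfinite(lp):
        return -math.inf
    lp += float(_population_terms(spec, individuals, mu, sigma).sum())
    for i in range(spec.n_participants):
        lp += _data_loglik(spec, i, individuals[i])
    return lp


@dataclass(frozen=True)
class HierMCMCConfig:
    """Blocked DE-MCMC settings for the hierarchical models."""

    n_chains: int = 24
    iterations: int = 4000
    burn_in: int = 2000
    jitter: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must be < iterations")
        if self.n_chains < 6:
            raise ValueError("need at least 6 chains for DE proposals")

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "HierMCMCConfig":
        defaults = dict(n_chains=16, iterations=800, burn_in=400, seed=seed)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class HierChains:
    """Retained hierarchical chains (group level plus individuals)."""

    target: str
    param_names: Tuple[str, ...]
    participants: List
    group_mu: np.ndarray  # (chains, retained, d)
    group_sigma: np.ndarray  # (chains, retained, d)
    individual: np.ndarray  # (chains, retained, P, d)
    acceptance_rate: float

    def rhat_group(self) -> Dict[str, float]:
        import arviz as az

        out = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for j, name in enumerate(self.param_names):
                out[f"mu_{name}"] = float(az.rhat(np.ascontiguousarray(self.group_mu[:, :, j])))
        return out


def sample_hierarchical(
    spec: HierarchicalSpec, cfg: Optional[HierMCMCConfig] = None
) -> HierChains:
    """Blocked DE-MCMC over the hierarchical posterior; seeded, reproducible."""
    if cfg is None:
        cfg = HierMCMCConfig()
    rng = np.random.default_rng(cfg.seed)
    P, d = spec.n_participants, spec.dim
    C = cfg.n_chains
    gamma_ind = 2.38 / math.sqrt(2.0 * d)
    gamma_grp = 2.38 / math.sqrt(2.0 * 2)  # (mu_j, sigma_j) pairs are updated jointly

    # --- initialisation: moment-based per-participant starts, jittered per
    # chain, with a data-support check; group level starts at the cohort
    # mean/SD of the individual starts
    mu = np.empty((C, d))
    sigma = np.empty((C, d))
    ind = np.empty((C, P, d))
    ll_data = np.empty((C, P))
    floor_thresh = np.array(
        [spec.floor * arr[0].size * (1 - 1e-9) for arr in spec.trial_arrays]
    )
    centres = np.empty((P, d))
    for i, (rt_s, upper, cued) in enumerate(spec.trial_arrays):
        centres[i] = _init_vector(spec, _ez_point(rt_s, upper, cued))
    eps = 1e-4 * (spec.hi - spec.lo)
    for c in range(C):
        for i in range(P):
            ok = False
            for attempt in range(200):
                scale = 0.03 * (1 + attempt / 20.0)
                theta = centres[i] * (1.0 + scale * rng.standard_normal(d)) + eps * rng.standard_normal(d)
                theta = np.clip(theta, spec.lo + eps, spec.hi - eps)
                ll = _data_loglik(spec, i, theta)
                if ll > floor_thresh[i]:
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    f"could not initialise participant {spec.participants[i]} "
                    "with data support"
                )
            ind[c, i] = theta
            ll_data[c, i] = ll
        mu[c] = np.clip(
            ind[c].mean(axis=0) * (1.0 + 0.02 * rng.standard_normal(d)),
            spec.lo + eps,
            spec.hi - eps,
        )
        spread = ind[c].std(axis=0) + 0.2 * spec.sigma_scale
        sigma[c] = spread * rng.uniform(0.7, 1.3, size=d)

    # per-parameter population and hyperprior terms (factorise over j)
    lp_pop_j = np.empty((C, d))  # summed over participants, per parameter
    lp_hyper_j = np.empty((C, d))
    for c in range(C):
        lp_pop_j[c] = _tn_logpdf(
            ind[c], mu[c][None, :], sigma[c][None, :], spec.lo[None, :], spec.hi[None, :]
        ).sum(axis=0)
        lp_hyper_j[c] = _tn_logpdf(
            mu[c], spec.mu_loc, spec.mu_scale, spec.lo, spec.hi
        ) + _halfnormal_logpdf(sigma[c], spec.sigma_scale)

    mu_store = np.empty((C, cfg.iterations, d))
    sig_store = np.empty((C, cfg.iterations, d))
    ind_store = np.empty((C, cfg.iterations, P, d))
    mu_store[:, 0], sig_store[:, 0], ind_store[:, 0] = mu, sigma, ind

    n_acc = 0
    n_prop = 0
    for t in range(1, cfg.iterations):
        for c in range(C):
            m, n = _partners(rng, C, c)
            # occasional full-step proposals help jump between modes
            g_ind = 1.0 if rng.uniform() < 0.1 else gamma_ind
            # participant blocks conditional on this chain's group level
            for i in range(P):
                prop = ind[c, i] + g_ind * (ind[m, i] - ind[n, i]) + rng.uniform(
                    -cfg.jitter, cfg.jitter, size=d
                )
                n_prop += 1
                if np.any(prop < spec.lo) or np.any(prop > spec.hi):
                    continue
                cur_vec = _tn_logpdf(ind[c, i], mu[c], sigma[c], spec.lo, spec.hi)
                prop_vec = _tn_logpdf(prop, mu[c], sigma[c], spec.lo, spec.hi)
                ll_prop = _data_loglik(spec, i, prop)
                log_alpha = (ll_prop + prop_vec.sum()) - (ll_data[c, i] + cur_vec.sum())
                if log_alpha >= 0 or math.log(rng.uniform()) < log_alpha:
                    ind[c, i] = prop
                    ll_data[c, i] = ll_prop
                    lp_pop_j[c] += prop_vec - cur_vec
                    n_acc += 1
            # group level: each (mu_j, sigma_j) pair conditional on individuals
            m, n = _partners(rng, C, c)
            g_grp = 1.0 if rng.uniform() < 0.1 else gamma_grp
            for j in range(d):
                dmu = mu[m, j] - mu[n, j]
                dsig = sigma[m, j] - sigma[n, j]
                mu_p = mu[c, j] + g_grp * dmu + rng.uniform(-cfg.jitter, cfg.jitter)
                sig_p = sigma[c, j] + g_grp * dsig + rng.uniform(-cfg.jitter, cfg.jitter)
                n_prop += 1
                if sig_p <= 0:
                    continue
                hyper_p = float(
                    _tn_logpdf(mu_p, spec.mu_loc[j], spec.mu_scale[j], spec.lo[j], spec.hi[j])
                ) + float(_halfnormal_logpdf(sig_p, spec.sigma_scale[j]))
                if not math.isfinite(hyper_p):
                    continue
                pop_p = float(
                    _tn_logpdf(ind[c, :, j], mu_p, sig_p, spec.lo[j], spec.hi[j]).sum()
                )
                log_alpha = (hyper_p + pop_p) - (lp_hyper_j[c, j] + lp_pop_j[c, j])
                if log_alpha >= 0 or math.log(rng.uniform()) < log_alpha:
                    mu[c, j] = mu_p
                    sigma[c, j] = sig_p
                    lp_pop_j[c, j] = pop_p
                    lp_hyper_j[c, j] = hyper_p
                    n_acc += 1
        mu_store[:, t], sig_store[:, t], ind_store[:, t] = mu, sigma, ind

    sl = slice(cfg.burn_in, cfg.iterations)
    return HierChains(
        target=spec.target,
        param_names=spec.param_names,
        participants=spec.participants,
        group_mu=mu_store[:, sl],
        group_sigma=sig_store[:, sl],
        individual=ind_store[:, sl],
        acceptance_rate=n_acc / max(n_prop, 1),
    )


def _ez_point(rt_s: np.ndarray, upper: np.ndarray, cued: np.ndarray):
    """Moment-based (EZ-style) starting values from accuracy and RT moments.

    Used only to initialise chains near the bulk of the posterior; the
    sampler, not this heuristic, determines the estimates.
    """
    n = rt_s.size
    pc = (upper.sum() + 0.5) / (n + 1.0)
    pc = min(max(pc, 0.55), 0.995)
    vrt = float(np.var(rt_s[upper])) if upper.sum() > 2 else 0.01
    vrt = max(vrt, 1e-4)
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    v = max(x, 1e-6) ** 0.25
    a = L / v
    a = min(max(a, 0.3), 4.0)
    v = min(max(v, 0.3), 8.0)
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(-v * a)) / (1.0 + math.exp(-v * a))
    out = {"v": v, "a": a}
    for cond, mask in (("cued", cued), ("miscued", ~cued)):
        if mask.any():
            mrt = float(rt_s[mask].mean())
            t0 = mrt - mdt
            # keep the start strictly below the fastest trial of the condition
            t0 = min(t0, float(rt_s[mask].min()) - 0.01)
            out[f"t0_{cond}"] = min(max(t0, 0.04), 0.9)
        else:
            out[f"t0_{cond}"] = 0.25
    return out


def _init_vector(spec: HierarchicalSpec, ez: Dict[str, float]) -> np.ndarray:
    t0c, t0m = ez["t0_cued"], ez["t0_miscued"]
    if spec.target == "t0":
        vals = {"a": ez["a"], "v": ez["v"], "dv": 0.05, "z_c": 0.52,
                "t0_c": t0c, "t0_m": t0m}
    elif spec.target == "z":
        vals = {"a": ez["a"], "v": ez["v"], "dv": 0.05,
                "t0": min(t0c, t0m), "dt0": min(max(t0m - t0c, 0.0), 0.3),
                "z_cued": 0.52, "z_miscued": 0.48}
    else:
        vals = {"a": ez["a"], "t0": min(t0c, t0m),
                "dt0": min(max(t0m - t0c, 0.0), 0.3), "z_c": 0.52,
                "v_cued": ez["v"], "v_miscued": ez["v"]}
    return np.array([vals[name] for name in spec.param_names])


def _partners(rng, C, c):
    m = int(rng.integers(0, C))
    while m == c:
        m = int(rng.integers(0, C))
    n = int(rng.integers(0, C))
    while n == c or n == m:
        n = int(rng.integers(0, C))
    return m, n


def _sample_tn(rng, loc, scale, lo, hi):
    from scipy.special import ndtri

    alpha = ndtr((lo - loc) / scale)
    beta = ndtr((hi - loc) / scale)
    u = rng.uniform(alpha, beta)
    # guard against u hitting 0/1 in extreme tails
    u = min(max(u, 1e-12), 1.0 - 1e-12)
    return float(loc + scale * ndtri(u))


@dataclass
class DifferenceSummary:
    """Posterior of the group-level cued-miscued difference in the target."""

    target: str
    draws: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    plausible_direction: str  # "negative" for t0, "positive" for z and v
    plausible_mass: float
    interval: str = "equal-tailed 95%"

    def excludes_zero(self) -> bool:
        return (self.ci_low > 0) or (self.ci_high < 0)

    def to_dict(self) -> Dict:
        return {
            "target": self.target,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "plausible_direction": self.plausible_direction,
            "plausible_mass": self.plausible_mass,
            "interval": self.interval,
        }


def group_difference(
    chains: HierChains, target: Optional[str] = None, hdi: bool = False
) -> DifferenceSummary:
    """Per-draw Delta = mu_target(cued) - mu_target(miscued) with 95% interval.

    Equal-tailed by default; ``hdi=True`` switches to the highest-density
    interval (arviz).
    """
    target = target or chains.target
    names = {
        "t0": ("t0_c", "t0_m"),
        "z": ("z_cued", "z_miscued"),
        "v": ("v_cued", "v_miscued"),
    }[target]
    try:
        jc = chains.param_names.index(names[0])
        jm = chains.param_names.index(names[1])
    except ValueError:
        raise KeyError(
            f"chains for target {chains.target!r} do not carry group means for {target!r}"
        ) from None
    draws = (chains.group_mu[:, :, jc] - chains.group_mu[:, :, jm]).ravel()
    if hdi:
        import arviz as az

        lo, hi = az.hdi(draws.reshape(1, -1), hdi_prob=0.95)
        interval = "95% HDI"
    else:
        lo, hi = np.percentile(draws, [2.5, 97.5])
        interval = "equal-tailed 95%"
    sign = _PLAUSIBLE_SIGN[target]
    mass = float(np.mean(sign * draws > 0))
    return DifferenceSummary(
        target=target,
        draws=draws,
        mean=float(draws.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        plausible_direction="negative" if sign < 0 else "positive",
        plausible_mass=mass,
        interval=interval,
    )
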