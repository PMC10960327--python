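"""Individual-level Bayesian fitting by differential-evolution MCMC.

Each model variant is fitted to one participant's trials by DE-MCMC: the
proposal for chain i is ``x_i + gamma * (x_m - x_n) + U(-jitter, jitter)``
with distinct random partner chains m, n, accepted by a Metropolis step on
the log-posterior.  The number of chains defaults to three per free
parameter, with 4,000 iterations and the first 2,000 discarded as burn-in.

Priors are reasonably uninformed truncated normals, wide relative to typical
parameter estimates, so the maximum-likelihood sample is contained well
inside the posterior.  The "maximum likelihood" estimate is the retained
posterior sample with the highest data log-likelihood (not log-posterior);
per-sample log-likelihoods are cached during sampling so extraction needs no
recomputation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .ddm import DEFAULT_LOG_FLOOR, loglik_trials
from .models import ModelSpec, expand_parameters, free_parameter_count, model_catalogue

__all__ = [
    "TruncNormPrior",
    "PriorSpec",
    "default_priors",
    "MCMCConfig",
    "Chains",
    "FitResult",
    "participant_log_likelihood",
    "de_mcmc",
    "extract_max_likelihood",
    "fit_participant",
    "fit_cohort",
]

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class TruncNormPrior:
    """Truncated normal prior on [lo, hi]."""

    loc: float
    scale: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.hi > self.lo and self.scale > 0):
            raise ValueError("require hi > lo and scale > 0")

    @cached_property
    def log_z(self) -> float:
        # log of the truncation mass
        alpha = (self.lo - self.loc) / self.scale
        beta = (self.hi - self.loc) / self.scale
        return math.log(ndtr(beta) - ndtr(alpha))

    def logpdf(self, x: float) -> float:
        if not (self.lo <= x <= self.hi):
            return -math.inf
        zscore = (x - self.loc) / self.scale
        return -0.5 * zscore * zscore - math.log(self.scale) - _HALF_LOG_2PI - self.log_z

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        # inverse-CDF sampling, exact on the truncation interval
        alpha = ndtr((self.lo - self.loc) / self.scale)
        beta = ndtr((self.hi - self.loc) / self.scale)
        u = rng.uniform(alpha, beta, size=size)
        from scipy.special import ndtri

        return self.loc + self.scale * ndtri(u)


#: default priors; wide relative to typical simple-DDM estimates (seconds, s = 1)
_DEFAULT_PRIORS: Dict[str, TruncNormPrior] = {
    "v": TruncNormPrior(2.0, 3.0, 0.0, 10.0),
    "a": TruncNormPrior(1.5, 1.5, 0.1, 5.0),
    "t0": TruncNormPrior(0.3, 0.3, 0.03, 1.0),
    "dt0": TruncNormPrior(0.0, 0.2, 0.0, 1.0),
    "z_c": TruncNormPrior(0.5, 0.2, 0.5, 0.99),
    "dv": TruncNormPrior(0.0, 2.0, 0.0, 10.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Priors for one model's free-parameter vector, in free_params order."""

    param_names: Tuple[str, ...]
    priors: Tuple[TruncNormPrior, ...]

    def __post_init__(self):
        if len(self.param_names) != len(self.priors):
            raise ValueError("one prior per free parameter required")
        object.__setattr__(self, "_cache", self._build_arrays())

    @classmethod
    def for_model(
        cls, spec: ModelSpec, overrides: Optional[Mapping[str, TruncNormPrior]] = None
    ) -> "PriorSpec":
        table = dict(_DEFAULT_PRIORS)
        if overrides:
            table.update(overrides)
        return cls(
            param_names=tuple(spec.free_params),
            priors=tuple(table[name] for name in spec.free_params),
        )

    def _build_arrays(self):
        loc = np.array([p.loc for p in self.priors])
        scale = np.array([p.scale for p in self.priors])
        lo = np.array([p.lo for p in self.priors])
        hi = np.array([p.hi for p in self.priors])
        # constant part of the per-parameter log-density
        const = -np.log(scale) - _HALF_LOG_2PI - np.array([p.log_z for p in self.priors])
        return loc, scale, lo, hi, const

    def logpdf(self, x: np.ndarray) -> float:
        loc, scale, lo, hi, const = self._cache
        if np.any(x < lo) or np.any(x > hi):
            return -math.inf
        zscore = (x - loc) / scale
        return float(np.sum(-0.5 * zscore**2 + const))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([p.sample(rng) for p in self.priors])


def default_priors(spec: ModelSpec, **overrides) -> PriorSpec:
    return PriorSpec.for_model(spec, overrides=overrides or None)


@dataclass(frozen=True)
class MCMCConfig:
    """DE-MCMC settings.  Defaults mirror the full analysis configuration
    (3 chains per free parameter, 4,000 iterations, 2,000 burn-in)."""

    chains_per_free_param: int = 3
    max_chains: Optional[int] = None
    iterations: int = 4000
    burn_in: int = 2000
    de_gamma: Optional[float] = None  # None -> 2.38 / sqrt(2k)
    jitter: float = 1e-4
    seed: int = 0
    min_trials: int = 50

    def __post_init__(self):
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError(
                f"burn_in ({self.burn_in}) must be < iterations ({self.iterations})"
            )
        if self.chains_per_free_param < 1:
            raise ValueError("chains_per_free_param must be >= 1")

    def n_chains(self, k: int) -> int:
        n = self.chains_per_free_param * k
        if self.max_chains is not None:
            n = min(n, self.max_chains)
        return max(n, 4)

    def gamma(self, k: int) -> float:
        return self.de_gamma if self.de_gamma is not None else 2.38 / math.sqrt(2.0 * k)

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "MCMCConfig":
        """Lighter settings for CI-scale runs (capped chains, 1,000 iterations)."""
        defaults = dict(max_chains=12, iterations=1000, burn_in=500, seed=seed)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class Chains:
    """Retained (post burn-in) DE-MCMC samples with cached log terms."""

    param_names: Tuple[str, ...]
    samples: np.ndarray  # (n_chains, n_retained, k)
    loglik: np.ndarray  # (n_chains, n_retained)
    logprior: np.ndarray  # (n_chains, n_retained)
    acceptance_rate: float

    def rhat(self) -> Dict[str, float]:
        """Split-R-hat per parameter (arviz)."""
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return {
                name: float(az.rhat(np.ascontiguousarray(self.samples[:, :, j])))
                for j, name in enumerate(self.param_names)
            }


@dataclass
class FitResult:
    spec_name: str
    param_names: Tuple[str, ...]
    chains: Chains
    ml_params: Dict[str, float]
    max_log_lik: float
    n_trials: int
    k: int
    diagnostics: Dict[str, float] = field(default_factory=dict)

    def summary(self) -> Dict:
        return {
            "model": self.spec_name,
            "k": self.k,
            "n_trials": self.n_trials,
            "max_log_lik": self.max_log_lik,
            "ml_params": dict(self.ml_params),
            "diagnostics": dict(self.diagnostics),
        }


def _trial_arrays(trials: pd.DataFrame):
    rt_s = trials["rt_ms"].to_numpy(dtype=float) / 1000.0
    upper = trials["correct"].to_numpy(dtype=bool)
    cued = (trials["condition"] == "cued").to_numpy(dtype=bool)
    return rt_s, upper, cued


def _expand_flat(spec: ModelSpec, x: np.ndarray, names: Sequence[str]):
    """(v_c, v_m, a, z_c, z_m, t0_c, t0_m) from a free vector, no validation."""
    fv = dict(zip(names, x))
    v = fv["v"]
    a = fv["a"]
    t0c = fv["t0"]
    t0m = t0c + fv["dt0"] if spec.t0_varies else t0c
    if spec.z_varies:
        zc = fv["z_c"]
        zm = 1.0 - zc
    else:
        zc = zm = 0.5
    if spec.v_varies:
        vc, vm = v + fv["dv"], v
    else:
        vc = vm = v
    return vc, vm, a, zc, zm, t0c, t0m


def participant_log_likelihood(
    trials: pd.DataFrame,
    spec: ModelSpec,
    fv: Mapping[str, float],
    s: float = 1.0,
    floor: float = DEFAULT_LOG_FLOOR,
    priors: Optional[PriorSpec] = None,
) -> float:
    """Summed log defective density over one participant's trials.

    The upper boundary codes the correct response; each trial uses the
    parameters of its cue-validity condition; RTs are converted ms -> s.
    Free vectors outside the prior support return -inf (soft rejection).
    """
    names = tuple(spec.free_params)
    x = np.array([float(fv[n]) for n in names])
    if priors is None:
        priors = PriorSpec.for_model(spec)
    if not math.isfinite(priors.logpdf(x)):
        return -math.inf
    rt_s, upper, cued = _trial_arrays(trials)
    vc, vm, a, zc, zm, t0c, t0m = _expand_flat(spec, x, names)
    return float(loglik_trials(rt_s, upper, cued, vc, vm, a, zc, zm, t0c, t0m, s, floor))


def de_mcmc(
    spec: ModelSpec,
    trials: pd.DataFrame,
    priors: Optional[PriorSpec] = None,
    cfg: Optional[MCMCConfig] = None,
    s: float = 1.0,
    floor: float = DEFAULT_LOG_FLOOR,
    init_points: Optional[Sequence[np.ndarray]] = None,
) -> Chains:
    """Differential-evolution MCMC over one model's posterior.

    Chains are initialised at independent prior draws, re-drawn until the
    start has some data support; ``init_points`` optionally seeds the first
    chains at given free vectors (nested-model warm starts), which speeds up
    discovery of the maximum-likelihood region without altering the target
    distribution.  Sampling is fully reproducible under the config seed.
    """
    if cfg is None:
        cfg = MCMCConfig()
    if priors is None:
        priors = PriorSpec.for_model(spec)
    n_trials = len(trials)
    if n_trials < cfg.min_trials:
        warnings.warn(
            f"only {n_trials} trials; fits below {cfg.min_trials} trials are unreliable"
        )
    k = free_parameter_count(spec)
    n_chains = cfg.n_chains(k)
    gamma = cfg.gamma(k)
    rng = np.random.default_rng(cfg.seed)
    rt_s, upper, cued = _trial_arrays(trials)
    names = tuple(spec.free_params)

    def loglik(x: np.ndarray) -> float:
        vc, vm, a, zc, zm, t0c, t0m = _expand_flat(spec, x, names)
        return loglik_trials(rt_s, upper, cued, vc, vm, a, zc, zm, t0c, t0m, s, floor)

    # initialise: prior draws with at least some in-support trials
    degenerate = floor * n_trials * (1.0 - 1e-9)
    state = np.empty((n_chains, k))
    cur_ll = np.empty(n_chains)
    cur_lp = np.empty(n_chains)
    warm = list(init_points or [])
    for i in range(n_chains):
        ok = False
        if i < len(warm):
            _, _, lo, hi, _ = priors._cache
            x = np.asarray(warm[i], dtype=float) + rng.normal(0.0, 1e-4, size=k)
            x = np.clip(x, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo))
            if math.isfinite(priors.logpdf(x)):
                ll = loglik(x)
                if ll > degenerate:
                    ok = True
        if not ok:
            for _ in range(500):
                x = priors.sample(rng)
                ll = loglik(x)
                if ll > degenerate:
                    ok = True
                    break
        if not ok:
            raise RuntimeError(
                "could not initialise chains with data support; check trial RTs "
                "against the non-decision-time prior"
            )
        state[i] = x
        cur_ll[i] = ll
        cur_lp[i] = priors.logpdf(x)

    samples = np.empty((n_chains, cfg.iterations, k))
    ll_store = np.empty((n_chains, cfg.iterations))
    lp_store = np.empty((n_chains, cfg.iterations))
    samples[:, 0] = state
    ll_store[:, 0] = cur_ll
    lp_store[:, 0] = cur_lp

    n_accept = 0
    n_prop = 0
    for t in range(1, cfg.iterations):
        partners = rng.integers(0, n_chains, size=(n_chains, 8))
        for i in range(n_chains):
            # two distinct partner chains, both different from i
            row = partners[i]
            m = n = i
            for cand in row:
                if cand != i and m == i:
                    m = cand
                elif cand != i and cand != m:
                    n = cand
                    break
            while m == i:
                m = int(rng.integers(0, n_chains))
            while n == i or n == m:
                n = int(rng.integers(0, n_chains))
            prop = state[i] + gamma * (state[m] - state[n]) + rng.uniform(
                -cfg.jitter, cfg.jitter, size=k
            )
            lp = priors.logpdf(prop)
            n_prop += 1
            if math.isfinite(lp):
                ll = loglik(prop)
                log_alpha = (ll + lp) - (cur_ll[i] + cur_lp[i])
                if log_alpha >= 0 or math.log(rng.uniform()) < log_alpha:
                    state[i] = prop
                    cur_ll[i] = ll
                    cur_lp[i] = lp
                    n_accept += 1
        samples[:, t] = state
        ll_store[:, t] = cur_ll
        lp_store[:, t] = cur_lp

    sl = slice(cfg.burn_in, cfg.iterations)
    return Chains(
        param_names=names,
        samples=samples[:, sl],
        loglik=ll_store[:, sl],
        logprior=lp_store[:, sl],
        acceptance_rate=n_accept / max(n_prop, 1),
    )


def extract_max_likelihood(chains: Chains) -> Tuple[Dict[str, float], float]:
    """Retained sample with the highest data log-likelihood.

    Ties break toward the first occurrence in (chain, iteration) order.
    """
    if chains.loglik.size == 0:
        raise ValueError("empty chains")
    flat = chains.loglik.ravel()  # C order = chain-major
    best = int(np.argmax(flat))
    ci, ti = divmod(best, chains.loglik.shape[1])
    ml = chains.samples[ci, ti]
    return dict(zip(chains.param_names, map(float, ml))), float(flat[best])


def _polish_ml(
    spec: ModelSpec,
    priors: PriorSpec,
    trials: pd.DataFrame,
    starts: Sequence[np.ndarray],
    s: float,
    floor: float = DEFAULT_LOG_FLOOR,
) -> Tuple[np.ndarray, float]:
    """Bounded Nelder-Mead refinement of the maximum likelihood.

    Maximum-over-samples estimates of the likelihood maximum fall short by an
    amount that grows with the number of free parameters, which would bias
    information criteria against flexible variants beyond the intended
    complexity penalty; a short deterministic polish from the best sampled
    points removes that artefact.
    """
    from scipy.optimize import minimize

    rt_s, upper, cued = _trial_arrays(trials)
    names = tuple(spec.free_params)
    _, _, lo, hi, _ = priors._cache
    span = hi - lo
    bounds = list(zip(lo + 1e-9 * span, hi - 1e-9 * span))

    def neg(x: np.ndarray) -> float:
        vc, vm, a, zc, zm, t0c, t0m = _expand_flat(spec, x, names)
        return -loglik_trials(rt_s, upper, cued, vc, vm, a, zc, zm, t0c, t0m, s, floor)

    best_x, best_ll = None, -math.inf
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo + 1e-9 * span, hi - 1e-9 * span)
        res = minimize(neg, x0, method="Nelder-Mead", bounds=bounds,
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if -res.fun > best_ll:
            best_ll = float(-res.fun)
            best_x = np.asarray(res.x, dtype=float)
    return best_x, best_ll


def fit_participant(
    trials: pd.DataFrame,
    spec: ModelSpec,
    priors: Optional[PriorSpec] = None,
    cfg: Optional[MCMCConfig] = None,
    s: float = 1.0,
    compute_rhat: bool = True,
    init_points: Optional[Sequence[np.ndarray]] = None,
    polish: bool = True,
) -> FitResult:
    """Fit one model variant to one participant's trials.

    With ``polish`` (default), the maximum-likelihood point is refined by a
    bounded simplex search started from the best retained sample (and any
    warm-start points), so BIC/AIC rest on a consistent ML estimate across
    variants of different dimensionality.
    """
    if priors is None:
        priors = PriorSpec.for_model(spec)
    chains = de_mcmc(spec, trials, priors=priors, cfg=cfg, s=s, init_points=init_points)
    ml_params, max_ll = extract_max_likelihood(chains)
    diagnostics: Dict[str, float] = {"acceptance_rate": chains.acceptance_rate}
    if polish:
        starts = [np.array([ml_params[n] for n in chains.param_names])]
        starts.extend(init_points or [])
        px, pll = _polish_ml(spec, priors, trials, starts, s)
        diagnostics["ml_polish_gain"] = max(pll - max_ll, 0.0)
        if pll > max_ll:
            max_ll = pll
            ml_params = dict(zip(chains.param_names, map(float, px)))
    if compute_rhat:
        for name, value in chains.rhat().items():
            diagnostics[f"rhat_{name}"] = value
    return FitResult(
        spec_name=spec.name,
        param_names=chains.param_names,
        chains=chains,
        ml_params=ml_params,
        max_log_lik=max_ll,
        n_trials=len(trials),
        k=free_parameter_count(spec),
        diagnostics=diagnostics,
    )


def fit_cohort(
    table: pd.DataFrame,
    specs: Optional[Sequence[ModelSpec]] = None,
    cfg: Optional[MCMCConfig] = None,
    prior_overrides: Optional[Mapping[str, TruncNormPrior]] = None,
    s: float = 1.0,
    compute_rhat: bool = False,
    progress: bool = False,
) -> Dict[Tuple, FitResult]:
    """Fit every model variant to every participant.

    Per-(participant, model) seeds are derived deterministically from the
    config seed, so reruns reproduce exactly.  Returns a dict keyed by
    (participant, model name).
    """
    if specs is None:
        specs = model_catalogue()
    if cfg is None:
        cfg = MCMCConfig()
    participants = list(pd.unique(table["participant"]))
    results: Dict[Tuple, FitResult] = {}
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(len(participants) * len(specs)) % (2**31)
    i = 0
    for pid in participants:
        trials = table[table["participant"] == pid]
        done: List[FitResult] = []
        for spec in specs:
            sub_cfg = replace(cfg, seed=int(seeds[i]))
            i += 1
            priors = PriorSpec.for_model(spec, overrides=prior_overrides)
            warm = _nested_warm_starts(spec, done, max_points=sub_cfg.n_chains(
                free_parameter_count(spec)) // 2)
            fr = fit_participant(
                trials, spec, priors=priors, cfg=sub_cfg, s=s,
                compute_rhat=compute_rhat, init_points=warm,
            )
            done.append(fr)
            results[(pid, spec.name)] = fr
        if progress:
            print(f"fitted participant {pid} ({len(specs)} models)")
    return results


#: boundary-adjacent values used when embedding a nested model's ML point
#: into a larger model's free space
_EMBED_DEFAULTS = {"dt0": 1e-3, "dv": 1e-3, "z_c": 0.501}


def _nested_warm_starts(
    spec: ModelSpec, fitted: Sequence[FitResult], max_points: int
) -> List[np.ndarray]:
    """ML points of already-fitted nested sub-models, embedded in spec's space.

    A variant nests another when its free parameters are a superset; the
    sub-model's maximum-likelihood point maps to the larger space with gap
    parameters placed just inside their support.  Best sub-fits first.
    """
    candidates = [
        fr
        for fr in fitted
        if set(fr.param_names) < set(spec.free_params)
    ]
    candidates.sort(key=lambda fr: -fr.max_log_lik)
    points = []
    for fr in candidates[:max_points]:
        fv = dict(fr.ml_params)
        points.append(
            np.array(
                [fv.get(name, _EMBED_DEFAULTS.get(name, 0.0)) for name in spec.free_params]
            )
        )
    return points
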