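"""Synthetic gaze-cueing cohorts with known generating mechanisms.

Participants are simulated from the simple DDM with a known mechanism behind
any cued/miscued difference: a non-decision-time gap (attentional orienting),
a starting-point bias toward the cued side (transient resource allocation), a
drift-rate advantage (sustained resource allocation), combinations, or no
difference at all ("simple", the null mechanism).  A truth sidecar records
each participant's mechanism and exact generating parameters, so recovery of
mechanisms and parameters can be scored.

Default base parameters (v = 3, a = 1.2, t0 = 0.30 s, s = 1) put accuracy in
the mid-90s% and mean RTs at a few hundred milliseconds, matching the ranges
typical of localisation cueing tasks.  Contaminant response times outside
[100, 5000] ms can be planted at small rates to exercise exclusion filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_rts
from .models import MODEL_NAMES, expand_parameters, get_model

__all__ = [
    "GenerativeProfile",
    "COHORT_PRESETS",
    "generate_participant",
    "generate_cohort",
    "contaminate",
]

#: default per-mechanism prevalence, echoing the qualitative finding that
#: orienting (t0) dominates, a minority show starting-point effects, and
#: drift effects are rare
DEFAULT_MIXTURE: Dict[str, float] = {
    "t0": 0.55,
    "z": 0.25,
    "v": 0.05,
    "simple": 0.10,
    "t0-z": 0.05,
}


@dataclass(frozen=True)
class GenerativeProfile:
    """Cohort-level generating conditions.

    Effect sizes and base parameters are drawn per participant from normal
    distributions truncated to plausible ranges; ``mixture`` gives each
    mechanism's prevalence.
    """

    n_participants: int
    trials_per_condition: int
    mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    base_v: Tuple[float, float] = (3.0, 0.5)  # (mean, sd)
    base_a: Tuple[float, float] = (1.2, 0.15)
    base_t0: Tuple[float, float] = (0.30, 0.03)
    dt0_ms: Tuple[float, float] = (50.0, 15.0)
    z_c: Tuple[float, float] = (0.60, 0.04)
    dv: Tuple[float, float] = (0.40, 0.15)
    fast_rate: float = 0.0
    slow_rate: float = 0.0
    s: float = 1.0
    dt: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        total = sum(self.mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mechanism mixture must sum to 1, got {total}")
        unknown = set(self.mixture) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown mechanisms in mixture: {sorted(unknown)}")


#: presets emulating the shapes of the three analysed data sets
#: (participants x trials/condition; contaminant rates match their removal rates)
COHORT_PRESETS: Dict[str, GenerativeProfile] = {
    "ds1-like": GenerativeProfile(
        n_participants=41, trials_per_condition=120, fast_rate=0.0007, slow_rate=0.0007
    ),
    "ds2-like": GenerativeProfile(
        n_participants=50, trials_per_condition=128, fast_rate=0.0005, slow_rate=0.0005
    ),
    "ds3-like": GenerativeProfile(
        n_participants=71, trials_per_condition=750, fast_rate=0.01, slow_rate=0.01
    ),
}

_EFFECT_KEYS = {"dt0": "dt0_ms", "z_c": "z_c", "dv": "dv"}


def _free_vector(mechanism: str, base: DDMParams, effects: Mapping[str, float]):
    spec = get_model(mechanism)
    fv = {"v": base.v, "a": base.a, "t0": base.t0}
    if spec.t0_varies:
        if "dt0_ms" not in effects:
            raise ValueError(f"mechanism {mechanism!r} needs effect 'dt0_ms'")
        fv["dt0"] = effects["dt0_ms"] / 1000.0
    if spec.z_varies:
        if "z_c" not in effects:
            raise ValueError(f"mechanism {mechanism!r} needs effect 'z_c'")
        fv["z_c"] = effects["z_c"]
    if spec.v_varies:
        if "dv" not in effects:
            raise ValueError(f"mechanism {mechanism!r} needs effect 'dv'")
        fv["dv"] = effects["dv"]
    return spec, fv


def generate_participant(
    mechanism: str,
    base: DDMParams,
    effects: Mapping[str, float],
    n_per_condition: int,
    seed: int,
    participant: str = "p1",
    dt: float = 1e-4,
) -> Tuple[pd.DataFrame, Dict]:
    """Simulate one participant's cued and miscued trials.

    The upper boundary codes the correct response, so a trial is correct iff
    the walk absorbs at the upper boundary.  Target side is balanced at
    random; the response side follows correctness.
    """
    spec, fv = _free_vector(mechanism, base, effects)
    cued_p, miscued_p = expand_parameters(spec, fv, s=base.s)
    ss = np.random.SeedSequence(seed)
    s_cued, s_miscued, s_sides = (int(x) for x in ss.generate_state(3) % (2**31))
    rng = np.random.default_rng(s_sides)

    frames = []
    for cond, params, sim_seed in (
        ("cued", cued_p, s_cued),
        ("miscued", miscued_p, s_miscued),
    ):
        rts, upper = simulate_rts(params, n_per_condition, dt=dt, seed=sim_seed)
        target = rng.choice(["left", "right"], size=n_per_condition)
        response = np.where(upper, target, np.where(target == "left", "right", "left"))
        frames.append(
            pd.DataFrame(
                {
                    "participant": participant,
                    "condition": cond,
                    "response_side": response,
                    "correct": upper,
                    "rt_ms": rts * 1000.0,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    truth = {
        "participant": participant,
        "mechanism": mechanism,
        "v_c": cued_p.v,
        "v_m": miscued_p.v,
        "a": cued_p.a,
        "z_c": cued_p.z,
        "z_m": miscued_p.z,
        "t0_c_s": cued_p.t0,
        "t0_m_s": miscued_p.t0,
        "s": cued_p.s,
    }
    return table, truth


def _draw_trunc(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def generate_cohort(profile: GenerativeProfile) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a whole cohort under a generative profile.

    Returns the trial table (contaminated at the profile's rates, with the
    truth flag column) and the truth sidecar, one row per participant.
    """
    rng = np.random.default_rng(profile.seed)
    mech_names = list(profile.mixture.keys())
    mech_probs = np.array([profile.mixture[m] for m in mech_names], dtype=float)
    ss = np.random.SeedSequence(profile.seed)
    seeds = ss.generate_state(profile.n_participants + 1) % (2**31)

    tables = []
    truths = []
    width = len(str(profile.n_participants))
    for i in range(profile.n_participants):
        pid = f"p{i + 1:0{width}d}"
        mechanism = mech_names[rng.choice(len(mech_names), p=mech_probs)]
        base = DDMParams(
            v=_draw_trunc(rng, *profile.base_v, 0.5, 8.0),
            a=_draw_trunc(rng, *profile.base_a, 0.5, 3.0),
            z=0.5,
            t0=_draw_trunc(rng, *profile.base_t0, 0.1, 0.8),
            s=profile.s,
        )
        effects = {
            "dt0_ms": _draw_trunc(rng, *profile.dt0_ms, 5.0, 200.0),
            "z_c": _draw_trunc(rng, *profile.z_c, 0.52, 0.80),
            "dv": _draw_trunc(rng, *profile.dv, 0.05, 2.0),
        }
        table, truth = generate_participant(
            mechanism,
            base,
            effects,
            profile.trials_per_condition,
            seed=int(seeds[i]),
            participant=pid,
            dt=profile.dt,
        )
        tables.append(table)
        truths.append(truth)
    cohort = pd.concat(tables, ignore_index=True)
    cohort = contaminate(
        cohort, profile.fast_rate, profile.slow_rate, seed=int(seeds[-1])
    )
    return cohort, pd.DataFrame(truths)


def contaminate(
    table: pd.DataFrame, fast_rate: float, slow_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Replace small fractions of RTs with contaminants outside [100, 5000] ms.

    Flags planted contaminants in an ``is_contaminant`` truth column so
    exclusion filters can be scored exactly.
    """
    for name, rate in (("fast_rate", fast_rate), ("slow_rate", slow_rate)):
        if not 0.0 <= rate <= 0.05:
            raise ValueError(f"{name} must be in [0, 0.05], got {rate}")
    out = table.copy()
    out["is_contaminant"] = False
    n = len(out)
    n_fast = int(round(fast_rate * n))
    n_slow = int(round(slow_rate * n))
    if n_fast + n_slow == 0:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_fast + n_slow, replace=False)
    fast_idx, slow_idx = chosen[:n_fast], chosen[n_fast:]
    rt = out["rt_ms"].to_numpy(dtype=float, copy=True)
    rt[fast_idx] = rng.uniform(20.0, 99.0, size=n_fast)
    rt[slow_idx] = rng.uniform(5001.0, 9000.0, size=n_slow)
    out["rt_ms"] = rt
    flag = out["is_contaminant"].to_numpy(copy=True)
    flag[chosen] = True
    out["is_contaminant"] = flag
    return out
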