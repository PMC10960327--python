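"""The eight constrained DDM variants compared across cueing conditions.

Each variant states which parameters may differ between cued and miscued
trials.  Constraints are directional, assuming a positive cueing effect:
non-decision time may only be shorter on cued trials (t0c <= t0m), the
starting point may only be biased toward the cued side (zc >= 0.5 with
zm = 1 - zc), and drift may only be higher on cued trials (vc >= vm).
Boundary separation ``a`` is shared in every variant, and when the starting
point is not free it is fixed at the unbiased midpoint z = 0.5.

Directional inequalities are realised by a gap reparameterisation: the free
vector carries the cued-condition value plus a nonnegative gap (``dt0``,
``dv``), so every admissible free vector maps to a constraint-satisfying
parameter pair by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

from .ddm import DDMParams

__all__ = [
    "ModelSpec",
    "MODEL_NAMES",
    "model_catalogue",
    "get_model",
    "expand_parameters",
    "free_parameter_count",
    "catalogue_to_json",
]

#: canonical ordering of the variants (simplest to most flexible)
MODEL_NAMES = ("simple", "t0", "z", "v", "z-v", "t0-v", "t0-z", "complex")

#: free-parameter names in canonical order
_PARAM_ORDER = ("v", "a", "t0", "dt0", "z_c", "dv")


@dataclass(frozen=True)
class ModelSpec:
    """One model variant: its free parameters and cross-condition constraints.

    ``constraint_map`` records, per DDM parameter, whether it is shared across
    conditions, fixed, or condition-specific with a direction.
    """

    name: str
    free_params: Tuple[str, ...]
    constraint_map: Mapping[str, str]

    @property
    def t0_varies(self) -> bool:
        return "dt0" in self.free_params

    @property
    def z_varies(self) -> bool:
        return "z_c" in self.free_params

    @property
    def v_varies(self) -> bool:
        return "dv" in self.free_params

    def varies(self, parameter: str) -> bool:
        """Does ``parameter`` (one of 't0', 'z', 'v') differ across conditions?"""
        return {"t0": self.t0_varies, "z": self.z_varies, "v": self.v_varies}[parameter]


def _make_spec(name: str, t0_free: bool, z_free: bool, v_free: bool) -> ModelSpec:
    free = ["v", "a", "t0"]
    if t0_free:
        free.append("dt0")
    if z_free:
        free.append("z_c")
    if v_free:
        free.append("dv")
    free.sort(key=_PARAM_ORDER.index)
    constraints = {
        "t0": "t0c <= t0m" if t0_free else "t0c = t0m",
        "z": "zc >= 0.5, zm = 1 - zc" if z_free else "z = 0.5 (fixed)",
        "v": "vc >= vm" if v_free else "vc = vm",
        "a": "ac = am",
    }
    return ModelSpec(name=name, free_params=tuple(free), constraint_map=constraints)


_CATALOGUE: Dict[str, ModelSpec] = {
    "simple": _make_spec("simple", False, False, False),
    "t0": _make_spec("t0", True, False, False),
    "z": _make_spec("z", False, True, False),
    "v": _make_spec("v", False, False, True),
    "z-v": _make_spec("z-v", False, True, True),
    "t0-v": _make_spec("t0-v", True, False, True),
    "t0-z": _make_spec("t0-z", True, True, False),
    "complex": _make_spec("complex", True, True, True),
}


def model_catalogue() -> List[ModelSpec]:
    """All eight variants, simplest first."""
    return [_CATALOGUE[n] for n in MODEL_NAMES]


def get_model(name: str) -> ModelSpec:
    try:
        return _CATALOGUE[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; expected one of {MODEL_NAMES}") from None


def free_parameter_count(spec: ModelSpec) -> int:
    """Number of free parameters k (drives chain counts and AIC/BIC penalties)."""
    return len(spec.free_params)


def expand_parameters(
    spec: ModelSpec, fv: Mapping[str, float], s: float = 1.0
) -> Tuple[DDMParams, DDMParams]:
    """Map a free vector to the (cued, miscued) DDMParams pair.

    The starting point is coded relative to the *correct* boundary: on cued
    trials the accumulator starts at z_c (>= 0.5, biased toward correct), on
    miscued trials at 1 - z_c (biased away), which is the zm = 1 - zc
    constraint under correctness coding.
    """
    supplied = set(fv)
    expected = set(spec.free_params)
    if supplied != expected:
        missing = expected - supplied
        extra = supplied - expected
        raise ValueError(
            f"free vector does not match model {spec.name!r}: "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    v = float(fv["v"])
    a = float(fv["a"])
    t0_c = float(fv["t0"])

    if spec.t0_varies:
        dt0 = float(fv["dt0"])
        if dt0 < 0:
            raise ValueError(f"non-decision-time gap dt0 must be >= 0, got {dt0}")
        t0_m = t0_c + dt0
    else:
        t0_m = t0_c

    if spec.z_varies:
        z_c = float(fv["z_c"])
        if not 0.5 <= z_c < 1.0:
            raise ValueError(f"cued starting point z_c must be in [0.5, 1), got {z_c}")
        z_m = 1.0 - z_c
    else:
        z_c = z_m = 0.5

    if spec.v_varies:
        dv = float(fv["dv"])
        if dv < 0:
            raise ValueError(f"drift gap dv must be >= 0, got {dv}")
        v_c, v_m = v + dv, v
    else:
        v_c = v_m = v

    cued = DDMParams(v=v_c, a=a, z=z_c, t0=t0_c, s=s)
    miscued = DDMParams(v=v_m, a=a, z=z_m, t0=t0_m, s=s)
    return cued, miscued


def catalogue_to_json() -> str:
    """Serialisable registry of the constraint set, for run manifests."""
    payload = [
        {
            "name": m.name,
            "free_params": list(m.free_params),
            "k": free_parameter_count(m),
            "constraints": dict(m.constraint_map),
        }
        for m in model_catalogue()
    ]
    return json.dumps(payload, indent=2)
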