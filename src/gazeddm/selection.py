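"""Model comparison: BIC/AIC, Akaike-style weights, inclusion probabilities.

Per participant, each fitted variant's maximum log-likelihood is converted to
BIC = k ln(n) - 2 max_ll and AIC = 2k - 2 max_ll (n = that participant's
analysed trial count), then to weighted model probabilities
w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2).  The inclusion probability
of a parameter (t0, z, or v) is the summed weight of the four variants in
which it varies across cueing conditions; inclusion and exclusion masses sum
to one by construction.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import MODEL_NAMES, free_parameter_count, get_model, model_catalogue

__all__ = [
    "information_criteria",
    "model_weights",
    "inclusion_probabilities",
    "selection_table",
    "cohort_summary",
    "inclusion_table",
    "best_model",
    "magnitude_weight_correlation",
    "INCLUSION_PARAMS",
]

INCLUSION_PARAMS = ("t0", "z", "v")


def information_criteria(max_log_lik: float, k: int, n: int) -> Tuple[float, float]:
    """(BIC, AIC) from a maximum log-likelihood; lower is better."""
    if k < 1:
        raise ValueError(f"free-parameter count k must be >= 1, got {k}")
    if n < 1:
        raise ValueError(f"trial count n must be >= 1, got {n}")
    bic = k * math.log(n) - 2.0 * max_log_lik
    aic = 2.0 * k - 2.0 * max_log_lik
    return bic, aic


def model_weights(scores: Mapping[str, float]) -> Dict[str, float]:
    """Convert one criterion's scores into weighted model probabilities.

    Numerically stabilised by shifting to the minimum score before
    exponentiating.
    """
    for name, score in scores.items():
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for model {name!r}")
    names = list(scores)
    values = np.array([scores[n] for n in names], dtype=float)
    delta = values - values.min()
    raw = np.exp(-delta / 2.0)
    w = raw / raw.sum()
    return dict(zip(names, map(float, w)))


def inclusion_probabilities(weights: Mapping[str, float]) -> Dict[str, float]:
    """Per-parameter inclusion probability from full-catalogue weights.

    inclusion(theta) = summed weight of the four variants where theta varies
    across conditions (for v: the v, t0-v, z-v, and complex variants).
    """
    missing = set(MODEL_NAMES) - set(weights)
    if missing:
        raise ValueError(f"weights missing models {sorted(missing)}")
    out = {}
    for param in INCLUSION_PARAMS:
        out[param] = float(
            sum(weights[m] for m in MODEL_NAMES if get_model(m).varies(param))
        )
    return out


def best_model(weights: Mapping[str, float]) -> str:
    """Highest-weight model; ties break to fewer free parameters, then name."""
    return max(
        weights,
        key=lambda m: (weights[m], -free_parameter_count(get_model(m)), _revname(m)),
    )


def _revname(name: str) -> tuple:
    # lexicographically smaller name wins a residual tie under max()
    return tuple(-ord(c) for c in name)


def selection_table(fit_results: Mapping[Tuple, "FitResult"]) -> pd.DataFrame:
    """Tidy per-participant-by-model table of criteria and weights.

    ``fit_results`` is keyed by (participant, model name), as returned by
    ``fit.fit_cohort``.
    """
    rows = []
    participants = sorted({pid for pid, _ in fit_results}, key=str)
    for pid in participants:
        scores_bic: Dict[str, float] = {}
        scores_aic: Dict[str, float] = {}
        per_model = {}
        for m in MODEL_NAMES:
            fr = fit_results[(pid, m)]
            bic, aic = information_criteria(fr.max_log_lik, fr.k, fr.n_trials)
            scores_bic[m] = bic
            scores_aic[m] = aic
            per_model[m] = fr
        w_bic = model_weights(scores_bic)
        w_aic = model_weights(scores_aic)
        best_bic = best_model(w_bic)
        best_aic = best_model(w_aic)
        for m in MODEL_NAMES:
            fr = per_model[m]
            rows.append(
                {
                    "participant": pid,
                    "model": m,
                    "k": fr.k,
                    "n_trials": fr.n_trials,
                    "max_log_lik": fr.max_log_lik,
                    "bic": scores_bic[m],
                    "aic": scores_aic[m],
                    "w_bic": w_bic[m],
                    "w_aic": w_aic[m],
                    "best_bic": best_bic,
                    "best_aic": best_aic,
                }
            )
    return pd.DataFrame(rows)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort averages per model: mean weights (as %), mean raw scores, and
    counts of participants best described by each variant."""
    if table["participant"].nunique() < 1:
        raise ValueError("need at least one participant")
    rows = []
    per_part = table.drop_duplicates("participant")
    for m in MODEL_NAMES:
        sub = table[table["model"] == m]
        rows.append(
            {
                "model": m,
                "prob_bic_pct": 100.0 * sub["w_bic"].mean(),
                "raw_bic": sub["bic"].mean(),
                "prob_aic_pct": 100.0 * sub["w_aic"].mean(),
                "raw_aic": sub["aic"].mean(),
                "n_best_bic": int((per_part["best_bic"] == m).sum()),
                "n_best_aic": int((per_part["best_aic"] == m).sum()),
            }
        )
    return pd.DataFrame(rows)


def inclusion_table(table: pd.DataFrame, criterion: str = "bic") -> pd.DataFrame:
    """Per-participant parameter-inclusion probabilities plus cohort means.

    BIC-based by default; AIC available via ``criterion="aic"``.
    """
    col = {"bic": "w_bic", "aic": "w_aic"}[criterion]
    rows = []
    for pid, sub in table.groupby("participant", sort=False):
        weights = dict(zip(sub["model"], sub[col]))
        inc = inclusion_probabilities(weights)
        rows.append({"participant": pid, **{f"inclusion_{p}": inc[p] for p in INCLUSION_PARAMS}})
    return pd.DataFrame(rows)


def magnitude_weight_correlation(
    simple_model_probs: Sequence[float], magnitudes: Sequence[float]
) -> Tuple[float, float]:
    """Pearson r between simple-model probability and cueing magnitude, with a
    default-prior (JZS, stretched-beta) Bayes factor for the correlation."""
    x = np.asarray(simple_model_probs, dtype=float)
    y = np.asarray(magnitudes, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    r = float(np.corrcoef(x, y)[0, 1])
    from pingouin import bayesfactor_pearson

    bf = float(bayesfactor_pearson(r, x.size))
    return r, bf
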