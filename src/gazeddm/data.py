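"""Trial tables, exclusion rules, and cueing-magnitude descriptives.

A trial table is a pandas DataFrame in long format with one row per trial and
the canonical columns

    participant   identifier
    condition     "cued" | "miscued"
    response_side "left" | "right"
    correct       bool
    rt_ms         response time in milliseconds

Exclusion rules: trials with response times below 100 ms or above 5,000 ms
are removed first (boundaries are kept: the rule is strictly less / strictly
greater); participants whose accuracy over their remaining trials falls below
80% are then removed entirely.

The cueing magnitude is each participant's mean miscued RT minus mean cued RT
(positive = faster at the cued location).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "TableAdapter",
    "ExclusionReport",
    "SMCResult",
    "CueingSummary",
    "load_trial_table",
    "validate_trial_table",
    "apply_exclusions",
    "cueing_magnitudes",
    "standardized_mean_change",
]

CANONICAL_COLUMNS = ("participant", "condition", "response_side", "correct", "rt_ms")

_CONDITIONS = ("cued", "miscued")


@dataclass(frozen=True)
class TableAdapter:
    """Per-dataset recoding applied before column mapping.

    keep_values: column -> allowed values; rows with other values are dropped
    (e.g., keeping only gaze-type cues, or dropping forward-gaze trials).
    value_maps: column -> {source value: canonical value} recodings.
    """

    keep_values: Mapping[str, Sequence] = field(default_factory=dict)
    value_maps: Mapping[str, Mapping] = field(default_factory=dict)

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df
        for col, allowed in self.keep_values.items():
            if col not in out.columns:
                raise KeyError(f"adapter filter column {col!r} not in table")
            out = out[out[col].isin(list(allowed))]
        out = out.copy()
        for col, mapping in self.value_maps.items():
            if col not in out.columns:
                raise KeyError(f"adapter recode column {col!r} not in table")
            out[col] = out[col].map(lambda x, m=mapping: m.get(x, x))
        return out


@dataclass
class ExclusionReport:
    n_trials_in: int
    n_trials_rt_excluded: int
    participants_excluded_accuracy: List
    n_trials_accuracy_excluded: int
    n_trials_out: int

    def to_dict(self) -> Dict:
        return {
            "n_trials_in": self.n_trials_in,
            "n_trials_rt_excluded": self.n_trials_rt_excluded,
            "participants_excluded_accuracy": list(self.participants_excluded_accuracy),
            "n_trials_accuracy_excluded": self.n_trials_accuracy_excluded,
            "n_trials_out": self.n_trials_out,
        }


@dataclass
class SMCResult:
    """Standardised mean change with the formula variant recorded."""

    smc: float
    variant: str  # "change" (mean change / SD of change) or "raw"
    bias_corrected: bool
    n: int
    se: Optional[float] = None


@dataclass
class CueingSummary:
    per_participant_magnitude_ms: pd.Series
    mean_ms: float
    sd_ms: float
    smc: SMCResult
    n_positive: int
    n_participants: int
    participants_missing_condition: List = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.per_participant_magnitude_ms.rename("magnitude_ms").reset_index()


def load_trial_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    adapter: Optional[TableAdapter] = None,
    sep: Optional[str] = None,
) -> pd.DataFrame:
    """Read a delimited trial file into the canonical trial table.

    column_map maps canonical names to the file's column names (identity by
    default).  The adapter, if given, filters/recodes source rows first (e.g.
    dropping non-gaze cue types).  Schema problems raise with the offending
    column named; non-numeric response times raise with the row indices.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if adapter is not None:
        df = adapter.apply(df)
    column_map = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in df.columns:
            raise KeyError(
                f"required column {canonical!r} (mapped to {source!r}) missing from {path}"
            )
        rename[source] = canonical
    df = df.rename(columns=rename)[list(CANONICAL_COLUMNS)].reset_index(drop=True)

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = df.index[rt.isna()].tolist()
    if bad:
        raise ValueError(f"non-numeric response times at row indices {bad[:20]}")
    df["rt_ms"] = rt.astype(float)
    if df["correct"].dtype != bool:
        df["correct"] = (
            df["correct"].map({True: True, False: False, 1: True, 0: False, "TRUE": True,
                               "FALSE": False, "True": True, "False": False})
        )
        if df["correct"].isna().any():
            bad = df.index[df["correct"].isna()].tolist()
            raise ValueError(f"unparseable correctness values at row indices {bad[:20]}")
        df["correct"] = df["correct"].astype(bool)
    validate_trial_table(df)
    return df


def validate_trial_table(df: pd.DataFrame) -> None:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"trial table missing columns {missing}")
    bad_cond = sorted(set(df["condition"].unique()) - set(_CONDITIONS))
    if bad_cond:
        raise ValueError(f"unrecognised condition values {bad_cond}; expected {_CONDITIONS}")
    if (df["rt_ms"] <= 0).any():
        raise ValueError("response times must be positive")


def apply_exclusions(
    table: pd.DataFrame,
    rt_min_ms: float = 100.0,
    rt_max_ms: float = 5000.0,
    min_accuracy: float = 0.80,
) -> Tuple[pd.DataFrame, ExclusionReport]:
    """Remove contaminant response times, then low-accuracy participants.

    RTs strictly below ``rt_min_ms`` or strictly above ``rt_max_ms`` are
    excluded (exactly 100 and 5000 ms are kept).  Participant accuracy is
    assessed over their RT-filtered trials; anyone below ``min_accuracy``
    loses all trials.  Idempotent.
    """
    if len(table) == 0:
        raise ValueError("cannot apply exclusions to an empty trial table")
    n_in = len(table)
    keep_rt = (table["rt_ms"] >= rt_min_ms) & (table["rt_ms"] <= rt_max_ms)
    filtered = table[keep_rt]
    n_rt_excluded = n_in - len(filtered)

    accuracy = filtered.groupby("participant", sort=False)["correct"].mean()
    bad_participants = accuracy.index[accuracy < min_accuracy].tolist()
    out = filtered[~filtered["participant"].isin(bad_participants)].reset_index(drop=True)
    n_acc_excluded = len(filtered) - len(out)

    report = ExclusionReport(
        n_trials_in=n_in,
        n_trials_rt_excluded=n_rt_excluded,
        participants_excluded_accuracy=bad_participants,
        n_trials_accuracy_excluded=n_acc_excluded,
        n_trials_out=len(out),
    )
    return out, report


def cueing_magnitudes(table: pd.DataFrame, correct_only: bool = True) -> CueingSummary:
    """Per-participant cueing magnitudes and cohort summary.

    magnitude = mean(miscued RT) - mean(cued RT), in ms.  Participants missing
    either condition (after the optional correct-only filter) are flagged and
    omitted from cohort statistics.
    """
    df = table[table["correct"]] if correct_only else table
    means = df.groupby(["participant", "condition"], sort=False)["rt_ms"].mean().unstack()
    missing = [
        p
        for p in means.index
        if ("cued" not in means.columns or pd.isna(means.loc[p].get("cued")))
        or ("miscued" not in means.columns or pd.isna(means.loc[p].get("miscued")))
    ]
    if missing:
        warnings.warn(
            f"participants missing a condition, omitted from cohort statistics: {missing}"
        )
        means = means.drop(index=missing)
    magnitudes = (means["miscued"] - means["cued"]).sort_index()
    mags = magnitudes.to_numpy()
    smc = standardized_mean_change(mags) if len(mags) >= 2 else SMCResult(
        smc=float("nan"), variant="change", bias_corrected=True, n=len(mags)
    )
    return CueingSummary(
        per_participant_magnitude_ms=magnitudes,
        mean_ms=float(np.mean(mags)) if len(mags) else float("nan"),
        sd_ms=float(np.std(mags, ddof=1)) if len(mags) > 1 else float("nan"),
        smc=smc,
        n_positive=int((mags > 0).sum()),
        n_participants=len(mags),
        participants_missing_condition=missing,
    )


def _hedges_j(m: int) -> float:
    # small-sample bias correction factor
    return 1.0 - 3.0 / (4.0 * m - 1.0)


def standardized_mean_change(
    magnitudes,
    paired_sds: Optional[Tuple[float, float]] = None,
    correlation: Optional[float] = None,
    variant: str = "change",
    bias_corrected: bool = True,
) -> SMCResult:
    """Standardised mean change for paired condition differences.

    variant="change": mean change / SD of the change scores (the change-score
    standardiser), with Hedges' small-sample correction J = 1 - 3/(4(n-1)-1).
    variant="raw": mean change divided by the supplied raw-score SD
    (``paired_sds`` as (sd_cued, sd_miscued), pooled), with the same
    correction; ``correlation`` between condition means enters the standard
    error only.
    """
    mags = np.asarray(magnitudes, dtype=float)
    n = mags.size
    if n < 2:
        raise ValueError("standardised mean change requires at least 2 participants")
    mean_change = float(np.mean(mags))
    j = _hedges_j(n - 1) if bias_corrected else 1.0
    if variant == "change":
        sd = float(np.std(mags, ddof=1))
        if sd == 0.0:
            if mean_change == 0.0:
                return SMCResult(0.0, "change", bias_corrected, n, se=0.0)
            raise ValueError("zero variance in change scores with nonzero mean change")
        d = j * mean_change / sd
        se = math.sqrt(1.0 / n + d**2 / (2.0 * n))
        return SMCResult(float(d), "change", bias_corrected, n, se=float(se))
    elif variant == "raw":
        if paired_sds is None:
            raise ValueError("raw-score variant needs paired_sds = (sd_cued, sd_miscued)")
        sd_raw = math.sqrt((paired_sds[0] ** 2 + paired_sds[1] ** 2) / 2.0)
        if sd_raw == 0.0:
            raise ValueError("zero raw-score SD")
        d = j * mean_change / sd_raw
        r = 0.0 if correlation is None else float(correlation)
        se = math.sqrt(2.0 * (1.0 - r) / n + d**2 / (2.0 * n))
        return SMCResult(float(d), "raw", bias_corrected, n, se=float(se))
    raise ValueError(f"unknown variant {variant!r}; expected 'change' or 'raw'")
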