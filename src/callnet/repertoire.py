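"""Per-bird call-type usage across recordings and breeding stages.

Recordings differ in length (about 220 +/- 20 min in a typical morning
session), so raw per-type counts are extrapolated to a common reference
duration — the longest recording, 243 min — before comparing calling
activity between birds or stages. Repertoire *composition* is summarised as
each type's fraction of the bird's total calls in that recording, which is
invariant under the extrapolation. Only descriptive statistics (medians,
quartiles, sample sizes) are produced here.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CALL_TYPES, ConfigError, condense_stage

__all__ = [
    "REFERENCE_MINUTES",
    "extrapolate_counts",
    "repertoire_table",
    "stage_summary",
]

#: Duration of the longest analysed recording, minutes.
REFERENCE_MINUTES: float = 243.0


def extrapolate_counts(
    count: float, duration: float, reference: float = REFERENCE_MINUTES
) -> float:
    """Scale a raw count to the reference recording duration.

    Fractional results are kept; rounding is a display concern.
    """
    if duration <= 0:
        raise ConfigError(f"recording duration must be positive, got {duration}")
    return count * reference / duration


def repertoire_table(
    events: pd.DataFrame,
    recordings: pd.DataFrame,
    birds: Optional[pd.DataFrame] = None,
    reference: float = REFERENCE_MINUTES,
    call_types: Sequence[str] = CALL_TYPES,
) -> pd.DataFrame:
    """One row per (bird, recording) with raw/extrapolated counts and proportions.

    ``recordings`` must provide ``recording_id`` and ``duration_min``; stage
    columns (``breeding_stage``) propagate into the output together with the
    condensed nest stage. Events typed ``"other"`` never enter the counts.
    Zero-total rows carry NaN proportions (undefined, not zero).
    """
    if "duration_min" not in recordings.columns:
        raise ConfigError("recordings need a duration_min column")
    rec = recordings.drop_duplicates("recording_id").set_index("recording_id")
    known = set(rec.index)
    missing = set(events["recording_id"].unique()) - known
    if missing:
        raise ConfigError(f"events reference unknown recordings: {sorted(missing)}")

    sub = events[events["call_type"].isin(call_types)]
    counts = (
        sub.groupby(["bird_id", "recording_id", "call_type"], sort=False)
        .size()
        .unstack("call_type", fill_value=0)
        .reindex(columns=call_types, fill_value=0)
        .reset_index()
    )
    # birds whose events were all "other" still get a (zero) row
    idx = events[["bird_id", "recording_id"]].drop_duplicates()
    counts = idx.merge(counts, on=["bird_id", "recording_id"], how="left")
    counts[list(call_types)] = counts[list(call_types)].fillna(0).astype(int)

    duration = counts["recording_id"].map(rec["duration_min"]).astype(float)
    if duration.isna().any():
        bad = counts.loc[duration.isna(), "recording_id"].iloc[0]
        raise ConfigError(f"recording {bad!r} has no duration")
    out = counts.copy()
    total_raw = out[list(call_types)].sum(axis=1)
    for t in call_types:
        out[f"{t}_norm"] = out[t] * reference / duration
        out[f"{t}_prop"] = np.where(total_raw > 0, out[t] / total_raw, np.nan)
    out["total"] = total_raw
    out["total_norm"] = out[[f"{t}_norm" for t in call_types]].sum(axis=1)
    out["duration_min"] = duration.values

    for col in ("breeding_stage", "stage", "trial_id"):
        if col in rec.columns:
            out[col] = out["recording_id"].map(rec[col])
    if "breeding_stage" in out.columns and "nest_stage" not in out.columns:
        out["nest_stage"] = out["breeding_stage"].map(
            lambda s: condense_stage(s) if isinstance(s, str) and s else None
        )
    if birds is not None and "sex" in birds.columns:
        sex = birds.drop_duplicates("bird_id").set_index("bird_id")["sex"]
        out["sex"] = out["bird_id"].map(sex)
    return out


def stage_summary(
    rows: pd.DataFrame,
    by: str = "nest_stage",
    call_types: Sequence[str] = CALL_TYPES,
) -> pd.DataFrame:
    """Descriptive per-stage (and per-sex, when present) usage summary.

    For every stage level, sex and call type: number of contributing birds,
    number of (bird, recording) data points, and median/quartiles of the
    extrapolated counts and of the repertoire proportions.
    """
    if rows.empty:
        raise ConfigError("stage_summary needs at least one repertoire row")
    if by not in rows.columns:
        raise ConfigError(f"unknown grouping column {by!r}")
    group_cols = [by] + (["sex"] if "sex" in rows.columns else [])
    out = []
    for keys, grp in rows.groupby(group_cols, dropna=False, sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        base = dict(zip(group_cols, keys))
        base["n_birds"] = grp["bird_id"].nunique()
        base["n_rows"] = len(grp)
        for t in list(call_types) + ["total"]:
            norm_col = f"{t}_norm" if t != "total" else "total_norm"
            rec = dict(base)
            rec["call_type"] = t
            vals = grp[norm_col].astype(float)
            rec["median_norm"] = float(np.median(vals))
            rec["q25_norm"] = float(np.percentile(vals, 25))
            rec["q75_norm"] = float(np.percentile(vals, 75))
            if t != "total":
                props = grp[f"{t}_prop"].dropna().astype(float)
                rec["median_prop"] = float(np.median(props)) if len(props) else np.nan
            else:
                rec["median_prop"] = np.nan
            out.append(rec)
    return pd.DataFrame(out)
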