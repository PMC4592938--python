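"""Pair-level statistics over interaction matrices.

Three views of how dyadic calling interactions organise around pairs:

* **Within-pair combination percentages** — for each pair, breeding stage,
  ordered call-type combination and responder sex, the percentage of
  possible within-pair dyads flagged significant-positive.
* **Pair specificity** — per bird, the percentage of possible dyads
  involving the partner that are significant versus the same percentage
  over non-partner group members, and their ratio. A ratio above 1 means
  the bird interacts vocally more with its partner than with the rest of
  the group.
* **Combination counts by success** — per pair and nest stage, the number
  of call-type combinations with a significant positive within-pair
  interaction, averaged over recordings within a stage and summarised by
  whether the pair went on to lay a clutch of eggs.

"Possible" dyads are valid, non-excluded matrix cells; cells that failed
the event-count validity rule are missing data and, by default, drop out
of the denominators (a switch restores them for sensitivity analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .interaction import InteractionMatrix
from .types import ConfigError

__all__ = [
    "PairStageStats",
    "within_pair_stats",
    "specificity_ratio",
    "stage_mean_ratio",
    "combo_counts_by_success",
    "pair_lookup",
]

logger = logging.getLogger(__name__)


def pair_lookup(birds: pd.DataFrame) -> dict[str, str]:
    """Map bird_id -> partner bird_id from a metadata frame."""
    partners: dict[str, str] = {}
    paired = birds.dropna(subset=["pair_id"]) if "pair_id" in birds.columns else birds.iloc[0:0]
    for pid, grp in paired.groupby("pair_id"):
        ids = [str(b) for b in grp["bird_id"]]
        if len(ids) != 2:
            raise ConfigError(f"pair {pid!r} has {len(ids)} members; expected 2")
        partners[ids[0]] = ids[1]
        partners[ids[1]] = ids[0]
    return partners


@dataclass
class PairStageStats:
    """Within-pair interaction bookkeeping for one pair at one stage."""

    pair_id: str
    stage: Optional[str]
    n_possible: int
    n_positive: int
    n_negative: int
    #: (initiator type, responder type, responder sex) -> % of possible
    #: within-pair dyads of that combination flagged significant-positive
    pct_positive_by_combo: dict[tuple[str, str, str], float] = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return self.n_positive + self.n_negative


def _sex_of(birds: pd.DataFrame) -> dict[str, str]:
    if "sex" not in birds.columns:
        return {}
    return {
        str(r["bird_id"]): str(r["sex"]) for _, r in birds.drop_duplicates("bird_id").iterrows()
    }


def within_pair_stats(
    matrix: InteractionMatrix,
    birds: pd.DataFrame,
    stage: Optional[str] = None,
    include_invalid: bool = False,
) -> list[PairStageStats]:
    """Within-pair positive-interaction percentages per call-type combination.

    Both directions of every pair are tallied, separated by the responding
    bird's sex. Birds without a pair are skipped with a log entry.
    """
    partners = pair_lookup(birds)
    sex = _sex_of(birds)
    pair_of = {}
    if "pair_id" in birds.columns:
        for _, r in birds.dropna(subset=["pair_id"]).iterrows():
            pair_of[str(r["bird_id"])] = str(r["pair_id"])
    matrix_birds = {b for b, _ in matrix.axes}
    unpaired = matrix_birds - set(partners)
    if unpaired:
        logger.info("within_pair_stats: skipping unpaired birds %s", sorted(unpaired))

    stats: dict[str, PairStageStats] = {}
    combo_tallies: dict[str, dict[tuple[str, str, str], list[int]]] = {}
    for a, b, res in matrix.iter_analysable():
        ib, it = a
        rb, rt = b
        if partners.get(ib) != rb:
            continue
        pid = pair_of.get(ib, f"{min(ib, rb)}+{max(ib, rb)}")
        st = stats.setdefault(
            pid, PairStageStats(pair_id=pid, stage=stage, n_possible=0, n_positive=0, n_negative=0)
        )
        combo = (it, rt, sex.get(rb, "unknown"))
        tally = combo_tallies.setdefault(pid, {}).setdefault(combo, [0, 0])
        if res.valid or include_invalid:
            st.n_possible += 1
            tally[1] += 1
            if res.significant > 0:
                st.n_positive += 1
                tally[0] += 1
            elif res.significant < 0:
                st.n_negative += 1
    for pid, st in stats.items():
        st.pct_positive_by_combo = {
            combo: (100.0 * pos / n if n else np.nan)
            for combo, (pos, n) in combo_tallies.get(pid, {}).items()
        }
    return sorted(stats.values(), key=lambda s: s.pair_id)


def _bird_dyad_counts(
    matrix: InteractionMatrix,
    bird: str,
    others: Iterable[str],
    include_invalid: bool,
) -> tuple[int, int]:
    """(possible, significant) over dyads linking ``bird`` with ``others``,
    in both roles."""
    others = set(others)
    possible = 0
    significant = 0
    for a, b, res in matrix.iter_analysable():
        if (a[0] == bird and b[0] in others) or (b[0] == bird and a[0] in others):
            if res.valid or include_invalid:
                possible += 1
                if res.significant != 0:
                    significant += 1
    return possible, significant


def specificity_ratio(
    matrix: InteractionMatrix,
    birds: pd.DataFrame,
    stage: Optional[str] = None,
    include_invalid: bool = False,
) -> pd.DataFrame:
    """Per-bird partner vs non-partner interaction percentages and ratio.

    Returns one row per paired bird on the matrix axes with columns
    ``pct_partner``, ``pct_nonpartner`` and ``ratio`` (NaN when the
    non-partner percentage is 0). Requires at least 3 birds so the
    non-partner set is non-empty.
    """
    partners = pair_lookup(birds)
    matrix_birds = sorted({b for b, _ in matrix.axes})
    if len(matrix_birds) < 3:
        raise ConfigError("specificity needs at least 3 birds")
    rows = []
    n_undefined = 0
    for bird in matrix_birds:
        partner = partners.get(bird)
        if partner is None or partner not in matrix_birds:
            continue
        non_partners = [b for b in matrix_birds if b not in (bird, partner)]
        poss_p, sig_p = _bird_dyad_counts(matrix, bird, [partner], include_invalid)
        poss_n, sig_n = _bird_dyad_counts(matrix, bird, non_partners, include_invalid)
        pct_p = 100.0 * sig_p / poss_p if poss_p else np.nan
        pct_n = 100.0 * sig_n / poss_n if poss_n else np.nan
        ratio = pct_p / pct_n if pct_n and not np.isnan(pct_n) else np.nan
        if np.isnan(ratio):
            n_undefined += 1
        rows.append(
            {
                "bird_id": bird,
                "stage": stage,
                "pct_partner": pct_p,
                "pct_nonpartner": pct_n,
                "ratio": ratio,
            }
        )
    if n_undefined:
        logger.info(
            "specificity_ratio: %d birds with undefined ratio (zero non-partner %%)",
            n_undefined,
        )
    return pd.DataFrame(rows)


def stage_mean_ratio(spec_rows: pd.DataFrame) -> float:
    """Stage-level aggregate: mean of per-bird ratios where defined."""
    vals = spec_rows["ratio"].dropna()
    return float(vals.mean()) if len(vals) else float("nan")


def combo_counts_by_success(
    matrices: Sequence[InteractionMatrix],
    birds: pd.DataFrame,
    per_direction: bool = False,
    later_breeding_stages: tuple[str, ...] = ("Nest building",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count positively interacting call-type combinations per pair and stage.

    For each matrix (one recording) and pair, an ordered call-type
    combination (a -> b) counts once if the within-pair cell is
    significant-positive in either direction (set ``per_direction`` to count
    the two responder identities separately). Counts are then averaged over
    recordings within each (pair, nest stage), and summarised as group
    mean +/- SD by egg-laying success. Matrices must carry a breeding-stage
    label; the later nest stage is restricted to the breeding stages in
    ``later_breeding_stages`` (later sub-stages exist only for successful
    pairs). Pairs with unknown success are excluded with a log entry.

    Returns ``(per_pair_stage, by_success)``.
    """
    from .types import condense_stage

    partners = pair_lookup(birds)
    pair_of = {}
    success_of = {}
    if "pair_id" in birds.columns:
        for _, r in birds.dropna(subset=["pair_id"]).iterrows():
            pair_of[str(r["bird_id"])] = str(r["pair_id"])
            success_of[str(r["pair_id"])] = str(r.get("success", "unknown"))

    records = []
    for m in matrices:
        if m.stage is None:
            raise ConfigError(f"matrix {m.recording_id!r} has no stage label")
        nest = condense_stage(m.stage)
        if nest == "Later nesting" and m.stage not in later_breeding_stages:
            continue
        combos: dict[str, set] = {}
        for a, b, res in m.iter_analysable():
            ib, it = a
            rb, rt = b
            if partners.get(ib) != rb or not res.valid:
                continue
            pid = pair_of.get(ib)
            if pid is None:
                continue
            if res.significant > 0:
                key = (it, rt, rb) if per_direction else (it, rt)
                combos.setdefault(pid, set()).add(key)
        pair_ids = sorted({pair_of[b] for b, _ in m.axes if b in pair_of})
        for pid in pair_ids:
            records.append(
                {
                    "pair_id": pid,
                    "nest_stage": nest,
                    "recording_id": m.recording_id,
                    "n_combos": len(combos.get(pid, ())),
                }
            )
    per_recording = pd.DataFrame(records)
    if per_recording.empty:
        raise ConfigError("no within-pair data in the supplied matrices")
    per_pair_stage = (
        per_recording.groupby(["pair_id", "nest_stage"], sort=False)["n_combos"]
        .mean()
        .reset_index()
    )
    per_pair_stage["success"] = per_pair_stage["pair_id"].map(success_of)
    unknown = per_pair_stage["success"].isin(["unknown", "nan", ""]) | per_pair_stage[
        "success"
    ].isna()
    if unknown.any():
        logger.info(
            "combo_counts_by_success: excluding %d pair-stage rows with unknown success",
            int(unknown.sum()),
        )
        per_pair_stage = per_pair_stage[~unknown]
    by_success = (
        per_pair_stage.groupby(["nest_stage", "success"], sort=False)["n_combos"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return per_pair_stage, by_success
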