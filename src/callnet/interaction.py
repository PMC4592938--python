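"""Peristimulus-time-histogram analysis of dyadic calling interactions.

For every ordered dyad of (bird, call type) event streams, the onsets of the
responder stream are expressed as lags relative to each onset of the initiator
("trigger") stream and accumulated into a peristimulus time histogram (PSTH)
spanning 4 s on either side of the trigger in 50 ms bins (160 bins). Two
0.5 s blocks summarise each PSTH:

* ``N_base`` — counts in the earliest 0.5 s of the window (lag in
  [-4.0, -3.5) s), maximally distant from the trigger onset;
* ``N_response`` — counts just after onset, with the first 50 ms discarded to
  avoid microphone crosstalk (lag in [0.05, 0.5) s).

The correlation index is ``R = (N_response - N_base) / (N_response + N_base)``,
in [-1, 1]: +1 when every relevant call falls in the response block (the
initiator's calls elicit calls), -1 when every one falls in the baseline block
(the initiator's calls suppress calls), 0 when balanced.

A dyad is *valid* only if its PSTH holds more than one event per bin on
average (total > 160 events). Significance is gated by an exact conditional
binomial test: under the null of a rate constant across the two blocks, each
of the ``N_base + N_response`` events falls in the response block with
probability ``p0 = 0.45 / 0.95`` (the response block is 50 ms shorter than
the baseline block after crosstalk exclusion). Each dyad is gated at its own
95% level; no multiple-testing correction is applied across dyads, so on
independent streams roughly 5% of valid dyads are expected to be flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CALL_TYPES, ConfigError

__all__ = [
    "PsthConfig",
    "Psth",
    "DyadResult",
    "InteractionMatrix",
    "build_psth",
    "correlation_index",
    "check_validity",
    "test_significance",
    "analyse_dyad",
    "build_interaction_matrix",
]


@dataclass(frozen=True)
class PsthConfig:
    """Geometry and gating parameters of the PSTH analysis.

    Parameters
    ----------
    window:
        Half-width of the lag window in seconds (total span ``2 * window``).
    binwidth:
        Bin width in seconds; must divide ``window`` evenly.
    base_block:
        Length of the baseline block at the far negative edge of the window.
    response_block:
        Length of the post-onset response block, measured from lag 0 before
        crosstalk exclusion.
    crosstalk_exclusion:
        Post-onset lag discarded because the same vocalisation can be picked
        up by both birds' microphones; shrinks the response block.
    alpha:
        Two-sided significance level of the binomial gate.
    validity_min_events:
        A PSTH is valid only if its total event count strictly exceeds this.
    baseline_mode:
        ``"first-block"`` (default) uses the earliest ``base_block`` seconds
        of the window as baseline; ``"all-pre-blocks"`` averages over every
        pre-onset ``base_block``-sized block.
    null_model:
        ``"duration-corrected"`` (default) sets the null response probability
        to the response/baseline duration ratio; ``"symmetric"`` uses 0.5.
    """

    window: float = 4.0
    binwidth: float = 0.05
    base_block: float = 0.5
    response_block: float = 0.5
    crosstalk_exclusion: float = 0.05
    alpha: float = 0.05
    validity_min_events: int = 160
    baseline_mode: str = "first-block"
    null_model: str = "duration-corrected"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.binwidth <= 0:
            raise ConfigError("window and binwidth must be positive")
        ratio = self.window / self.binwidth
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"binwidth {self.binwidth} does not divide window {self.window}"
            )
        if not 0 <= self.crosstalk_exclusion < self.response_block:
            raise ConfigError("crosstalk_exclusion must lie in [0, response_block)")
        if self.base_block <= 0 or self.response_block <= 0:
            raise ConfigError("block lengths must be positive")
        if self.base_block > self.window or self.response_block > self.window:
            raise ConfigError("blocks cannot exceed the window")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.baseline_mode not in ("first-block", "all-pre-blocks"):
            raise ConfigError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.null_model not in ("duration-corrected", "symmetric"):
            raise ConfigError(f"unknown null_model {self.null_model!r}")

    @property
    def n_bins(self) -> int:
        """Total number of lag bins (160 at defaults)."""
        return int(round(2 * self.window / self.binwidth))

    @property
    def response_duration(self) -> float:
        """Effective response-block length after crosstalk exclusion."""
        return self.response_block - self.crosstalk_exclusion

    @property
    def base_duration(self) -> float:
        """Effective baseline length entering the null proportion."""
        if self.baseline_mode == "all-pre-blocks":
            return self.window
        return self.base_block

    @property
    def null_p(self) -> float:
        """Null probability that one event falls in the response block."""
        if self.null_model == "symmetric":
            return 0.5
        return self.response_duration / (self.response_duration + self.base_duration)


@dataclass
class Psth:
    """Binned cross-event-count histogram for one ordered dyad."""

    initiator: tuple[str, str]
    responder: tuple[str, str]
    counts: np.ndarray
    n_triggers: int
    config: PsthConfig = field(default_factory=PsthConfig)

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    def lag_edges(self) -> np.ndarray:
        """Bin edges on the lag axis, from -window to +window."""
        c = self.config
        return -c.window + c.binwidth * np.arange(c.n_bins + 1)


@dataclass
class DyadResult:
    """Correlation index, counts, validity and significance for one dyad.

    ``n_base`` is the raw baseline-block count entering the binomial test
    (in ``all-pre-blocks`` mode this is the whole pre-onset count, and the
    correlation index uses its per-block mean). ``significant`` is +1/-1 for
    a rejected null with excess/deficit of response-block events, 0 otherwise;
    invalid dyads are always 0.
    """

    n_base: int = 0
    n_response: int = 0
    r_index: float = math.nan
    valid: bool = False
    significant: int = 0
    total_events: int = 0
    n_triggers: int = 0
    p_value: float = math.nan


def _as_sorted_array(onsets: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(onsets, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        raise ValueError(f"{name} onsets must be sorted ascending")
    return arr


def build_psth(
    triggers: Sequence[float],
    responses: Sequence[float],
    config: PsthConfig | None = None,
    *,
    initiator: tuple[str, str] = ("", ""),
    responder: tuple[str, str] = ("", ""),
) -> Psth:
    """Accumulate responder onsets into lag bins around every trigger onset.

    Every (trigger, response) pair with lag in ``[-window, +window)`` is
    counted — a response event near two triggers contributes to both — with
    no per-trigger normalisation. Bins are half-open ``[left, right)``.
    """
    cfg = config or PsthConfig()
    trig = _as_sorted_array(triggers, "trigger")
    resp = _as_sorted_array(responses, "response")
    n_bins = cfg.n_bins
    counts = np.zeros(n_bins, dtype=np.int64)
    if trig.size and resp.size:
        lo = np.searchsorted(resp, trig - cfg.window, side="left")
        hi = np.searchsorted(resp, trig + cfg.window, side="left")
        n_pairs = hi - lo
        if n_pairs.sum():
            # flat index of every in-window (trigger, response) pair
            idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
            lags = resp[idx] - np.repeat(trig, n_pairs)
            # 1e-9-bin epsilon keeps lags that are exact bin-edge multiples
            # (e.g. 0.2 s) in their nominal bin despite float cancellation
            bins = np.floor((lags + cfg.window) / cfg.binwidth + 1e-9).astype(np.int64)
            np.clip(bins, 0, n_bins - 1, out=bins)  # guard float edge rounding
            counts = np.bincount(bins, minlength=n_bins).astype(np.int64)
    return Psth(
        initiator=initiator,
        responder=responder,
        counts=counts,
        n_triggers=int(trig.size),
        config=cfg,
    )


def _block_counts(psth: Psth) -> tuple[int, int, float]:
    """Return (raw base count, response count, effective base for R)."""
    c = psth.config
    bw = c.binwidth
    n_bins = c.n_bins

    def _slice(lo_lag: float, hi_lag: float) -> int:
        i0 = int(round((lo_lag + c.window) / bw))
        i1 = int(round((hi_lag + c.window) / bw))
        return int(psth.counts[i0:i1].sum())

    n_resp = _slice(c.crosstalk_exclusion, c.response_block)
    if c.baseline_mode == "first-block":
        n_base = _slice(-c.window, -c.window + c.base_block)
        base_eff = float(n_base)
    else:
        n_base = _slice(-c.window, 0.0)
        base_eff = n_base * c.base_block / c.window  # mean per 0.5 s block
    return n_base, n_resp, base_eff


def correlation_index(psth: Psth, config: PsthConfig | None = None) -> DyadResult:
    """Compute the dyad's correlation index and validity from its PSTH."""
    if config is not None and config != psth.config:
        psth = replace(psth, config=config)
    n_base, n_resp, base_eff = _block_counts(psth)
    total = psth.total_events
    valid = total > psth.config.validity_min_events
    if n_resp + base_eff > 0:
        r = (n_resp - base_eff) / (n_resp + base_eff)
    else:
        r = math.nan
        valid = False
    return DyadResult(
        n_base=n_base,
        n_response=n_resp,
        r_index=r,
        valid=valid,
        significant=0,
        total_events=total,
        n_triggers=psth.n_triggers,
    )


def check_validity(psth: Psth, config: PsthConfig | None = None) -> bool:
    """True iff the PSTH holds strictly more than ``validity_min_events``."""
    cfg = config or psth.config
    return psth.total_events > cfg.validity_min_events


def test_significance(result: DyadResult, config: PsthConfig) -> int:
    """Gate a dyad with a two-sided exact binomial test at ``config.alpha``.

    Returns +1 (significant excess of response-block events), -1 (significant
    deficit) or 0. Invalid dyads or dyads with no events return 0.
    """
    n = result.n_base + result.n_response
    if not result.valid or n == 0:
        result.significant = 0
        return 0
    p0 = config.null_p
    test = stats.binomtest(result.n_response, n=n, p=p0, alternative="two-sided")
    result.p_value = test.pvalue
    if test.pvalue < config.alpha:
        frac = result.n_response / n
        result.significant = 1 if frac > p0 else (-1 if frac < p0 else 0)
    else:
        result.significant = 0
    return result.significant


def analyse_dyad(
    triggers: Sequence[float],
    responses: Sequence[float],
    config: PsthConfig | None = None,
) -> DyadResult:
    """PSTH + correlation index + validity + significance in one call."""
    cfg = config or PsthConfig()
    psth = build_psth(triggers, responses, cfg)
    result = correlation_index(psth)
    test_significance(result, cfg)
    return result


class InteractionMatrix:
    """Square matrix of dyad results over all (bird, call type) combinations.

    Initiators index one axis, responders the other; with ``n`` birds and the
    five analysable call types the matrix has ``(5 n)^2`` cells, of which the
    ``25 n`` within-bird cells are excluded from analysis. Cells that fail the
    validity rule are retained but marked invalid (missing), mirroring the
    distinction between "no significant interaction" and "no data".
    """

    def __init__(
        self,
        axes: Sequence[tuple[str, str]],
        cells: Mapping[tuple[tuple[str, str], tuple[str, str]], DyadResult],
        recording_id: str = "",
        stage: Optional[str] = None,
    ) -> None:
        self.axes = list(axes)
        self.cells = dict(cells)
        self.recording_id = recording_id
        self.stage = stage

    @property
    def n_cells(self) -> int:
        return len(self.axes) ** 2

    @property
    def n_excluded(self) -> int:
        return sum(
            1
            for a in self.axes
            for b in self.axes
            if a[0] == b[0]
        )

    @property
    def n_analysable(self) -> int:
        return self.n_cells - self.n_excluded

    def is_excluded(self, initiator: tuple[str, str], responder: tuple[str, str]) -> bool:
        return initiator[0] == responder[0]

    def result(
        self, initiator: tuple[str, str], responder: tuple[str, str]
    ) -> Optional[DyadResult]:
        """The dyad's result, or None for excluded within-bird cells."""
        if self.is_excluded(initiator, responder):
            return None
        return self.cells.get((initiator, responder))

    def display_value(
        self, initiator: tuple[str, str], responder: tuple[str, str]
    ) -> float:
        """Significance-gated index for display: R if significant, else 0,
        NaN for invalid or excluded cells."""
        res = self.result(initiator, responder)
        if res is None or not res.valid:
            return math.nan
        return res.r_index if res.significant != 0 else 0.0

    def iter_analysable(self):
        """Yield (initiator, responder, DyadResult) over non-excluded cells."""
        for a in self.axes:
            for b in self.axes:
                if a[0] == b[0]:
                    continue
                res = self.cells.get((a, b))
                if res is not None:
                    yield a, b, res

    def to_long(self) -> pd.DataFrame:
        """Long-format table with one row per cell, excluded cells flagged."""
        rows = []
        for a in self.axes:
            for b in self.axes:
                excluded = a[0] == b[0]
                res = None if excluded else self.cells.get((a, b))
                rows.append(
                    {
                        "recording_id": self.recording_id,
                        "stage": self.stage if self.stage is not None else "",
                        "initiator_bird": a[0],
                        "initiator_type": a[1],
                        "responder_bird": b[0],
                        "responder_type": b[1],
                        "excluded": excluded,
                        "valid": bool(res.valid) if res is not None else False,
                        "r_index": (
                            res.r_index
                            if res is not None and res.valid
                            else math.nan
                        ),
                        "significant": res.significant if res is not None else 0,
                        "n_base": res.n_base if res is not None else 0,
                        "n_response": res.n_response if res is not None else 0,
                        "total_events": res.total_events if res is not None else 0,
                    }
                )
        return pd.DataFrame(rows)


def build_interaction_matrix(
    events: pd.DataFrame,
    birds: Iterable[str],
    config: PsthConfig | None = None,
    recording_id: str = "",
    stage: Optional[str] = None,
    call_types: Sequence[str] = CALL_TYPES,
) -> InteractionMatrix:
    """Analyse every ordered between-bird dyad of one recording.

    Parameters
    ----------
    events:
        Event table for a single recording with columns ``bird_id``,
        ``call_type``, ``onset_s``. Events typed ``"other"`` are ignored.
    birds:
        Bird identifiers defining the matrix axes (8 birds x 5 types gives
        a 40 x 40 matrix). Birds without events still get axis rows.
    """
    cfg = config or PsthConfig()
    bird_list = [str(b) for b in birds]
    if len(bird_list) < 2:
        raise ConfigError("interaction matrix needs at least 2 birds")
    axes = [(b, t) for b in bird_list for t in call_types]

    streams: dict[tuple[str, str], np.ndarray] = {}
    if len(events):
        sub = events[events["call_type"].isin(call_types)]
        for (b, t), grp in sub.groupby(["bird_id", "call_type"], sort=False):
            streams[(str(b), str(t))] = np.sort(grp["onset_s"].to_numpy(float))
    empty = np.empty(0, dtype=float)

    cells: dict[tuple[tuple[str, str], tuple[str, str]], DyadResult] = {}
    for a in axes:
        trig = streams.get(a, empty)
        for b in axes:
            if a[0] == b[0]:
                continue
            resp = streams.get(b, empty)
            psth = build_psth(trig, resp, cfg, initiator=a, responder=b)
            res = correlation_index(psth)
            test_significance(res, cfg)
            cells[(a, b)] = res
    return InteractionMatrix(axes, cells, recording_id=recording_id, stage=stage)
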