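"""Synthetic group calling: coupled point-process call streams and audio.

The generator emulates the structure the interaction analysis assumes: each
(bird, call type) stream calls at a baseline homogeneous Poisson rate over a
recording of a few hours, and excitatory dyadic coupling lets a call by bird
X of type a trigger a call by bird Y of type b with probability ``p`` at a
short latency (uniform on [0.05, 0.45] s by default, matching the analysis
response window after crosstalk exclusion). Coupling is single-generation:
triggered calls do not trigger further calls, keeping the process subcritical
and the null/alternative structure transparent. A per-bird refractory period
(default 0.1 s) suppresses unrealistic event pile-up.

A companion audio branch renders call streams as mono waveforms: five
syllable archetypes (one per call type) with distinct temporal-spectral
signatures — harmonic stacks with linear frequency modulation, a noise
mixing weight and an attack/decay envelope — placed over a Gaussian noise
floor, so the segmentation / feature / classification stages close the loop
against a known truth table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CALL_TYPES, ConfigError

__all__ = [
    "GroupSimConfig",
    "SyllableArchetype",
    "DEFAULT_ARCHETYPES",
    "simulate_group_calls",
    "simulate_stage_series",
    "synth_syllable",
    "synth_recording",
    "paired_group_config",
]

logger = logging.getLogger(__name__)

CouplingKey = tuple[str, str, str, str]  # initiator bird, type, responder bird, type


@dataclass(frozen=True)
class GroupSimConfig:
    """Full parameterisation of the synthetic group-calling point process.

    ``baseline_rates`` maps (bird, call type) to events/second; ``coupling``
    maps (initiator bird, initiator type, responder bird, responder type) to
    a response probability. Entries whose initiator and responder bird agree
    are ignored (within-bird interactions are excluded from the analysis).
    """

    baseline_rates: Mapping[tuple[str, str], float]
    duration: float = 4 * 3600.0  # seconds
    coupling: Mapping[CouplingKey, float] = field(default_factory=dict)
    pair_map: Mapping[str, str] = field(default_factory=dict)
    latency_low: float = 0.05
    latency_high: float = 0.45
    refractory: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if not 0 <= self.latency_low < self.latency_high:
            raise ConfigError("need 0 <= latency_low < latency_high")
        if self.refractory < 0:
            raise ConfigError("refractory must be >= 0")
        for key, rate in self.baseline_rates.items():
            if rate < 0:
                raise ConfigError(f"negative baseline rate for {key}")
        for key, p in self.coupling.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"coupling probability for {key} outside [0, 1]")

    @property
    def birds(self) -> list[str]:
        return sorted({b for b, _ in self.baseline_rates})


def simulate_group_calls(
    config: GroupSimConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Draw one recording of coupled call streams.

    Returns an onset-sorted event table with columns ``bird_id``,
    ``call_type``, ``onset_s`` and ``triggered`` (True for coupling-induced
    events). The same config and seed give bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    # Baseline: homogeneous Poisson per (bird, type), drawn in sorted key
    # order for determinism.
    baseline: dict[tuple[str, str], np.ndarray] = {}
    for key in sorted(config.baseline_rates):
        rate = config.baseline_rates[key]
        n = rng.poisson(rate * config.duration)
        baseline[key] = np.sort(rng.uniform(0.0, config.duration, size=n))

    # Single-generation coupling: each baseline initiator event triggers at
    # most one candidate response per coupling entry.
    candidates: dict[str, list[tuple[float, str]]] = {}
    for key in sorted(config.coupling):
        ib, it, rb, rt = key
        if ib == rb:
            continue  # within-bird coupling ignored
        p = config.coupling[key]
        trig = baseline.get((ib, it))
        if trig is None or trig.size == 0 or p == 0:
            continue
        fire = rng.random(trig.size) < p
        lat = rng.uniform(config.latency_low, config.latency_high, size=int(fire.sum()))
        for t in trig[fire] + lat:
            if t < config.duration:
                candidates.setdefault(rb, []).append((t, rt))

    # Refractory: candidates are accepted in time order, rejected if within
    # `refractory` of the responder bird's previous (baseline or accepted
    # triggered) event. Baseline events are never suppressed.
    rows: list[tuple[str, str, float, bool]] = []
    for key, times in baseline.items():
        b, t = key
        rows.extend((b, t, float(x), False) for x in times)

    all_baseline_by_bird: dict[str, np.ndarray] = {}
    for (b, _), times in baseline.items():
        prev = all_baseline_by_bird.get(b)
        all_baseline_by_bird[b] = (
            times if prev is None else np.concatenate([prev, times])
        )
    for b in all_baseline_by_bird:
        all_baseline_by_bird[b] = np.sort(all_baseline_by_bird[b])

    for b in sorted(candidates):
        cand = sorted(candidates[b])
        base_times = all_baseline_by_bird.get(b, np.empty(0))
        accepted: list[float] = []
        for t, rt in cand:
            prev = -np.inf
            i = np.searchsorted(base_times, t)
            if i > 0:
                prev = base_times[i - 1]
            if accepted:
                prev = max(prev, accepted[-1])
            if t - prev >= config.refractory or np.isinf(prev):
                accepted.append(t)
                rows.append((b, rt, t, True))

    df = pd.DataFrame(rows, columns=["bird_id", "call_type", "onset_s", "triggered"])
    return df.sort_values("onset_s", kind="mergesort").reset_index(drop=True)


def simulate_stage_series(
    configs: Mapping[str, GroupSimConfig] | Sequence[tuple[str, GroupSimConfig]],
    recordings_per_stage: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an ordered series of stages with stage-specific coupling.

    Each stage yields ``recordings_per_stage`` independent recordings tagged
    with the stage label. Returns ``(events, recordings)`` where events carry
    ``recording_id`` and ``stage`` columns and recordings list id, stage and
    duration in minutes.
    """
    items = list(configs.items()) if isinstance(configs, Mapping) else list(configs)
    if not items:
        raise ConfigError("stage series needs at least one stage")
    if rng is None:
        rng = np.random.default_rng(items[0][1].seed)
    event_frames = []
    rec_rows = []
    for si, (stage, cfg) in enumerate(items):
        for ri in range(recordings_per_stage):
            rec_id = f"stage{si}_rec{ri}"
            ev = simulate_group_calls(cfg, rng=rng)
            ev.insert(0, "recording_id", rec_id)
            ev["stage"] = stage
            event_frames.append(ev)
            rec_rows.append(
                {
                    "recording_id": rec_id,
                    "stage": stage,
                    "duration_min": cfg.duration / 60.0,
                }
            )
    events = pd.concat(event_frames, ignore_index=True)
    recordings = pd.DataFrame(rec_rows)
    return events, recordings


def paired_group_config(
    n_pairs: int = 4,
    rate: float = 0.05,
    pair_coupling: float = 0.0,
    cross_coupling: float = 0.0,
    pair_combos: Sequence[tuple[str, str]] = (
        ("tet", "tet"),
        ("stack", "stack"),
        ("tet", "stack"),
        ("cackle", "cackle"),
        ("stack", "cackle"),
    ),
    duration: float = 4 * 3600.0,
    seed: int = 0,
) -> GroupSimConfig:
    """Convenience builder: ``n_pairs`` female/male pairs with uniform
    per-type baseline rates, excitatory within-pair coupling on the given
    call-type combinations (both directions) and optional uniform coupling
    between non-partners on tet->tet."""
    females = [f"F{i}" for i in range(n_pairs)]
    males = [f"M{i}" for i in range(n_pairs)]
    birds = females + males
    pair_map = {}
    for f, m in zip(females, males):
        pair_map[f] = m
        pair_map[m] = f
    rates = {(b, t): rate for b in birds for t in CALL_TYPES}
    coupling: dict[CouplingKey, float] = {}
    if pair_coupling > 0:
        for f, m in zip(females, males):
            for it, rt in pair_combos:
                coupling[(f, it, m, rt)] = pair_coupling
                coupling[(m, it, f, rt)] = pair_coupling
    if cross_coupling > 0:
        for a in birds:
            for b in birds:
                if a != b and pair_map.get(a) != b:
                    coupling[(a, "tet", b, "tet")] = cross_coupling
    return GroupSimConfig(
        baseline_rates=rates,
        duration=duration,
        coupling=coupling,
        pair_map=pair_map,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Syllable audio
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyllableArchetype:
    """Temporal-spectral recipe for one synthetic call type.

    The five default archetypes are pairwise separated in the nine-feature
    space (duration, fundamental, harmonic content, modulation, noisiness)
    so that true cluster separation exceeds within-cluster spread.
    """

    call_type: str
    duration_mean: float  # seconds
    duration_sd: float
    f0_mean: float  # Hz
    f0_sd: float
    n_harmonics: int = 1
    fm_depth: float = 0.0  # Hz, linear sweep across the syllable
    noisiness: float = 0.0  # 0..1 broadband-noise mixing weight

    def __post_init__(self) -> None:
        if self.duration_mean <= 0 or self.duration_sd < 0:
            raise ConfigError("duration parameters must be positive")
        if not 0 <= self.noisiness <= 1:
            raise ConfigError("noisiness must lie in [0, 1]")
        if self.n_harmonics < 1:
            raise ConfigError("need at least one harmonic")


#: Default archetypes, loosely inspired by the relative character of the five
#: call types (distance calls long and loud, tets/stacks short and soft,
#: cackles/whines associated with nesting); tuned for feature-space
#: separability, not for acoustic realism.
DEFAULT_ARCHETYPES: dict[str, SyllableArchetype] = {
    "distance": SyllableArchetype("distance", 0.120, 0.010, 3000.0, 60.0, 3, 900.0, 0.05),
    "tet": SyllableArchetype("tet", 0.040, 0.004, 2400.0, 50.0, 2, 200.0, 0.02),
    "stack": SyllableArchetype("stack", 0.065, 0.005, 4200.0, 60.0, 1, 500.0, 0.02),
    "cackle": SyllableArchetype("cackle", 0.050, 0.005, 1500.0, 40.0, 4, 700.0, 0.10),
    "whine": SyllableArchetype("whine", 0.160, 0.012, 1000.0, 30.0, 5, 100.0, 0.05),
}

_PEAK = 0.5  # full-scale peak amplitude of every rendered syllable


def synth_syllable(
    archetype: SyllableArchetype,
    sample_rate: int = 44100,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[np.ndarray, str]:
    """Render one syllable waveform; returns ``(waveform, call_type)``.

    Harmonic stack (amplitudes 1/h) on a fundamental drawn from the
    archetype, linear FM of ``fm_depth`` across the syllable, mixed with
    broadband noise by ``noisiness``, shaped by a raised-cosine
    attack/decay envelope and peak-normalised to 0.5 full scale.
    """
    if sample_rate < 22050:
        raise ConfigError("sample_rate must be at least 22050 Hz")
    if rng is None:
        rng = np.random.default_rng(seed)
    dur = 0.0
    while dur <= 0.005:  # truncated normal: re-draw non-positive durations
        dur = rng.normal(archetype.duration_mean, archetype.duration_sd)
    n = max(int(round(dur * sample_rate)), 32)
    t = np.arange(n) / sample_rate
    f0 = rng.normal(archetype.f0_mean, archetype.f0_sd)
    # linear sweep from f0 - depth/2 to f0 + depth/2
    inst_f = f0 + archetype.fm_depth * (t / t[-1] - 0.5)
    phase = 2 * np.pi * np.cumsum(inst_f) / sample_rate
    tone = np.zeros(n)
    nyq = sample_rate / 2
    for h in range(1, archetype.n_harmonics + 1):
        if h * (f0 + abs(archetype.fm_depth) / 2) >= nyq:
            break
        tone += np.sin(h * phase) / h
    if tone.any():
        tone /= np.max(np.abs(tone))
    noise = rng.standard_normal(n)
    noise /= max(np.max(np.abs(noise)), 1e-12)
    w = (1 - archetype.noisiness) * tone + archetype.noisiness * noise
    # raised-cosine attack/decay over 15% of the syllable each (>= 2 ms)
    ramp = max(int(0.15 * n), int(0.002 * sample_rate), 2)
    ramp = min(ramp, n // 2)
    env = np.ones(n)
    ramp_shape = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[:ramp] = ramp_shape
    env[-ramp:] = ramp_shape[::-1]
    w *= env
    peak = np.max(np.abs(w))
    if peak > 0:
        w *= _PEAK / peak
    return w.astype(np.float64), archetype.call_type


def synth_recording(
    events: pd.DataFrame,
    archetypes: Mapping[str, SyllableArchetype] = DEFAULT_ARCHETYPES,
    noise_floor_db: float = -40.0,
    sample_rate: int = 44100,
    duration: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render per-bird mono waveforms for an event table.

    Syllables are placed at event onsets over Gaussian noise whose RMS sits
    ``noise_floor_db`` below the syllable peak (0.5 full scale). Overlapping
    syllables of the same bird are resolved by shifting the later onset
    forward (logged); the returned truth table lists the realised onsets,
    offsets and labels, which downstream interaction analysis consumes
    instead of the audio.

    Returns ``(waveforms, truth)`` with one waveform per bird.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(events):
        events = events.sort_values("onset_s", kind="mergesort")
    total = duration
    if total is None:
        last = float(events["onset_s"].max()) if len(events) else 0.0
        total = last + 0.5
    n_total = int(round(total * sample_rate))
    sigma = _PEAK * 10 ** (noise_floor_db / 20)

    waveforms: dict[str, np.ndarray] = {}
    truth_rows = []
    bird_ids = sorted(events["bird_id"].unique()) if len(events) else []
    n_shifted = 0
    for b in bird_ids:
        w = rng.standard_normal(n_total) * sigma
        prev_off = -np.inf
        for _, row in events[events["bird_id"] == b].iterrows():
            ctype = str(row["call_type"])
            arch = archetypes.get(ctype)
            if arch is None:
                continue
            syl, _ = synth_syllable(arch, sample_rate, rng=rng)
            onset = float(row["onset_s"])
            if onset < prev_off + 0.005:  # forward-shift to resolve overlap
                onset = prev_off + 0.005
                n_shifted += 1
            i0 = int(round(onset * sample_rate))
            i1 = i0 + syl.size
            if i1 > n_total:
                break  # syllable would run past the recording end
            w[i0:i1] += syl
            realised_onset = i0 / sample_rate
            realised_offset = i1 / sample_rate
            truth_rows.append(
                {
                    "bird_id": b,
                    "call_type": ctype,
                    "onset_s": realised_onset,
                    "offset_s": realised_offset,
                }
            )
            prev_off = realised_offset
        waveforms[b] = w
    if n_shifted:
        logger.info("synth_recording: forward-shifted %d overlapping syllables", n_shifted)
    truth = pd.DataFrame(
        truth_rows, columns=["bird_id", "call_type", "onset_s", "offset_s"]
    )
    return waveforms, truth
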