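"""Core domain vocabulary: call types, breeding/nest stages, event records.

The analysable call repertoire of group-housed zebra finches consists of five
call types — distance calls, tets, stacks, cackles and whines. Everything else
(song syllables, intermediate "arc" calls, unclassifiable vocalisations) is
demoted to the catch-all label ``"other"`` and excluded from all interaction
and repertoire statistics rather than rejected at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "CALL_TYPES",
    "OTHER",
    "ALL_LABELS",
    "BREEDING_STAGES",
    "NEST_STAGES",
    "STAGE_CONDENSATION",
    "normalize_call_type",
    "condense_stage",
    "CallEvent",
    "Recording",
    "BirdMeta",
    "CallnetError",
    "ConfigError",
    "FormatError",
]

#: The five analysable call types, in canonical display order.
CALL_TYPES: tuple[str, ...] = ("distance", "tet", "stack", "cackle", "whine")

#: Catch-all label for calls excluded from interaction/repertoire statistics.
OTHER: str = "other"

ALL_LABELS: tuple[str, ...] = CALL_TYPES + (OTHER,)

#: Detailed seven-level reproductive-status labels, in chronological order.
BREEDING_STAGES: tuple[str, ...] = (
    "Unpaired",
    "No nest",
    "Territorial",
    "Nest inspection",
    "Nest building",
    "Laying",
    "Incubation",
)

#: Condensed three-level labels.
NEST_STAGES: tuple[str, ...] = ("Pre-nesting", "Early nesting", "Later nesting")

#: Total, fixed condensation map from breeding stage to nest stage.
STAGE_CONDENSATION: dict[str, str] = {
    "Unpaired": "Pre-nesting",
    "No nest": "Pre-nesting",
    "Territorial": "Early nesting",
    "Nest inspection": "Early nesting",
    "Nest building": "Later nesting",
    "Laying": "Later nesting",
    "Incubation": "Later nesting",
}


class CallnetError(Exception):
    """Base class for callnet errors."""


class ConfigError(CallnetError, ValueError):
    """Invalid parameterisation of an operation."""


class FormatError(CallnetError, ValueError):
    """Malformed input table or file."""


def normalize_call_type(label: str) -> str:
    """Map a raw call-type string onto the closed vocabulary.

    Known labels pass through (case-insensitively); anything else — including
    "arc" and song syllables — becomes ``"other"``.
    """
    s = str(label).strip().lower()
    return s if s in ALL_LABELS else OTHER


def condense_stage(breeding_stage: str) -> str:
    """Condense one of the seven breeding stages to its nest stage.

    Raises
    ------
    ConfigError
        If ``breeding_stage`` is not one of the seven known labels.
    """
    try:
        return STAGE_CONDENSATION[breeding_stage]
    except KeyError:
        raise ConfigError(
            f"unknown breeding stage {breeding_stage!r}; "
            f"expected one of {BREEDING_STAGES}"
        ) from None


@dataclass(frozen=True)
class CallEvent:
    """One time-stamped, typed vocalisation by one identified bird.

    ``onset`` is seconds from the start of the recording; onsets from
    different recordings are never compared.
    """

    recording_id: str
    bird_id: str
    onset: float
    call_type: str
    offset: Optional[float] = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.offset is not None and self.offset < self.onset:
            raise ValueError(
                f"offset {self.offset} precedes onset {self.onset}"
            )
        if self.call_type not in ALL_LABELS:
            raise ValueError(f"unknown call type {self.call_type!r}")


@dataclass(frozen=True)
class Recording:
    """One analysed recording period (a morning session of one group)."""

    recording_id: str
    trial_id: str = ""
    duration: float = 243.0  # minutes
    day_index: int = 0
    breeding_stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("recording duration must be positive")

    @property
    def nest_stage(self) -> Optional[str]:
        if self.breeding_stage is None:
            return None
        return condense_stage(self.breeding_stage)


@dataclass(frozen=True)
class BirdMeta:
    """Identity and pairing metadata for one bird."""

    bird_id: str
    sex: str = "unknown"  # {"female", "male", "unknown"}
    pair_id: Optional[str] = None
    success: str = "unknown"  # {"successful", "unsuccessful", "unknown"}


def validate_pairs(birds: list[BirdMeta]) -> None:
    """Check that each pair_id covers exactly two birds of opposite sex."""
    by_pair: dict[str, list[BirdMeta]] = {}
    for b in birds:
        if b.pair_id is not None:
            by_pair.setdefault(str(b.pair_id), []).append(b)
    for pid, members in by_pair.items():
        if len(members) != 2:
            raise FormatError(
                f"pair {pid!r} has {len(members)} members; expected 2"
            )
        sexes = {m.sex for m in members}
        if sexes != {"female", "male"}:
            raise FormatError(
                f"pair {pid!r} is not one female + one male (got {sorted(sexes)})"
            )
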