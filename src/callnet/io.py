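"""Readers and writers for event tables, matrices and WAV audio.

The interchange format for call events is a UTF-8 TSV with a header row.
Required columns: ``recording_id``, ``bird_id``, ``call_type``, ``onset_s``;
optional: ``offset_s``, ``sex``, ``pair_id``, ``breeding_stage``, ``success``,
``duration_min``, ``trial_id``, ``day_index``. Onsets are seconds from the
start of the recording and written with six decimal places; unknown
call-type strings are demoted to ``"other"`` (with a logged count) rather
than rejected.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .types import ALL_LABELS, OTHER, FormatError, normalize_call_type

__all__ = [
    "EventTable",
    "read_event_table",
    "write_event_table",
    "write_matrix_long",
    "read_matrix_long",
    "read_wav",
    "write_wav",
    "config_digest",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("recording_id", "bird_id", "call_type", "onset_s")
OPTIONAL_COLUMNS = (
    "offset_s",
    "sex",
    "pair_id",
    "breeding_stage",
    "success",
    "duration_min",
    "trial_id",
    "day_index",
    "stage",
    "triggered",
)

PathLike = Union[str, Path]


@dataclass
class EventTable:
    """Validated event table plus per-recording and per-bird metadata.

    ``events`` holds one row per vocalisation, onset-sorted within each
    recording; ``recordings`` and ``birds`` are derived from the optional
    metadata columns (one row per id).
    """

    events: pd.DataFrame
    recordings: pd.DataFrame = field(default_factory=pd.DataFrame)
    birds: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_other: int = 0

    def analysable(self) -> pd.DataFrame:
        """Events excluding the catch-all ``"other"`` type."""
        return self.events[self.events["call_type"] != OTHER]


def read_event_table(path: PathLike) -> EventTable:
    """Read and validate a call-event TSV.

    Raises
    ------
    FormatError
        If a required column is missing (named in the message) or an onset
        is non-numeric or negative (reported with its line number).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    onset = pd.to_numeric(df["onset_s"], errors="coerce")
    bad = onset.isna() | (onset < 0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise FormatError(
            f"non-numeric or negative onset_s at line {line} of {path}: "
            f"{df['onset_s'].iloc[line - 2]!r}"
        )
    df["onset_s"] = onset.astype(float)
    if "offset_s" in df.columns:
        off = pd.to_numeric(df["offset_s"], errors="coerce")
        if ((off < df["onset_s"]) & off.notna()).any():
            line = int(np.flatnonzero((off < df["onset_s"]).to_numpy())[0]) + 2
            raise FormatError(f"offset_s precedes onset_s at line {line} of {path}")
        df["offset_s"] = off

    raw_types = df["call_type"].astype(str)
    df["call_type"] = raw_types.map(normalize_call_type)
    demoted = int(((df["call_type"] == OTHER) & (raw_types.str.strip().str.lower() != OTHER)).sum())
    if demoted:
        logger.warning(
            "read_event_table: %d events with unknown call types demoted to %r",
            demoted,
            OTHER,
        )

    df = df.sort_values(["recording_id", "onset_s"], kind="mergesort").reset_index(
        drop=True
    )

    rec_cols = [
        c
        for c in ("recording_id", "trial_id", "duration_min", "day_index", "breeding_stage", "stage")
        if c in df.columns
    ]
    recordings = df[rec_cols].drop_duplicates("recording_id").reset_index(drop=True)
    if "duration_min" in recordings.columns:
        recordings["duration_min"] = pd.to_numeric(
            recordings["duration_min"], errors="coerce"
        )
    bird_cols = [c for c in ("bird_id", "sex", "pair_id", "success") if c in df.columns]
    birds = df[bird_cols].drop_duplicates("bird_id").reset_index(drop=True)

    logger.info(
        "read_event_table: %d events, %d recordings, %d birds (%d demoted to other)",
        len(df),
        recordings["recording_id"].nunique(),
        birds["bird_id"].nunique(),
        demoted,
    )
    return EventTable(events=df, recordings=recordings, birds=birds, n_other=demoted)


def write_event_table(events: pd.DataFrame, path: PathLike) -> Path:
    """Write an event table as TSV with 6-decimal onsets."""
    path = Path(path)
    df = events.copy()
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in REQUIRED_COLUMNS
    ]
    df = df[cols]
    for c in ("onset_s", "offset_s"):
        if c in df.columns:
            df[c] = df[c].map(lambda x: "" if pd.isna(x) else f"{float(x):.6f}")
    df.to_csv(path, sep="\t", index=False)
    return path


def write_matrix_long(matrix, path: PathLike) -> Path:
    """Write an interaction matrix as a long-format TSV, one row per cell.

    Invalid cells keep ``valid=False`` and an *empty* r_index (missing data,
    as opposed to a non-significant 0); within-bird cells are flagged
    ``excluded``.
    """
    path = Path(path)
    df = matrix.to_long()
    df["r_index"] = df["r_index"].map(lambda x: "" if pd.isna(x) else f"{x:.6f}")
    df.to_csv(path, sep="\t", index=False)
    return path


def read_matrix_long(path: PathLike) -> pd.DataFrame:
    """Read a long-format matrix TSV back into a DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"initiator_bird": str, "responder_bird": str})
    df["r_index"] = pd.to_numeric(df["r_index"], errors="coerce")
    for col in ("excluded", "valid"):
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df


def read_wav(path: PathLike) -> tuple[int, np.ndarray]:
    """Read a mono WAV file; returns ``(sample_rate, float64 waveform)``.

    Integer PCM is rescaled to [-1, 1).
    """
    rate, data = wavfile.read(Path(path))
    if data.ndim > 1:
        raise FormatError(f"{path} is not mono")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(np.float64)
    return int(rate), data


def write_wav(path: PathLike, sample_rate: int, waveform: np.ndarray) -> Path:
    """Write a float32 mono WAV file."""
    path = Path(path)
    wavfile.write(path, int(sample_rate), np.asarray(waveform, dtype=np.float32))
    return path


def config_digest(obj) -> str:
    """Short stable digest of a configuration for run logging."""
    def _plain(x):
        if hasattr(x, "__dataclass_fields__"):
            return {k: _plain(getattr(x, k)) for k in x.__dataclass_fields__}
        if isinstance(x, dict):
            return {str(k): _plain(v) for k, v in sorted(x.items(), key=lambda kv: str(kv[0]))}
        if isinstance(x, (list, tuple)):
            return [_plain(v) for v in x]
        if isinstance(x, (str, int, float, bool)) or x is None:
            return x
        return str(x)

    payload = json.dumps(_plain(obj), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
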