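"""Reading and writing recordings, event/artifact tables and score tables.

All files are plain comma-delimited UTF-8 text with a header row; recording
metadata travels in a JSON sidecar. Signals are stored one column per channel
with headers like ``TA_r``; columns may appear in any order on disk and are
re-ordered into the canonical montage order on read.

Time convention: seconds, 0-based from the first sample; windows are
half-open ``[start_s, end_s)``; sample index = ``floor(t * fs)``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, MontageError, ParseError, ValidationError
from .montage import (
    ALL_TASKS,
    CANONICAL_CHANNELS,
    CHANNEL_INDEX,
    JOINTS,
    LEGS,
    ChannelLabel,
    TaskId,
)

SESSIONS = ("test", "retest")
GROUPS = ("CP", "control", "reference_adult")

#: Numeric precision used when writing signal/score files; round-trip
#: identity holds at this precision.
FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class EmgRecording:
    """A multichannel surface EMG recording in microvolts.

    ``samples`` is an ``(n_samples, 10)`` float array in canonical channel
    order. ``side_map`` resolves the clinical leg labels to physical sides,
    e.g. ``{"less": "r", "more": "l"}``.
    """

    samples: np.ndarray
    fs: float
    channels: tuple[ChannelLabel, ...] = CANONICAL_CHANNELS
    notch_flags: np.ndarray = field(default_factory=lambda: np.zeros(10, dtype=bool))
    subject_id: str = "anonymous"
    session: str = "test"
    side_map: dict = field(default_factory=lambda: {"less": "r", "more": "l"})

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "notch_flags", np.asarray(self.notch_flags, dtype=bool))
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 2 or samples.shape[1] != len(CANONICAL_CHANNELS):
            raise MontageError(
                f"expected {len(CANONICAL_CHANNELS)} channels, got shape {samples.shape}"
            )
        if tuple(self.channels) != CANONICAL_CHANNELS:
            raise MontageError("channels must be in canonical order; use read_recording")
        if self.notch_flags.shape != (len(CANONICAL_CHANNELS),):
            raise ValidationError("notch_flags must have one entry per channel")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("recording contains non-finite samples")
        if samples.shape[0] < self.fs * 3:
            raise ValidationError(
                "recording shorter than 3 s; no baseline window can be located"
            )
        if self.session not in SESSIONS:
            raise ValidationError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if set(self.side_map) != set(LEGS) or set(self.side_map.values()) != {"r", "l"}:
            raise ValidationError(f"side_map must map {LEGS} onto both sides, got {self.side_map}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def tested_side(self, task: TaskId) -> str:
        """Physical side ('r'/'l') tested by a task for this subject."""
        return self.side_map[task.leg]

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        return replace(self, samples=samples)

    def sample_slice(self, start_s: float, end_s: float) -> slice:
        """Half-open sample range covering ``[start_s, end_s)``."""
        return slice(int(np.floor(start_s * self.fs)), int(np.floor(end_s * self.fs)))


def read_recording(signal_path, sidecar_path) -> EmgRecording:
    """Read a signal CSV plus its JSON sidecar into a validated recording.

    Columns are re-ordered into canonical montage order; a missing or
    duplicated channel raises :class:`MontageError` naming it, and any
    non-numeric cell raises :class:`ParseError` with its row index.
    """
    signal_path = Path(signal_path)
    with open(signal_path, encoding="utf-8") as fh:
        raw_header = [c.strip() for c in fh.readline().rstrip("\n").split(",")]
    try:
        header = [ChannelLabel.parse(c) for c in raw_header]
    except ValueError as exc:
        raise MontageError(str(exc)) from exc
    seen: set[ChannelLabel] = set()
    for label in header:
        if label in seen:
            raise MontageError(f"duplicate channel {label}")
        seen.add(label)
    df = pd.read_csv(signal_path, dtype=str)
    df.columns = raw_header
    missing = [str(c) for c in CANONICAL_CHANNELS if c not in seen]
    if missing:
        raise MontageError(f"missing channel(s): {', '.join(missing)}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        raise ParseError(f"non-numeric cell at data row {row} of {signal_path.name}")
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0, 0])
        raise ParseError(f"empty cell at data row {row} of {signal_path.name}")

    order = [df.columns[[str(h) for h in header].index(str(c))] for c in CANONICAL_CHANNELS]
    samples = numeric[order].to_numpy(dtype=float)

    with open(sidecar_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    fs = float(meta.get("fs", 0))
    flags_raw = meta.get("notch_flags", {})
    if isinstance(flags_raw, dict):
        flags = np.array([bool(flags_raw.get(str(c), False)) for c in CANONICAL_CHANNELS])
    else:
        flags = np.asarray(flags_raw, dtype=bool)
    return EmgRecording(
        samples=samples,
        fs=fs,
        notch_flags=flags,
        subject_id=str(meta.get("subject_id", "anonymous")),
        session=str(meta.get("session", "test")),
        side_map=dict(meta.get("side_map", {"less": "r", "more": "l"})),
    )


def write_recording(rec: EmgRecording, signal_path, sidecar_path) -> None:
    df = pd.DataFrame(rec.samples, columns=[str(c) for c in rec.channels])
    df.to_csv(signal_path, index=False, float_format=FLOAT_FORMAT)
    meta = {
        "fs": rec.fs,
        "notch_flags": {str(c): bool(f) for c, f in zip(rec.channels, rec.notch_flags)},
        "subject_id": rec.subject_id,
        "session": rec.session,
        "side_map": rec.side_map,
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Event tables


@dataclass(frozen=True)
class EventTable:
    """Per-task, per-repetition half-open time windows.

    Rows are sorted by (leg, joint, repetition); each of the 8 tasks present
    must have exactly 3 non-overlapping, ordered repetitions.
    """

    df: pd.DataFrame  # columns: joint, leg, repetition, start_s, end_s

    COLUMNS = ("joint", "leg", "repetition", "start_s", "end_s")

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing column(s) {missing}")
        df["repetition"] = df["repetition"].astype(int)
        df[["start_s", "end_s"]] = df[["start_s", "end_s"]].astype(float)
        for _, row in df.iterrows():
            TaskId(row["joint"], row["leg"])  # validates vocabulary
            if not row["end_s"] > row["start_s"]:
                raise ValidationError(
                    f"empty or inverted window [{row['start_s']}, {row['end_s']}) "
                    f"for {row['joint']}_{row['leg']} rep {row['repetition']}"
                )
        for (joint, leg), grp in df.groupby(["joint", "leg"], sort=False):
            reps = sorted(grp["repetition"])
            if reps != [1, 2, 3]:
                raise ValidationError(
                    f"task {joint}_{leg} has repetitions {reps}; expected exactly [1, 2, 3]"
                )
            g = grp.sort_values("repetition")
            starts, ends = g["start_s"].to_numpy(), g["end_s"].to_numpy()
            if not (np.all(np.diff(starts) > 0) and np.all(ends[:-1] <= starts[1:])):
                raise ValidationError(f"repetitions of {joint}_{leg} overlap or are unordered")
        df = df.sort_values(["leg", "joint", "repetition"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "df", df)

    @property
    def tasks(self) -> list[TaskId]:
        pairs = self.df[["joint", "leg"]].drop_duplicates().itertuples(index=False)
        return [TaskId(j, l) for j, l in pairs]

    def window(self, task: TaskId, repetition: int) -> tuple[float, float]:
        sel = self.df[
            (self.df["joint"] == task.joint)
            & (self.df["leg"] == task.leg)
            & (self.df["repetition"] == repetition)
        ]
        if sel.empty:
            raise DataError(f"no window for {task} repetition {repetition}")
        row = sel.iloc[0]
        return float(row["start_s"]), float(row["end_s"])

    def check_inside(self, duration_s: float) -> None:
        if (self.df["start_s"] < 0).any() or (self.df["end_s"] > duration_s + 1e-9).any():
            raise ValidationError("event window extends outside the recording")


def read_events(path) -> EventTable:
    df = pd.read_csv(path)
    return EventTable(df)


def write_events(table: EventTable, path) -> None:
    table.df.to_csv(path, index=False, columns=list(EventTable.COLUMNS))


# ---------------------------------------------------------------------------
# Artifact tables


@dataclass(frozen=True)
class ArtifactTable:
    """Documented movement-artifact segments.

    ``scope`` is either ``"all"`` (the segment is excised from the time axis
    on every channel) or a single channel label (the overlapped repetitions
    of that channel are excluded from RMS averaging).
    """

    df: pd.DataFrame  # columns: start_s, end_s, scope, reason

    COLUMNS = ("start_s", "end_s", "scope", "reason")

    def __post_init__(self) -> None:
        df = self.df.copy()
        if df.empty and not set(self.COLUMNS) <= set(df.columns):
            df = pd.DataFrame(columns=list(self.COLUMNS))
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"artifact table missing column(s) {missing}")
        df[["start_s", "end_s"]] = df[["start_s", "end_s"]].astype(float)
        for _, row in df.iterrows():
            if not row["end_s"] > row["start_s"]:
                raise ValidationError(
                    f"empty artifact window [{row['start_s']}, {row['end_s']})"
                )
            if row["scope"] != "all":
                ChannelLabel.parse(str(row["scope"]))
        object.__setattr__(self, "df", df.reset_index(drop=True))

    @classmethod
    def empty(cls) -> "ArtifactTable":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)))

    def check_inside(self, duration_s: float) -> None:
        if not self.df.empty and (
            (self.df["start_s"] < 0).any() or (self.df["end_s"] > duration_s + 1e-9).any()
        ):
            raise ValidationError("artifact window extends outside the recording")


def read_artifacts(path) -> ArtifactTable:
    return ArtifactTable(pd.read_csv(path))


def write_artifacts(table: ArtifactTable, path) -> None:
    table.df.to_csv(path, index=False, columns=list(ArtifactTable.COLUMNS))


# ---------------------------------------------------------------------------
# Score tables

_TASK_SI_COLUMNS = [f"si_{t.joint}_{t.leg}" for t in ALL_TASKS]
_SCALE_COLUMNS = [f"scale_{j}_{leg}" for leg in LEGS for j in JOINTS]

#: Stable column order of the score-table dialect.
SCORE_COLUMNS = (
    ["subject_id", "session", "group"]
    + _TASK_SI_COLUMNS
    + ["si_leg_less", "si_leg_more", "si_total"]
    + _SCALE_COLUMNS
    + ["gmfcs"]
)


def validate_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and column-order a score table DataFrame."""
    for col in ("subject_id", "session"):
        if col not in df.columns:
            raise ValidationError(f"score table missing column {col!r}")
    out = df.copy()
    for col in SCORE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    si_cols = _TASK_SI_COLUMNS + ["si_leg_less", "si_leg_more", "si_total"]
    si = out[si_cols].astype(float)
    bad = ((si < -1e-12) | (si > 1 + 1e-12)) & si.notna()
    if bad.to_numpy().any():
        col = si_cols[int(np.argwhere(bad.to_numpy())[0, 1])]
        raise ValidationError(f"similarity index outside [0, 1] in column {col}")
    sc = out[_SCALE_COLUMNS].astype(float)
    bad = (~sc.isin([0.0, 1.0, 2.0])) & sc.notna()
    if bad.to_numpy().any():
        raise ValidationError("ordinal joint score outside {0, 1, 2}")
    return out[list(SCORE_COLUMNS)]


def write_scores(df: pd.DataFrame, path) -> None:
    """Write a score table with the stable column order; round-trips exactly."""
    validate_scores(df).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "session": str, "group": str})
    return validate_scores(df)
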