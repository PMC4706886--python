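"""Recording / event-table / layout I/O, band-pass filtering, and epoching.

A recording is an M-channel x T-sample matrix of scalp potentials in
microvolts with a sampling rate (250 Hz in the study design this package
targets) and ordered channel ids.  Events map each question to a half-open
sample interval [start, end) and a binary label: 1 = correct answer (true
memory), 0 = incorrect answer (false memory).

On-disk formats are deliberately plain: raw float64 binary (`.dat`) or
delimited text for the matrix, a JSON sidecar for metadata, and CSV for
events and electrode layouts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import (
    ChannelLookupError,
    ConsistencyError,
    FormatError,
    LabelError,
    LayoutError,
    ParameterError,
    QuestionLookupError,
    RangeError,
    UniquenessError,
)

#: Longest allowed answer window, in seconds.
MAX_EPOCH_SECONDS = 30.0

_TEXT_SUFFIXES = {".csv", ".txt", ".tsv"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel EEG potentials (microvolts), channels x samples."""

    potentials: np.ndarray
    sampling_rate: float
    channel_ids: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self):
        pot = np.asarray(self.potentials, dtype=float)
        if pot.ndim != 2 or pot.shape[0] < 1 or pot.shape[1] < 1:
            raise ConsistencyError("potentials must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(pot)):
            raise FormatError("potentials contain non-finite values")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        ids = tuple(str(c) for c in self.channel_ids)
        if len(ids) != pot.shape[0]:
            raise ConsistencyError(
                f"{len(ids)} channel ids for {pot.shape[0]} matrix rows"
            )
        if len(set(ids)) != len(ids):
            raise UniquenessError("channel_ids must be unique")
        object.__setattr__(self, "potentials", pot)
        object.__setattr__(self, "channel_ids", ids)

    @property
    def n_channels(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[1]


@dataclass(frozen=True)
class EventTable:
    """Per-question answer intervals (half-open, 0-based) and labels."""

    question_ids: tuple[str, ...]
    start_samples: np.ndarray
    end_samples: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        qids = tuple(str(q) for q in self.question_ids)
        start = np.asarray(self.start_samples, dtype=int)
        end = np.asarray(self.end_samples, dtype=int)
        lab = np.asarray(self.labels)
        n = len(qids)
        if not (start.shape == end.shape == lab.shape == (n,)):
            raise ConsistencyError("event columns have mismatched lengths")
        if len(set(qids)) != n:
            raise UniquenessError("duplicate question_id in event table")
        if np.any(start < 0):
            raise RangeError("start_sample must be >= 0")
        if np.any(start >= end):
            raise RangeError("each event needs start_sample < end_sample")
        if not np.isin(lab, (0, 1)).all():
            raise LabelError("labels must be 0 or 1")
        object.__setattr__(self, "question_ids", qids)
        object.__setattr__(self, "start_samples", start)
        object.__setattr__(self, "end_samples", end)
        object.__setattr__(self, "labels", lab.astype(int))

    def __len__(self) -> int:
        return len(self.question_ids)

    def interval(self, question_id: str) -> tuple[int, int, int]:
        """Return (start, end, label) for one question."""
        try:
            i = self.question_ids.index(str(question_id))
        except ValueError:
            raise QuestionLookupError(question_id) from None
        return int(self.start_samples[i]), int(self.end_samples[i]), int(self.labels[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "question_id": self.question_ids,
                "start_sample": self.start_samples,
                "end_sample": self.end_samples,
                "label": self.labels,
            }
        )


@dataclass(frozen=True)
class ElectrodeLayout:
    """2-D scalp projection of electrode positions inside the head disc."""

    channel_ids: tuple[str, ...]
    positions: np.ndarray  # (M, 2) unitless x, y
    head_radius: float = 1.0

    def __post_init__(self):
        ids = tuple(str(c) for c in self.channel_ids)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] != len(ids):
            raise ConsistencyError("positions must be (n_channels, 2)")
        if len(set(ids)) != len(ids):
            raise UniquenessError("layout channel_ids must be unique")
        if self.head_radius <= 0:
            raise ParameterError("head_radius must be positive")
        r = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(r > self.head_radius * (1 + 1e-9)):
            raise LayoutError("electrode outside the head disc")
        if pos.shape[0] < 3 or _collinear(pos):
            raise LayoutError("layout needs >= 3 non-collinear electrodes")
        object.__setattr__(self, "channel_ids", ids)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.channel_ids)

    def position_of(self, channel_id: str) -> np.ndarray:
        try:
            i = self.channel_ids.index(str(channel_id))
        except ValueError:
            raise ChannelLookupError(channel_id) from None
        return self.positions[i]


def _collinear(pos: np.ndarray, tol: float = 1e-12) -> bool:
    d = pos - pos[0]
    cross = d[:, 0, None] * d[None, :, 1] - d[:, 1, None] * d[None, :, 0]
    return bool(np.all(np.abs(cross) < tol))


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------


def _meta_path(matrix_path: Path) -> Path:
    return matrix_path.with_suffix(".json")


def write_recording(rec: EEGRecording, matrix_path, meta_path=None) -> None:
    """Write a recording as float64 binary (or delimited text) + JSON sidecar."""
    matrix_path = Path(matrix_path)
    meta_path = Path(meta_path) if meta_path else _meta_path(matrix_path)
    if matrix_path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(matrix_path, rec.potentials, delimiter=",")
    else:
        rec.potentials.astype("<f8").tofile(matrix_path)
    meta = {
        "sampling_rate": rec.sampling_rate,
        "channel_ids": list(rec.channel_ids),
        "subject_id": rec.subject_id,
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def read_recording(matrix_path, meta_path=None) -> EEGRecording:
    """Read a recording written by :func:`write_recording`.

    Binary `.dat` files are row-major float64; `.csv`/`.txt`/`.tsv` files are
    delimited text.  The sidecar's channel count fixes the row count; a
    mismatch with the matrix size is a consistency error.
    """
    matrix_path = Path(matrix_path)
    meta_path = Path(meta_path) if meta_path else _meta_path(matrix_path)
    try:
        meta = json.loads(meta_path.read_text())
        rate = float(meta["sampling_rate"])
        channel_ids = [str(c) for c in meta["channel_ids"]]
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"bad metadata sidecar {meta_path}: {exc}") from exc
    m = len(channel_ids)
    if matrix_path.suffix.lower() in _TEXT_SUFFIXES:
        try:
            flat = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"non-numeric matrix file {matrix_path}") from exc
        if flat.shape[0] != m:
            raise ConsistencyError(
                f"metadata lists {m} channels but matrix has {flat.shape[0]} rows"
            )
        pot = flat
    else:
        raw = np.fromfile(matrix_path, dtype="<f8")
        if m == 0 or raw.size == 0 or raw.size % m:
            raise ConsistencyError(
                f"matrix size {raw.size} is not a multiple of {m} channels"
            )
        pot = raw.reshape(m, -1)
    return EEGRecording(pot, rate, tuple(channel_ids), meta.get("subject_id", ""))


# ---------------------------------------------------------------------------
# Event-table and layout I/O
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ("question_id", "start_sample", "end_sample", "label")


def read_events(path, sampling_rate: float | None = None) -> EventTable:
    """Read a `question_id,start_sample,end_sample,label` CSV.

    When *sampling_rate* is given, each answer window is additionally checked
    against the 30-second protocol limit.
    """
    try:
        df = pd.read_csv(path, dtype={"question_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse event table {path}: {exc}") from exc
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event table missing columns {sorted(missing)}")
    try:
        table = EventTable(
            tuple(df["question_id"]),
            df["start_sample"].to_numpy(dtype=int),
            df["end_sample"].to_numpy(dtype=int),
            df["label"].to_numpy(),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, (RangeError, LabelError, UniquenessError, ConsistencyError)):
            raise
        raise FormatError(f"non-numeric event table cell in {path}") from exc
    if sampling_rate is not None:
        _check_epoch_durations(table, sampling_rate)
    return table


def _check_epoch_durations(table: EventTable, sampling_rate: float) -> None:
    limit = MAX_EPOCH_SECONDS * sampling_rate
    dur = table.end_samples - table.start_samples
    if np.any(dur > limit):
        raise RangeError(
            f"answer window exceeds {MAX_EPOCH_SECONDS:.0f} s at {sampling_rate} Hz"
        )


def write_events(table: EventTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_layout(path, head_radius: float = 1.0) -> ElectrodeLayout:
    """Read a `channel_id,x,y` CSV layout."""
    try:
        df = pd.read_csv(path, dtype={"channel_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse layout {path}: {exc}") from exc
    missing = {"channel_id", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"layout missing columns {sorted(missing)}")
    return ElectrodeLayout(
        tuple(df["channel_id"]),
        df[["x", "y"]].to_numpy(dtype=float),
        head_radius=head_radius,
    )


def write_layout(layout: ElectrodeLayout, path) -> None:
    pd.DataFrame(
        {
            "channel_id": layout.channel_ids,
            "x": layout.positions[:, 0],
            "y": layout.positions[:, 1],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def bandpass_filter(
    rec: EEGRecording, low_hz: float = 1.0, high_hz: float = 48.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    A forward-backward (``sosfiltfilt``) 4th-order Butterworth band-pass is
    used so in-band components keep their timing; the effective attenuation
    slope is doubled by the two passes.
    """
    nyquist = rec.sampling_rate / 2.0
    if not (0 < low_hz < high_hz):
        raise ParameterError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ParameterError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    sos = butter(order, (low_hz, high_hz), btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = sosfiltfilt(sos, rec.potentials, axis=1)
    return replace(rec, potentials=filtered)


def select_channels(rec: EEGRecording, keep: Sequence[str]) -> EEGRecording:
    """Keep (and reorder to) the given channel ids."""
    keep = [str(c) for c in keep]
    if not keep:
        raise ParameterError("keep list must be non-empty")
    index = {c: i for i, c in enumerate(rec.channel_ids)}
    try:
        rows = [index[c] for c in keep]
    except KeyError as exc:
        raise ChannelLookupError(f"unknown channel {exc.args[0]!r}") from None
    return replace(rec, potentials=rec.potentials[rows], channel_ids=tuple(keep))


def extract_question_epoch(
    rec: EEGRecording, events: EventTable, question_id: str
) -> EEGRecording:
    """Cut the [start, end) answer window of one question out of a recording."""
    start, end, _ = events.interval(question_id)
    if end > rec.n_samples:
        raise RangeError(
            f"event [{start}, {end}) exceeds recording length {rec.n_samples}"
        )
    return replace(rec, potentials=rec.potentials[:, start:end])
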