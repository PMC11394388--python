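"""Readers and writers for every external format the tool touches.

Accelerometer recordings travel as CSV with a header row naming the columns
(``t, ax, ay, az`` plus an optional 0/1 ``marker`` column), heart sounds as
PCM mono WAV, detected events as JSON, and maternal-perception markers either
embedded in the CSV or as a plain text file of timestamps.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import FormatError, SamplingError
from .signals import TIME_GRID_TOL, AudioClip, TriaxialRecord

log = logging.getLogger(__name__)

# accepted aliases for each required CSV column (lower-case, stripped)
_COLUMN_ALIASES = {
    "t": ("t", "time", "time_s", "seconds"),
    "ax": ("ax", "x", "acc_x", "accx"),
    "ay": ("ay", "y", "acc_y", "accy"),
    "az": ("az", "z", "acc_z", "accz"),
}
_MARKER_ALIASES = ("marker", "markers", "button", "mp")


def _resolve_columns(columns) -> dict:
    lookup = {str(c).strip().lower(): c for c in columns}
    resolved = {}
    for key, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lookup:
                resolved[key] = lookup[alias]
                break
        else:
            raise FormatError(f"missing required column '{key}'")
    for alias in _MARKER_ALIASES:
        if alias in lookup:
            resolved["marker"] = lookup[alias]
            break
    return resolved


def read_accel_csv(
    path,
    units_scale: float = 1.0,
    fs: float | None = None,
) -> TriaxialRecord:
    """Read a triaxial accelerometer CSV into a :class:`TriaxialRecord`.

    The file must have a header row naming a time column and three
    acceleration columns; an optional 0/1 marker column carries maternal
    perception button presses.  ``fs`` is inferred from the time column when
    not given.  Acceleration values are multiplied by ``units_scale`` (the
    factor from file units to g); the reader never guesses units silently.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"cannot parse accelerometer CSV {path}: {e}") from e
    cols = _resolve_columns(df.columns)
    t = df[cols["t"]].to_numpy(dtype=float)
    if t.size < 2 and fs is None:
        raise SamplingError("cannot infer fs from fewer than 2 samples")
    if fs is None:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SamplingError("time column is not strictly increasing")
        fs = float(np.round(1.0 / np.median(dt), 9))
    markers: tuple[float, ...] = ()
    if "marker" in cols:
        flag = df[cols["marker"]].to_numpy(dtype=float)
        markers = tuple(t[flag > 0])
    scale = float(units_scale)
    return TriaxialRecord(
        t=t,
        ax=df[cols["ax"]].to_numpy(dtype=float) * scale,
        ay=df[cols["ay"]].to_numpy(dtype=float) * scale,
        az=df[cols["az"]].to_numpy(dtype=float) * scale,
        fs=fs,
        markers=markers,
        units_scale=scale,
    )


def write_accel_csv(rec: TriaxialRecord, path) -> None:
    """Write a record back to the CSV layout :func:`read_accel_csv` reads."""
    df = pd.DataFrame({"t": rec.t, "ax": rec.ax, "ay": rec.ay, "az": rec.az})
    if rec.markers:
        marker = np.zeros(len(rec), dtype=int)
        idx = np.searchsorted(rec.t, np.asarray(rec.markers))
        idx = np.clip(idx, 0, len(rec) - 1)
        marker[idx] = 1
        df["marker"] = marker
    df.to_csv(path, index=False)


def read_markers(path) -> list[float]:
    """Read maternal-perception timestamps (one or more per line, seconds).

    Values are sorted and de-duplicated; negative times raise
    :class:`FormatError`.
    """
    text = Path(path).read_text()
    times: set[float] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        for token in line.replace(",", " ").split():
            try:
                value = float(token)
            except ValueError as e:
                raise FormatError(
                    f"non-numeric marker '{token}' on line {lineno}"
                ) from e
            if value < 0:
                raise FormatError(f"negative marker time {value} on line {lineno}")
            times.add(value)
    return sorted(times)


def read_wav(path, strict_mono: bool = True) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip` normalised to [-1, 1].

    Multi-channel input raises :class:`FormatError` in strict mode, otherwise
    channels are averaged with a logged warning.
    """
    try:
        fs, data = wavfile.read(str(path))
    except ValueError as e:
        raise FormatError(f"cannot read WAV {path}: {e}") from e
    if data.ndim == 2:
        if strict_mono:
            raise FormatError(
                f"{path} has {data.shape[1]} channels; mono required in strict mode"
            )
        log.warning("%s has %d channels; down-mixing to mono", path, data.shape[1])
        data = data.mean(axis=1)
    if data.dtype == np.uint8:          # 8-bit PCM is unsigned, midpoint 128
        samples = (data.astype(float) - 128.0) / 128.0
    elif data.dtype == np.int16:
        samples = data.astype(float) / 32768.0
    elif data.dtype == np.int32:        # covers 24-bit PCM (left-justified)
        samples = data.astype(float) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = np.clip(data.astype(float), -1.0, 1.0)
    else:
        raise FormatError(f"unsupported WAV sample format {data.dtype}")
    return AudioClip(samples=samples, fs=float(fs))


def write_wav(clip: AudioClip, path, bit_depth: int = 16) -> None:
    """Write an :class:`AudioClip` as PCM WAV (16-bit by default)."""
    if bit_depth != 16:
        raise FormatError(f"only 16-bit PCM output is supported, got {bit_depth}")
    # scale by 32768 (the read-side divisor) so write/read round-trips are
    # idempotent; +1.0 saturates at 32767, one LSB below full scale
    scaled = np.round(np.clip(clip.samples, -1.0, 1.0) * 32768.0)
    wavfile.write(
        str(path), int(round(clip.fs)),
        np.clip(scaled, -32768, 32767).astype(np.int16),
    )


def write_events(events, path) -> None:
    """Serialise movement/beat events as a JSON array; round-trips losslessly."""
    # imported lazily to keep the IO layer free of detector dependencies
    from .fm_detection import MovementEvent
    from .fpcg_chain import BeatEvent

    items = []
    for ev in events:
        if isinstance(ev, MovementEvent):
            items.append(
                {"kind": "fm", "onset": ev.onset, "time": ev.peak_time, "peak_amp": ev.peak_amp}
            )
        elif isinstance(ev, BeatEvent):
            items.append({"kind": "beat", "time": ev.time, "peak_amp": ev.envelope_peak})
        else:
            raise FormatError(f"cannot serialise event of type {type(ev).__name__}")
    Path(path).write_text(json.dumps(items, indent=None, separators=(",", ":")))


def read_events(path) -> list:
    """Read back a JSON event array written by :func:`write_events`."""
    from .fm_detection import MovementEvent
    from .fpcg_chain import BeatEvent

    try:
        items = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"cannot parse event JSON {path}: {e}") from e
    events = []
    for item in items:
        kind = item.get("kind")
        if kind == "fm":
            events.append(
                MovementEvent(onset=item["onset"], peak_time=item["time"], peak_amp=item["peak_amp"])
            )
        elif kind == "beat":
            events.append(BeatEvent(time=item["time"], envelope_peak=item["peak_amp"]))
        else:
            raise FormatError(f"unknown event kind {kind!r}")
    return events


def duration_minutes(n_samples: int, fs: float, ndigits: int = 2) -> float:
    """Recording duration in minutes, n / (60 fs), rounded to ``ndigits``."""
    return round(n_samples / (60.0 * fs), ndigits)


@dataclass(frozen=True)
class RecordStats:
    """Per-axis summary statistics of a triaxial record."""

    mean: dict
    sd: dict
    n_samples: int
    duration_min: float


def record_stats(rec: TriaxialRecord, ddof: int = 0) -> RecordStats:
    """Per-axis mean and SD, sample count, and duration in minutes (2 d.p.).

    The SD is the population SD by default (``ddof=0``); pass ``ddof=1`` for
    the sample convention.
    """
    axes = {"x": rec.ax, "y": rec.ay, "z": rec.az}
    return RecordStats(
        mean={k: float(np.mean(v)) for k, v in axes.items()},
        sd={k: float(np.std(v, ddof=ddof)) for k, v in axes.items()},
        n_samples=len(rec),
        duration_min=duration_minutes(len(rec), rec.fs),
    )
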