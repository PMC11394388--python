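"""Core signal containers.

Three small containers carry every signal the package touches:

* :class:`TriaxialRecord` — an abdominal accelerometer recording (X/Y/Z in g)
  with optional maternal push-button perception markers,
* :class:`SampleSeries` — a generic uniformly sampled 1-D signal with a units
  tag (fused acceleration magnitude, detrended signal, front-end voltages),
* :class:`AudioClip` — mono heart-sound audio normalised to [-1, 1].

All containers validate their invariants on construction so downstream code
can assume a uniform, strictly increasing time grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, SamplingError

#: tolerance (seconds) on deviation of the time grid from 1/fs spacing
TIME_GRID_TOL = 1e-6


@dataclass(frozen=True)
class SampleSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        Samples, converted to a float64 array.
    fs : float
        Sampling frequency in Hz (> 0).
    units : str
        Free-form units tag, e.g. ``"g"``, ``"V"``, ``"dimensionless"``.
    """

    values: np.ndarray
    fs: float
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise FormatError("SampleSeries requires a non-empty 1-D array")
        if not self.fs > 0:
            raise SamplingError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n / fs)."""
        return self.values.size / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds, starting at 0."""
        return np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray, units: str | None = None) -> "SampleSeries":
        return SampleSeries(values, self.fs, self.units if units is None else units)


@dataclass(frozen=True)
class TriaxialRecord:
    """A triaxial accelerometer recording on a uniform time grid.

    ``ax``/``ay``/``az`` are per-axis accelerations, nominally in g once
    ``units_scale`` has been applied by the reader.  ``markers`` are maternal
    perception button-press times (seconds on the same clock as ``t``).
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    markers: tuple[float, ...] = field(default_factory=tuple)
    units_scale: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        axes = [np.asarray(a, dtype=float) for a in (self.ax, self.ay, self.az)]
        if t.size < 1:
            raise FormatError("record must contain at least one sample")
        if any(a.shape != t.shape for a in axes):
            raise FormatError("t, ax, ay, az must all have equal length")
        if not self.fs > 0:
            raise SamplingError(f"fs must be positive, got {self.fs}")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise SamplingError("time column is not strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > TIME_GRID_TOL:
                raise SamplingError(
                    f"time grid is not uniform at fs={self.fs} Hz "
                    f"(max deviation {np.max(np.abs(dt - 1.0 / self.fs)):.3g} s)"
                )
        markers = tuple(sorted(float(m) for m in self.markers))
        for m in markers:
            if not (t[0] <= m <= t[-1]):
                raise FormatError(
                    f"marker at {m} s lies outside the record span "
                    f"[{t[0]}, {t[-1]}] s"
                )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ax", axes[0])
        object.__setattr__(self, "ay", axes[1])
        object.__setattr__(self, "az", axes[2])
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "units_scale", float(self.units_scale))

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n / fs)."""
        return self.t.size / self.fs

    def with_markers(self, markers) -> "TriaxialRecord":
        """Return a copy with the given maternal-perception marker times.

        Raises :class:`FormatError` if any marker falls outside the record.
        """
        return replace(self, markers=tuple(markers))


@dataclass(frozen=True)
class AudioClip:
    """Mono audio with samples normalised to [-1, 1]."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size < 1:
            raise FormatError("AudioClip requires non-empty mono samples")
        if not self.fs > 0:
            raise SamplingError(f"fs must be positive, got {self.fs}")
        if np.max(np.abs(s)) > 1.0 + 1e-9:
            raise FormatError("AudioClip samples must lie within [-1, 1]")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def as_series(self, units: str = "V") -> SampleSeries:
        """View the clip as a :class:`SampleSeries` (amplitudes taken as volts)."""
        return SampleSeries(self.samples, self.fs, units)
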