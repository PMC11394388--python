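"""Fetal-movement detection from abdominal accelerometry.

The pipeline mirrors a streaming wearable: the three accelerometer axes are
fused into a single magnitude signal

    A_xyz[n] = sqrt(ax[n]^2 + ay[n]^2 + az[n]^2),

the fused signal is detrended with a first-order DC-blocking IIR filter

    H(z) = (1/T) * (1 - z^-1) / (1 - p z^-1),      p = 0.99 by default,

whose zero at z = 1 removes gravity and slow maternal respiration drift while
passing kick transients, and fetal movements are counted as contiguous
excursions of |x_filt| above an amplitude threshold (0.002 g by default).
Excursions closer than a merge window are treated as one movement, matching
the physiology of a single kick producing several near-simultaneous peaks.

Detected movements can be validated against maternal perception button
presses via greedy one-to-one matching within a time window.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .signals import SampleSeries, TriaxialRecord


@dataclass(frozen=True)
class DetrendFilterSpec:
    """DC-blocking detrend filter parameters.

    ``pole`` is the feedback pole p in (0, 1): closer to 1 means a narrower
    stop-band around DC (slower drift removal, better transient fidelity).
    ``scale_T`` is the output scale divisor T; the default 1.0 keeps the
    output on the same g scale as the input so the movement threshold applies
    directly.  Set ``scale_T = 1/fs`` for a discrete-derivative reading.
    """

    pole: float = 0.99
    scale_T: float = 1.0
    causal: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.pole < 1.0:
            raise ConfigError(f"pole must be in (0, 1), got {self.pole}")
        if not self.scale_T > 0:
            raise ConfigError(f"scale_T must be positive, got {self.scale_T}")


@dataclass(frozen=True)
class PeakDetectorConfig:
    """Movement peak-detection parameters (threshold in g)."""

    threshold: float = 0.002
    min_event_gap: float = 1.0
    min_event_duration: float = 0.02
    settle_time: float = 2.0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ConfigError(f"threshold must be positive, got {self.threshold}")
        if self.min_event_gap < 0:
            raise ConfigError(f"min_event_gap must be >= 0, got {self.min_event_gap}")
        if self.min_event_duration < 0:
            raise ConfigError(
                f"min_event_duration must be >= 0, got {self.min_event_duration}"
            )
        if self.settle_time < 0:
            raise ConfigError(f"settle_time must be >= 0, got {self.settle_time}")


@dataclass(frozen=True)
class MovementEvent:
    """One detected fetal movement: a suprathreshold excursion."""

    onset: float
    peak_time: float
    peak_amp: float


@dataclass(frozen=True)
class FmReport:
    """Movement counts compared against maternal perception."""

    fm_count: int
    events: tuple = field(default_factory=tuple)
    mp_count: int = 0
    matched: int = 0
    false_negatives: int = 0


def fuse_axes(rec: TriaxialRecord) -> SampleSeries:
    """Euclidean norm of the three axes, sample by sample.

    Invariant to axis permutations and per-axis sign flips.
    """
    fused = np.sqrt(rec.ax**2 + rec.ay**2 + rec.az**2)
    return SampleSeries(fused, rec.fs, units="g")


def detrend_filter(x: SampleSeries, spec: DetrendFilterSpec | None = None) -> SampleSeries:
    """Apply the DC-blocking IIR detrend filter.

    Causal form with zero initial state:

        y[n] = p * y[n-1] + (x[n] - x[n-1]) / T,   x[-1] = y[-1] = 0.

    DC gain is exactly zero, so constant inputs decay geometrically with
    ratio ``p``.  With ``causal=False`` the filter is applied forward and
    backward (zero phase), useful offline but not on a streaming device.
    """
    spec = spec or DetrendFilterSpec()
    b = np.array([1.0, -1.0]) / spec.scale_T
    a = np.array([1.0, -spec.pole])
    if spec.causal:
        y = sps.lfilter(b, a, x.values)
    else:
        y = sps.filtfilt(b, a, x.values)
    return x.with_values(y)


def detect_fm(
    xfilt: SampleSeries, cfg: PeakDetectorConfig | None = None
) -> list[MovementEvent]:
    """Detect fetal movements as suprathreshold excursions of |x_filt|.

    Contiguous runs of samples with ``|x| > threshold`` form candidate
    events; runs separated by less than ``min_event_gap`` seconds are merged
    (one kick can ring for several cycles); runs shorter than
    ``min_event_duration`` are dropped.  The first ``settle_time`` seconds
    are ignored: the causal DC-blocking filter starts from zero state, so
    the gravity baseline enters as a step whose decay would otherwise read
    as a spurious movement at power-on.  Events are returned sorted by onset.
    """
    cfg = cfg or PeakDetectorConfig()
    mag = np.abs(xfilt.values)
    mask = mag > cfg.threshold
    settle = int(round(cfg.settle_time * xfilt.fs))
    if settle > 0:
        mask[:settle] = False
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
    starts, ends = edges[::2], edges[1::2]  # ends exclusive
    if starts.size == 0:
        return []

    # merge runs whose silent gap is shorter than min_event_gap; track the
    # total suprathreshold time so isolated noise spikes bridged by the
    # merge window cannot masquerade as a sustained movement
    gap_samples = cfg.min_event_gap * xfilt.fs
    merged: list[list[int]] = [[int(starts[0]), int(ends[0]), int(ends[0] - starts[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap_samples:
            merged[-1][1] = int(e)
            merged[-1][2] += int(e - s)
        else:
            merged.append([int(s), int(e), int(e - s)])

    fs = xfilt.fs
    events = []
    for s, e, above in merged:
        if above / fs < cfg.min_event_duration:
            continue
        peak_idx = s + int(np.argmax(mag[s:e]))
        events.append(
            MovementEvent(
                onset=s / fs,
                peak_time=peak_idx / fs,
                peak_amp=float(mag[peak_idx]),
            )
        )
    return events


def count_fm(events) -> int:
    """The movement count P_FM: the number of detected events."""
    return len(events)


def compare_with_mp(
    events, markers, match_window: float = 5.0
) -> FmReport:
    """Compare detected movements with maternal-perception markers.

    Each marker is greedily matched to the nearest unmatched event whose
    peak time lies within ``±match_window`` seconds.  ``false_negatives`` is
    the number of maternal perceptions with no matching detection — the
    quantity the device must drive to zero.
    """
    if match_window < 0:
        raise ConfigError(f"match_window must be >= 0, got {match_window}")
    events = sorted(events, key=lambda e: e.peak_time)
    markers = sorted(float(m) for m in markers)
    unmatched = list(range(len(events)))
    matched = 0
    for m in markers:
        if not unmatched:
            break
        best = min(unmatched, key=lambda i: abs(events[i].peak_time - m))
        if abs(events[best].peak_time - m) <= match_window:
            unmatched.remove(best)
            matched += 1
    return FmReport(
        fm_count=len(events),
        events=tuple(events),
        mp_count=len(markers),
        matched=matched,
        false_negatives=len(markers) - matched,
    )


def run_fm_pipeline(
    rec: TriaxialRecord,
    detrend: DetrendFilterSpec | None = None,
    peaks: PeakDetectorConfig | None = None,
    match_window: float = 5.0,
) -> FmReport:
    """Fuse, detrend, detect, and (if markers exist) compare with perception."""
    xfilt = detrend_filter(fuse_axes(rec), detrend)
    events = detect_fm(xfilt, peaks)
    if rec.markers:
        return compare_with_mp(events, rec.markers, match_window)
    return FmReport(fm_count=len(events), events=tuple(events))
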