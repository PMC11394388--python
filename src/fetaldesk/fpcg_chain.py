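"""Phonocardiography acquisition chain and fetal-heart-rate estimation.

A discrete-time model of the analog acquisition board: a preamplifier
(closed-loop voltage gain 2) followed by a fourth-order low-pass Butterworth
filter with cutoff 200 Hz, realised as two cascaded biquad sections the way
the hardware cascades two second-order Sallen-Key stages.  The board's
op-amp also has a 60 dB open gain; an explicit open-gain mode reproduces
that regime as a pure mathematical scaling (no supply-rail clipping is
modelled).

Heart sounds leaving the front end are reduced to beats with a moving-RMS
envelope and a relative threshold, with a 300 ms refractory period so the
two components of one heart sound (S1/S2) are not double-counted.  FHR is
the beat count in a tumbling 6-second window multiplied by 10 — the
count-times-ten estimator quantises FHR to multiples of 10 bpm.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, SamplingError
from .signals import SampleSeries

#: FHR analysis window length in seconds; count x 10 gives bpm.
FHR_WINDOW_S = 6.0
FHR_COUNT_FACTOR = 10


@dataclass(frozen=True)
class FrontEndSpec:
    """Acquisition-board model parameters."""

    preamp_gain: float = 2.0
    open_gain_db: float = 60.0
    cutoff_hz: float = 200.0
    order: int = 4
    sim_fs: float = 8000.0

    def __post_init__(self) -> None:
        if not self.preamp_gain > 0:
            raise ConfigError(f"preamp_gain must be positive, got {self.preamp_gain}")
        if not 0 < self.cutoff_hz < self.sim_fs / 2:
            raise ConfigError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, {self.sim_fs / 2}) Hz"
            )
        if self.order < 2 or self.order % 2:
            raise ConfigError(f"order must be even and >= 2, got {self.order}")


@dataclass(frozen=True)
class BeatDetectorConfig:
    """Envelope beat-detector parameters (times in seconds)."""

    refractory: float = 0.3
    envelope_window: float = 0.05
    rel_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.refractory > 0:
            raise ConfigError(f"refractory must be positive, got {self.refractory}")
        if not 0.0 < self.rel_threshold < 1.0:
            raise ConfigError(
                f"rel_threshold must be in (0, 1), got {self.rel_threshold}"
            )
        if not self.envelope_window > 0:
            raise ConfigError(
                f"envelope_window must be positive, got {self.envelope_window}"
            )


@dataclass(frozen=True)
class BeatEvent:
    """One detected heart beat (envelope threshold crossing)."""

    time: float
    envelope_peak: float


@dataclass(frozen=True)
class FhrEstimate:
    """FHR for one 6-s window: bpm = beat_count x 10."""

    bpm: int
    window_start: float
    window_end: float
    beat_count: int
    complete: bool = True


def apply_gain(x: SampleSeries, gain: float | None = None, *, gain_db: float | None = None) -> SampleSeries:
    """Scale a signal by a linear gain or a dB gain (10^(dB/20))."""
    if (gain is None) == (gain_db is None):
        raise ConfigError("specify exactly one of gain or gain_db")
    g = 10.0 ** (gain_db / 20.0) if gain_db is not None else float(gain)
    if not np.isfinite(g):
        raise ConfigError(f"gain must be finite, got {g}")
    return x.with_values(x.values * g)


def design_butterworth_lpf(spec: FrontEndSpec | None = None) -> np.ndarray:
    """Discrete Butterworth low-pass as cascaded second-order sections.

    Bilinear transform with prewarping at the cutoff, so the -3 dB point
    lands exactly on ``cutoff_hz``; DC gain is exactly 1.  For order 4 the
    result is two biquads, mirroring the two Sallen-Key hardware stages.
    """
    spec = spec or FrontEndSpec()
    return sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.sim_fs, output="sos")


def butterworth_ba(spec: FrontEndSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """The same filter as a single direct-form transfer function (b, a)."""
    spec = spec or FrontEndSpec()
    return sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.sim_fs, output="ba")


def frequency_response(sos: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Complex response of an SOS cascade at the given frequencies (Hz)."""
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    return h


def minus_3db_frequency(
    sos: np.ndarray, fs: float, n_grid: int = 200_001
) -> float:
    """Locate the -3 dB crossing of an SOS low-pass relative to its DC gain."""
    freqs = np.linspace(0.0, fs / 2.0, n_grid)
    mag = np.abs(frequency_response(sos, fs, freqs))
    target = mag[0] / np.sqrt(2.0)
    below = np.flatnonzero(mag < target)
    if below.size == 0:
        raise ValueError("response never falls 3 dB below DC gain")
    i = below[0]
    # linear interpolation between the straddling grid points
    f0, f1 = freqs[i - 1], freqs[i]
    m0, m1 = mag[i - 1], mag[i]
    return float(f0 + (target - m0) * (f1 - f0) / (m1 - m0))


def run_frontend(
    x: SampleSeries,
    spec: FrontEndSpec | None = None,
    mode: str = "normal",
    on_fs_mismatch: str = "error",
) -> SampleSeries:
    """Run the full acquisition chain: gain stage then causal low-pass.

    ``mode="normal"`` applies the closed-loop preamp gain; ``mode="open_gain"``
    applies the op-amp's open gain in dB instead (a simulation-only regime).
    Input sampled at a rate other than ``sim_fs`` is an error unless
    ``on_fs_mismatch="resample"``.
    """
    spec = spec or FrontEndSpec()
    if abs(x.fs - spec.sim_fs) > 1e-9:
        if on_fs_mismatch == "resample":
            up, down = int(round(spec.sim_fs)), int(round(x.fs))
            x = SampleSeries(sps.resample_poly(x.values, up, down), spec.sim_fs, x.units)
        else:
            raise SamplingError(
                f"input fs {x.fs} Hz != front-end sim_fs {spec.sim_fs} Hz"
            )
    if mode == "normal":
        y = apply_gain(x, spec.preamp_gain)
    elif mode == "open_gain":
        y = apply_gain(x, gain_db=spec.open_gain_db)
    else:
        raise ConfigError(f"unknown front-end mode {mode!r}")
    sos = design_butterworth_lpf(spec)
    return y.with_values(sps.sosfilt(sos, y.values))


def envelope_rms(x: SampleSeries, window: float) -> SampleSeries:
    """Moving-RMS amplitude envelope over ``window`` seconds (centred)."""
    n = max(1, int(round(window * x.fs)))
    kernel = np.ones(n) / n
    power = np.convolve(x.values**2, kernel, mode="same")
    return x.with_values(np.sqrt(np.maximum(power, 0.0)))


def detect_beats(
    x: SampleSeries, cfg: BeatDetectorConfig | None = None
) -> list[BeatEvent]:
    """Detect beats as envelope upward crossings with a refractory period.

    The threshold is ``rel_threshold`` times the envelope maximum, making
    detection invariant to overall signal scale.  A crossing within
    ``refractory`` seconds of the previous accepted beat is suppressed —
    the mechanism that prevents double-counting one heart sound.  Silence
    yields an empty list.
    """
    cfg = cfg or BeatDetectorConfig()
    env = envelope_rms(x, cfg.envelope_window).values
    peak = env.max()
    if peak <= 0:
        return []
    thr = cfg.rel_threshold * peak
    above = env >= thr
    crossings = np.flatnonzero(np.diff(np.r_[0, above.astype(np.int8)]) == 1)
    beats: list[BeatEvent] = []
    refractory_samples = cfg.refractory * x.fs
    last = -np.inf
    for i in crossings:
        if i - last < refractory_samples:
            continue
        last = i
        span_end = min(len(env), i + int(refractory_samples))
        beats.append(
            BeatEvent(time=i / x.fs, envelope_peak=float(env[i:span_end].max()))
        )
    return beats


def estimate_fhr(
    beats,
    t0: float = 0.0,
    duration: float | None = None,
    window: float = FHR_WINDOW_S,
) -> list[FhrEstimate]:
    """Count-times-ten FHR over tumbling windows starting at ``t0``.

    Each window of ``window`` seconds contributes ``bpm = count * 10``.
    With ``duration`` given, a final window extending past ``t0 + duration``
    is flagged incomplete.  No beats at all yields an empty list unless a
    duration is given, in which case zero-count windows are reported
    (bpm = 0 signals loss of heart-sound contact, treated downstream as
    distress).
    """
    times = np.asarray([b.time if isinstance(b, BeatEvent) else float(b) for b in beats])
    times = np.sort(times)
    if duration is None:
        if times.size == 0:
            return []
        duration = float(times[-1]) - t0 + 1e-12
    n_windows = max(1, int(np.ceil(duration / window - 1e-12)))
    estimates = []
    for k in range(n_windows):
        start = t0 + k * window
        end = start + window
        count = int(np.sum((times >= start) & (times < end)))
        estimates.append(
            FhrEstimate(
                bpm=count * FHR_COUNT_FACTOR,
                window_start=start,
                window_end=end,
                beat_count=count,
                complete=end <= t0 + duration + 1e-12,
            )
        )
    return estimates
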