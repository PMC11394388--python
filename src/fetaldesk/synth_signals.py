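"""Synthetic signal generators with ground truth.

Everything the pipeline consumes can be generated here so the whole tool is
testable without external recordings:

* accelerometer records — a gravity baseline plus slow maternal respiration
  drift, sparse fetal-kick transients (damped sinusoids, amplitudes drawn
  from the 0.015–0.06 g range typical of perceived kicks), optional
  maternal-laughter bursts at kick-like amplitude, and Gaussian sensor
  noise; maternal-perception markers are placed at kick times plus a
  reaction latency,
* phonocardiography audio — a band-limited damped wavelet per heart beat at
  a configurable bpm, plus noise,
* full monitoring scenarios — paired signals, a scripted FHR timeline, and
  the expected state/alert sequence for each alarm-system test case
  (normal, low movement, tachycardic and bradycardic distress).

All generators are seeded and bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .signals import AudioClip, TriaxialRecord
from . import distress_logic as dl
from .distress_logic import DistressThresholds, FetalMonitor, State

SCENARIO_NAMES = ("normal", "low_fm", "distress_tachy", "distress_brady")


@dataclass(frozen=True)
class SynthAccelConfig:
    """Accelerometer generator parameters (amplitudes in g, times in s)."""

    fs: float = 500.0
    duration: float = 60.0
    gravity_baseline: tuple[float, float, float] = (0.0, 0.0, 1.0)
    kick_times: tuple[float, ...] | None = None
    kick_rate: float | None = None  # kicks per minute for random placement
    kick_amp: float | None = None  # None: uniform in [0.015, 0.06] per kick
    kick_shape: float = 0.2  # damped-sinusoid width (s)
    kick_freq_hz: float = 15.0
    respiration_amp: float = 0.002  # quasi-static breathing tilt, ~2 mg
    respiration_hz: float = 0.25
    min_kick_separation: float = 2.0  # distinctly perceived movements
    laughter_times: tuple[float, ...] = ()
    laughter_amp: float = 0.02
    laughter_duration: float = 2.0
    noise_sd: float = 0.0004  # ADXL355-class noise floor at ~250 Hz bandwidth
    marker_latency: float = 0.5
    place_markers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kick_shape", "fs", "duration"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("respiration_amp", "laughter_amp", "noise_sd", "marker_latency"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.kick_amp is not None and self.kick_amp < 0:
            raise ConfigError("kick_amp must be >= 0")
        for t in (self.kick_times or ()) + tuple(self.laughter_times):
            if not 0 <= t <= self.duration:
                raise ConfigError(f"scheduled event at {t} s exceeds duration {self.duration} s")


#: kick-amplitude range (g) of maternally perceptible movements
KICK_AMP_RANGE = (0.015, 0.06)


@dataclass(frozen=True)
class SynthPcgConfig:
    """Phonocardiography generator parameters (amplitudes in volts)."""

    fs: float = 8000.0
    duration: float = 6.0
    bpm: float = 140.0
    beat_band: tuple[float, float] = (20.0, 200.0)
    beat_freq_hz: float = 100.0  # wavelet carrier, inside beat_band
    beat_width: float = 0.05
    beat_amp: float = 0.0025
    noise_sd: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bpm > 0:
            raise ConfigError(f"bpm must be positive, got {self.bpm}")
        if not 0 < self.beat_band[0] < self.beat_band[1] < self.fs / 2:
            raise ConfigError(f"beat_band {self.beat_band} must lie within (0, fs/2)")
        if not self.beat_band[0] <= self.beat_freq_hz <= self.beat_band[1]:
            raise ConfigError("beat_freq_hz must lie inside beat_band")
        if 60.0 / self.bpm < 1.5 * self.beat_width:
            raise ConfigError(
                f"bpm {self.bpm} implies a beat interval shorter than the wavelet"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected."""

    kick_times: tuple[float, ...] = ()
    laughter_times: tuple[float, ...] = ()
    beat_times: tuple[float, ...] = ()
    true_bpm: float | None = None


def _damped_sinusoid(fs: float, width: float, freq: float) -> np.ndarray:
    """Unit-peak damped sinusoid of ~2x width support."""
    n = max(2, int(round(2.0 * width * fs)))
    tt = np.arange(n) / fs
    w = np.sin(2 * np.pi * freq * tt) * np.exp(-tt / (width / 4.0))
    return w / np.max(np.abs(w))


def _add_at(target: np.ndarray, waveform: np.ndarray, start_idx: int) -> None:
    end = min(target.size, start_idx + waveform.size)
    if end > start_idx >= 0:
        target[start_idx:end] += waveform[: end - start_idx]


def gen_accel(cfg: SynthAccelConfig | None = None) -> tuple[TriaxialRecord, GroundTruth]:
    """Generate a triaxial record with known kick times.

    Kicks ride mainly on the axis normal to the abdomen (z here, aligned
    with the gravity baseline) with a small random leakage onto x and y, so
    the fused magnitude carries the kick at its nominal amplitude.
    """
    cfg = cfg or SynthAccelConfig()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    bx, by, bz = cfg.gravity_baseline
    x = np.full(n, bx)
    y = np.full(n, by)
    z = np.full(n, bz)

    if cfg.respiration_amp > 0:
        z = z + cfg.respiration_amp * np.sin(2 * np.pi * cfg.respiration_hz * t)

    if cfg.kick_times is not None:
        kick_times = tuple(float(k) for k in cfg.kick_times)
    elif cfg.kick_rate:
        n_kicks = rng.poisson(cfg.kick_rate * cfg.duration / 60.0)
        # keep kicks clear of the record edges so markers stay in range,
        # and apart from each other so each is a distinct perceived movement
        # lower edge stays clear of the detrend filter's power-on warm-up
        lo = 3.0
        hi = max(lo, cfg.duration - cfg.marker_latency - 1.0)
        placed: list[float] = []
        attempts = 0
        while len(placed) < n_kicks and attempts < 10_000:
            candidate = float(rng.uniform(lo, hi))
            if all(abs(candidate - p) >= cfg.min_kick_separation for p in placed):
                placed.append(candidate)
            attempts += 1
        kick_times = tuple(sorted(placed))
    else:
        kick_times = ()

    kick_wave = _damped_sinusoid(cfg.fs, cfg.kick_shape, cfg.kick_freq_hz)
    for kt in kick_times:
        amp = cfg.kick_amp if cfg.kick_amp is not None else rng.uniform(*KICK_AMP_RANGE)
        idx = int(round(kt * cfg.fs))
        _add_at(z, amp * kick_wave, idx)
        _add_at(x, 0.2 * amp * rng.choice([-1.0, 1.0]) * kick_wave, idx)
        _add_at(y, 0.2 * amp * rng.choice([-1.0, 1.0]) * kick_wave, idx)

    if cfg.laughter_times and cfg.laughter_amp > 0:
        # quasi-periodic chuckle: 6 Hz carrier under a Hann envelope
        m = int(round(cfg.laughter_duration * cfg.fs))
        tt = np.arange(m) / cfg.fs
        burst = (
            cfg.laughter_amp
            * np.sin(2 * np.pi * 6.0 * tt)
            * np.hanning(m)
        )
        for lt in cfg.laughter_times:
            _add_at(z, burst, int(round(lt * cfg.fs)))

    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, n)
        y = y + rng.normal(0.0, cfg.noise_sd, n)
        z = z + rng.normal(0.0, cfg.noise_sd, n)

    markers: tuple[float, ...] = ()
    if cfg.place_markers and kick_times:
        markers = tuple(
            min(kt + cfg.marker_latency, t[-1]) for kt in kick_times
        )

    rec = TriaxialRecord(t=t, ax=x, ay=y, az=z, fs=cfg.fs, markers=markers)
    return rec, GroundTruth(kick_times=kick_times, laughter_times=tuple(cfg.laughter_times))


def gen_pcg(cfg: SynthPcgConfig | None = None) -> tuple[AudioClip, GroundTruth]:
    """Generate heart-sound audio: one damped wavelet per beat plus noise."""
    cfg = cfg or SynthPcgConfig()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    samples = np.zeros(n)
    period = 60.0 / cfg.bpm
    beat_times = []
    k = 0
    while k * period < cfg.duration - 1e-12:
        beat_times.append(k * period)
        k += 1
    wave = cfg.beat_amp * _damped_sinusoid(cfg.fs, cfg.beat_width, cfg.beat_freq_hz)
    for bt in beat_times:
        _add_at(samples, wave, int(round(bt * cfg.fs)))
    if cfg.noise_sd > 0:
        samples = samples + rng.normal(0.0, cfg.noise_sd, n)
    samples = np.clip(samples, -1.0, 1.0)
    clip = AudioClip(samples=samples, fs=cfg.fs)
    return clip, GroundTruth(beat_times=tuple(beat_times), true_bpm=cfg.bpm)


@dataclass(frozen=True)
class Scenario:
    """One alarm-system test case: signals, scripted FHR timeline, expectations."""

    name: str
    accel: TriaxialRecord
    pcg: AudioClip
    truth_accel: GroundTruth
    truth_pcg: GroundTruth
    fhr_bpm: float  # scripted FHR driving the state machine replay
    timeline_duration: float
    expected_final_state: State
    expected_led: dl.Led
    expected_display: str
    expected_alerts: tuple[tuple[str, str], ...]  # (recipient, text)


def gen_scenario(name: str, seed: int = 0) -> Scenario:
    """Build one of the four preset alarm-system scenarios.

    The signal pair exercises the detection chain; the scripted FHR value
    drives the state-machine replay the same way the hardware test injected
    FHR with a potentiometer.
    """
    if name not in SCENARIO_NAMES:
        raise ConfigError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    presets = {
        "normal": dict(fhr=140.0, kicks=True, timeline=60.0,
                       state=State.NORMAL, alerts=()),
        "low_fm": dict(fhr=140.0, kicks=False, timeline=4800.0,
                       state=State.MONITOR,
                       alerts=(("proxy", dl.MONITOR_ALERT_TEXT),)),
        "distress_tachy": dict(fhr=162.0, kicks=True, timeline=60.0,
                               state=State.DISTRESS,
                               alerts=(("proxy", dl.DISTRESS_ALERT_TEXT),
                                       ("ems", dl.DISTRESS_ALERT_TEXT))),
        "distress_brady": dict(fhr=116.0, kicks=True, timeline=60.0,
                               state=State.DISTRESS,
                               alerts=(("proxy", dl.DISTRESS_ALERT_TEXT),
                                       ("ems", dl.DISTRESS_ALERT_TEXT))),
    }
    p = presets[name]
    kick_times = (8.0, 20.0, 33.0, 47.0) if p["kicks"] else None
    acc_cfg = SynthAccelConfig(
        duration=60.0,
        kick_times=kick_times,
        seed=seed,
    )
    accel, truth_a = gen_accel(acc_cfg)
    pcg_cfg = SynthPcgConfig(duration=12.0, bpm=p["fhr"], seed=seed + 1)
    pcg, truth_p = gen_pcg(pcg_cfg)
    return Scenario(
        name=name,
        accel=accel,
        pcg=pcg,
        truth_accel=truth_a,
        truth_pcg=truth_p,
        fhr_bpm=p["fhr"],
        timeline_duration=p["timeline"],
        expected_final_state=p["state"],
        expected_led=dl.STATE_LED[p["state"]],
        expected_display=dl.STATE_DISPLAY[p["state"]],
        expected_alerts=p["alerts"],
    )


def run_scenario(
    scenario: Scenario,
    thresholds: DistressThresholds | None = None,
    cooldown: float = 600.0,
    window: float = 6.0,
):
    """Replay a scenario through the state machine.

    Movement events follow the generated kick schedule, repeated each
    accelerometer-record length across the timeline; FHR windows carry the
    scripted bpm.  Returns the status sequence and the full alert log.
    """
    monitor = FetalMonitor(thresholds=thresholds, cooldown=cooldown)
    statuses, alerts = [], []
    status, msgs = monitor.step(0.0)  # power-on: INITIALISING
    statuses.append(status)
    alerts.extend(msgs)
    rec_len = scenario.accel.duration
    kicks = scenario.truth_accel.kick_times
    now = window
    while now <= scenario.timeline_duration + 1e-9:
        win_start = now - window
        events = []
        if kicks:
            base = np.floor(win_start / rec_len) * rec_len
            for offset in (base, base + rec_len):
                for kt in kicks:
                    t = offset + kt
                    if win_start <= t < now:
                        events.append(t)
        status, msgs = monitor.step(now, fhr=scenario.fhr_bpm, events=events)
        statuses.append(status)
        alerts.extend(msgs)
        now += window
    return statuses, alerts
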