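"""Rule-based fetal-status classification and alarm state machine.

The monitor maps the FHR stream and the fetal-movement event stream onto
four states with fixed LED colours and display strings:

=============  ======  ============================
state          LED     display
=============  ======  ============================
INITIALISING   white   "Fetal Monitor Initialising…"
NORMAL         green   "Normal"
MONITOR        yellow  "Monitor"
DISTRESS       red     "! Fetal Distress!"
=============  ======  ============================

Classification rules (strict inequalities at the band edges):

* DISTRESS  iff FHR < 120 bpm or FHR > 160 bpm,
* MONITOR   iff FHR in band and no movement for more than 4500 s
  (the upper bound of a normal fetal rest period),
* NORMAL    otherwise.

On a transition into MONITOR the proxy contact is texted
"Warning: Low Fetal Movement count"; on a transition into DISTRESS both the
proxy and emergency services receive "EMERGENCY: Fetal Distress Detected!".
Repeats of the same state re-alert only after a cooldown (default 600 s)
so a persistent condition does not flood the recipient.  FHR = 0 (no beats
detected at all) classifies as distress and is additionally flagged as
signal loss.  The GSM/LED/LCD hardware is abstracted behind a pluggable
notifier; delivery failures are retried and never crash the monitor loop.
"""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .errors import ConfigError, SequencingError

log = logging.getLogger(__name__)


class State(str, Enum):
    INITIALISING = "INITIALISING"
    NORMAL = "NORMAL"
    MONITOR = "MONITOR"
    DISTRESS = "DISTRESS"


class Led(str, Enum):
    WHITE = "WHITE"
    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"


STATE_LED = {
    State.INITIALISING: Led.WHITE,
    State.NORMAL: Led.GREEN,
    State.MONITOR: Led.YELLOW,
    State.DISTRESS: Led.RED,
}

STATE_DISPLAY = {
    State.INITIALISING: "Fetal Monitor Initialising…",
    State.NORMAL: "Normal",
    State.MONITOR: "Monitor",
    State.DISTRESS: "! Fetal Distress!",
}

MONITOR_ALERT_TEXT = "Warning: Low Fetal Movement count"
DISTRESS_ALERT_TEXT = "EMERGENCY: Fetal Distress Detected!"


@dataclass(frozen=True)
class DistressThresholds:
    """Normal FHR band (bpm) and the no-movement timeout (seconds)."""

    fhr_low: float = 120.0
    fhr_high: float = 160.0
    no_fm_timeout: float = 4500.0

    def __post_init__(self) -> None:
        if not self.fhr_low < self.fhr_high:
            raise ConfigError(
                f"fhr_low ({self.fhr_low}) must be below fhr_high ({self.fhr_high})"
            )
        if not self.no_fm_timeout > 0:
            raise ConfigError(f"no_fm_timeout must be positive, got {self.no_fm_timeout}")


@dataclass(frozen=True)
class FetalStatus:
    state: State
    led: Led
    display: str
    since: float
    signal_loss: bool = False


@dataclass(frozen=True)
class AlertMessage:
    recipient: str  # "proxy" or "ems"
    text: str
    at: float
    severity: str = "alarm"


@dataclass(frozen=True)
class DeliveryRecord:
    message: AlertMessage
    attempts: int
    delivered: bool
    at: float


def classify(
    fhr: float, seconds_since_last_fm: float, th: DistressThresholds | None = None
) -> State:
    """Map one (FHR, time-since-last-movement) pair to a state.

    Strict inequalities: 120 and 160 bpm are in-band, and the movement clock
    must exceed the timeout to warrant MONITOR.
    """
    th = th or DistressThresholds()
    if fhr < th.fhr_low or fhr > th.fhr_high:
        return State.DISTRESS
    if seconds_since_last_fm > th.no_fm_timeout:
        return State.MONITOR
    return State.NORMAL


def make_status(state: State, since: float, signal_loss: bool = False) -> FetalStatus:
    return FetalStatus(
        state=state,
        led=STATE_LED[state],
        display=STATE_DISPLAY[state],
        since=since,
        signal_loss=signal_loss,
    )


def _alerts_for(state: State, now: float, signal_loss: bool) -> list[AlertMessage]:
    severity = "signal_loss" if signal_loss else "alarm"
    if state is State.MONITOR:
        return [AlertMessage("proxy", MONITOR_ALERT_TEXT, now, severity="warning")]
    if state is State.DISTRESS:
        return [
            AlertMessage("proxy", DISTRESS_ALERT_TEXT, now, severity=severity),
            AlertMessage("ems", DISTRESS_ALERT_TEXT, now, severity=severity),
        ]
    return []


class FetalMonitor:
    """The alarm state machine.

    Call :meth:`step` with non-decreasing timestamps, passing any new FHR
    estimate and any movement events observed since the previous step.  The
    machine stays INITIALISING until the first FHR arrives; the movement
    clock starts at the first step.
    """

    def __init__(
        self,
        thresholds: DistressThresholds | None = None,
        cooldown: float = 600.0,
        notifier=None,
        notify_retries: int = 2,
    ) -> None:
        if cooldown < 0:
            raise ConfigError(f"cooldown must be >= 0, got {cooldown}")
        self.thresholds = thresholds or DistressThresholds()
        self.cooldown = cooldown
        self.notifier = notifier
        self.notify_retries = notify_retries
        self._now: float | None = None
        self._start: float | None = None
        self._last_fm: float | None = None
        self._fhr: float | None = None
        self._state = State.INITIALISING
        self._since: float = 0.0
        self._last_emit: dict[State, float] = {}
        self.deliveries: list[DeliveryRecord] = []

    @property
    def state(self) -> State:
        return self._state

    def step(self, now: float, fhr=None, events=()) -> tuple[FetalStatus, list[AlertMessage]]:
        if self._now is not None and now < self._now:
            raise SequencingError(f"time went backwards: {now} < {self._now}")
        if self._start is None:
            self._start = now
            self._since = now
        self._now = now

        for ev in events:
            t = getattr(ev, "peak_time", None)
            if t is None:
                t = getattr(ev, "time", ev)
            t = float(t)
            if self._last_fm is None or t > self._last_fm:
                self._last_fm = t

        if fhr is not None:
            self._fhr = float(getattr(fhr, "bpm", fhr))

        signal_loss = self._fhr == 0.0
        if self._fhr is None:
            new_state = State.INITIALISING
        else:
            since_fm = now - (self._last_fm if self._last_fm is not None else self._start)
            new_state = classify(self._fhr, since_fm, self.thresholds)

        alerts: list[AlertMessage] = []
        transitioned = new_state is not self._state
        if transitioned:
            self._state = new_state
            self._since = now
        if new_state in (State.MONITOR, State.DISTRESS):
            last = self._last_emit.get(new_state)
            # emit on transition unless this state alerted within cooldown;
            # while the state persists, re-alert every cooldown seconds
            if last is None or now - last >= self.cooldown:
                alerts = _alerts_for(new_state, now, signal_loss)
                self._last_emit[new_state] = now

        if self.notifier is not None:
            for msg in alerts:
                self.deliveries.append(
                    notify(msg, self.notifier, retries=self.notify_retries)
                )
        return make_status(new_state, self._since, signal_loss), alerts


def notify(msg: AlertMessage, sink, retries: int = 0) -> DeliveryRecord:
    """Deliver one alert through a notifier sink, retrying on failure.

    The sink is any object with a ``send(msg)`` method (or a bare callable).
    Failures are logged and retried up to ``retries`` times; a monitor loop
    never crashes because a delivery path is down.
    """
    send = getattr(sink, "send", sink)
    attempts = 0
    for _ in range(retries + 1):
        attempts += 1
        try:
            send(msg)
            return DeliveryRecord(msg, attempts, True, msg.at)
        except Exception:  # noqa: BLE001 - any sink failure is survivable
            log.warning("alert delivery attempt %d failed", attempts, exc_info=True)
    return DeliveryRecord(msg, attempts, False, msg.at)


class ConsoleNotifier:
    """Prints alerts to stderr — the desk stand-in for LEDs + GSM texts."""

    def send(self, msg: AlertMessage) -> None:
        print(f"[{msg.at:.1f}s] to {msg.recipient}: {msg.text}", file=sys.stderr)


class JsonlNotifier:
    """Appends alerts to a JSON-lines file."""

    def __init__(self, path) -> None:
        self.path = Path(path)

    def send(self, msg: AlertMessage) -> None:
        record = {
            "at": msg.at,
            "recipient": msg.recipient,
            "text": msg.text,
            "severity": msg.severity,
        }
        with self.path.open("a") as fh:
            fh.write(json.dumps(record) + "\n")


class CallbackNotifier:
    """Wraps a plain callable as a notifier."""

    def __init__(self, fn) -> None:
        self.fn = fn

    def send(self, msg: AlertMessage) -> None:
        self.fn(msg)
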