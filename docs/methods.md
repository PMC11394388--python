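# Methods

This note records the models implemented in `fetaldesk`, the parameters
that matter, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Movement detection

The detector operates on the fused magnitude `A_xyz = √(Ax²+Ay²+Az²)` of a
triaxial abdominal accelerometer sampled at 500 Hz. Fusion makes detection
independent of sensor orientation (invariant to axis permutations and sign
flips), at the cost of folding all axes' artifacts into one channel.

Detrending uses the first-order DC-blocking IIR

    y[n] = p·y[n−1] + (x[n] − x[n−1])/T ,   p = 0.99, T = 1,

run causally from zero state, as a streaming device would. Its DC gain is
exactly zero; a constant input decays geometrically with ratio `p`. At
500 Hz the −3 dB corner sits near 0.8 Hz: kick transients (≳10 Hz content)
pass at essentially unit gain while a 0.25 Hz respiration component is
attenuated about 3×. That attenuation is modest — the design presumes
respiration-induced acceleration is only a few mg so that its filtered
remnant stays below the detection threshold. `T` is kept at 1
(dimensionless) so the filter output remains on the g scale on which the
0.002 g threshold is defined; setting `T = 1/fs` gives a true discrete
derivative instead, with correspondingly rescaled amplitudes.

Detection thresholds the rectified output at **0.002 g**. Because the
filter output oscillates through zero within one kick, contiguous
suprathreshold runs closer than a **1 s merge window** are grouped into one
movement. Two guards are applied on top of the literal threshold rule,
both device-design choices:

* **settle_time = 2 s** — from zero state the causal filter sees the ~1 g
  gravity baseline as a step whose decay (time constant 0.2 s at 500 Hz)
  would always register as a spurious movement at power-on; the first two
  seconds (10 time constants) are excluded from detection.
* **min_event_duration = 20 ms** — a movement must spend at least 20 ms
  above threshold (summed within a merged group, so isolated noise spikes
  bridged by the merge window cannot add up to an event). A single-sample
  excursion is sensor noise, not a kick; real kicks at ≥0.015 g remain
  above 0.002 g for ≳100 ms.

Validation against maternal perception matches each button press to the
nearest unmatched detection within ±5 s (greedy, one-to-one; the reaction
window is a choice, not a measured quantity). `false_negatives` — felt
movements with no detection — is the safety-critical count.

A note on monotonicity: the *time* spent above threshold is monotone
non-increasing in the threshold, but the *number of grouped events* need
not be — raising the threshold can split one broad excursion into several
narrow ones. The property tests assert the former.

## Phonocardiography front end

The analog acquisition board is modelled in discrete time at 8 kHz: a
preamplifier stage (closed-loop voltage gain 2) followed by a fourth-order
Butterworth low-pass with cutoff 200 Hz, designed by bilinear transform
with prewarping so the −3 dB point lands exactly on the cutoff, and
realised as two cascaded biquad sections the way the hardware cascades two
second-order Sallen-Key stages. DC gain of the filter is exactly 1; the
magnitude response is maximally flat and monotone to Nyquist. Sallen-Key
component values, op-amp nonidealities (bandwidth, slew, noise, supply
rails) are not modelled.

The board's op-amp also has a 60 dB open gain. Closed-loop gain 2 and the
open-gain regime are different circuits, so both are exposed as explicit
modes: the normal chain multiplies by `preamp_gain` (2), the open-gain
simulation multiplies by `10^(open_gain_db/20)` (1000×). The open-gain mode
is a pure mathematical scaling — a 100 mV input maps to 100 V, a level no
5 V board could produce; it exists to reproduce the simulation regime, not
the hardware.

## Beat detection and FHR

The published operating rules fix only two constants: a **300 ms
refractory period** between counted beats and a **6 s counting window
multiplied by 10**. The detector between them is this package's own,
chosen as the simplest consistent with both: a moving-RMS envelope
(50 ms window) thresholded at half its maximum, beats placed at upward
crossings, crossings within the refractory of the last beat suppressed.
The relative threshold makes detection invariant to overall scale;
silence yields no beats rather than an error.

FHR uses tumbling (non-overlapping) 6 s windows; `bpm = count × 10`, so
estimates are quantised to multiples of 10 bpm and a true rate `r` is
always recovered within ±10 bpm. A final partial window is flagged rather
than extrapolated. A window with zero beats reports 0 bpm, which the alarm
logic treats as distress with a signal-loss flag — loss of heart-sound
contact is never silently benign.

## Alarm state machine

States INITIALISING/NORMAL/MONITOR/DISTRESS map one-to-one onto
white/green/yellow/red LEDs and fixed display strings. Classification:
DISTRESS iff FHR < 120 or FHR > 160 bpm (strict, so the band edges are
in-band); else MONITOR iff no movement for more than 4500 s (the upper end
of a normal fetal rest period); else NORMAL. Abnormal FHR alone is
sufficient for distress — movement state only distinguishes NORMAL from
MONITOR. Transitions into MONITOR text the proxy contact
(`Warning: Low Fetal Movement count`); transitions into DISTRESS text
proxy and EMS (`EMERGENCY: Fetal Distress Detected!`). A persistent
condition re-alerts only after a **600 s cooldown** (a flood-control choice;
any positive value preserves the one-alert-per-transition behaviour).
Delivery goes through pluggable notifiers with bounded retries; a failing
sink is logged and never interrupts monitoring.

## Synthetic signals

The accelerometer generator emulates the artifact mix seen on a pregnant
abdomen: a constant gravity baseline (default (0,0,1) g), respiration as a
0.25 Hz sinusoid at **2 mg** (quasi-static breathing tilt; ~1 cm of
abdominal displacement at 0.25 Hz corresponds to ~2.5 mg), white sensor
noise at **0.4 mg RMS** (a low-noise MEMS accelerometer's ~25 µg/√Hz
density over a 250 Hz bandwidth), fetal kicks as 0.2 s damped sinusoids at
15 Hz with peak amplitudes drawn uniformly from **0.015–0.06 g** (the range
of maternally perceptible movements), and optional maternal-laughter bursts
(6 Hz carrier under a Hann envelope, seconds long, kick-like amplitude) for
studying false positives deliberately. Random kick placement keeps kicks
≥2 s apart (distinctly perceived movements) and clear of the filter
warm-up and the record end; perception markers are placed at kick time
plus a 0.5 s reaction latency. The phonocardiography generator emits one
100 Hz damped wavelet (50 ms) per beat at a configurable bpm, amplitude
2.5 mV, plus white noise (0.1 mV default).

What passing tests show — and do not. On these signals the pipeline
achieves zero false negatives over 100 seeded trials and recovers FHR
within the ±10 bpm quantisation from 110–170 bpm. The generator does not
model fetal heart-sound morphology (S1/S2 splitting), maternal heart
sounds, sensor placement variability, contractions, or maternal motion
beyond respiration and laughter, so these results bound algorithmic
correctness, not clinical performance on real recordings.

The alarm-table scenarios drive the state machine with scripted FHR values
(140/162/116 bpm) over a replayed timeline, mirroring how the hardware
alarm system was tested by injecting FHR with a potentiometer; the signal
path is verified alongside on the same bundle (beat detection on the
generated audio recovers the scripted rate within quantisation, movement
detection recovers the kick schedule exactly). The low-movement scenario
replays 4800 s of timeline at 6 s steps — state-machine steps are cheap, so
the timeout is exercised at full scale while raw signals stay short (60 s
accelerometer, 12 s audio).

## Numerical and IO choices

* Filters run in float64; the detrend filter's streaming output matches
  the brute-force recursion to 1e-12 on 10⁴-sample inputs.
* The −3 dB frequency is located by linear interpolation on a 200 001-point
  magnitude grid.
* Accelerometer CSV requires a header naming `t, ax, ay, az` (aliases
  accepted), with an optional 0/1 `marker` column; `fs` is inferred from
  the median time step and the grid must be uniform to 1 µs. Units are
  never guessed: a `units_scale` factor (default 1) converts file units
  to g explicitly.
* Record statistics use the population SD (`ddof=0`) by default,
  configurable; durations are reported in minutes to 2 d.p.
* 16-bit WAV output scales by 32768 (the read-side divisor) and saturates
  +1.0 at 32767, making write/read round-trips sample-exact.
* Event JSON round-trips losslessly (floats serialised at full precision).

## Known limitations

* The movement threshold (0.002 g) was estimated from a small number of
  records in the source data and is not clinically calibrated; the config
  exposes it, along with every other operating constant.
* The detrend filter passes an appreciable fraction of sub-Hz drift
  (~30% at 0.25 Hz); large respiration or slow maternal motion can still
  cross the threshold. Artifact classification (e.g. separating laughter
  from kicks) is out of scope.
* Beat detection assumes one dominant envelope peak per cardiac cycle; it
  has no maternal-sound cancellation and is untested on real fPCG audio.
* The monitor's time base is the caller's; it assumes non-decreasing
  timestamps and 6 s steps in the provided replay helpers.
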