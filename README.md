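# fetaldesk

Software model of a low-cost wearable home fetal monitor. Reduced fetal
movement and an abnormal fetal heart rate (FHR) are the two bedside signs of
fetal distress; the device this package models watches both from the
maternal abdomen — fetal movements with a single triaxial accelerometer,
heart sounds with an electret microphone behind an analog phonocardiography
(fPCG) acquisition board — and raises alarms over LEDs, a display, and text
messages. `fetaldesk` implements the whole signal path in software so the
algorithms can be studied, tested, and re-tuned at a desk, with seeded
synthetic-signal generators standing in for recordings.

Intended users: biomedical-signal-processing researchers and device
engineers prototyping fetal monitoring pipelines.

## The algorithms

**Fetal movement (FM).** The three acceleration axes are fused into one
magnitude signal (per-sample Euclidean norm)

```
A_xyz[n] = sqrt(Ax[n]² + Ay[n]² + Az[n]²)
```

then detrended with a first-order DC-blocking IIR filter

```
H(z) = (1/T) · (1 − z⁻¹) / (1 − 0.99 z⁻¹)
```

whose zero at DC removes gravity and slow respiration drift while passing
kick transients. A fetal movement is counted whenever the filtered signal
exceeds a 0.002 g threshold; contiguous excursions merge within a 1 s
window so one kick counts once. Detections can be validated against
maternal push-button perception markers (greedy one-to-one matching).

**Fetal heart rate.** Heart-sound audio passes through a discrete-time
model of the acquisition board — preamplifier with voltage gain 2, then a
fourth-order Butterworth low-pass at 200 Hz realised as two cascaded
biquads, mirroring the two Sallen-Key stages of the hardware. Beats are
detected on a moving-RMS envelope with a relative threshold and a 300 ms
refractory period (so the two components of one heart sound are not double
counted); FHR is the beat count in a tumbling 6 s window × 10, in bpm.

**Distress logic.** A four-state rule machine: FHR outside 120–160 bpm ⇒
DISTRESS (red LED, `"! Fetal Distress!"`, texts proxy and EMS); no movement
for more than 4500 s with FHR in band ⇒ MONITOR (yellow LED, `"Monitor"`,
texts proxy); otherwise NORMAL (green LED, `"Normal"`). The GSM/LED/LCD
hardware is abstracted behind pluggable notifiers.

## Worked example

```python
import fetaldesk as fd

# a 30 s accelerometer recording with two kicks, at 10 s and 20 s
rec, truth = fd.gen_accel(fd.SynthAccelConfig(
    duration=30.0, kick_times=(10.0, 20.0), kick_amp=0.03, seed=1))
report = fd.run_fm_pipeline(rec)
print(report.fm_count, report.mp_count, report.false_negatives)

# a 6 s phonocardiogram at 140 bpm through the front-end model
clip, _ = fd.gen_pcg(fd.SynthPcgConfig(bpm=140, duration=6.0, seed=0))
y = fd.run_frontend(clip.as_series())
beats = fd.detect_beats(y)
print(fd.estimate_fhr(beats, duration=6.0)[0].bpm)
```

prints

```
2 2 0
140
```

— both injected kicks are detected, both maternal perception markers are
matched (zero false negatives), and the 14 beats counted in the 6 s window
give 140 bpm, the mid-band normal FHR.

The same flows are available from the shell:

```sh
fetaldesk synth scenario --name normal --out-dir fixtures/
fetaldesk fm count --input fixtures/normal_accel.csv
fetaldesk fpcg fhr --input fixtures/normal_pcg.wav
fetaldesk monitor run --accel fixtures/normal_accel.csv \
    --pcg fixtures/normal_pcg.wav --alerts alerts.jsonl
fetaldesk fpcg bode --out response.csv
```

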