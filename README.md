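# mislfp

Simulation and analysis of a **memristive integrating sensor (MIS)** for
single-trial detection of cue-evoked events in local field potentials
(LFPs).

In an MIS, an amplified LFP voltage directly biases a nonvolatile
memristor at 500 Hz. The device acts as a bipolar, thresholded, weighted
integrator: sub-threshold background leaves its resistance untouched,
while the large bipolar peaks of a cue-evoked LFP event drive it between
a high (HRS ≈ 40 kΩ) and a low (LRS ≈ 20 kΩ) resistive state. Periodic
readouts of the resistance are grouped into batches of *N* cycles (140 ms
at *N* = 70), each batch is compressed into a scalar biomarker ΔR by one
of three strategies

| strategy  | biomarker                                   |
|-----------|---------------------------------------------|
| `maxdiff` | largest consecutive-readout difference      |
| `maxdrop` | R_max − R_min within the batch              |
| `batch`   | \|R_init − R_end\| (boundary readouts only) |

and a detection is flagged whenever **ΔR > A · R_init**, with *A* a
dimensionless threshold coefficient. Detections are scored against event
windows delimited on the filtered LFP (half-height crossings of the first
and last prominent peaks after each cue), an ROC curve is traced by
sweeping *A*, and the operating point is picked by the *minimal-secant*
rule — slide a 45° line across the curve and keep the point nearest the
ideal-classifier secant, which at 45° is exactly the maximizer of
Youden's J = TPR − FPR. An analytic budget tallies the per-channel energy
of the programming/readout pulses (E = V²·G·t·n) and the digital stages.

The package provides every stage: a seeded synthetic-LFP generator (1/f
background, ~450 ms neural latency, ~1.7 s oscillatory events), the analog
front end (130 Hz Butterworth low-pass, gain ~10⁴, ±3 V clip, 500 Hz
resampling), a phenomenological memristor and the MIS bias/read cycle,
the three biomarker extractors and threshold classifier, windowed
confusion-matrix evaluation with ROC/secant calibration and latency
analysis, a Savitzky–Golay peak-detection software baseline, the energy
model, and a CLI. It is aimed at neuroengineering researchers exploring
in-sensor computing for low-power neural interfaces.

## Worked example

Calibrate the detection threshold on a noisy synthetic session (300 s,
~25 cues, 30 µV RMS pink background under 80 µV events — SNR below
10 dB):

```python
import mislfp as m
from mislfp.pipeline import _simulate_session

cfg = m.RunConfig(seed=7, duration=300.0,
                  synthetic=m.SyntheticParams(background_rms=30e-6))
_, _, series, windows = _simulate_session(cfg, cfg.seed)

model = m.MisThresholdModel(series, windows, strategy="batch", batch_size=70)
res = model.fit()
print(res.summary())
```

```
          MIS threshold calibration
=============================================
strategy: batch      batch size N: 70
classification rate: 7.14 Hz
secant angle: 45.0 deg   grid points: 200
---------------------------------------------
optimal threshold A*       0.01335
operating point (FPR,TPR)  (0.214, 0.783)
ROC AUC                    0.8285
---------------------------------------------
TP    18   FP   443   FN     5   TN  1625
sensitivity  0.7826
specificity  0.7858
accuracy     0.7857
median latency (s)         1.124
=============================================
```

At this noise level the calibrated threshold catches 18 of 23 event
windows while ~21% of quiet batches false-alarm; with the background off
the same pipeline separates perfectly (accuracy 1.0 at A = 0.022).
The median cue-to-flag latency of ~1.1 s is the ~0.45 s neural latency
plus the event's rise to threshold plus up to one 140 ms batch.

The per-channel energy budget for a projected 100 kΩ-class device:

```python
print(m.budget(m.EnergyParams.projected()).summary())
```

```
Per-channel energy/power budget
---------------------------------------
  programming energy / batch      0.56 nJ
  readout energy / batch         8e-05 nJ
  total memristor energy          0.56 nJ
  memristor power                    4 nW
  system power                    4.14 nW
  energy per operation           0.579 nJ
```

i.e. ~4.14 nW per channel and ~0.58 nJ per 140 ms classification — about
7× below the 29.8 nW of a published analog-CMOS spike detector evaluated
at a 5 Hz event rate (`m.cmos_baseline_power(5.0)`).

The same pipeline is scriptable from the shell:

```sh
mislfp evaluate --seed 42 --out runs/demo     # full chain + report.json
mislfp roc --seed 42 --out runs/roc           # ROC sweep + secant optimum
mislfp energy --preset projected              # analytic budget
mislfp sweep --axis detection.batch_size --values 70,140,210 --out sweep.csv
```

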