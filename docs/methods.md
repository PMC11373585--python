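# Methods

This note documents the models implemented in `mislfp`, the parameter
choices that matter, and what the synthetic data do and do not show.

## Synthetic LFP sessions

A session is a cue schedule plus a voltage trace. Cues sit on a jittered
regular grid (default 12 s mean interval, 1 s Gaussian jitter over a
600 s session, ≈ 50 cues); the interval is long enough that consecutive
events (neural latency + event duration ≈ 2.2 s) cannot overlap.

The trace is the sum of:

- **Background**: Gaussian white noise spectrally shaped to 1/f^β
  (β = 1 by default) and rescaled to a target RMS, 30 µV by default. This
  reproduces the power-law spectrum of extracellular recordings but none
  of their nonstationarity, line noise, or movement artifacts.
- **Events**: one per cue, a sinusoid at 7 Hz (inside the < 130 Hz LFP
  band) under a Hann envelope of 1.68 s (12 × 140 ms), with onset delayed
  by a neural latency drawn from N(0.45 s, 0.05 s) and a peak amplitude
  drawn per event from N(80 µV, 15 µV). The Hann-enveloped burst captures
  the bipolar swell-and-fade morphology of a cue-evoked LFP event without
  claiming fidelity to any particular recording.

One root seed spawns independent child streams for schedule jitter,
latencies, amplitudes and noise, so changing the noise level does not
perturb event placement and runs are bit-reproducible. Ground-truth event
spans are recorded on the trace.

With defaults the event-to-background ratio is below 10 dB. Passing tests
on these traces demonstrates the pipeline's mechanics and calibration
behavior, not performance on in vivo data: real LFPs contain non-evoked
transients, drifting baselines and correlated noise that the generator
deliberately omits.

## Front end

A digital Butterworth low-pass (order 6, 130 Hz, bilinear design) stands
in for the analog Sallen–Key filter. Filtering is zero-phase
(forward–backward) by default because event windows are delimited on the
filtered trace; a causal single-pass mode is available for latency
studies, and it is the mode whose magnitude follows the textbook
|H(f)| = 1/√(1 + (f/fc)^(2·order)). Amplification is a sample-wise
`clamp(gain·v + offset, ±3 V)`; resampling to the 500 Hz device rate is
plain sample-picking since the signal is already band-limited far below
250 Hz (interpolation, logged, for non-integer strides).

The module default gain is 1×10⁴. The *run-config* default is 2.5×10⁴:
with 80 µV event peaks the device then sees ≈ 2 V — inside the 1–2 V
switching-threshold window — while a 30 µV background maps to 0.75 V RMS,
mostly sub-threshold. This mirrors how a physical front end's gain and
offset are trimmed to place events above and background below the
device's switching thresholds; with the plain 1×10⁴ gain the 0.8 V peaks
would never switch a 1 V-threshold device.

## Memristor model

The device is a phenomenological bipolar thresholded integrator with
state R ∈ [R_LRS, R_HRS] (defaults 20/40 kΩ). A programming pulse of
width dt at voltage v updates the state only when |v| exceeds the
relevant threshold (1 V each way by default):

    dR = − k_down · (|v| − v_th_down) · dt · w(R)   (driving polarity)
    dR = + k_up   · (|v| − v_th_up)   · dt · w(R)   (opposite polarity)

with the parabolic soft-saturation window
w(R) = (R − R_LRS)(R_HRS − R) / ((R_HRS − R_LRS)/2)², floored at
`window_floor` and the result hard-clamped to the rails.

Numerical choices:

- **Window floor (0.25).** A pure parabola is exactly zero at the rails,
  so a device resting at HRS could never switch at all. The floor sets
  the residual switching rate there; 0.25 keeps a full-scale event that
  begins at HRS moving by kΩ per 140 ms batch, consistent with the
  event-driven drops the encoding relies on, while leaving the midrange
  (w = 1) behavior and its closed-form single-step values untouched.
- **Rate constants** default to k_down = 5×10⁷ Ω/(V·s) and
  k_up = 1.25×10⁷. The magnitude makes a 2 V event (tens of
  suprathreshold 10 µs pulses) traverse a quarter of the HRS−LRS range;
  the 4:1 down/up asymmetry reflects the usual SET/RESET asymmetry of
  bipolar oxide devices and is what turns a *bipolar* oscillation into a
  net resistive drop. With symmetric rates the up and down half-cycles
  would cancel and events would encode as jitter, not displacement.
- **Emergency reset.** A nonvolatile device saturates at LRS after a few
  events and, under sub-threshold background, would stay there. The
  on-demand reset returns the state to HRS whenever it falls within
  `reset_margin` of LRS (off at module level, enabled in the default run
  config). The margin is 2 kΩ — 10% of the range — so the reset reliably
  triggers *during* a saturating event (the upward jump lands inside the
  event window and merges into the same behavioral detection) rather
  than leaving the device parked at the bottom of its range with no
  dynamic range for the next event.
- **Volatile variant.** Optional exponential relaxation toward HRS with
  time constant `relax_tau` (off by default) emulates self-resetting
  devices.

The MIS cycle applies one 10 µs programming pulse per 2 ms period
(500 Hz) and a non-disturbing 200 mV readout every cycle (per-cycle mode)
or once per N cycles (per-batch mode). Readout noise (`noise_sd`) and
per-pulse state drift (`drift_sd`) are Gaussian and off by default. With
noise off, the simulator takes a fast path that only visits
suprathreshold samples; it is float-identical to sequential single steps
(asserted in tests).

## Detection

Readouts are grouped into non-overlapping batches of N (trailing partial
batch dropped). R_init chains across batches: the last readout of the
previous batch, the first available readout (per-cycle) or the device's
initial resistance (per-batch) for the first. `maxdiff` uses the
*absolute* consecutive difference by default — on a device whose events
register as drops, the literal signed maximum would be negative inside an
event and could never exceed the positive threshold A·R_init; a flag
restores the literal formula. The classifier is strict
(`ΔR > A·R_init`; ties are no detection), with per-strategy default
coefficients A_maxdiff = 0.03, A_maxdrop = 0.01, A_batch = 0.022. The
batch strategy's output rate is device_rate/N (7.14 Hz at N = 70).

## Evaluation

Event windows: per cue, prominent peaks of the rectified filtered trace
(prominence ≥ 5 × the trace's median absolute deviation — "prominent" is
otherwise unspecified) within 2.5 s of the cue delimit the window at the
half-height crossing before the first and after the last peak, with
sub-sample linear interpolation. Overlapping windows merge with a
warning. When noise swamps peak extraction on synthetic data,
`windows_from_ground_truth` scores against the generator's recorded
spans instead.

Scoring mixes granularities on purpose: TP/FN count windows (multiple
flags inside one window collapse into one behavioral detection), FP
counts stray detections, TN counts quiet out-of-window batches. A flag in
the latency gap between cue and window start counts as FP. Sensitivity,
specificity and accuracy follow the usual definitions from these counts;
zero denominators yield an explicit undefined marker, never a silent 0.

The ROC sweep evaluates 200 log-spaced A values in [10⁻⁴, 10⁻¹]
(biomarkers computed once, thresholding and scoring repeated). Because
one batch yields at most one detection, FP + TN is constant across the
sweep and both ROC coordinates are non-increasing in A. The operating
point maximizes cos(α)·TPR − sin(α)·FPR over the grid (ties to the
smaller A); at the default α = 45° this is Youden's J and coincides with
minimizing the perpendicular distance to the 45° secant through the
ideal-classifier corner. Larger α favors a lower false-positive rate.

Latency is the interval from cue to the first in-window flag, summarized
by the median; it decomposes as neural latency + the event's rise to
threshold + up to one batch length of grid quantization, which is why the
median grows with N. The software baseline (Savitzky–Golay smoothing +
prominence-based peak picking) provides the comparison detector.

## Energy model

Everything follows from E = V²·G·t·n per pulse group. The experimental
scenario (2 V programming across 0.5 mS for 100 ns × 70; 0.2 V read
across 20 µS for 600 µs × 1; 140 ms batch) gives 14 nJ + 0.48 nJ =
14.48 nJ per batch, ≈ 0.1 µW per channel. The projected scenario (20 µS
device, 100 ns read) gives 0.56 nJ + 80 fJ per batch; adding the fixed
digital contributions (ADC 17 pW, feature extraction 62.7 pW,
classification 58.2 pW) totals 4.14 nW per channel and 0.58 nJ per
classification operation. The energy parameters are deliberately
independent of the MIS cycle timing defaults (100 ns vs 10 µs pulses):
the budget describes projected, engineered devices. The comparison
baseline is the published linear power model 29.4 + 0.077·f nW for an
analog CMOS spike detector (29.8 nW at f = 5 Hz).

## Problem sizes and test design

Unit tests run on 40–120 s sessions; the end-to-end suite uses one 600 s
session (≈ 50 cues, 3.6×10⁵ device cycles) plus three noisier variants
for the SNR-degradation check — sizes chosen so the complete suite runs
in well under two minutes on one core while still exercising every stage
at full device rate. Oracles are kept independent of the code paths they
check: exhaustive scans for the biomarkers, the analog closed form for
the filter magnitude, a 100×-oversampled continuous template for event
windows, perpendicular-distance geometry for the secant optimum, and
scikit-learn's ROC on a construction where windowed scoring reduces to
per-sample classification.

## Known limitations

- The device model is behavioral: no filamentary/electro-thermal
  physics, no device-to-device variation beyond Gaussian noise knobs, no
  series-resistance IR drop (the energy model simply assumes it
  compensated).
- The front end has no amplifier noise model and no automatic
  gain/offset optimization; polarity conventions are exposed as flags.
- Synthetic events are stereotyped single bursts; the generator does not
  model spiking activity, multi-channel structure, or non-evoked LFP
  transients, so false-positive rates on real recordings will be higher
  than on synthetic background of equal RMS.
- Batch boundaries are free-running from trace start, not cue-aligned;
  latency therefore includes a uniform batch-phase offset.
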