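# Methods

This note documents the modeling choices behind `oroflow`: the
processing pipeline and its assumptions, the defaults and why they are
set where they are, what the synthetic data generator emulates, the
numerical conventions, and the limits of what the shipped experiments
demonstrate.

## Problem setting

Two recorders run simultaneously on the same child: device A carries
the nasal-pressure cannula and an accelerometry ("activity") channel,
device B carries the oral-pressure cannula and its own activity
channel. The devices' clocks are offset by an unknown constant (start
buttons pressed at different moments). Scoring is segment-level: for
every 10 s window, decide whether mouth breathing covered at least half
of it. All mouth breathing counts — a window of oronasal (mixed-route)
breathing is an event; the presence of nasal flow never vetoes one.

## Synchronization

The clock offset is estimated as the argmax over integer sample lags of
the normalized cross-correlation of the mean-removed activity signals,
searched within ±60 s. Both activity channels are first decimated to a
common 10 Hz grid (anti-aliased polyphase resampling): body movement is
low-frequency and the decimation cuts the correlation cost by an order
of magnitude. Assumptions and conventions:

- **Constant offset.** Clock *drift* over the night is not modeled; the
  lag is a single scalar. Sign convention: positive lag means device B
  started later than device A.
- **Resolution.** No sub-sample interpolation — one sample at 10 Hz
  (0.1 s) is two orders of magnitude below the 10 s analysis window, so
  refinement would buy nothing. Ties in the correlation are broken
  toward the smallest |lag|.
- **Degenerate input.** A constant activity signal has no correlation
  structure and raises an error rather than returning an arbitrary lag.

After alignment both pressure channels are cropped to the common
interval; if their rates differ, the higher-rate channel is decimated
to the common rate. Annotations scored on device B's timeline are
shifted by the estimated lag; events falling outside the common
interval are dropped or clipped.

## Filtering and normalization

Both pressure channels pass a 6th-order Butterworth low-pass — oral at
2.0 Hz, nasal at 1.5 Hz. Breathing at 13–22 breaths/min has its
fundamental at 0.2–0.4 Hz; the cutoffs keep the waveform morphology
(2–3 harmonics) and strip sensor noise. Butterworth is the natural
family here (maximally flat passband, no ripple to distort breath
amplitudes, standard for respiratory flow).

Application is **zero-phase** (forward–backward, `sosfiltfilt`) by
default: offline analysis permits it, and it avoids group delay that
would shift events relative to their annotations. "Order" refers to the
designed filter; the forward–backward pass squares the magnitude
response, which only sharpens the roll-off (the single-pass response at
5× cutoff is ≈ −84 dB; doubled in dB terms for zero-phase). A causal
mode is available behind a config flag for parity with streaming use.
Edges are handled by signal reflection so warm-up transients do not
contaminate the first and last windows.

Normalization is a **per-recording z-score** (population SD). The
alternative — per-window scaling — would be wrong here: the amplitude
contrast between an active pressure channel and the muted noise floor
of the unused channel is precisely the cue that separates breathing
from no-flow, and per-window scaling would amplify the noise floor into
a breathing-sized trace. Zero-variance input is an error, not a silent
pass-through.

## Segmentation, labeling, rebalancing

Windows are 10 s long, advanced by 5 s, anchored at the start of the
common timeline; only fully contained windows are emitted, so the count
is `floor((T − W)/S) + 1`. Labeling merges overlapping annotations
first (coverage is a property of time covered, not of event count),
sums the merged overlap per window, and applies the inclusive ≥ 50 %
rule: exactly 5.0 s of coverage in a 10 s window is an event.

Events are rare over a night, so the non-event class is down-sampled to
a configurable fraction (default 2 %) of its original size — events are
never dropped, the subset is uniform, and the output order is shuffled.
The train/test split (default 33 % test) is **stratified**: at a ~13 %
event share an unstratified split can produce an event-free test set on
which sensitivity is undefined. Every random operation takes an
explicit seed recorded in the run manifest.

## The classifier

A dual-input 1-D CNN. For each input signal (oral, nasal) and each
kernel width k ∈ {2, 4, 8, 16} samples there is a convolution branch:
16 kernels of width k, rectified, then global max pooling. The eight
pooled branch outputs are concatenated (256 features), pass one dense
rectified layer (64 units), then a 2-unit softmax matching the one-hot
targets. Global max pooling makes the decision translation-invariant
within the window — "this motif occurred somewhere", which is how a
human scorer recognizes mouth-breathing landmarks.

Training: categorical cross-entropy, Adam at 10⁻³, exactly 50 epochs at
batch size 10, with 20 % of the training windows held out for per-epoch
validation curves. Prediction is argmax (an implicit 0.5 threshold on
the event probability); no threshold tuning or calibration.

The network is implemented directly on numpy: explicit forward/backward
passes (the max-pool gradient flows only to the argmax position, so the
convolution backward pass reduces to a cheap gather), Adam in float32,
all initialization and shuffling driven by one seed. At this size
(~25 k parameters) a 2000-segment corpus trains in well under a minute
per 10 epochs on one CPU core, and runs are bit-reproducible — two runs
with the same config and seed produce byte-identical reports.

Kernel widths, epoch count, batch size, and the validation/test
fractions are the pipeline's operating point; depth, filters per size
(16), dense width (64) and learning rate are free knobs chosen minimal
and exposed in the config.

## Metrics

Confusion matrix rows are truth, columns prediction, class order
[event, non-event]. Accuracy, precision, TPR, FPR, sensitivity ≡ TPR
and specificity ≡ 1 − FPR are derived from the four counts. Any metric
with a zero denominator is reported as an explicit undefined marker
(`null` in JSON) — an event-free control recording has no meaningful
sensitivity, and reporting 0 there would poison pooled summaries.
Pooling across recordings sums confusion matrices, which is exactly
equivalent to concatenating windows.

## The synthetic generator

The generator produces what the pipeline is sensitive to, not a full
respiratory physiology model:

- **Breath waveform**: per breath, a positive half-sine inspiration
  with 2nd/3rd-harmonic shaping, a smaller negative half-sine
  expiration, an end-expiratory pause, and ±15 % per-breath period
  jitter around the subject's rate. The harmonic form keeps every
  statistic analytically checkable (RMS contrasts, spectral peak at the
  breath rate).
- **Routes**: nasal (oral channel at the sensor noise floor), mouth
  (nasal muted), oronasal (both attenuated by a split factor). Episodes
  of mouth/oronasal breathing are scheduled as a renewal process whose
  expected covered fraction equals `mouth_fraction`, with episode
  lengths uniform on 8–45 s (minimum ≥ 5 s so every event can dominate
  a window) and at least 10 s between episodes. Route switches are
  crossfaded over 0.5 s.
- **Devices**: device B's window is shifted by the clock offset; both
  devices see the same movement bursts (Poisson at `artifact_rate`/h,
  1–4 s long) in their activity channels and as high-amplitude
  transients in the pressure channels — shared motion is what makes
  cross-correlation synchronization solvable, and the transients give
  the classifier the same artifact confounders a real night contains.
- **Subject idiosyncrasies**: when enabled, per-subject amplitudes,
  breath rate, harmonic content, inspiration/expiration ratio and
  oronasal split are drawn once per subject. This is what makes the
  within-subject vs unseen-subject generalization experiment possible.

Defaults: 200 Hz pressure channels, 25 Hz activity, 18 breaths/min,
`mouth_fraction` 0.04 (a few percent of the night in mouth-breathing
episodes — plausible for a snoring child), noise SD 0.03 against
breath amplitudes near 1, artifacts 20/h, clock offset 4 s. Presets:
`easy` (pure routes, no artifacts, devices in sync), `default`
(subject variability on), `hard` (60 artifacts/h, higher noise, mostly
oronasal episodes).

What it does **not** emulate: cardiogenic oscillations, apneas and
hypopneas, snore-related high-frequency content, baseline drift from
cannula displacement, and real oral-pressure morphology under partial
mouth breathing (the oronasal amplitude split is a free parameter,
default 50/50). Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the classifier learns the amplitude/shape
cues the generator encodes — not clinical-grade performance on real
recordings.

## Experiment sizing

The shipped tests and the acceptance script run desk-scale versions of
the studies: pressure channels at 50 Hz where waveform bandwidth is not
the question (breathing content lives below 2 Hz, so 50 Hz is ample),
recordings of 150–600 s, training cohorts of 3–4 subjects with
`mouth_fraction` raised to 0.25 so a small corpus still contains enough
event windows to train on, non-event down-sampling at 0.3 at this
scale, and 10-subject unseen cohorts at `mouth_fraction` 0.1. The
separable end-to-end check uses a 400-window bank of pure mouth-only /
nasal-only windows at the full 200 Hz — "pure" because a window
straddling an episode boundary at exactly the 50 % coverage point is
inherently ambiguous for any classifier, and the bank isolates the
question "does the trained network recover a cleanly separable
decision rule?" (it must reach 100 % held-out accuracy, agreeing with
an independent per-channel energy-threshold oracle). The bank is
z-scored per channel *globally* across windows, preserving the
active-vs-muted amplitude contrast exactly as per-recording
normalization does.

## Numerical conventions and degenerate inputs

- Filter design in second-order sections for stability; reflective
  padding at edges.
- Correlation ties break toward the smallest |lag|; lag estimation on
  constant signals raises.
- Window arithmetic uses integer sample indices derived by rounding
  `t·fs`, so float jitter never changes a window count.
- Normalization and lag estimation reject non-finite samples outright.
- The EDF writer quantizes to 16 bits over the observed signal range
  with 5 % headroom; digital values are computed from the
  header-encoded (ASCII-rounded) physical bounds so a round trip is
  exact to one quantization step. Constant channels get a ±1 band so
  the scale stays defined.
- All seeds are small integers; seeds derived inside the pipeline stay
  below 2³¹.

## Known limitations

- Single constant lag; no drift correction between devices.
- Segment-level output only: total mouth-breathing time is quantized by
  the 10 s / ≥ 50 % rule (each detected incident implies roughly 5–10 s
  of mouth breathing). A regression or multi-class formulation would be
  the natural refinement.
- Segment-random splitting mixes windows of the same subject across
  train and test, which is what makes the within-subject numbers
  optimistic relative to unseen subjects; the secondary-validation path
  exists precisely to measure that gap, and subject-wise splitting can
  be built from `subject_ids` carried on every window.
- The classifier's performance claims are established on synthetic data
  only; on real recordings the defaults (cutoffs, 2 % down-sampling,
  architecture width) should be revisited against a manually scored
  corpus.
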