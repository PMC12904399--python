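# Methods

## The detection problem and the model

Manatee vocalizations are short tonal calls: a 2–6 kHz fundamental with
a handful of harmonics, lasting about 0.3–0.8 s, heard at rates on the
order of tens per hour against a site-specific noise background.
`sirenet` treats detection as binary classification of fixed 0.2 s
audio slices. Each slice is rendered as a peak-normalized dB magnitude
spectrogram and scored by a CNN with a two-way softmax; the positive
class probability is thresholded (default 0.5, `score >= threshold`
predicts a call) for hard decisions, or swept for precision–recall
analysis.

A slice is ground-truth positive when any portion of an annotated call
overlaps it with positive measure — "partial positives" (a sliver of a
call plus background) are positives, in both training and evaluation.
Segments are half-open intervals `[t, t + 0.2)`; an annotation that
merely touches an endpoint does not make a slice positive, and overlaps
below 1 ns are treated as the floating-point tiling artifacts they are.

## Front-end

Audio is brought to 96 kHz by polyphase resampling (a Kaiser-windowed
FIR with passband to ~0.94 of the output Nyquist and > 40 dB stopband
attenuation; upsampling is rejected rather than fabricated). Each
19,200-sample slice maps to a 513 × 75 spectrogram: frequency bins
0–512 at 93.75 Hz spacing, 75 frames at 256-sample (≈2.67 ms) hops.

The 75-frame geometry deserves a note: `floor(19200/256) = 75` matches
neither a centered STFT (76 frames) nor an uncentered no-padding STFT
(72 frames). We therefore take frames at offsets `k·hop` for
`k = 0..74`, zero-padding the signal tail so frame 74 is complete, and
treat the printed geometry as an interoperability contract. The last
frame is consequently three-quarters padding; tests that probe
per-frame behavior use the 74 full frames or account for the padded
one.

Magnitudes are converted with `20·log10(max(|S|, 1e-10))` (amplitude
dB, no top clamp) and min–max normalized to [0, 1] per spectrogram; a
constant slice maps to all zeros. Per-slice normalization makes the
representation invariant to overall gain — scaling a waveform by any
positive constant leaves the spectrogram unchanged — which is the
behavior wanted when hydrophone calibration is unknown.

## Augmentation

Training slices pass a gate that fires with probability 0.9. When it
fires, three transforms apply independently, in a fixed order (the
order is a reproducibility choice): time stretch (p 0.5, duration
factor uniform in [0.9, 1.1]; length restored by symmetric trim or tail
zero-pad), time mask (p 0.5, a contiguous run of 5–20 % of the samples
zeroed at a uniform position — masking acts on waveform samples), and
band-stop (p 0.5, zero-phase order-4 Butterworth band-reject; center
uniform in [0, 43 kHz], bandwidth 5–20 % of the center, low edge
clamped to 1 Hz). Validation and test paths never augment.

## Classifier and training recipe

Both backbones accept 1 × 513 × 75 input and share the head recipe:
a 256-unit ReLU layer with 0.5 dropout and a 2-unit softmax.

- `resnet18_2d`: the standard 18-layer residual layout — 7×7 stride-2
  stem, four stages of two basic blocks with [64, 128, 256, 512]
  filters, global average pooling. It is provided for fidelity to the
  reference architecture; training it on CPU is possible but slow.
- `small_cnn` (default for desk-scale work): four conv/BN/ReLU blocks
  (8, 16, 32, 32 channels; an aggressive 5×5 stride-4 stem keeps
  activation maps small on CPU), then **time-only average pooling with
  the frequency axis flattened** (32 × 17 = 544 features) into the same
  head. Pooling over time but not frequency is deliberate: the
  call/no-call signal lives in *where* on the frequency axis a tonal
  ridge sits, and full global pooling throws that away — in early
  experiments a globally-pooled variant would sometimes mistake a
  low-frequency vessel band for call energy on out-of-domain noise.

Training: Adam (lr 1e-3, betas 0.9/0.999, eps 1e-8), cross-entropy,
batch size 32, exponential learning-rate decay `lr_k = 1e-3 · 0.995^k`
applied per epoch, no early stopping. Fine-tuning uses the identical
optimizer and schedule, updates **all** weights (no freezing), and runs
3 epochs on a seeded uniform subsample (a fraction of the target
site's training rows). Everything is seeded and single-threaded; two
runs with the same seed produce bitwise-identical histories. The
engine (`sirenet.nn`) computes in float32; convolution gradients are
verified against central differences in float64 in the test suite.

Class imbalance: at realistic call rates barely 1–2 % of slices are
positive, which makes small-data training degenerate. Training
manifests therefore pair every positive slice with at most 5 mined
background slices (`assemble_training_rows`, ratio configurable).
Evaluation always uses the full tiling of the recording — training
negatives come from inter-call gaps, but every slice counts at test
time.

## Evaluation

`metrics` computes accuracy, precision, recall, F1 from a confusion
matrix, mapping 0/0 to 0 with a degenerate flag. AUC-PR uses the
average-precision step integral (ties collapse to one threshold), not
trapezoidal interpolation, which is optimistic on PR curves; the
implementation is checked against an exhaustive threshold sweep on
every random instance up to 20 segments.

One published-arithmetic caveat: a segment confusion matrix of TP=356,
FP=26, FN=7, TN=21,375 yields precision 93.2 %, recall 98.1 %,
F1 95.6 % — and accuracy 99.85 %, which rounds to 99.8 %, not the
99.9 % sometimes quoted alongside those counts. The three
positive-class metrics are the contract this package checks.

Slice decisions become call events by merging maximal runs of
consecutive positive slices — the simplest monotone rule; it is
isolated behind `assemble_events` so a more elaborate smoother can
replace it. Density series count each event once, in the hour or
minute bin containing its start, keeping empty bins. Pearson r is
computed on raw counts and Spearman ρ on average ranks (scipy);
constant series yield a flagged undefined result rather than a number.
Whether density should count merged events or raw positive slices is
genuinely ambiguous; merged events are the default and both are
reachable through the API.

## The synthetic soundscape generator

Calls are sums of `n` harmonically related linear chirps with
1/harmonic amplitude decay and 10 ms raised-cosine fades, RMS-normalized
before mixing. Placement is a homogeneous Poisson process (optionally
piecewise-inhomogeneous via `rate_profile`, used to create the activity
peaks that density correlation needs) with rejection of overlaps; the
exact placed intervals are emitted as a Raven selection table, so the
ground truth is perfect by construction. The noise bed is spectrally
tilted Gaussian noise (dB/octave re 1 kHz) plus Poisson impulse
("shrimp click") transients plus an optional band-limited vessel noise
band. Long recordings are colored in ~44 s blocks so memory stays
bounded; audio is float32.

SNR is defined *in the call's occupied band* (fundamental through last
harmonic, ±100 Hz), over the call's duration: each call is scaled so
its band power is `snr_db` above the noise band power in the same
window. Tests verify the realized SNR within ±1 dB by FFT band-power
measurement on the separated components.

Defaults mirror field conditions: 2–6 kHz fundamentals, 0.3–0.8 s
durations, 3 harmonics, 44 calls/hour, 96 kHz. The noise parameters
are free inventions for testability — they are not claims about any
real site, and the generator makes no attempt at propagation modeling
(multipath, transmission loss) or at the fine harmonic structure of
real manatee calls.

## The reference study and its problem sizes

The end-to-end properties run on a fixed pair of synthetic sites
(`reference_study_configs`): a clean site (tilt −3 dB/oct, 2 clicks/s,
calls at 15 dB in-band SNR) and a shifted site (flat tilt, 10 clicks/s,
a strong 300–1200 Hz vessel band, calls at 2 dB SNR). The shift is
masking-type: a clean-trained detector keeps its precision but misses
many faint calls, which is the regime in which a small amount of
target-site annotation helps most. Both sites share an inhomogeneous
activity profile (quiet and busy minutes) so density series have
variance to correlate.

Problem sizes are deliberately desk-scale, chosen once as the package's
standard study: 10 min of clean training audio, 20 min of shifted
annotated audio (90 % of its rows available to fine-tuning), 10 min
test recordings per site, 300 calls/hour (elevated above field rates so
minutes-long recordings carry ~100 calls), 40 training epochs of the
small CNN, 3-epoch fine-tuning on a 10 % subsample across five seeds,
and per-minute density bins (the hour/minute choice is a unit switch,
not a method change). Under these conditions the pipeline reaches
same-site F1 ≳ 0.9, shows a large zero-shot recall drop on the shifted
site, recovers a substantial part of it from the 10 % subsample, and
achieves density correlations ≥ 0.9.

What passing these tests does and does not show: the synthetic study
validates the machinery (labeling conventions, feature geometry,
training loop, transfer direction, density accounting) under controlled
conditions with perfect ground truth. It does not certify performance
on real recordings — real soundscapes drift over time, annotations are
imperfect and biased toward clear calls, call repertoires vary by
behavioral context, and the real noise is not Gaussian-plus-clicks.

## Numerical and degenerate-case choices

- Threshold comparison is `>=`, stated because sweeps touch exact ties.
- Segment tiling drops the trailing remainder shorter than the window;
  slices at recording edges are zero-padded at inference, while
  training manifests contain only full slices.
- `metrics` flags 0/0 as degenerate instead of raising; an all-zero
  confusion matrix raises.
- Constant spectrogram → all-zeros; constant density series →
  flagged undefined correlation.
- Selection-table times are serialized at 4 decimals (0.1 ms), so
  write/read round-trips are identity to 1e-4 s.
- Checkpoints store weights, BatchNorm running statistics, the full
  config, history, and provenance (the append-only list of dataset ids
  a model has seen); loading rebuilds the exact predictor.
- ImageNet initialization is accepted as a config value but falls back
  to seeded He initialization with a warning; no weights are bundled
  and no network access is attempted.

## Known limitations

- The CNN engine is CPU/numpy: adequate for the small backbone and
  desk-scale corpora, far too slow for field-scale ResNet-18 training.
- Event assembly has no hysteresis or minimum-duration rule; a single
  spurious slice becomes a (short) event.
- Overlapping calls are out of scope (the simulator refuses to place
  them; the labeling would not distinguish them).
- Multi-channel audio is reduced to channel 0 with a warning.
- No absolute calibration (dB re 1 µPa); all levels are relative.
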