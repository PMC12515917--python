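# Methods

This note records the models, algorithms and design choices behind
`ctgkit`, and what the built-in benchmarks do and do not demonstrate.

## Synthetic CTG generator

A record is two channels sampled at 4 Hz with per-sample validity
masks:

    FHR(t) = baseline + variability(t) + Σ event excursions(t)
    UC(t)  = resting tone + Σ contraction bumps(t)

**Variability** is band-limited noise: beat-scale jitter (2nd-order
Butterworth band-pass, 0.5–1.5 Hz) plus slow wander (low-pass,
0.03 Hz), mixed 1 : 1.2 and rescaled so the *median per-minute
peak-to-trough amplitude* equals the requested `variability_amp`
(bpm). The clinical definitions fix only this amplitude, not a
spectrum; the two-component mix gives strips whose short-term texture
and slow drift both look plausible. Defaults follow a cohort prior of
142 ± 8 bpm baseline and a moderate 10 bpm amplitude.

**Contractions** are raised-cosine bumps (amplitude 35–65 mmHg,
duration 60–90 s, rate ~4/10 min by default) on an 8 mmHg resting
tone; no waveform morphology is prescribed clinically, and a smooth
unimodal bump matches real strips. **Decelerations** are timed against
a target contraction's peak: early = symmetric dip with nadir at the
peak and onset-to-nadir ≥ 30 s; late = the same shape with the nadir
lagging the peak; variable = abrupt dip (onset-to-nadir < 30 s, depth
≥ 15 bpm, duration 15–120 s). **Sinusoidal windows** replace the trace
with a pure sinusoid (3–5 cycles/min, ≥ 20 min) about the local
median, suppressing any overlapping accelerations. Requests that
overlap or do not fit are rejected (or skipped, under
`skip_conflicts`, for bulk cohort generation). Everything derives from
one integer seed; identical parameters give bit-identical records.

**Rendering** maps each valid sample to one column (default
0.25 s/column, matching 4 Hz on a 2,339-column strip) and one row via
the inverse of the digitizer's affine templates; invalid samples leave
grid-only columns. The grid is drawn at intensity 200/255 against a
0/255 trace so the τ = 50 threshold separates them cleanly. Values
outside the clinical range are clipped to the band edge and counted in
the render report. Because the trace is drawn one pixel per column,
the render → digitize round trip is exact to the row quantization
(FHR 150/288 ≈ 0.52 bpm, UC 100/142 ≈ 0.70 mmHg); the acceptance
round trip confirms ≤ one step over 50 seeded strips with randomly
placed signal-loss gaps.

What the generator does *not* emulate: maternal ECG/Doppler artifacts,
pen skips and overlapping traces, scan skew/rotation, printed
annotations, twin traces. Passing tests therefore certify the
algorithms on clean strips, not robustness to real-world scan defects.

## Digitizer

Grayscale is the channel mean. Binarization is a fixed strict
threshold; the default `dark_trace` polarity marks G < τ as foreground
(scanned ink), and a `light_trace` switch exposes the opposite
convention for inverted sources. The value templates are affine,
strictly decreasing in row index, anchored so the band top maps to the
range maximum and the band bottom to the minimum (a template constant
that instead offsets the map by y_max + y_min cannot reproduce both
anchors, so the two-point form is used). Band row indices are 0-based
inclusive and fully layout-configurable. A column's value is the mean
template value over its foreground rows; an empty column is a gap
(NaN + mask). A paper-faithful mode returns 0 for empty columns via an
ε = 10⁻⁶-guarded mean instead. No interpolation is ever applied, in
keeping with the no-fill data policy the toolkit is built around.

## Rule engine

The clinical definitions specify criteria, not algorithms. The
implemented procedures:

- **Baseline**: histogram mode (1-bpm bins, smoothed) of valid samples
  as a robust anchor; excursions are sustained departures > 7 bpm from
  the anchor (on a 2-s-smoothed trace), grown to their 2-bpm crossings
  and padded 10 s; the baseline is the mean over excursion-free stable
  runs ≥ 2 min. Tachy-/bradycardia are flagged when the locally refined
  mode of any 10-min window (1-min step) exceeds 160 / falls below
  110 bpm, with a 0.5 bpm measurement margin against wander. Records
  under 10 min of valid signal are indeterminate.
- **Variability**: median over event-free 1-min windows of the
  peak-to-trough amplitude. Absent < 1.5 bpm, minimal ≤ 5, moderate
  6–25, marked above 25 (the `marked` level is carried so that > 25 bpm
  traces have a defined class; it simply fails the Class I
  moderate-variability condition).
- **Accelerations**: excursions above baseline meeting the
  gestational-age thresholds (≥ 32 wk: ≥ 15 bpm for ≥ 15 s; earlier:
  ≥ 10 bpm for ≥ 10 s; both < 2 min, onset-to-peak < 30 s); 2–10-min
  excursions are prolonged accelerations; ≥ 10 min is left to baseline
  re-estimation. Peak heights are read on a lightly (1 s) smoothed
  trace with 0.25 bpm slack, since any smoothing shaves a fraction of
  a bpm off a true peak.
- **Decelerations**: dips ≥ 10 bpm deep; abrupt ones (onset-to-nadir
  < 30 s, depth ≥ 15 bpm, 15 s–2 min) are variable decelerations and
  need no UC context. Gradual dips are typed against the nearest
  contraction peak: within ± 10 s → early (the "often coincident"
  clause carries no tolerance; ± 10 s is the package's choice), later
  → late; with no concurrent contraction, or no usable UC channel,
  they are reported indeterminate with a warning — precisely the
  misreading mechanism that makes unimodal FHR-only interpretation
  unreliable, and testably so: removing the UC channel from an
  early-deceleration Class I fixture demotes it to Class II.
  The nadir is the center of the near-maximal plateau (top 15% of the
  dip) rather than an argmax, which is far more stable under noise.
- **Sinusoidal**: a run of ≥ 20 consecutive 1-min blocks, each with
  ≥ 60% of its non-DC periodogram power concentrated at a dominant
  3–5 cycles/min bin and peak-to-trough ≥ 4 bpm. Per-block gating makes
  a 19-min sinusoid fail (the longest qualifying run is 19 blocks) and
  rejects broadband moderate variability; accelerations break block
  concentration, enforcing the no-acceleration clause implicitly.
- **Contractions**: prominence-gated peaks (≥ 15 mmHg, ≥ 30 s apart);
  rate per 10 min averaged over the valid span, flagged low-confidence
  under 30 min; tachysystole above 5/10 min.
- **Classification**: Class III iff sinusoidal, or absent variability
  with recurrent late decelerations, recurrent variable decelerations
  or bradycardia; "recurrent" = on ≥ 50% of contractions (the usual
  convention; the term is otherwise undefined). Class I requires
  baseline 110–160 without flags, moderate variability, and no
  late/variable/untyped decelerations; early decelerations and
  accelerations are allowed. Everything else — including any
  indeterminate component — is Class II, with the failed conditions as
  the reason trace. The default binary policy maps I → normal and
  II/III → abnormal; how indeterminate (II) strips should map to a
  binary screening label is genuinely underdetermined, so the policy
  is explicit and configurable.

Event-kind recovery on 100 seeded fixtures (events ≥ 1 min from the
edges, moderate 5–10 bpm variability, gradual decels with
onset-to-nadir ≥ 40 s and abrupt ones ≤ 12 s) is ≈ 99%; the residual
misses are low-amplitude accelerations absorbed by slow wander.

## DenseNet121-SK classifier

The backbone is standard DenseNet121: 7×7/2 stem into 2K channels,
blocks of (6, 12, 24, 16) bottleneck layers (BN–ReLU–1×1 conv to 4K →
BN–ReLU–3×3 conv to K, K = 32), transitions with 1×1 conv at 0.5
compression plus 2×2 average pooling, and a BN–ReLU–GAP–linear head.
With the 1000-class reference head it counts exactly 7,978,856
trainable parameters.

One SK module follows each of the 58 dense layers, operating on that
layer's K-channel output *before* concatenation. Branches are 3×3
(dilation 1) and 3×3 dilation 2 (5×5 receptive field), each
conv–BN–ReLU with grouped convolutions; fuse is elementwise sum →
global average pooling → linear squeeze to d = max(C/r, L) with r = 16,
L = 32 → BN–ReLU; select applies per-channel softmax over the two gate
logits (a_c + b_c = 1 by construction) and mixes the branches. With
**groups = 8** the SK modules add exactly 322,944 parameters (0.32 M)
for a total of 8,301,800 (8.3 M) — the reference budget; depthwise
(groups = 32) branches would undershoot it at 0.22 M, and ungrouped
ones overshoot severalfold, making groups = 8 the unique grouping
consistent with the budget. Incompatible channel/group combinations
are rejected at construction.

The network, including grouped/dilated convolution, batch norm,
pooling and the focal-loss head, runs on a small reverse-mode autodiff
core over numpy (`ctgkit.nn`), with analytic gradients verified
against central differences in the test suite. Focal loss is
−α(1−p_t)^γ log p_t with γ = 2 and α = 0.25 (α is a free choice);
γ = 0, α = 1 recovers cross-entropy.

### Training protocol and problem sizes

Optimization is Adam at learning rate 0.001, batch size 32, focal
loss, 7:3 stratified split with largest-remainder rounding — the
standard recipe throughout. Model selection keeps the epoch with the
best validation accuracy. Because short runs move the weights much
faster than the exponentially averaged BN statistics can follow, BN
running statistics are recalibrated (cumulative average over the
training set) before every evaluation; without this, eval-mode
predictions after a 10-epoch run are near-arbitrary even when
train-mode accuracy is 1.0.

The package's own benchmark scale, chosen for single-CPU runs: charts
rendered on a reduced 96 × 128 px layout (30-min strips) and a compact
DenseNet-SK (K = 16, blocks (2, 2, 2), 1-channel input, ~92 k
parameters). The trainability benchmark uses 200 charts of *separable*
classes — Class I strips versus gross pathology (tachycardic or
bradycardic baselines, absent variability with deep recurrent late
decelerations) — where 10 epochs reach held-out accuracy 1.0.

The bimodal ablation uses 160 charts (16-min strips, 64 × 160 px)
whose classes differ **only** in deceleration timing: normal = early
decelerations on every contraction, abnormal = late decelerations
lagging the peak by 55 s, same depths and shapes. Masking the UC band
removes the discriminative signal by construction, so the FHR-only
model hovers at chance (AUC ≈ 0.5) while the bimodal model reaches
AUC ≈ 0.9+ — the direction, not the magnitude, is the claim, mirrored
on three seeds. The implied relative AUC drop is also reported as a
generalization-decay-style percentage.

These synthetic results demonstrate that the architecture can extract
FHR–UC timing relations from strip images; they say nothing about
performance on clinical data, which requires real cohorts and labels.

## Metrics

The confusion matrix takes the *normal* class as positive
(TP = correctly predicted normal, TN = correctly predicted abnormal),
with per-class precision/recall/F1 and accuracy defined accordingly.
ROC sweeps thresholds over the abnormal-class probability, one point
per distinct score so tied scores cross simultaneously; the trapezoid
AUC then equals the pairwise-comparison probability with ties counted
half, verified to 10⁻⁹ against an O(n²) oracle. GDR is
(AUC_train − AUC_external)/AUC_train × 100, flagged above 15%.

## Numerical and degenerate-input conventions

- Thresholding is strict on both polarities: a pixel exactly at τ is
  background.
- Empty extraction columns are NaN + mask (default) or 0
  (paper-faithful mode); downstream code treats masked samples as
  missing, never interpolated.
- Band bounds are inclusive; the quantization step uses the full band
  extent (rows b − a per range).
- `split_dataset` with a zero fraction permits an empty side; with two
  non-empty sides, a class vanishing from either side is an error.
- AUC requires both classes; GDR requires a positive training AUC;
  focal loss clamps zero true-class probabilities at 10⁻¹² with a
  warning.
- All stochastic components take explicit integer seeds; derived seeds
  stay below 2³¹.

## Known limitations

- The digitizer assumes an axis-aligned, single-trace, known-geometry
  chart; skew, multi-trace overlap and printed text are out of scope.
- The rule engine's excursion detection is tuned for the generator's
  clean morphology; real strips with artifact spikes would need a
  pre-cleaning stage.
- The numpy NN core is single-threaded and keeps whole activations in
  memory; it is sized for the compact benchmark models, not for
  224 × 224 training of the full 8.3 M-parameter network (which is
  built and counted, and trainable in principle, but not exercised at
  full scale by the benchmarks).
- Character-area localization of printed chart annotations is not
  implemented; no algorithm for it is defined in the digitization
  scheme the package follows.
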