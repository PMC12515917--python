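# ctgkit

A toolkit for **bimodal cardiotocography (CTG) analysis**: the joint
reading of fetal heart rate (FHR, beats/min) and uterine contraction
pressure (UC, mmHg) that obstetricians use to judge fetal well-being
during pregnancy and labor. It is aimed at researchers building or
evaluating automated CTG interpretation — in particular the common
setting where the only available data are *paper strip images* from
fetal monitors rather than raw signals.

The package covers the full pipeline, with no external data required:

1. **`ctgkit.synth`** — a seeded generator of paired FHR/UC records
   carrying the standard intrapartum event vocabulary (accelerations,
   early/late/variable decelerations, sinusoidal patterns,
   contractions, tachy-/bradycardia), plus a renderer that draws them
   onto paper-style chart strips.
2. **`ctgkit.digitize`** — recovery of the two series from a chart
   image: grayscale → fixed-threshold binarization (τ = 50) → per-band
   affine value templates → masked column averaging. On the default
   1,653 × 2,339 px geometry the FHR band occupies rows 281–569
   (60–210 bpm) and the UC band rows 628–770 (0–100 mmHg). Signal-loss
   gaps are preserved as gaps; nothing is ever interpolated.
3. **`ctgkit.rules`** — a deterministic FIGO-style interpreter:
   baseline (normal 110–160 bpm), variability (absent / minimal ≤ 5 /
   moderate 6–25 bpm per minute peak-to-trough), event detection with
   deceleration-vs-contraction timing, and the three-tier Class I/II/III
   read-out with a reason trace.
4. **`ctgkit.model`** — a DenseNet121 backbone with **Selective-Kernel
   (SK) attention** after each dense layer, implemented on a small
   numpy autodiff core (`ctgkit.nn`). The SK module runs two branches
   (3×3, and 3×3 with dilation 2 ≡ 5×5 receptive field), fuses them by
   summation + global average pooling, squeezes to
   d = max(C/r, L) dimensions (r = 16, L = 32), and mixes the branches
   with a per-channel softmax gate (a_c + b_c = 1). Reference budget
   with the 1000-class head: 7.98 M base, 0.32 M SK, 8.3 M total.
5. **`ctgkit.evaluate`** — stratified 7:3 splitting, Adam + focal-loss
   training (−α(1−p_t)^γ log p_t, γ = 2), confusion-matrix metrics with
   the *normal* class as positive, ROC/AUC by threshold sweep, and the
   generalization decay rate GDR = (AUC_train − AUC_ext)/AUC_train × 100 %.

## Worked example

```python
import ctgkit as ck

# simulate a 30-minute strip with a late deceleration on contraction 3
params = ck.SimParams(baseline_bpm=142, variability_amp=10, duration_s=1800,
                      seed=7, event_requests=[
                          ("late_decel", {"contraction_index": 3, "depth": 28,
                                          "duration_s": 85, "lag_s": 35})])
rec = ck.simulate_record(params)

# render at paper scale (the strip holds the first 584.75 s) and digitize back
layout = ck.ChartLayout()          # 1653 x 2339 px, 4 Hz, 1 column / 0.25 s
img = ck.render_chart(rec, layout)
fhr, uc, fhr_gap, uc_gap = ck.extract_signals(img)
print(abs(fhr - rec.fhr[:len(fhr)]).max())        # 0.26041... (≤ one pixel row)

# rule-based interpretation
cls = ck.classify_ctg(rec)
print(cls.ctg_class.value, cls.reasons)           # II ['late-decelerations-present']

# the classifier and its parameter budget
model, report = ck.build_model(ck.ModelConfig(num_classes=1000), ck.SKConfig())
print(report["base_millions"], report["sk_millions"], report["total_millions"])
# 7.98 0.32 8.3
```

The digitization error is bounded by one pixel row of the value band
(150/288 ≈ 0.52 bpm for FHR, 100/142 ≈ 0.70 mmHg for UC); the class II
call comes from the detected late deceleration under otherwise normal
baseline and variability.

A CLI mirrors the library:

```bash
ctg simulate rec.csv --seed 7 --duration 584.75
ctg render rec.csv chart.png
ctg digitize chart.png extracted.csv
ctg classify-rules rec.csv
ctg model-summary --num-classes 1000
```

## Scope

The package analyses singleton FHR/UC strips. It does not model
maternal ECG artifacts or transducer physics, does not de-skew or OCR
real-world scans, and ships no pretrained weights — training runs on
the synthetic cohorts. See `docs/methods.md` for the model and its
assumptions.
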