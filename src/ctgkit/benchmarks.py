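"""Standard self-contained benchmarks: fixed study conditions, seeded.

These routines wire the synthetic generator, digitizer, rule engine and
classifier together at the problem sizes the package uses for its
built-in verification: a paper-scale digitization round trip, a
100-record event-recovery sweep, a 200-chart trainability benchmark, and
the bimodal-vs-FHR-only ablation on timing-defined abnormality. Tests
and the acceptance script both call these entry points so the measured
conditions are identical.
"""

from __future__ import annotations

import numpy as np

from .evaluate import (
    TrainConfig,
    compute_metrics,
    labels_to_ints,
    predict,
    prepare_inputs,
    split_dataset,
    train,
)
from .layout import ChartLayout
from .model import ModelConfig, SKConfig, build_model
from .rules import event_recovery
from .synth import (
    make_event_fixture,
    make_separable_dataset,
    make_timing_dataset,
    render_chart,
    simulate_record,
)
from .records import SimParams

__all__ = [
    "compact_model_config",
    "roundtrip_benchmark",
    "recovery_benchmark",
    "smoke_benchmark",
    "bimodal_benchmark",
]


def compact_model_config() -> ModelConfig:
    """Reduced DenseNet-SK for chart-scale experiments on one CPU."""
    return ModelConfig(growth_rate=16, block_layout=(2, 2, 2), num_classes=2, in_channels=1)


# ----------------------------------------------------------------------
def roundtrip_benchmark(n_records: int = 50, seed: int = 0) -> dict:
    """Render seeded records at paper scale and re-extract them.

    Returns the maximum absolute FHR/UC error over valid columns and
    whether gap positions were preserved exactly, across ``n_records``
    simulated strips (including occasional signal-loss gaps).
    """
    from .digitize import extract_signals

    layout = ChartLayout()  # paper-scale: 1653 x 2339, 1 column per sample
    duration = layout.width_px * layout.seconds_per_column
    rng = np.random.default_rng(seed)
    max_fhr = max_uc = 0.0
    gaps_ok = True
    for _ in range(n_records):
        gap_spec = {}
        if rng.random() < 0.5:
            start = float(rng.uniform(30, duration - 90))
            gap_spec["fhr"] = [(start, start + float(rng.uniform(10, 45)))]
        if rng.random() < 0.3:
            start = float(rng.uniform(30, duration - 90))
            gap_spec["uc"] = [(start, start + float(rng.uniform(10, 45)))]
        params = SimParams(
            baseline_bpm=float(rng.uniform(115, 155)),
            variability_amp=float(rng.uniform(4, 18)),
            contraction_rate=float(rng.uniform(3, 5)),
            duration_s=duration,
            seed=int(rng.integers(2**31)),
            gap_spec=gap_spec,
        )
        rec = simulate_record(params)
        img = render_chart(rec, layout)
        fhr, uc, fhr_gap, uc_gap = extract_signals(img)
        n = min(len(fhr), rec.n_samples)
        gaps_ok &= bool(np.array_equal(fhr_gap[:n], ~rec.fhr_valid[:n]))
        gaps_ok &= bool(np.array_equal(uc_gap[:n], ~rec.uc_valid[:n]))
        vf = rec.fhr_valid[:n]
        vu = rec.uc_valid[:n]
        if vf.any():
            max_fhr = max(max_fhr, float(np.max(np.abs(fhr[:n][vf] - rec.fhr[:n][vf]))))
        if vu.any():
            max_uc = max(max_uc, float(np.max(np.abs(uc[:n][vu] - rec.uc[:n][vu]))))
    return {
        "n_records": n_records,
        "max_fhr_error_bpm": max_fhr,
        "max_uc_error_mmhg": max_uc,
        "fhr_quantization_step": layout.fhr_step,
        "uc_quantization_step": layout.uc_step,
        "gaps_exact": gaps_ok,
    }


def recovery_benchmark(n_records: int = 100, seed: int = 0) -> dict:
    """Injected-event kind recovery over seeded fixtures (edge-margin 1 min)."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_records):
        rec = make_event_fixture(seed=int(rng.integers(2**31)))
        h, t = event_recovery(rec)
        hits += h
        total += t
    return {
        "n_records": n_records,
        "events_scored": total,
        "events_recovered": hits,
        "recovery_rate_pct": 100.0 * hits / max(total, 1),
    }


# ----------------------------------------------------------------------
_SMOKE_LAYOUT = dict(duration_s=1800.0, width_px=128, height_px=96)


def smoke_benchmark(seed: int = 7, n_records: int = 200, epochs: int = 10) -> dict:
    """Train the compact DenseNet-SK on separable classes; 7:3 split.

    Uses the standard hyperparameters (Adam, lr 0.001, batch 32, focal
    loss) for ``epochs`` epochs and reports held-out accuracy and AUC.
    """
    layout = ChartLayout.compact(**_SMOKE_LAYOUT)
    data = make_separable_dataset(n_records, seed=seed, layout=layout,
                                  duration_s=_SMOKE_LAYOUT["duration_s"])
    tr, te = split_dataset(data, (0.7, 0.3), seed=seed)
    Xtr = prepare_inputs([img for img, _ in tr])
    Xte = prepare_inputs([img for img, _ in te])
    ytr, yte = labels_to_ints(tr), labels_to_ints(te)
    model, _ = build_model(compact_model_config(), SKConfig(), seed=seed)
    model, history = train(model, (Xtr, ytr), TrainConfig(epochs=epochs, seed=seed),
                           val_data=(Xte, yte))
    pred, score = predict(model, Xte)
    report = compute_metrics(yte, pred, score)
    return {
        "n_train": len(ytr),
        "n_test": len(yte),
        "holdout_accuracy": report.accuracy,
        "holdout_auc": report.auc,
        "loss_history": history["loss"],
        "val_accuracy_history": history["val_accuracy"],
    }


_TIMING = dict(duration_s=960.0, width_px=160, height_px=64, lag_s=55.0)


def bimodal_benchmark(seed: int = 1, n_records: int = 160, epochs: int = 16) -> dict:
    """Bimodal vs FHR-only (UC band masked) AUC on timing-defined abnormals.

    The abnormal class differs from normal *only* in deceleration timing
    relative to the contraction peak (late vs early), so masking the UC
    band removes the discriminative information.
    """
    layout = ChartLayout.compact(duration_s=_TIMING["duration_s"],
                                 width_px=_TIMING["width_px"],
                                 height_px=_TIMING["height_px"])
    data = make_timing_dataset(n_records, seed=seed, layout=layout,
                               duration_s=_TIMING["duration_s"], lag_s=_TIMING["lag_s"])
    tr, te = split_dataset(data, (0.7, 0.3), seed=seed)
    ytr, yte = labels_to_ints(tr), labels_to_ints(te)
    out: dict = {"n_train": len(ytr), "n_test": len(yte)}
    for key, mask in (("auc_bimodal", False), ("auc_fhr_only", True)):
        Xtr = prepare_inputs([img for img, _ in tr], mask_uc=mask)
        Xte = prepare_inputs([img for img, _ in te], mask_uc=mask)
        model, _ = build_model(compact_model_config(), SKConfig(), seed=seed)
        model, _hist = train(model, (Xtr, ytr), TrainConfig(epochs=epochs, seed=seed),
                             val_data=(Xte, yte))
        pred, score = predict(model, Xte)
        report = compute_metrics(yte, pred, score)
        out[key] = report.auc
        out[key.replace("auc", "accuracy")] = report.accuracy
    return out
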