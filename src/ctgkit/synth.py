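"""Synthetic cardiotocography: paired FHR/UC traces and chart rendering.

The generator produces records carrying the standard intrapartum event
vocabulary — accelerations, early/late/variable decelerations, sinusoidal
windows, contractions, tachy-/bradycardia segments — with ground-truth
annotations, and renders them into the band layout the digitizer expects.
Everything is driven by a single integer seed and is bit-reproducible.

Signal model
------------
FHR = baseline + band-limited variability + event excursions. Variability
is beat-scale jitter (0.5-1.5 Hz) plus slow wander, rescaled so the median
per-minute peak-to-trough amplitude equals ``variability_amp``. UC is a
resting tone plus raised-cosine contraction bumps. Decelerations are
timed relative to a target contraction's peak: early = nadir at the peak,
late = nadir delayed, variable = abrupt (<30 s onset-to-nadir) dip.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .layout import ChartImage, ChartLayout
from .records import (
    FHR_RANGE,
    UC_RANGE,
    BinaryLabel,
    CTGClass,
    CTGRecord,
    EventAnnotation,
    EventKind,
    SimParams,
)

__all__ = [
    "simulate_record",
    "inject_deceleration",
    "inject_sinusoidal",
    "render_chart",
    "make_dataset",
    "make_timing_dataset",
]


# ----------------------------------------------------------------------
# building blocks
def _variability(n: int, fs: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited fluctuation with per-minute peak-to-trough ~= amp bpm."""
    if amp <= 0 or n < 8:
        return np.zeros(n)
    jitter = rng.standard_normal(n)
    sos = sps.butter(2, [0.5, 1.5], btype="bandpass", fs=fs, output="sos")
    jitter = sps.sosfiltfilt(sos, jitter)
    wander = rng.standard_normal(n)
    sos_lo = sps.butter(2, 0.03, btype="lowpass", fs=fs, output="sos")
    wander = sps.sosfiltfilt(sos_lo, wander)
    raw = jitter / (np.std(jitter) + 1e-12) + 1.2 * wander / (np.std(wander) + 1e-12)
    win = max(int(60 * fs), 8)
    nwin = max(n // win, 1)
    ptps = [np.ptp(raw[i * win : (i + 1) * win]) for i in range(nwin)]
    scale = amp / (np.median(ptps) + 1e-12)
    return raw * scale


def _half_cosine_bump(t: np.ndarray, onset: float, peak: float, end: float) -> np.ndarray:
    """Unit-height smooth bump rising over [onset, peak], falling over [peak, end]."""
    out = np.zeros_like(t)
    rise = (t >= onset) & (t <= peak)
    fall = (t > peak) & (t <= end)
    if peak > onset:
        out[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - onset) / (peak - onset)))
    else:
        out[t == peak] = 1.0
    if end > peak:
        out[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - peak) / (end - peak)))
    return out


def _place_contractions(params: SimParams, rng: np.random.Generator):
    """Non-overlapping raised-cosine bumps at ~contraction_rate per 10 min."""
    n_contr = int(round(params.contraction_rate * params.duration_s / 600.0))
    events: list[EventAnnotation] = []
    if n_contr == 0:
        return events
    slot = params.duration_s / n_contr
    lo_d, hi_d = params.contraction_duration
    lo_a, hi_a = params.contraction_amplitude
    for i in range(n_contr):
        dur = rng.uniform(lo_d, hi_d)
        amp = rng.uniform(lo_a, hi_a)
        center = (i + 0.5) * slot + rng.uniform(-0.15, 0.15) * slot
        onset = max(0.0, center - dur / 2)
        end = min(params.duration_s, center + dur / 2)
        if end - onset < 30:
            continue
        events.append(
            EventAnnotation(
                kind=EventKind.CONTRACTION,
                onset_s=onset,
                nadir_or_peak_s=(onset + end) / 2,
                end_s=end,
                magnitude=amp,
            )
        )
    return events


def _fhr_events_overlap(events, new: EventAnnotation) -> EventAnnotation | None:
    fhr_kinds = {
        EventKind.ACCELERATION,
        EventKind.PROLONGED_ACCELERATION,
        EventKind.EARLY_DECEL,
        EventKind.LATE_DECEL,
        EventKind.VARIABLE_DECEL,
        EventKind.SINUSOIDAL,
    }
    for e in events:
        if e.kind in fhr_kinds and e.overlaps(new):
            return e
    return None


# ----------------------------------------------------------------------
def simulate_record(params: SimParams) -> CTGRecord:
    """Generate a CTGRecord from generator controls.

    Contractions are placed first; requested FHR events (see
    ``SimParams.event_requests``) are then injected in order. Overlapping
    FHR event requests are rejected. Identical params (including seed)
    yield bit-identical records.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    contractions = _place_contractions(params, rng)
    uc = np.full(n, params.resting_tone, dtype=float)
    for e in contractions:
        uc += e.magnitude * _half_cosine_bump(t, e.onset_s, e.nadir_or_peak_s, e.end_s)

    fhr = params.baseline_bpm + _variability(n, params.fs, params.variability_amp, rng)

    record = CTGRecord(
        fhr=np.clip(fhr, *FHR_RANGE),
        uc=np.clip(uc, *UC_RANGE),
        fhr_valid=np.ones(n, bool),
        uc_valid=np.ones(n, bool),
        fs=params.fs,
        gestational_age=params.gestational_age,
        events=contractions,
    )

    for kind, kw in params.event_requests:
        kind = EventKind(kind)
        kw = dict(kw)
        try:
            if kind in (EventKind.EARLY_DECEL, EventKind.LATE_DECEL, EventKind.VARIABLE_DECEL):
                record = inject_deceleration(record, kind, **kw)
            elif kind == EventKind.SINUSOIDAL:
                record = inject_sinusoidal(record, **kw)
            elif kind in (EventKind.ACCELERATION, EventKind.PROLONGED_ACCELERATION):
                record = _inject_acceleration(record, kind, **kw)
            elif kind in (EventKind.TACHYCARDIA_SEGMENT, EventKind.BRADYCARDIA_SEGMENT):
                record = _inject_baseline_segment(record, kind, **kw)
            else:
                raise ValueError(f"unsupported event request kind: {kind}")
        except ValueError as err:
            skippable = "overlaps existing" in str(err) or "does not fit" in str(err)
            if not (params.skip_conflicts and skippable):
                raise

    for channel, spans in params.gap_spec.items():
        mask = record.fhr_valid if channel == "fhr" else record.uc_valid
        for start_s, end_s in spans:
            i0, i1 = record.sample_index(start_s), record.sample_index(end_s)
            mask[i0:i1] = False

    return record


def _inject_acceleration(
    record: CTGRecord,
    kind: EventKind,
    at_s: float,
    height: float = 20.0,
    duration_s: float = 30.0,
    onset_to_peak_s: float | None = None,
) -> CTGRecord:
    """Superpose a smooth unimodal acceleration (onset-to-peak < 30 s)."""
    if height <= 0:
        raise ValueError("acceleration height must be positive")
    if kind == EventKind.ACCELERATION and not duration_s < 120:
        raise ValueError("a plain acceleration lasts < 2 min")
    if kind == EventKind.PROLONGED_ACCELERATION and not (120 <= duration_s < 600):
        raise ValueError("a prolonged acceleration lasts >= 2 min but < 10 min")
    rise = onset_to_peak_s if onset_to_peak_s is not None else min(duration_s / 2, 20.0)
    if rise >= 30:
        raise ValueError("acceleration onset-to-peak time must be < 30 s")
    rec = record.copy()
    onset, end = at_s, at_s + duration_s
    peak = onset + rise
    ann = EventAnnotation(kind, onset, peak, end, height)
    if end > rec.duration_s:
        raise ValueError("acceleration does not fit in the record")
    clash = _fhr_events_overlap(rec.events, ann)
    if clash is not None:
        raise ValueError(f"acceleration at {at_s}s overlaps existing {clash.kind.value}")
    rec.fhr = np.clip(rec.fhr + height * _half_cosine_bump(rec.time_s, onset, peak, end), *FHR_RANGE)
    rec.events.append(ann)
    return rec


def _inject_baseline_segment(
    record: CTGRecord, kind: EventKind, start_s: float, end_s: float, level: float | None = None
) -> CTGRecord:
    """Shift the baseline to a tachy-/bradycardic level over [start_s, end_s]."""
    if end_s - start_s < 600:
        raise ValueError("a baseline segment must be sustained >= 10 min")
    if level is None:
        level = 170.0 if kind == EventKind.TACHYCARDIA_SEGMENT else 100.0
    if kind == EventKind.TACHYCARDIA_SEGMENT and level <= 160:
        raise ValueError("tachycardia requires a baseline > 160 bpm")
    if kind == EventKind.BRADYCARDIA_SEGMENT and level >= 110:
        raise ValueError("bradycardia requires a baseline < 110 bpm")
    rec = record.copy()
    t = rec.time_s
    ramp = 30.0
    w = np.clip((t - start_s) / ramp, 0, 1) * np.clip((end_s - t) / ramp, 0, 1)
    w = np.minimum(w, 1.0)
    base = np.median(rec.fhr)
    rec.fhr = np.clip(rec.fhr + (level - base) * w, *FHR_RANGE)
    rec.events.append(
        EventAnnotation(kind, start_s, (start_s + end_s) / 2, end_s, abs(level - base))
    )
    return rec


def inject_deceleration(
    record: CTGRecord,
    kind: EventKind | str,
    contraction_index: int,
    depth: float,
    duration_s: float = 80.0,
    lag_s: float = 30.0,
    onset_to_nadir_s: float = 10.0,
) -> CTGRecord:
    """Superpose a deceleration timed against a target contraction.

    * early: symmetric gradual dip, nadir aligned with the contraction peak,
      onset-to-nadir (= duration/2) >= 30 s;
    * late: as early but nadir ``lag_s`` seconds *after* the peak;
    * variable: abrupt dip — onset-to-nadir < 30 s, depth >= 15 bpm,
      total duration in [15 s, 120 s).
    """
    kind = EventKind(kind)
    contractions = record.events_of_kind(EventKind.CONTRACTION)
    if not (0 <= contraction_index < len(contractions)):
        raise ValueError(
            f"contraction_index {contraction_index} out of range "
            f"({len(contractions)} contractions present)"
        )
    if depth <= 0:
        raise ValueError("deceleration depth must be positive")
    peak_t = contractions[contraction_index].nadir_or_peak_s

    if kind in (EventKind.EARLY_DECEL, EventKind.LATE_DECEL):
        if duration_s / 2 < 30:
            raise ValueError("a gradual deceleration needs onset-to-nadir >= 30 s")
        nadir_t = peak_t if kind == EventKind.EARLY_DECEL else peak_t + lag_s
        if kind == EventKind.LATE_DECEL and lag_s <= 0:
            raise ValueError("a late deceleration needs a positive lag after the peak")
        onset, end = nadir_t - duration_s / 2, nadir_t + duration_s / 2
    else:  # variable
        if depth < 15:
            raise ValueError("a variable deceleration requires a decline >= 15 bpm")
        if not onset_to_nadir_s < 30:
            raise ValueError("a variable deceleration has onset-to-nadir < 30 s")
        if not (15 <= duration_s < 120):
            raise ValueError("variable deceleration duration must be in [15 s, 120 s)")
        nadir_t = peak_t + lag_s if lag_s else peak_t
        onset, end = nadir_t - onset_to_nadir_s, nadir_t + (duration_s - onset_to_nadir_s)

    if onset < 0 or end > record.duration_s:
        raise ValueError("deceleration does not fit in the record")
    ann = EventAnnotation(kind, onset, nadir_t, end, depth)
    rec = record.copy()
    clash = _fhr_events_overlap(rec.events, ann)
    if clash is not None:
        raise ValueError(
            f"{kind.value} on contraction {contraction_index} overlaps existing {clash.kind.value}"
        )
    rec.fhr = np.clip(rec.fhr - depth * _half_cosine_bump(rec.time_s, onset, nadir_t, end), *FHR_RANGE)
    rec.events.append(ann)
    return rec


def inject_sinusoidal(
    record: CTGRecord,
    cycles_per_min: float,
    duration_s: float,
    start_s: float = 0.0,
    amplitude: float = 8.0,
) -> CTGRecord:
    """Replace a window with a smooth sinusoid about the local baseline.

    The pattern requires 3-5 cycles/min and >= 20 min duration;
    accelerations inside the window are suppressed (annotations removed,
    signal overwritten).
    """
    if not 3 <= cycles_per_min <= 5:
        raise ValueError("sinusoidal pattern requires 3-5 cycles/min")
    if duration_s < 1200:
        raise ValueError("sinusoidal pattern must last >= 20 min (1200 s)")
    end_s = start_s + duration_s
    if start_s < 0 or end_s > record.duration_s:
        raise ValueError("sinusoidal window does not fit in the record")
    rec = record.copy()
    i0, i1 = rec.sample_index(start_s), rec.sample_index(end_s)
    local_base = float(np.median(rec.fhr[i0:i1]))
    t = rec.time_s[i0:i1]
    rec.fhr[i0:i1] = local_base + amplitude * np.sin(2 * np.pi * (cycles_per_min / 60.0) * (t - start_s))
    rec.fhr = np.clip(rec.fhr, *FHR_RANGE)
    ann = EventAnnotation(EventKind.SINUSOIDAL, start_s, (start_s + end_s) / 2, end_s, amplitude)
    accel_kinds = (EventKind.ACCELERATION, EventKind.PROLONGED_ACCELERATION)
    rec.events = [e for e in rec.events if not (e.kind in accel_kinds and e.overlaps(ann))]
    rec.events.append(ann)
    return rec


# ----------------------------------------------------------------------
def render_chart(record: CTGRecord, layout: ChartLayout, pen: int = 1) -> ChartImage:
    """Draw a record onto a paper-style strip.

    Each valid sample is mapped to a column via the layout time scale and
    to a row via the inverse affine value template; invalid samples leave
    grid-only columns. Values outside the clinical range are clipped to
    the band edge and counted in the render report.
    """
    H, W = layout.height_px, layout.width_px
    img = np.full((H, W), layout.background_intensity, dtype=np.uint8)
    img[:: layout.grid_row_step, :] = layout.grid_intensity
    img[:, :: layout.grid_col_step] = layout.grid_intensity

    report = {"clipped_fhr": 0, "clipped_uc": 0, "truncated_samples": 0,
              "blank_fhr_columns": 0, "blank_uc_columns": 0}
    cols_all = layout.column_of_time(record.time_s)
    in_range = cols_all < W
    report["truncated_samples"] = int((~in_range).sum())

    channels = (
        (record.fhr, record.fhr_valid, layout.row_of_fhr_value, layout.fhr_range,
         "clipped_fhr", "blank_fhr_columns"),
        (record.uc, record.uc_valid, layout.row_of_uc_value, layout.uc_range,
         "clipped_uc", "blank_uc_columns"),
    )
    for series, valid, row_of, (lo, hi), clip_key, blank_key in channels:
        use = valid & in_range
        vals = series[use]
        report[clip_key] = int(((vals < lo) | (vals > hi)).sum())
        rows = np.round(row_of(vals)).astype(int)
        cols = cols_all[use]
        for k in range(pen):
            rr = np.clip(rows + (k - pen // 2), 0, H - 1)
            img[rr, cols] = layout.trace_intensity
        drawn = np.zeros(W, bool)
        drawn[cols] = True
        report[blank_key] = int((~drawn).sum())

    return ChartImage(pixels=img, layout=layout, report=report)


# ----------------------------------------------------------------------
# dataset factories
def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _class_i_params(rng, duration_s, fs):
    p = SimParams(
        baseline_bpm=float(np.clip(rng.normal(142, 8), 115, 155)),
        variability_amp=float(rng.uniform(8, 15)),
        contraction_rate=float(rng.uniform(3, 4.5)),
        duration_s=duration_s,
        fs=fs,
        seed=int(rng.integers(2**31)),
        skip_conflicts=True,
    )
    reqs = []
    n_contr = int(round(p.contraction_rate * duration_s / 600))
    for at in rng.uniform(0.1, 0.9, size=rng.integers(1, 3)) * duration_s:
        reqs.append(("acceleration", {"at_s": float(at), "height": float(rng.uniform(16, 24)),
                                      "duration_s": float(rng.uniform(20, 50))}))
    if n_contr >= 2 and rng.random() < 0.5:
        reqs.append(("early_decel", {"contraction_index": int(rng.integers(1, n_contr - 1)),
                                     "depth": float(rng.uniform(20, 30)),
                                     "duration_s": float(rng.uniform(80, 95))}))
    p.event_requests = reqs
    return p


def _class_ii_params(rng, duration_s, fs):
    variant = rng.integers(3)
    seed = int(rng.integers(2**31))
    if variant == 0:  # minimal variability, nothing else
        return SimParams(baseline_bpm=float(rng.uniform(120, 150)),
                         variability_amp=float(rng.uniform(2.5, 4.5)),
                         contraction_rate=3.5, duration_s=duration_s, fs=fs, seed=seed)
    if variant == 1:  # tachycardic baseline
        return SimParams(baseline_bpm=float(rng.uniform(166, 178)),
                         variability_amp=float(rng.uniform(8, 14)),
                         contraction_rate=3.5, duration_s=duration_s, fs=fs, seed=seed)
    # moderate variability with late decelerations (not recurrent-with-absent-var)
    p = SimParams(baseline_bpm=float(rng.uniform(125, 150)),
                  variability_amp=float(rng.uniform(8, 13)),
                  contraction_rate=4.0, duration_s=duration_s, fs=fs, seed=seed)
    p.skip_conflicts = True
    n_contr = int(round(p.contraction_rate * duration_s / 600))
    inner = np.arange(1, max(n_contr - 1, 2))
    idx = rng.choice(inner, size=max(1, len(inner) // 2), replace=False)
    p.event_requests = [("late_decel", {"contraction_index": int(i),
                                        "depth": float(rng.uniform(20, 32)),
                                        "duration_s": float(rng.uniform(65, 85)),
                                        "lag_s": float(rng.uniform(25, 45))}) for i in sorted(idx)]
    return p


def _class_iii_params(rng, duration_s, fs):
    variant = rng.integers(3)
    seed = int(rng.integers(2**31))
    if variant == 0 and duration_s >= 1500:  # sinusoidal
        return SimParams(
            baseline_bpm=float(rng.uniform(125, 150)), variability_amp=0.0,
            contraction_rate=3.0, duration_s=duration_s, fs=fs, seed=seed,
            event_requests=[("sinusoidal", {"cycles_per_min": float(rng.uniform(3.2, 4.8)),
                                            "duration_s": float(min(duration_s, rng.uniform(1250, 1500))),
                                            "start_s": 0.0,
                                            "amplitude": float(rng.uniform(6, 10))})])
    p = SimParams(baseline_bpm=float(rng.uniform(125, 150)),
                  variability_amp=float(rng.uniform(0.0, 1.0)),
                  contraction_rate=4.0, duration_s=duration_s, fs=fs, seed=seed)
    p.skip_conflicts = True
    n_contr = int(round(p.contraction_rate * duration_s / 600))
    kind = "late_decel" if variant != 2 else "variable_decel"
    reqs = []
    for i in range(1, max(n_contr - 1, 2)):  # recurrent: on every inner contraction
        if kind == "late_decel":
            reqs.append((kind, {"contraction_index": i, "depth": float(rng.uniform(22, 35)),
                                "duration_s": float(rng.uniform(65, 85)),
                                "lag_s": float(rng.uniform(25, 45))}))
        else:
            reqs.append((kind, {"contraction_index": i, "depth": float(rng.uniform(20, 40)),
                                "duration_s": float(rng.uniform(40, 70)),
                                "onset_to_nadir_s": float(rng.uniform(5, 15))}))
    p.event_requests = reqs
    return p


_CLASS_RECIPES = {CTGClass.I: _class_i_params, CTGClass.II: _class_ii_params,
                  CTGClass.III: _class_iii_params}


def make_dataset(
    n_records: int,
    class_mix: tuple[float, float, float],
    seed: int,
    layout: ChartLayout | None = None,
    duration_s: float = 1800.0,
    fs: float = 4.0,
    render: bool = True,
) -> list[tuple[ChartImage | None, CTGRecord]]:
    """Stratified synthetic cohort with ground-truth class per record.

    ``class_mix`` gives (Class I, Class II, Class III) proportions and must
    sum to 1; counts use largest-remainder rounding. Binary labels follow
    the default policy (I -> normal; II, III -> abnormal).
    """
    if n_records <= 0:
        raise ValueError("n_records must be positive")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must be three proportions summing to 1")
    if layout is None and render:
        layout = ChartLayout.compact(duration_s=duration_s)
    rng = np.random.default_rng(seed)
    counts = _largest_remainder(n_records, mix)
    labels = sum(([c] * k for c, k in zip(CTGClass, counts)), [])
    order = rng.permutation(n_records)
    out = []
    for pos in order:
        cls = labels[pos]
        params = _CLASS_RECIPES[cls](rng, duration_s, fs)
        rec = simulate_record(params)
        rec.figo_class = cls
        rec.binary_label = BinaryLabel.NORMAL if cls == CTGClass.I else BinaryLabel.ABNORMAL
        img = render_chart(rec, layout) if render else None
        out.append((img, rec))
    return out


def make_separable_dataset(
    n_records: int,
    seed: int,
    layout: ChartLayout | None = None,
    duration_s: float = 1800.0,
    abnormal_fraction: float = 0.31,
    fs: float = 4.0,
) -> list[tuple[ChartImage, CTGRecord]]:
    """Visually separable two-class cohort for trainability benchmarks.

    Normal records are Class I strips (baseline near 142 bpm, moderate
    variability). Abnormal records carry gross, position/shape-level
    pathology — tachycardic (>165 bpm) or bradycardic (<105 bpm)
    baselines, or absent variability with deep recurrent late
    decelerations — the patterns a reader separates at a glance.
    """
    if n_records <= 0:
        raise ValueError("n_records must be positive")
    if layout is None:
        layout = ChartLayout.compact(duration_s=duration_s)
    rng = np.random.default_rng(seed)
    n_abn = int(round(abnormal_fraction * n_records))
    out = []
    for i in range(n_records):
        abnormal = i < n_abn
        seed_i = int(rng.integers(2**31))
        if not abnormal:
            p = _class_i_params(rng, duration_s, fs)
            p.seed = seed_i
            cls = CTGClass.I
        else:
            variant = rng.integers(3)
            if variant == 0:
                p = SimParams(baseline_bpm=float(rng.uniform(168, 180)),
                              variability_amp=float(rng.uniform(8, 14)),
                              contraction_rate=3.5, duration_s=duration_s, fs=fs, seed=seed_i)
                cls = CTGClass.II
            elif variant == 1:
                p = SimParams(baseline_bpm=float(rng.uniform(95, 104)),
                              variability_amp=float(rng.uniform(0.0, 1.0)),
                              contraction_rate=3.5, duration_s=duration_s, fs=fs, seed=seed_i)
                cls = CTGClass.III
            else:
                p = SimParams(baseline_bpm=float(rng.uniform(125, 150)),
                              variability_amp=float(rng.uniform(0.0, 1.0)),
                              contraction_rate=4.0, duration_s=duration_s, fs=fs,
                              seed=seed_i, skip_conflicts=True)
                n_contr = int(round(p.contraction_rate * duration_s / 600))
                p.event_requests = [
                    ("late_decel", {"contraction_index": ci, "depth": float(rng.uniform(28, 40)),
                                    "duration_s": float(rng.uniform(80, 95)),
                                    "lag_s": float(rng.uniform(30, 45))})
                    for ci in range(1, max(n_contr - 1, 2))
                ]
                cls = CTGClass.III
        rec = simulate_record(p)
        rec.figo_class = cls
        rec.binary_label = BinaryLabel.ABNORMAL if abnormal else BinaryLabel.NORMAL
        out.append((render_chart(rec, layout), rec))
    rng.shuffle(out)
    return out


def make_event_fixture(seed: int, duration_s: float = 1800.0, fs: float = 4.0) -> CTGRecord:
    """One record with a randomized set of annotated events for detector checks.

    Carries 1-2 accelerations and 2 decelerations of random type on
    distinct contractions, under moderate variability; event geometry
    keeps the clinical margins (gradual decels with onset-to-nadir 40 s
    and up, abrupt ones 8-12 s) so ground truth is unambiguous.
    """
    rng = np.random.default_rng(seed)
    p = SimParams(
        baseline_bpm=float(np.clip(rng.normal(142, 8), 120, 155)),
        variability_amp=float(rng.uniform(5, 10)),
        contraction_rate=float(rng.uniform(3.5, 4.5)),
        duration_s=duration_s,
        fs=fs,
        seed=int(rng.integers(2**31)),
        skip_conflicts=True,
    )
    n_contr = int(round(p.contraction_rate * duration_s / 600))
    reqs: list[tuple] = []
    decel_targets = rng.choice(np.arange(1, n_contr - 1), size=2, replace=False)
    for ci in sorted(int(c) for c in decel_targets):
        kind = rng.choice(["early_decel", "late_decel", "variable_decel"])
        if kind == "variable_decel":
            reqs.append((kind, {"contraction_index": ci, "depth": float(rng.uniform(25, 40)),
                                "duration_s": float(rng.uniform(45, 60)),
                                "onset_to_nadir_s": float(rng.uniform(8, 12))}))
        elif kind == "late_decel":
            reqs.append((kind, {"contraction_index": ci, "depth": float(rng.uniform(22, 35)),
                                "duration_s": float(rng.uniform(80, 95)),
                                "lag_s": float(rng.uniform(35, 45))}))
        else:
            reqs.append((kind, {"contraction_index": ci, "depth": float(rng.uniform(22, 35)),
                                "duration_s": float(rng.uniform(80, 95))}))
    slot = duration_s / n_contr
    for _ in range(int(rng.integers(1, 3))):
        k = int(rng.integers(1, n_contr))
        at = k * slot - rng.uniform(10, 20)  # inter-contraction trough
        reqs.append(("acceleration", {"at_s": float(at), "height": float(rng.uniform(17, 25)),
                                      "duration_s": float(rng.uniform(25, 50))}))
    p.event_requests = reqs
    return simulate_record(p)


def make_timing_dataset(
    n_records: int,
    seed: int,
    layout: ChartLayout | None = None,
    duration_s: float = 960.0,
    lag_s: float = 50.0,
    fs: float = 4.0,
) -> list[tuple[ChartImage, CTGRecord]]:
    """Cohort whose abnormal class is defined *only* by FHR-UC timing.

    Normal records carry early decelerations (nadir at the contraction
    peak) on every contraction; abnormal records carry late decelerations
    (nadir ``lag_s`` seconds after the peak) of the same depth and shape.
    With the UC channel hidden the two classes are statistically
    indistinguishable, which is the bimodal-vs-unimodal test bed.
    """
    if layout is None:
        layout = ChartLayout.compact(duration_s=duration_s)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_records):
        abnormal = i >= n_records // 2
        p = SimParams(
            baseline_bpm=float(np.clip(rng.normal(142, 8), 120, 155)),
            variability_amp=float(rng.uniform(6, 10)),
            contraction_rate=float(rng.uniform(4.0, 5.0)),
            duration_s=duration_s,
            fs=fs,
            seed=int(rng.integers(2**31)),
            skip_conflicts=True,
        )
        n_contr = int(round(p.contraction_rate * duration_s / 600))
        reqs = []
        for ci in range(1, max(n_contr - 1, 2)):
            depth = float(rng.uniform(25, 40))
            dur = float(rng.uniform(65, 85))
            if abnormal:
                reqs.append(("late_decel", {"contraction_index": ci, "depth": depth,
                                            "duration_s": dur, "lag_s": lag_s}))
            else:
                reqs.append(("early_decel", {"contraction_index": ci, "depth": depth,
                                             "duration_s": dur}))
        p.event_requests = reqs
        rec = simulate_record(p)
        rec.binary_label = BinaryLabel.ABNORMAL if abnormal else BinaryLabel.NORMAL
        rec.figo_class = CTGClass.II if abnormal else CTGClass.I
        out.append((render_chart(rec, layout), rec))
    return out
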