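"""Deterministic FIGO-style interpretation of CTG records.

Implements the standard intrapartum vocabulary — baseline, variability,
accelerations, early/late/variable decelerations, sinusoidal pattern,
contraction frequency — and the three-tier Class I/II/III read-out, with
the deceleration-vs-contraction timing logic that makes the UC channel
indispensable for early/late typing.

Algorithmic choices (the clinical definitions give criteria, not
algorithms): the baseline is the histogram mode of valid samples refined
to the mean of excursion-free stable segments; excursions are detected
against that mode on a lightly smoothed trace and extended out to their
baseline crossings; variability is the median per-minute peak-to-trough
amplitude over event-free windows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import (
    BinaryLabel,
    CTGClass,
    CTGRecord,
    EventAnnotation,
    EventKind,
)

__all__ = [
    "BaselineEstimate",
    "VariabilityLevel",
    "VariabilityClass",
    "Classification",
    "DecelerationReport",
    "ContractionStats",
    "estimate_baseline",
    "classify_variability",
    "detect_accelerations",
    "detect_decelerations",
    "detect_sinusoidal",
    "contraction_stats",
    "classify_ctg",
    "to_binary",
    "detect_events",
    "event_recovery",
]

#: tolerance (s) for calling a deceleration nadir "coincident" with a contraction peak
ED_ALIGN_TOL_S = 10.0
#: fraction of contractions that must carry a deceleration type to call it recurrent
RECURRENT_FRACTION = 0.5


# ----------------------------------------------------------------------
# result containers
@dataclass
class BaselineEstimate:
    value: float | None
    stable_segments: list[tuple[float, float]]
    tachycardia: bool
    bradycardia: bool
    indeterminate: bool = False


class VariabilityLevel(str, enum.Enum):
    ABSENT = "absent"
    MINIMAL = "minimal"
    MODERATE = "moderate"
    MARKED = "marked"


@dataclass
class VariabilityClass:
    level: VariabilityLevel | None
    amplitude_bpm: float | None
    indeterminate: bool = False


@dataclass
class DecelerationReport:
    events: list[EventAnnotation] = field(default_factory=list)
    indeterminate: list[tuple[float, float, float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def of_kind(self, kind: EventKind) -> list[EventAnnotation]:
        return [e for e in self.events if e.kind == kind]


@dataclass
class ContractionStats:
    rate_per_10min: float | None
    tachysystole: bool
    n_contractions: int
    peak_times_s: list[float]
    low_confidence: bool = False
    indeterminate: bool = False


@dataclass
class Classification:
    ctg_class: CTGClass
    reasons: list[str]
    baseline: BaselineEstimate | None = None
    variability: VariabilityClass | None = None
    accelerations: list[EventAnnotation] = field(default_factory=list)
    decelerations: DecelerationReport | None = None
    sinusoidal: bool = False
    contractions: ContractionStats | None = None


# ----------------------------------------------------------------------
# helpers
def _smooth(x: np.ndarray, mask: np.ndarray, fs: float, span_s: float = 2.0) -> np.ndarray:
    """Moving average that ignores invalid samples."""
    w = max(int(span_s * fs), 1)
    kern = np.ones(w)
    num = np.convolve(np.where(mask, x, 0.0), kern, mode="same")
    den = np.convolve(mask.astype(float), kern, mode="same")
    out = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
    return out


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i0, i1) index runs of consecutive True."""
    if not flags.any():
        return []
    d = np.diff(flags.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        ends.append(len(flags))
    return list(zip(starts, ends))


def _mode_bpm(values: np.ndarray) -> float:
    """Smoothed-histogram mode with 1-bpm bins (robust to decel sweeps)."""
    hist, edges = np.histogram(values, bins=np.arange(55.0, 216.0, 1.0))
    hist = np.convolve(hist, np.array([1, 2, 3, 2, 1], float), mode="same")
    k = int(np.argmax(hist))
    return float((edges[k] + edges[k + 1]) / 2)


def _find_excursions(
    x: np.ndarray,
    mask: np.ndarray,
    reference: float,
    sign: float,
    enter_bpm: float,
    exit_bpm: float,
    fs: float,
    span_s: float = 2.0,
):
    """Sustained departures from the reference level in one direction.

    Regions where the smoothed signed deviation exceeds ``enter_bpm`` are
    grown outward to their ``exit_bpm`` crossings, then nearby regions are
    merged. The peak is the center of the near-maximal plateau (top 15%
    of the excursion height), which is far more noise-stable than a raw
    argmax. Returns (i0, i1, peak_idx, height) tuples with half-open
    sample bounds.
    """
    sm = _smooth(x, mask, fs, span_s)
    dev = sign * (sm - reference)
    dev = np.where(mask & np.isfinite(dev), dev, -np.inf)
    core = dev > enter_bpm
    regions = _runs(core)
    # grow to exit threshold
    grown = []
    n = len(x)
    for i0, i1 in regions:
        while i0 > 0 and dev[i0 - 1] > exit_bpm:
            i0 -= 1
        while i1 < n and dev[i1] > exit_bpm:
            i1 += 1
        grown.append((i0, i1))
    # merge overlapping / nearly touching (< 5 s apart)
    gap = int(5 * fs)
    merged: list[list[int]] = []
    for i0, i1 in sorted(grown):
        if merged and i0 <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], i1)
        else:
            merged.append([i0, i1])
    fine = sign * (_smooth(x, mask, fs, 1.0) - reference)  # height read on light smoothing
    out = []
    for i0, i1 in merged:
        seg = dev[i0:i1]
        smax = float(seg.max())
        top = np.where(seg >= 0.85 * smax)[0]
        peak = i0 + int(round(top.mean())) if top.size else i0 + int(np.argmax(seg))
        height = float(np.nanmax(fine[i0:i1]))
        out.append((i0, i1, peak, height))
    return out


# ----------------------------------------------------------------------
def estimate_baseline(fhr: np.ndarray, mask: np.ndarray, fs: float = 4.0) -> BaselineEstimate:
    """Baseline as the mean over stable (excursion-free) segments >= 2 min.

    Tachy-/bradycardia are flagged when the windowed baseline (10-min
    windows, 1-min step) stays above 160 / below 110 bpm. Requires at
    least 10 min of valid signal, otherwise the result is indeterminate.
    """
    fhr = np.asarray(fhr, float)
    mask = np.asarray(mask, bool)
    n = len(fhr)
    if mask.sum() < 600 * fs:
        return BaselineEstimate(None, [], False, False, indeterminate=True)
    mode = _mode_bpm(fhr[mask])

    exc = np.zeros(n, bool)
    for sign in (+1.0, -1.0):
        for i0, i1, _pk, _h in _find_excursions(fhr, mask, mode, sign, 7.0, 2.0, fs):
            pad = int(10 * fs)
            exc[max(0, i0 - pad) : min(n, i1 + pad)] = True
    stable = mask & ~exc

    min_run = int(120 * fs)
    segments = [(i0 / fs, i1 / fs) for i0, i1 in _runs(stable) if i1 - i0 >= min_run]
    if segments:
        seg_mask = np.zeros(n, bool)
        for s, e in segments:
            seg_mask[int(s * fs) : int(e * fs)] = True
        value = float(fhr[seg_mask].mean())
        indeterminate = False
    elif stable.any():
        value = float(fhr[stable].mean())
        indeterminate = True
    else:
        return BaselineEstimate(None, [], False, False, indeterminate=True)

    # windowed sustained-level flags
    win, step = int(600 * fs), int(60 * fs)
    tachy = brady = False
    for start in range(0, max(n - win, 0) + 1, step):
        sl = slice(start, start + win)
        m = stable[sl] if stable[sl].sum() >= 0.3 * win else mask[sl]
        if m.sum() < 0.5 * win:
            continue
        vals = fhr[sl][m]
        wmode = _mode_bpm(vals)
        near = vals[np.abs(vals - wmode) <= 5]  # refine past 1-bpm bin granularity
        wlevel = float(near.mean()) if near.size else wmode
        tachy |= wlevel > 160.5  # 0.5 bpm measurement margin against wander
        brady |= wlevel < 109.5
    if n <= win:  # record shorter than/equal to one window
        tachy |= value > 160 and not indeterminate
        brady |= value < 110 and not indeterminate
    return BaselineEstimate(value, segments, tachy, brady, indeterminate)


def classify_variability(
    fhr: np.ndarray,
    mask: np.ndarray,
    fs: float = 4.0,
    exclude: list[tuple[float, float]] | None = None,
    window_s: float = 60.0,
) -> VariabilityClass:
    """Median per-minute peak-to-trough amplitude over event-free windows.

    ``exclude`` lists (start_s, end_s) intervals (accelerations,
    decelerations, sinusoidal windows) whose overlapping windows are
    dropped. Levels: absent < 1.5 bpm, minimal <= 5, moderate 6-25
    (boundary values up to 25), marked above.
    """
    fhr = np.asarray(fhr, float)
    mask = np.asarray(mask, bool)
    n = len(fhr)
    w = int(window_s * fs)
    drop = np.zeros(n, bool)
    for s, e in exclude or []:
        drop[max(0, int(s * fs)) : min(n, int(np.ceil(e * fs)))] = True
    amps = []
    for start in range(0, n - w + 1, w):
        sl = slice(start, start + w)
        if drop[sl].any():
            continue
        m = mask[sl]
        if m.sum() < 0.8 * w:
            continue
        amps.append(float(np.ptp(fhr[sl][m])))
    if not amps:
        return VariabilityClass(None, None, indeterminate=True)
    amp = float(np.median(amps))
    if amp < 1.5:
        level = VariabilityLevel.ABSENT
    elif amp <= 5.0:
        level = VariabilityLevel.MINIMAL
    elif amp <= 25.0:
        level = VariabilityLevel.MODERATE
    else:
        level = VariabilityLevel.MARKED
    return VariabilityClass(level, amp)


def detect_accelerations(
    fhr: np.ndarray,
    mask: np.ndarray,
    baseline: float,
    gestational_age: float = 34.0,
    fs: float = 4.0,
) -> list[EventAnnotation]:
    """Transient rises meeting the gestational-age-specific thresholds.

    >= 32 weeks: height >= 15 bpm for >= 15 s; before 32 weeks: >= 10 bpm
    for >= 10 s; both < 2 min and with onset-to-peak < 30 s. Excursions of
    2-10 min become prolonged accelerations; >= 10 min are left to
    baseline re-estimation.
    """
    fhr = np.asarray(fhr, float)
    mask = np.asarray(mask, bool)
    if gestational_age >= 32:
        min_height, min_dur = 15.0, 15.0
    else:
        min_height, min_dur = 10.0, 10.0
    out = []
    for i0, i1, pk, height in _find_excursions(fhr, mask, baseline, +1.0, 5.0, 1.5, fs):
        dur = (i1 - i0) / fs
        # 0.25 bpm slack: smoothing shaves a fraction of a bpm off true peaks
        if height < min_height - 0.25 or dur < min_dur:
            continue
        onset_to_peak = (pk - i0) / fs
        if dur < 120:
            if onset_to_peak >= 35:  # sudden-rise requirement, with smoothing slack
                continue
            kind = EventKind.ACCELERATION
        elif dur < 600:
            kind = EventKind.PROLONGED_ACCELERATION
        else:
            continue  # baseline change, not an acceleration
        out.append(EventAnnotation(kind, i0 / fs, pk / fs, i1 / fs, height))
    return out


def detect_decelerations(
    fhr: np.ndarray,
    uc: np.ndarray,
    fhr_mask: np.ndarray,
    uc_mask: np.ndarray,
    baseline: float,
    fs: float = 4.0,
) -> DecelerationReport:
    """Detect FHR dips and type them against contraction peaks.

    Abrupt dips (onset-to-nadir < 30 s, depth >= 15 bpm, 15 s <= duration
    < 2 min) are variable decelerations regardless of the UC channel.
    Gradual dips need a concurrent contraction: nadir within
    +-10 s of the peak -> early; nadir more than 10 s after the peak ->
    late. Without a usable UC channel gradual dips are reported
    indeterminate — the failure mode a unimodal (FHR-only) reading hits.
    """
    fhr = np.asarray(fhr, float)
    uc = np.asarray(uc, float)
    fhr_mask = np.asarray(fhr_mask, bool)
    uc_mask = np.asarray(uc_mask, bool)
    report = DecelerationReport()

    uc_usable = uc_mask.sum() >= 60 * fs
    peaks_s: list[float] = []
    if uc_usable:
        peaks_s = contraction_stats(uc, uc_mask, fs).peak_times_s

    for i0, i1, nadir_i, depth in _find_excursions(
        fhr, fhr_mask, baseline, -1.0, 8.0, 2.0, fs, span_s=6.0
    ):
        onset_s, nadir_s, end_s = i0 / fs, nadir_i / fs, i1 / fs
        dur = end_s - onset_s
        o2n = nadir_s - onset_s
        if depth < 10:
            continue
        if o2n < 30 and depth >= 15 - 0.25 and 15 <= dur < 120:
            report.events.append(
                EventAnnotation(EventKind.VARIABLE_DECEL, onset_s, nadir_s, end_s, depth)
            )
            continue
        if o2n < 30:
            continue  # abrupt but shallow/short: not a classifiable deceleration
        # gradual dip: needs contraction timing
        if not uc_usable:
            report.indeterminate.append((onset_s, nadir_s, end_s, depth))
            report.warnings.append(
                f"gradual deceleration at {nadir_s:.0f}s indeterminate: no usable UC channel"
            )
            continue
        near = [p for p in peaks_s if onset_s - 30 <= p <= end_s + 30]
        if not near:
            report.indeterminate.append((onset_s, nadir_s, end_s, depth))
            report.warnings.append(
                f"gradual deceleration at {nadir_s:.0f}s has no concurrent contraction; left untyped"
            )
            continue
        peak = min(near, key=lambda p: abs(p - nadir_s))
        if abs(nadir_s - peak) <= ED_ALIGN_TOL_S:
            kind = EventKind.EARLY_DECEL
        elif nadir_s > peak:
            kind = EventKind.LATE_DECEL
        else:
            report.indeterminate.append((onset_s, nadir_s, end_s, depth))
            report.warnings.append(
                f"gradual deceleration at {nadir_s:.0f}s precedes the contraction peak; left untyped"
            )
            continue
        report.events.append(EventAnnotation(kind, onset_s, nadir_s, end_s, depth))
    return report


def detect_sinusoidal(
    fhr: np.ndarray, mask: np.ndarray, fs: float = 4.0
) -> tuple[bool, tuple[float, float] | None]:
    """True iff >= 20 consecutive minutes oscillate smoothly at 3-5 cycles/min.

    Each 1-min block qualifies when its periodogram concentrates (>= 60%
    of non-DC power) in a dominant 3-5 cycles/min bin and its amplitude
    is appreciable (peak-to-trough >= 4 bpm); a qualifying run of >= 20
    blocks makes the pattern. Accelerations break block smoothness, so
    the no-acceleration clause is enforced implicitly.
    """
    fhr = np.asarray(fhr, float)
    mask = np.asarray(mask, bool)
    if mask.sum() < 1200 * fs:
        return False, None
    w = int(60 * fs)
    n_blocks = len(fhr) // w
    good = np.zeros(n_blocks, bool)
    for b in range(n_blocks):
        sl = slice(b * w, (b + 1) * w)
        m = mask[sl]
        if m.sum() < 0.9 * w:
            continue
        x = fhr[sl][m] - fhr[sl][m].mean()
        if np.ptp(x) < 4.0:
            continue
        freqs, power = sps.periodogram(x, fs=fs)
        cpm = freqs * 60.0
        band = (cpm >= 1.0) & (cpm <= 30.0)
        if not band.any() or power[band].sum() <= 0:
            continue
        k = int(np.argmax(np.where(band, power, 0.0)))
        if not 2.5 <= cpm[k] <= 5.5:
            continue
        around = np.abs(cpm - cpm[k]) <= 1.0
        if power[around].sum() / power[band].sum() >= 0.6 and 3.0 - 0.5 <= cpm[k] <= 5.0 + 0.5:
            good[b] = True
    best = max(_runs(good), key=lambda r: r[1] - r[0], default=None)
    if best and best[1] - best[0] >= 20:
        return True, (best[0] * 60.0, best[1] * 60.0)
    return False, None


def contraction_stats(uc: np.ndarray, mask: np.ndarray, fs: float = 4.0) -> ContractionStats:
    """Prominence-gated contraction count and per-10-min rate.

    Rate is averaged over the valid observation span; spans under 30 min
    are extrapolated and flagged low-confidence. Tachysystole is > 5
    contractions / 10 min.
    """
    uc = np.asarray(uc, float)
    mask = np.asarray(mask, bool)
    if not mask.any():
        return ContractionStats(None, False, 0, [], indeterminate=True)
    filled = np.where(mask, uc, float(np.median(uc[mask])))
    peaks, _props = sps.find_peaks(filled, prominence=15.0, distance=int(30 * fs))
    peaks = [p for p in peaks if mask[p]]
    span_s = mask.sum() / fs
    rate = len(peaks) / span_s * 600.0
    return ContractionStats(
        rate_per_10min=rate,
        tachysystole=rate > 5.0,
        n_contractions=len(peaks),
        peak_times_s=[p / fs for p in peaks],
        low_confidence=span_s < 1800.0,
    )


# ----------------------------------------------------------------------
def detect_events(record: CTGRecord) -> tuple[list[EventAnnotation], Classification]:
    """Run every detector on a record; return detected events + components."""
    cls = classify_ctg(record)
    events: list[EventAnnotation] = list(cls.accelerations)
    if cls.decelerations is not None:
        events.extend(cls.decelerations.events)
    if cls.sinusoidal:
        ok, win = detect_sinusoidal(record.fhr, record.fhr_valid, record.fs)
        if ok:
            events.append(
                EventAnnotation(EventKind.SINUSOIDAL, win[0], sum(win) / 2, win[1], 1.0)
            )
    if cls.contractions is not None:
        for p in cls.contractions.peak_times_s:
            events.append(EventAnnotation(EventKind.CONTRACTION, max(p - 1, 0), p, p + 1, 1.0))
    return events, cls


def event_recovery(record: CTGRecord, tol_s: float = 30.0, edge_margin_s: float = 60.0):
    """Fraction of injected events re-detected with the correct kind.

    Only ground-truth FHR events at least ``edge_margin_s`` from both
    record edges are scored; a truth event is recovered when a detected
    event of the same kind has its nadir/peak within ``tol_s``.
    """
    scored_kinds = {
        EventKind.ACCELERATION,
        EventKind.PROLONGED_ACCELERATION,
        EventKind.EARLY_DECEL,
        EventKind.LATE_DECEL,
        EventKind.VARIABLE_DECEL,
        EventKind.SINUSOIDAL,
    }
    truth = [
        e
        for e in record.events
        if e.kind in scored_kinds
        and e.onset_s >= edge_margin_s
        and e.end_s <= record.duration_s - edge_margin_s
    ]
    detected, _cls = detect_events(record)
    hits = 0
    for t in truth:
        for d in detected:
            if d.kind != t.kind:
                continue
            if t.kind == EventKind.SINUSOIDAL:
                overlap = min(t.end_s, d.end_s) - max(t.onset_s, d.onset_s)
                if overlap >= 0.5 * t.duration_s:
                    hits += 1
                    break
            elif abs(d.nadir_or_peak_s - t.nadir_or_peak_s) <= tol_s:
                hits += 1
                break
    return hits, len(truth)


def classify_ctg(record: CTGRecord) -> Classification:
    """Three-tier interpretation with a reason trace.

    Class III: absent variability with recurrent late decels, recurrent
    variable decels or bradycardia — or a sinusoidal pattern. Class I:
    baseline 110-160 bpm, moderate variability, no late/variable decels
    (early decels and accelerations allowed). Everything else, including
    records with indeterminate components, is Class II.
    """
    fs = record.fs
    base = estimate_baseline(record.fhr, record.fhr_valid, fs)
    reasons: list[str] = []

    if base.indeterminate or base.value is None:
        return Classification(CTGClass.II, ["indeterminate-component:baseline"], baseline=base)

    decels = detect_decelerations(
        record.fhr, record.uc, record.fhr_valid, record.uc_valid, base.value, fs
    )
    accels = detect_accelerations(
        record.fhr, record.fhr_valid, base.value, record.gestational_age, fs
    )
    sinus, sinus_win = detect_sinusoidal(record.fhr, record.fhr_valid, fs)
    contr = contraction_stats(record.uc, record.uc_valid, fs)

    exclude = [(e.onset_s, e.end_s) for e in accels + decels.events]
    exclude += [(o, e) for o, _n, e, _d in decels.indeterminate]
    if sinus_win:
        exclude.append(sinus_win)
    var = classify_variability(record.fhr, record.fhr_valid, fs, exclude=exclude)

    n_contr = max(contr.n_contractions, 1) if not contr.indeterminate else None
    ld = decels.of_kind(EventKind.LATE_DECEL)
    vd = decels.of_kind(EventKind.VARIABLE_DECEL)
    recurrent_ld = n_contr is not None and len(ld) / n_contr >= RECURRENT_FRACTION
    recurrent_vd = n_contr is not None and len(vd) / n_contr >= RECURRENT_FRACTION

    cls_kwargs = dict(
        baseline=base, variability=var, accelerations=accels,
        decelerations=decels, sinusoidal=sinus, contractions=contr,
    )

    # --- Class III
    if sinus:
        return Classification(CTGClass.III, ["sinusoidal-pattern"], **cls_kwargs)
    if var.level == VariabilityLevel.ABSENT:
        if recurrent_ld:
            return Classification(
                CTGClass.III, ["absent-variability", "recurrent-late-decelerations"], **cls_kwargs
            )
        if recurrent_vd:
            return Classification(
                CTGClass.III, ["absent-variability", "recurrent-variable-decelerations"], **cls_kwargs
            )
        if base.bradycardia:
            return Classification(
                CTGClass.III, ["absent-variability", "bradycardia"], **cls_kwargs
            )

    # --- indeterminate components fall to Class II
    if var.indeterminate or contr.indeterminate:
        which = "variability" if var.indeterminate else "contractions"
        return Classification(
            CTGClass.II, [f"indeterminate-component:{which}"], **cls_kwargs
        )

    # --- Class I: all five conditions
    failures = []
    if not (110 <= base.value <= 160) or base.tachycardia or base.bradycardia:
        failures.append("baseline-out-of-range")
    if var.level != VariabilityLevel.MODERATE:
        failures.append(f"variability-{var.level.value}")
    if ld:
        failures.append("late-decelerations-present")
    if vd:
        failures.append("variable-decelerations-present")
    if decels.indeterminate:
        failures.append("untyped-decelerations-present")
    if not failures:
        return Classification(
            CTGClass.I,
            ["baseline-normal", "variability-moderate", "no-late-or-variable-decelerations"],
            **cls_kwargs,
        )
    return Classification(CTGClass.II, failures, **cls_kwargs)


def to_binary(ctg_class: CTGClass, policy: str = "strict") -> BinaryLabel:
    """Map a three-tier class to the normal/abnormal screening label.

    ``strict`` (default): I -> normal; II and III -> abnormal.
    ``ii_normal``: I and II -> normal; III -> abnormal.
    """
    if policy == "strict":
        return BinaryLabel.NORMAL if ctg_class == CTGClass.I else BinaryLabel.ABNORMAL
    if policy == "ii_normal":
        return BinaryLabel.ABNORMAL if ctg_class == CTGClass.III else BinaryLabel.NORMAL
    raise ValueError(f"unknown binary policy: {policy}")
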