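"""Core data containers for paired FHR/UC cardiotocography records.

A CTG record holds two synchronously sampled channels: fetal heart rate
(FHR, beats/min) and uterine contraction pressure (UC, mmHg), both at 4 Hz
by convention, together with per-sample validity masks (signal-loss gaps
are marked invalid and never interpolated) and a list of annotated
physiological events (accelerations, decelerations, contractions, ...).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Clinical FHR chart range in beats/min.
FHR_RANGE = (60.0, 210.0)
#: Clinical UC chart range in mmHg.
UC_RANGE = (0.0, 100.0)
#: Default sampling frequency of both channels, Hz.
FS_DEFAULT = 4.0


class EventKind(str, enum.Enum):
    """Vocabulary of annotated CTG events."""

    ACCELERATION = "acceleration"
    PROLONGED_ACCELERATION = "prolonged_acceleration"
    EARLY_DECEL = "early_decel"
    LATE_DECEL = "late_decel"
    VARIABLE_DECEL = "variable_decel"
    SINUSOIDAL = "sinusoidal"
    CONTRACTION = "contraction"
    TACHYCARDIA_SEGMENT = "tachycardia_segment"
    BRADYCARDIA_SEGMENT = "bradycardia_segment"


DECEL_KINDS = (EventKind.EARLY_DECEL, EventKind.LATE_DECEL, EventKind.VARIABLE_DECEL)


class CTGClass(str, enum.Enum):
    """Three-tier intrapartum CTG interpretation."""

    I = "I"
    II = "II"
    III = "III"


class BinaryLabel(str, enum.Enum):
    NORMAL = "normal"
    ABNORMAL = "abnormal"


@dataclass(frozen=True)
class EventAnnotation:
    """One annotated event with its onset / nadir-or-peak / end timing.

    ``magnitude`` is in bpm for FHR events (deceleration depth or
    acceleration height above baseline) and in mmHg for contractions
    (amplitude above resting tone).
    """

    kind: EventKind
    onset_s: float
    nadir_or_peak_s: float
    end_s: float
    magnitude: float

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.nadir_or_peak_s <= self.end_s):
            raise ValueError(
                f"event timing must satisfy onset <= nadir/peak <= end, got "
                f"({self.onset_s}, {self.nadir_or_peak_s}, {self.end_s})"
            )
        if self.magnitude <= 0:
            raise ValueError("event magnitude must be positive")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s

    def overlaps(self, other: "EventAnnotation") -> bool:
        return self.onset_s < other.end_s and other.onset_s < self.end_s

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "onset_s": self.onset_s,
            "nadir_or_peak_s": self.nadir_or_peak_s,
            "end_s": self.end_s,
            "magnitude": self.magnitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventAnnotation":
        return cls(
            kind=EventKind(d["kind"]),
            onset_s=float(d["onset_s"]),
            nadir_or_peak_s=float(d["nadir_or_peak_s"]),
            end_s=float(d["end_s"]),
            magnitude=float(d["magnitude"]),
        )


@dataclass
class CTGRecord:
    """Paired FHR/UC series with validity masks and event annotations."""

    fhr: np.ndarray
    uc: np.ndarray
    fhr_valid: np.ndarray
    uc_valid: np.ndarray
    fs: float = FS_DEFAULT
    gestational_age: float = 34.0
    events: list[EventAnnotation] = field(default_factory=list)
    figo_class: CTGClass | None = None
    binary_label: BinaryLabel | None = None

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.uc = np.asarray(self.uc, dtype=float)
        self.fhr_valid = np.asarray(self.fhr_valid, dtype=bool)
        self.uc_valid = np.asarray(self.uc_valid, dtype=bool)
        n = len(self.fhr)
        if not (len(self.uc) == len(self.fhr_valid) == len(self.uc_valid) == n):
            raise ValueError("fhr, uc and validity masks must have equal length")
        lo, hi = FHR_RANGE
        v = self.fhr[self.fhr_valid]
        if v.size and (v.min() < lo or v.max() > hi):
            raise ValueError(f"valid FHR samples must lie in [{lo}, {hi}] bpm")
        lo, hi = UC_RANGE
        v = self.uc[self.uc_valid]
        if v.size and (v.min() < lo or v.max() > hi):
            raise ValueError(f"valid UC samples must lie in [{lo}, {hi}] mmHg")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.fhr)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def events_of_kind(self, *kinds: EventKind) -> list[EventAnnotation]:
        return [e for e in self.events if e.kind in kinds]

    def copy(self) -> "CTGRecord":
        return replace(
            self,
            fhr=self.fhr.copy(),
            uc=self.uc.copy(),
            fhr_valid=self.fhr_valid.copy(),
            uc_valid=self.uc_valid.copy(),
            events=list(self.events),
        )

    def sample_index(self, t_s: float) -> int:
        return int(round(t_s * self.fs))

    # ------------------------------------------------------------------
    # I/O: CSV series plus JSON annotation sidecar
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "fhr_bpm": self.fhr,
                "uc_mmhg": self.uc,
                "fhr_valid": self.fhr_valid.astype(int),
                "uc_valid": self.uc_valid.astype(int),
            }
        )

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "fs": self.fs,
                "gestational_age": self.gestational_age,
                "figo_class": self.figo_class.value if self.figo_class else None,
                "binary_label": self.binary_label.value if self.binary_label else None,
                "events": [e.to_dict() for e in self.events],
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CTGRecord":
        path = Path(path)
        df = pd.read_csv(path)
        kwargs: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            kwargs = {
                "fs": float(meta.get("fs", FS_DEFAULT)),
                "gestational_age": float(meta.get("gestational_age", 34.0)),
                "events": [EventAnnotation.from_dict(d) for d in meta.get("events", [])],
            }
            if meta.get("figo_class"):
                kwargs["figo_class"] = CTGClass(meta["figo_class"])
            if meta.get("binary_label"):
                kwargs["binary_label"] = BinaryLabel(meta["binary_label"])
        elif len(df) > 1:
            kwargs = {"fs": 1.0 / float(df["time_s"].iloc[1] - df["time_s"].iloc[0])}
        return cls(
            fhr=df["fhr_bpm"].to_numpy(float),
            uc=df["uc_mmhg"].to_numpy(float),
            fhr_valid=df["fhr_valid"].to_numpy(bool),
            uc_valid=df["uc_valid"].to_numpy(bool),
            **kwargs,
        )


@dataclass
class SimParams:
    """Controls for the synthetic CTG generator.

    Defaults follow the cohort prior of a 142 bpm mean baseline and a
    moderate 10 bpm/min peak-to-trough variability; contractions arrive
    at ``contraction_rate`` per 10 minutes as smooth unimodal bumps.
    ``event_requests`` is a list of ``(kind, params_dict)`` pairs handled
    by :func:`ctgkit.synth.simulate_record`.
    """

    baseline_bpm: float = 142.0
    variability_amp: float = 10.0
    contraction_rate: float = 4.0
    event_requests: list[tuple] = field(default_factory=list)
    duration_s: float = 1800.0
    seed: int = 0
    gap_spec: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    fs: float = FS_DEFAULT
    gestational_age: float = 34.0
    contraction_amplitude: tuple[float, float] = (35.0, 65.0)
    contraction_duration: tuple[float, float] = (60.0, 90.0)
    resting_tone: float = 8.0
    skip_conflicts: bool = False  # drop (rather than reject) overlapping event requests

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.contraction_rate < 0:
            raise ValueError("contraction_rate must be >= 0")
        if self.variability_amp < 0:
            raise ValueError("variability_amp must be >= 0")
        bad = set(self.gap_spec) - {"fhr", "uc"}
        if bad:
            raise ValueError(f"gap_spec channels must be 'fhr'/'uc', got {bad}")
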