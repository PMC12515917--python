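"""Chart geometry: how FHR/UC values map onto rows of a paper-style strip.

The default geometry reproduces a 1,653 x 2,339 px monitor scan in which
the FHR curve occupies rows 281-569 (60-210 bpm) and the UC curve rows
628-770 (0-100 mmHg). Band bounds are 0-based and inclusive. Both value
templates are affine and *decreasing* in row index: the band top carries
the range maximum, the band bottom the minimum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml


class Polarity(str, enum.Enum):
    """Which side of the gray threshold is treated as trace foreground."""

    DARK_TRACE = "dark_trace"    # foreground where G < tau (scanned ink)
    LIGHT_TRACE = "light_trace"  # foreground where G > tau (printed formula)


@dataclass(frozen=True)
class ChartLayout:
    height_px: int = 1653
    width_px: int = 2339
    fhr_band: tuple[int, int] = (281, 569)
    uc_band: tuple[int, int] = (628, 770)
    fhr_range: tuple[float, float] = (60.0, 210.0)
    uc_range: tuple[float, float] = (0.0, 100.0)
    threshold: int = 50
    polarity: Polarity = Polarity.DARK_TRACE
    seconds_per_column: float = 0.25
    trace_intensity: int = 0
    grid_intensity: int = 200
    background_intensity: int = 255
    grid_row_step: int = 24
    grid_col_step: int = 40

    def __post_init__(self) -> None:
        for name, (a, b) in (("fhr_band", self.fhr_band), ("uc_band", self.uc_band)):
            if not (0 <= a < b < self.height_px):
                raise ValueError(f"{name} must be an ordered row interval inside the image")
        if self.fhr_band[1] >= self.uc_band[0] and self.uc_band[1] >= self.fhr_band[0]:
            if not (self.fhr_band[1] < self.uc_band[0] or self.uc_band[1] < self.fhr_band[0]):
                raise ValueError("FHR and UC bands must be disjoint")
        if not (0 < self.threshold < 255):
            raise ValueError("threshold must lie strictly inside (0, 255)")
        for name, (lo, hi) in (("fhr_range", self.fhr_range), ("uc_range", self.uc_range)):
            if not lo < hi:
                raise ValueError(f"{name} must be ordered")
        if self.seconds_per_column <= 0:
            raise ValueError("seconds_per_column must be positive")

    # -- affine templates ------------------------------------------------
    def _template(self, rows, band, rng, name):
        a, b = band
        lo, hi = rng
        rows = np.asarray(rows)
        if np.any(rows < a) or np.any(rows > b):
            raise ValueError(f"row outside the {name} band [{a}, {b}]")
        # decreasing affine map: row a -> hi, row b -> lo
        return hi + (lo - hi) * (rows - a) / (b - a)

    def fhr_value_of_row(self, rows):
        """bpm at a row of the FHR band (band top -> 210, bottom -> 60)."""
        return self._template(rows, self.fhr_band, self.fhr_range, "FHR")

    def uc_value_of_row(self, rows):
        """mmHg at a row of the UC band (band top -> 100, bottom -> 0)."""
        return self._template(rows, self.uc_band, self.uc_range, "UC")

    def _row_of(self, values, band, rng):
        a, b = band
        lo, hi = rng
        values = np.clip(np.asarray(values, dtype=float), lo, hi)
        return a + (hi - values) * (b - a) / (hi - lo)

    def row_of_fhr_value(self, values):
        """Fractional row at which a bpm value is drawn (inverse template)."""
        return self._row_of(values, self.fhr_band, self.fhr_range)

    def row_of_uc_value(self, values):
        return self._row_of(values, self.uc_band, self.uc_range)

    # -- quantization ----------------------------------------------------
    @property
    def fhr_step(self) -> float:
        """bpm per pixel row in the FHR band."""
        a, b = self.fhr_band
        lo, hi = self.fhr_range
        return (hi - lo) / (b - a)

    @property
    def uc_step(self) -> float:
        a, b = self.uc_band
        lo, hi = self.uc_range
        return (hi - lo) / (b - a)

    def column_of_time(self, t_s) -> np.ndarray:
        return np.floor(np.asarray(t_s) / self.seconds_per_column + 1e-9).astype(int)

    def n_columns_for(self, duration_s: float) -> int:
        return int(round(duration_s / self.seconds_per_column))

    # -- convenience geometries -----------------------------------------
    @classmethod
    def compact(cls, duration_s: float = 960.0, width_px: int = 192,
                height_px: int = 96) -> "ChartLayout":
        """A reduced strip geometry for fast rendering / CNN input.

        Bands keep the default 2:1 FHR:UC height ratio and the clinical
        value ranges; the time scale is stretched so ``duration_s`` of
        signal fills ``width_px`` columns.
        """
        fhr_top = round(height_px * 0.10)
        fhr_bot = round(height_px * 0.60)
        uc_top = round(height_px * 0.68)
        uc_bot = round(height_px * 0.94)
        return cls(
            height_px=height_px,
            width_px=width_px,
            fhr_band=(fhr_top, fhr_bot),
            uc_band=(uc_top, uc_bot),
            seconds_per_column=duration_s / width_px,
            grid_row_step=max(4, height_px // 12),
            grid_col_step=max(8, width_px // 16),
        )

    # -- YAML ------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["polarity"] = self.polarity.value
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChartLayout":
        d = yaml.safe_load(Path(path).read_text())
        if "polarity" in d:
            d["polarity"] = Polarity(d["polarity"])
        for key in ("fhr_band", "uc_band", "fhr_range", "uc_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_(self, **kw) -> "ChartLayout":
        return replace(self, **kw)


@dataclass
class ChartImage:
    """A rendered (or loaded) strip raster plus its layout and render report."""

    pixels: np.ndarray  # uint8, (H, W) gray or (H, W, 3) RGB
    layout: ChartLayout
    report: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def to_rgb(self) -> np.ndarray:
        if self.pixels.ndim == 3:
            return self.pixels
        return np.repeat(self.pixels[:, :, None], 3, axis=2)

    def save(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray(self.pixels).save(path)

    @classmethod
    def load(cls, path: str | Path, layout: ChartLayout) -> "ChartImage":
        from PIL import Image

        return cls(pixels=np.asarray(Image.open(path)), layout=layout)
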