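"""Chart-image digitization: recover FHR/UC series from a strip raster.

Pipeline: grayscale -> fixed-threshold binarization -> per-band affine
value templates -> masked column averaging. A column with no foreground
pixel in a band is a *gap*; gaps are reported through boolean masks and
are never interpolated. A paper-faithful mode instead emits 0 for empty
columns through an epsilon-guarded mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import ChartImage, ChartLayout, Polarity

__all__ = [
    "SignalMatrix",
    "to_grayscale",
    "binarize",
    "fhr_template",
    "uc_template",
    "extract_column",
    "extract_signals",
    "assemble_matrix",
]

_EPS = 1e-6


@dataclass
class SignalMatrix:
    """Stacked two-channel extraction output: 2N interleaved rows x n columns.

    Rows alternate (FHR_k, UC_k) for each source image k. ``gap_mask`` is
    True where the source column carried no trace pixel.
    """

    X: np.ndarray
    channel_of_row: list[str]
    gap_mask: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.gap_mask = np.atleast_2d(np.asarray(self.gap_mask, dtype=bool))
        if self.X.shape[0] % 2:
            raise ValueError("SignalMatrix must have an even number of rows")
        if self.X.shape != self.gap_mask.shape:
            raise ValueError("gap_mask must match X in shape")

    @property
    def n_records(self) -> int:
        return self.X.shape[0] // 2


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Channel-mean grayscale; gray input passes through unchanged."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(float)
    if image.ndim == 3 and image.shape[2] == 3:
        return image.mean(axis=2)
    raise ValueError(f"expected a gray or 3-channel image, got shape {image.shape}")


def binarize(gray: np.ndarray, layout: ChartLayout) -> np.ndarray:
    """Fixed-threshold foreground mask.

    With ``dark_trace`` polarity (scanned ink) foreground is G < tau;
    ``light_trace`` keeps the printed formula's G > tau. The threshold
    itself is background under both conventions (strict inequalities).
    """
    gray = np.asarray(gray, dtype=float)
    if layout.polarity == Polarity.DARK_TRACE:
        return (gray < layout.threshold).astype(np.uint8)
    return (gray > layout.threshold).astype(np.uint8)


def fhr_template(rows, layout: ChartLayout):
    """bpm value template over FHR-band rows; strictly decreasing affine."""
    return layout.fhr_value_of_row(rows)


def uc_template(rows, layout: ChartLayout):
    """mmHg value template over UC-band rows; strictly decreasing affine."""
    return layout.uc_value_of_row(rows)


def extract_column(
    mask: np.ndarray,
    column: int,
    band: tuple[int, int],
    template: np.ndarray,
    paper_faithful: bool = False,
) -> float:
    """Mean template value over the column's foreground rows within a band.

    Empty columns yield NaN (gap), or 0 in paper-faithful mode via the
    epsilon-guarded normalization.
    """
    if not 0 <= column < mask.shape[1]:
        raise ValueError("column outside the image")
    a, b = band
    col = mask[a : b + 1, column].astype(bool)
    if paper_faithful:
        return float((template * col).sum() / (col.sum() + _EPS))
    if not col.any():
        return float("nan")
    return float(template[col].mean())


def extract_signals(
    image: ChartImage | np.ndarray,
    layout: ChartLayout | None = None,
    paper_faithful: bool = False,
):
    """Digitize both bands of a chart column by column.

    Returns ``(fhr, uc, fhr_gap, uc_gap)`` — two length-n value series and
    their gap masks. No interpolation is ever applied: a blank source
    column stays a gap (or 0 in paper-faithful mode).
    """
    if isinstance(image, ChartImage):
        layout = layout or image.layout
        pixels = image.pixels
    else:
        if layout is None:
            raise ValueError("layout required when passing a bare array")
        pixels = image
    gray = to_grayscale(pixels)
    if gray.shape != (layout.height_px, layout.width_px):
        raise ValueError(
            f"image shape {gray.shape} does not match layout "
            f"({layout.height_px}, {layout.width_px})"
        )
    mask = binarize(gray, layout)

    out = []
    for band, template_fn in ((layout.fhr_band, fhr_template), (layout.uc_band, uc_template)):
        a, b = band
        rows = np.arange(a, b + 1)
        tmpl = template_fn(rows, layout)
        sub = mask[a : b + 1, :].astype(float)
        counts = sub.sum(axis=0)
        sums = tmpl @ sub
        if paper_faithful:
            values = sums / (counts + _EPS)
            gaps = counts == 0
        else:
            gaps = counts == 0
            with np.errstate(invalid="ignore", divide="ignore"):
                values = np.where(gaps, np.nan, sums / np.maximum(counts, 1))
        out.extend([values, gaps])
    fhr, fhr_gap, uc, uc_gap = out
    return fhr, uc, fhr_gap, uc_gap


def assemble_matrix(extracted: list[tuple]) -> SignalMatrix:
    """Stack per-image (fhr, uc, fhr_gap, uc_gap) tuples into a 2N x n matrix."""
    if not extracted:
        return SignalMatrix(
            X=np.zeros((0, 0)), channel_of_row=[], gap_mask=np.zeros((0, 0), bool)
        )
    lengths = {len(item[0]) for item in extracted} | {len(item[1]) for item in extracted}
    if len(lengths) != 1:
        raise ValueError(f"all series must share one length, got {sorted(lengths)}")
    rows, gaps, tags = [], [], []
    for fhr, uc, fhr_gap, uc_gap in extracted:
        rows.extend([fhr, uc])
        gaps.extend([fhr_gap, uc_gap])
        tags.extend(["fhr", "uc"])
    return SignalMatrix(X=np.vstack(rows), channel_of_row=tags, gap_mask=np.vstack(gaps))
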