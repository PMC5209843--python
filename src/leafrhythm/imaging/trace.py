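"""Leaf-tip tracing across a time-lapse stack.

The left (right) tip row of a segmented plant is the mean row index of
foreground pixels within a small border band of the leftmost (rightmost)
foreground column — the pixels of the binarised seedling that cut across its
outline.  Only the vertical coordinate is traced; it is emitted in an
upward-positive convention (image height minus row) so that plots read
naturally.  Period estimates are invariant to both the sign convention and
the constant chamber offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ..config import Config
from ..errors import EmptyMaskError
from ..series import TimeSeries
from .marks import PlateLayout
from .segment import SeedlingMask, segment_seedling


@dataclass
class PlateImageSeries:
    """An ordered time-lapse stack of one plate."""

    image_paths: list[Path]
    interval_min: float = 10.0
    t0_h: float = 0.0

    def __post_init__(self) -> None:
        self.image_paths = [Path(p) for p in self.image_paths]
        if len(self.image_paths) < 2:
            raise ValueError("a stack needs at least 2 images")
        if self.interval_min <= 0:
            raise ValueError("interval_min must be positive")

    @classmethod
    def from_directory(cls, directory, interval_min: float = 10.0,
                       t0_h: float = 0.0) -> "PlateImageSeries":
        """All PNG/JPEG frames of a directory in lexicographic order."""
        directory = Path(directory)
        paths = sorted(p for p in directory.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        return cls(paths, interval_min, t0_h)

    @property
    def times_h(self) -> np.ndarray:
        return self.t0_h + np.arange(len(self.image_paths)) * self.interval_min / 60.0


@dataclass
class SeedlingTrace:
    """Left/right tip-position series of one chamber."""

    chamber_index: int
    left: TimeSeries
    right: TimeSeries
    detect_rate: float = 0.0
    usable: bool = True


def trace_tips(mask: SeedlingMask, band: int = 4) -> tuple[float, float]:
    """Tip rows (left, right) of a mask, in full-resolution chamber pixels.

    With x_min (x_max) the leftmost (rightmost) foreground column, the left
    tip row is the mean row of foreground pixels with x <= x_min + band and
    the right tip row the mean over x >= x_max - band; rows are rescaled to
    full resolution by the mask's scale factor.

    Raises
    ------
    EmptyMaskError
        If the mask contains no foreground.
    """
    if mask.empty:
        raise EmptyMaskError(f"chamber {mask.chamber_index}: empty mask")
    rows, cols = np.nonzero(mask.mask)
    left_rows = rows[cols <= cols.min() + band]
    right_rows = rows[cols >= cols.max() - band]
    return (float(left_rows.mean() / mask.scale),
            float(right_rows.mean() / mask.scale))


def extract_traces(series: PlateImageSeries, layout: PlateLayout,
                   config: Config | None = None) -> list[SeedlingTrace]:
    """Segment and trace every chamber in every frame of a stack.

    Frames where no plant is detected are recorded as missing (NaN); a
    chamber whose detection rate falls below ``config.detect_floor`` is
    flagged unusable (such seedlings are discarded from period statistics).
    The emitted vertical coordinate is ``image_height - plate_row``
    (upward-positive).
    """
    config = config or Config()
    times = series.times_h
    n_frames = len(series.image_paths)
    n_chambers = len(layout.chambers)
    left = np.full((n_chambers, n_frames), np.nan)
    right = np.full((n_chambers, n_frames), np.nan)

    height = None
    for k, path in enumerate(series.image_paths):
        frame = iio.imread(path)
        if height is None:
            height = frame.shape[0]
        elif frame.shape[0] != height:
            raise ValueError("all frames must share identical pixel dimensions")
        for ci, (x0, x1, y0, y1) in enumerate(layout.chambers):
            crop = frame[y0:y1, x0:x1]
            mask = segment_seedling(crop, ci, config)
            if mask.empty:
                continue
            l_row, r_row = trace_tips(mask, config.band)
            left[ci, k] = height - (y0 + l_row)
            right[ci, k] = height - (y0 + r_row)

    traces = []
    for ci in range(n_chambers):
        rate = float(np.mean(~np.isnan(left[ci])))
        traces.append(SeedlingTrace(
            chamber_index=ci,
            left=TimeSeries(times, left[ci], label=f"c{ci}_left"),
            right=TimeSeries(times, right[ci], label=f"c{ci}_right"),
            detect_rate=rate,
            usable=rate >= config.detect_floor,
        ))
    return traces
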