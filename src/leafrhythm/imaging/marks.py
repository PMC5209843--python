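"""Red registration-mark detection and chamber-grid layout.

The plates carry four red fiducial dots: two at opposite outer corners of the
plate and two at the anti-diagonal corners (top-right and bottom-left) of the
top-left reference chamber.  Mark pixels are selected by a radial HSV filter
(hue within 15 degrees of red, with saturation/value floors), cleaned by one
erosion + dilation, and blobs smaller than 0.5% of the image are discarded;
exactly four blobs must remain.  The chamber grid is then tiled from the
plate origin using the reference chamber's width and height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, measure, morphology

from ..config import Config
from ..errors import LayoutError, MarkDetectionError


def red_mask(image: np.ndarray, hue_tol_deg: float = 15.0,
             sat_min: float = 0.4, val_min: float = 0.3) -> np.ndarray:
    """Boolean mask of pixels within the radial red-hue window.

    Hue wraps at 0: admissible hue is [360 - tol, 360) union [0, tol]
    degrees; saturation and value floors exclude grey and dark pixels that
    share the hue angle.
    """
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("a 3-channel colour image is required")
    hsv = color.rgb2hsv(image[..., :3])
    hue = hsv[..., 0]  # in [0, 1)
    tol = hue_tol_deg / 360.0
    return (((hue <= tol) | (hue >= 1.0 - tol))
            & (hsv[..., 1] >= sat_min) & (hsv[..., 2] >= val_min))


def detect_red_marks(image: np.ndarray,
                     config: Config | None = None) -> list[tuple[float, float]]:
    """Centroids (x, y) of the four red registration marks.

    Raises
    ------
    MarkDetectionError
        When the cleaned, size-filtered mask does not contain exactly four
        blobs (mis-marked plate or wrong lighting; supply a marks file
        instead).
    """
    config = config or Config()
    mask = red_mask(image, config.hue_tol_deg, config.sat_min, config.val_min)
    footprint = np.ones((3, 3), dtype=bool)
    mask = morphology.dilation(morphology.erosion(mask, footprint), footprint)
    labels = measure.label(mask, connectivity=2)
    min_area = config.min_mark_area_frac * image.shape[0] * image.shape[1]
    blobs = [r for r in measure.regionprops(labels) if r.area >= min_area]
    if len(blobs) != 4:
        raise MarkDetectionError(
            f"expected 4 registration marks, found {len(blobs)} blobs "
            f">= {min_area:.0f} px")
    return [(float(r.centroid[1]), float(r.centroid[0])) for r in blobs]


@dataclass
class PlateLayout:
    """Four mark centroids plus the derived chamber rectangles.

    Rectangles are [x0, x1) x [y0, y1) in 0-based full-resolution pixels,
    row-major from the plate's top-left.
    """

    marks: list[tuple[float, float]]
    n_rows: int
    n_cols: int
    chambers: list[tuple[int, int, int, int]]

    @property
    def plate_span(self) -> tuple[int, int, int, int]:
        x0 = min(r[0] for r in self.chambers)
        x1 = max(r[1] for r in self.chambers)
        y0 = min(r[2] for r in self.chambers)
        y1 = max(r[3] for r in self.chambers)
        return x0, x1, y0, y1


def build_layout(marks: list[tuple[float, float]], n_rows: int = 5,
                 n_cols: int = 5, layout_slack: float = 0.10) -> PlateLayout:
    """Derive the chamber grid from the four mark centroids.

    Marks are assigned by distance from the top-left of their bounding box:
    nearest = plate origin, farthest = opposite plate corner; of the
    remaining two (the reference chamber's anti-diagonal corners), the more
    horizontal one sets the chamber width and the other the chamber height.

    Raises
    ------
    LayoutError
        When the marks are not four distinct points, when the reference
        chamber is degenerate, or when the tiled grid exceeds the plate span
        by more than ``layout_slack``.
    """
    if len(marks) != 4 or len({(round(x, 6), round(y, 6)) for x, y in marks}) != 4:
        raise LayoutError("four distinct mark centroids are required")
    if n_rows < 1 or n_cols < 1:
        raise LayoutError("n_rows and n_cols must be >= 1")
    pts = np.asarray(marks, dtype=float)
    ref = pts.min(axis=0)
    order = np.argsort(np.hypot(*(pts - ref).T))
    origin, far = pts[order[0]], pts[order[3]]
    mids = pts[order[1]], pts[order[2]]
    deltas = [m - origin for m in mids]
    # the more horizontal chamber mark defines the width, the other the height
    if abs(deltas[0][0]) - abs(deltas[0][1]) >= abs(deltas[1][0]) - abs(deltas[1][1]):
        h_mark, v_mark = mids
    else:
        v_mark, h_mark = mids
    cw = h_mark[0] - origin[0]
    ch = v_mark[1] - origin[1]
    span_w = far[0] - origin[0]
    span_h = far[1] - origin[1]
    if cw <= 0 or ch <= 0 or span_w <= 0 or span_h <= 0:
        raise LayoutError("mark geometry is degenerate (non-positive spans)")
    if n_cols * cw > (1.0 + layout_slack) * span_w or \
            n_rows * ch > (1.0 + layout_slack) * span_h:
        raise LayoutError(
            f"reference chamber tiled {n_cols}x{n_rows} "
            f"({n_cols * cw:.0f}x{n_rows * ch:.0f} px) exceeds the plate span "
            f"({span_w:.0f}x{span_h:.0f} px) by more than {layout_slack:.0%}")
    chambers = []
    for r in range(n_rows):
        for c in range(n_cols):
            chambers.append((int(round(origin[0] + c * cw)),
                             int(round(origin[0] + (c + 1) * cw)),
                             int(round(origin[1] + r * ch)),
                             int(round(origin[1] + (r + 1) * ch))))
    return PlateLayout(marks=[tuple(p) for p in pts], n_rows=n_rows,
                       n_cols=n_cols, chambers=chambers)


def read_marks_file(path) -> list[tuple[float, float]]:
    """Read a manual marks override: four 'x y' lines, 0-based pixels."""
    marks = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        x, y = line.split()[:2]
        marks.append((float(x), float(y)))
    if len(marks) != 4:
        raise MarkDetectionError(f"marks file must contain 4 points, got {len(marks)}")
    return marks
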