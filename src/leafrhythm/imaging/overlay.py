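"""QC overlay images: recognised chambers and detected seedlings.

Replaces an interactive review step with a saved picture: chamber borders
are drawn in white and each detected seedling's bounding box in red on a
copy of the input frame.
"""

from __future__ import annotations

import numpy as np

from .marks import PlateLayout
from .segment import SeedlingMask

CHAMBER_COLOUR = (255, 255, 255)
BOX_COLOUR = (255, 0, 0)


def _rect_perimeter(image: np.ndarray, x0: int, x1: int, y0: int, y1: int,
                    colour) -> None:
    h, w = image.shape[:2]
    x0, x1 = np.clip([x0, x1 - 1], 0, w - 1)
    y0, y1 = np.clip([y0, y1 - 1], 0, h - 1)
    image[y0, x0:x1 + 1] = colour
    image[y1, x0:x1 + 1] = colour
    image[y0:y1 + 1, x0] = colour
    image[y0:y1 + 1, x1] = colour


def write_overlay(image: np.ndarray, layout: PlateLayout,
                  detections: list[SeedlingMask] | None = None) -> np.ndarray:
    """Return a copy of ``image`` with chamber borders and detection boxes.

    Purely additive: only perimeter pixels change, the input is left
    unmodified.  Detections are matched to chambers by their
    ``chamber_index``; empty masks draw nothing.
    """
    out = np.array(image[..., :3], dtype=np.uint8, copy=True)
    for (x0, x1, y0, y1) in layout.chambers:
        _rect_perimeter(out, x0, x1, y0, y1, CHAMBER_COLOUR)
    for det in detections or []:
        bbox = det.bbox_full_res()
        if bbox is None:
            continue
        cx0, cx1, cy0, cy1 = layout.chambers[det.chamber_index]
        bx0, bx1, by0, by1 = bbox
        _rect_perimeter(out, cx0 + bx0, cx0 + bx1, cy0 + by0, cy0 + by1, BOX_COLOUR)
    return out
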