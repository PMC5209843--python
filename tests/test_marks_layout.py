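"""Red fiducial detection and chamber-grid derivation."""

import numpy as np
import pytest

from leafrhythm import Config, LayoutError, MarkDetectionError
from leafrhythm.imaging import build_layout, detect_red_marks


def white_image(h=1000, w=1000):
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = 255
    return img


def draw_disc(img, cx, cy, r, colour=(255, 0, 0)):
    yy, xx = np.mgrid[:img.shape[0], :img.shape[1]]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2] = colour


CENTRES = [(100, 100), (900, 120), (130, 880), (870, 860)]


class TestDetectRedMarks:
    def test_four_disc_centres_recovered(self):
        img = white_image()
        for cx, cy in CENTRES:
            draw_disc(img, cx, cy, 45)
        marks = detect_red_marks(img)
        assert len(marks) == 4
        found = {min(range(4), key=lambda i: np.hypot(x - CENTRES[i][0],
                                                      y - CENTRES[i][1]))
                 for x, y in marks}
        assert found == {0, 1, 2, 3}
        for x, y in marks:
            assert min(np.hypot(x - cx, y - cy) for cx, cy in CENTRES) <= 2.0

    def test_small_blob_below_half_percent_is_filtered(self):
        img = white_image()
        for cx, cy in CENTRES:
            draw_disc(img, cx, cy, 45)
        draw_disc(img, 500, 500, 10)   # area 314 px^2 << 0.5% of 1e6
        assert len(detect_red_marks(img)) == 4

    def test_three_discs_raise(self):
        img = white_image()
        for cx, cy in CENTRES[:3]:
            draw_disc(img, cx, cy, 45)
        with pytest.raises(MarkDetectionError):
            detect_red_marks(img)

    def test_brightness_scaling_invariance(self):
        # hue is brightness-independent: dimming the image (within the
        # value floor) must not move the centroids
        img = white_image()
        for cx, cy in CENTRES:
            draw_disc(img, cx, cy, 45)
        dim = (img.astype(float) * 0.6).astype(np.uint8)
        bright = detect_red_marks(img)
        dimmed = detect_red_marks(dim)
        for (x1, y1), (x2, y2) in zip(sorted(bright), sorted(dimmed)):
            assert np.hypot(x1 - x2, y1 - y2) <= 1.0

    def test_grey_pixels_with_red_hue_excluded(self):
        # saturation floor: a desaturated reddish blob must not count
        img = white_image()
        for cx, cy in CENTRES[:3]:
            draw_disc(img, cx, cy, 45)
        draw_disc(img, 500, 500, 45, colour=(180, 160, 160))  # pale pink
        with pytest.raises(MarkDetectionError):
            detect_red_marks(img)


class TestBuildLayout:
    def test_exact_tiling(self):
        marks = [(0, 0), (500, 500), (100, 0), (0, 100)]
        layout = build_layout(marks, 5, 5)
        assert len(layout.chambers) == 25
        assert layout.chambers[0] == (0, 100, 0, 100)
        assert layout.chambers[24] == (400, 500, 400, 500)
        # disjoint row-major tiling covering the plate
        assert layout.plate_span == (0, 500, 0, 500)

    def test_ten_percent_slack_boundary(self):
        # 5 x 110 = 550 <= 1.1 * 500: accepted
        build_layout([(0, 0), (500, 500), (110, 0), (0, 110)], 5, 5)
        # 5 x 120 = 600 > 550: rejected
        with pytest.raises(LayoutError):
            build_layout([(0, 0), (500, 500), (120, 0), (0, 120)], 5, 5)

    def test_duplicate_marks_rejected(self):
        with pytest.raises(LayoutError):
            build_layout([(0, 0), (0, 0), (100, 0), (0, 100)], 5, 5)

    def test_mark_order_is_irrelevant(self):
        marks = [(0, 0), (500, 500), (100, 0), (0, 100)]
        ref = build_layout(marks, 5, 5).chambers
        perm = [marks[i] for i in (2, 0, 3, 1)]
        assert build_layout(perm, 5, 5).chambers == ref

    def test_renderer_ground_truth_geometry(self, short_plate):
        import imageio.v3 as iio
        spec, paths, truth = short_plate
        marks = detect_red_marks(iio.imread(paths[0]), Config())
        for mx, my in marks:
            assert min(np.hypot(mx - tx, my - ty)
                       for tx, ty in truth.marks) <= 2.0
        layout = build_layout(marks, spec.n_rows, spec.n_cols)
        derived = np.asarray(layout.chambers)
        programmed = np.asarray(truth.chamber_rects)
        assert np.abs(derived - programmed).max() <= 2

    def test_chambers_cover_plate_span(self, short_plate):
        import imageio.v3 as iio
        spec, paths, truth = short_plate
        layout = build_layout(detect_red_marks(iio.imread(paths[0])),
                              spec.n_rows, spec.n_cols)
        x0, x1, y0, y1 = layout.plate_span
        covered = sum((cx1 - cx0) * (cy1 - cy0)
                      for cx0, cx1, cy0, cy1 in layout.chambers)
        assert covered >= 0.95 * (x1 - x0) * (y1 - y0)
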