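"""Leaf-tip tracing and full-stack trace extraction."""

import imageio.v3 as iio
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafrhythm import Config, EmptyMaskError
from leafrhythm.imaging import (PlateImageSeries, build_layout, detect_red_marks,
                                extract_traces, trace_tips, write_overlay)
from leafrhythm.imaging.segment import SeedlingMask


def mask_of(shape, pixels, scale=1.0, chamber=0):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return SeedlingMask(chamber, m, scale)


class TestTraceTips:
    def test_symmetric_block_mean_row(self):
        # 10x10 square at rows 20..29: mean row 24.5 on both rims
        m = np.zeros((60, 60), dtype=bool)
        m[20:30, 20:30] = True
        left, right = trace_tips(SeedlingMask(0, m, 1.0), band=4)
        assert left == pytest.approx(24.5)
        assert right == pytest.approx(24.5)

    def test_single_pixel_arms(self):
        mask = mask_of((60, 60), [(7, 0), (3, 50)])
        left, right = trace_tips(mask, band=4)
        assert (left, right) == (7.0, 3.0)

    def test_scale_rescales_to_full_resolution(self):
        m = np.zeros((60, 60), dtype=bool)
        m[20:30, 20:30] = True
        left, right = trace_tips(SeedlingMask(0, m, 0.5), band=4)
        assert left == pytest.approx(49.0)   # 24.5 / 0.5

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            trace_tips(SeedlingMask(0, np.zeros((5, 5), dtype=bool), 1.0))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 39), st.integers(0, 39)),
                    min_size=1, max_size=60, unique=True),
           st.integers(3, 5))
    def test_mirror_swaps_left_and_right_exactly(self, pixels, band):
        m = np.zeros((40, 40), dtype=bool)
        for r, c in pixels:
            m[r, c] = True
        left, right = trace_tips(SeedlingMask(0, m, 1.0), band=band)
        ml, mr = trace_tips(SeedlingMask(0, m[:, ::-1], 1.0), band=band)
        assert (ml, mr) == (right, left)


class TestExtractTraces:
    def test_static_plant_constant_trace(self, tmp_path):
        from leafrhythm.synthetic import PlateRenderSpec, SimulationSpec
        from leafrhythm.synthetic.plate import render_plate_series
        spec = PlateRenderSpec(
            n_frames=3, seed=2,
            motion=SimulationSpec(period_h=24, amplitude=0, noise_frac=0,
                                  duration_h=120))
        paths, truth = render_plate_series(spec, tmp_path)
        layout = build_layout(detect_red_marks(iio.imread(paths[0])))
        cfg = Config(interval_min=spec.interval_min)
        traces = extract_traces(PlateImageSeries(paths, spec.interval_min),
                                layout, cfg)
        for tr in traces:
            assert np.allclose(tr.left.y, tr.left.y[0])
            assert np.allclose(tr.right.y, tr.right.y[0])

    def test_programmed_motion_recovered(self, short_plate, config):
        spec, paths, truth = short_plate
        cfg = Config(interval_min=spec.interval_min)
        layout = build_layout(detect_red_marks(iio.imread(paths[0])))
        traces = extract_traces(PlateImageSeries(paths, spec.interval_min),
                                layout, cfg)
        for idx in truth.planted:
            tr = traces[idx]
            ok = ~np.isnan(tr.left.y)
            assert ok.mean() >= 0.9
            r = np.corrcoef(tr.left.y[ok], truth.motion[idx][ok])[0, 1]
            assert r >= 0.99

    def test_empty_chamber_flagged_unusable(self, short_plate):
        spec, paths, truth = short_plate
        cfg = Config(interval_min=spec.interval_min)
        layout = build_layout(detect_red_marks(iio.imread(paths[0])))
        traces = extract_traces(PlateImageSeries(paths, spec.interval_min),
                                layout, cfg)
        empty = traces[spec.empty_chambers[0]]
        assert empty.detect_rate == 0.0
        assert not empty.usable
        assert np.isnan(empty.left.y).all()

    def test_stack_needs_two_frames(self, short_plate):
        spec, paths, _ = short_plate
        with pytest.raises(ValueError):
            PlateImageSeries(paths[:1], spec.interval_min)


class TestOverlay:
    def test_border_only_when_no_detections(self, short_plate):
        spec, paths, truth = short_plate
        img = iio.imread(paths[0])
        layout = build_layout(detect_red_marks(img))
        out = write_overlay(img, layout, [])
        diff = np.any(out != img[..., :3], axis=-1)
        # changed pixels lie exactly on chamber perimeters
        perimeter = np.zeros_like(diff)
        for x0, x1, y0, y1 in layout.chambers:
            perimeter[y0, x0:x1] = perimeter[y1 - 1, x0:x1] = True
            perimeter[y0:y1, x0] = perimeter[y0:y1, x1 - 1] = True
        assert not np.logical_and(diff, ~perimeter).any()
        assert img.base is None or True  # input untouched checked below
        assert np.array_equal(iio.imread(paths[0]), img)

    def test_plant_centres_inside_boxes(self, short_plate, config):
        from leafrhythm.imaging import segment_seedling
        spec, paths, truth = short_plate
        img = iio.imread(paths[0])
        layout = build_layout(detect_red_marks(img))
        detections = [segment_seedling(img[y0:y1, x0:x1], ci, config)
                      for ci, (x0, x1, y0, y1) in enumerate(layout.chambers)]
        out = write_overlay(img, layout, detections)
        ox, oy = spec.plate_origin
        c = spec.chamber_size
        for idx in truth.planted:
            row, col = divmod(idx, spec.n_cols)
            cx = int(ox + col * c + c / 2)
            cy = int(truth.tip_rows[idx][0])
            bbox = detections[idx].bbox_full_res()
            assert bbox is not None
            x0, x1, y0, y1 = layout.chambers[idx]
            bx0, bx1, by0, by1 = bbox
            assert x0 + bx0 <= cx <= x0 + bx1
            assert y0 + by0 <= cy <= y0 + by1
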