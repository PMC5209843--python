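"""Synthetic plate-image renderer with stored ground truth.

Renders time-lapse frames of a vertical 25-chamber plate the way the camera
sees it: white background, four red registration discs that encode the plate
and reference-chamber geometry, and per chamber a seedling silhouette (stem
plus two elliptical cotyledons) whose outer tip rows follow a programmed
cosine motion.  The programmed geometry and tip trajectories are returned
alongside the frames so the imaging pipeline can be tested without a camera.

The silhouette model is deliberately minimal — only the tip rows matter to
the tests; it makes no attempt at photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ..errors import SpecError
from .series import SimulationSpec, derived_seed

BACKGROUND = np.array([255, 255, 255], dtype=np.uint8)
PLANT_COLOUR = np.array([30, 70, 30], dtype=np.uint8)
MARK_COLOUR = np.array([230, 20, 20], dtype=np.uint8)   # pure hue 0, high sat/val
SPECKLE_COLOUR = np.array([60, 60, 60], dtype=np.uint8)


@dataclass(frozen=True)
class PlateRenderSpec:
    """Geometry and motion of a synthetic plate time-lapse.

    The four marks follow the layout convention: two at opposite outer plate
    corners and two at the anti-diagonal corners (top-right, bottom-left) of
    the top-left reference chamber.
    """

    width: int = 600
    height: int = 600
    n_rows: int = 5
    n_cols: int = 5
    plate_origin: tuple[float, float] = (50.0, 50.0)   # (x, y) of plate top-left
    chamber_size: float = 100.0                        # square chambers, px
    mark_radius: float = 26.0
    motion: SimulationSpec = field(default_factory=lambda: SimulationSpec(
        period_h=24.0, amplitude=10.0, noise_frac=0.0, duration_h=120.0))
    motion_by_chamber: dict[int, SimulationSpec] | None = None
    empty_chambers: tuple[int, ...] = ()
    speckle_density: float = 0.0     # expected clutter speckles per chamber per frame
    n_frames: int = 72
    interval_min: float = 100.0      # chosen so 72 frames span five 24-h cycles
    t0_h: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        ox, oy = self.plate_origin
        if self.n_frames < 2:
            raise SpecError("need at least 2 frames")
        if self.chamber_size <= 0 or self.mark_radius <= 0:
            raise SpecError("chamber_size and mark_radius must be positive")
        if (ox + self.n_cols * self.chamber_size > self.width
                or oy + self.n_rows * self.chamber_size > self.height):
            raise SpecError("chamber grid does not fit inside the image")
        mark_area = np.pi * self.mark_radius ** 2
        if mark_area < 0.005 * self.width * self.height:
            raise SpecError("mark_radius too small to pass the 0.5% size filter")

    @property
    def times_h(self) -> np.ndarray:
        return self.t0_h + np.arange(self.n_frames) * self.interval_min / 60.0

    @property
    def mark_centres(self) -> list[tuple[float, float]]:
        ox, oy = self.plate_origin
        c = self.chamber_size
        return [(ox, oy),
                (ox + self.n_cols * c, oy + self.n_rows * c),
                (ox + c, oy),
                (ox, oy + c)]

    @property
    def chamber_rects(self) -> list[tuple[int, int, int, int]]:
        """Row-major [x0, x1) x [y0, y1) rectangles of the programmed grid."""
        ox, oy = self.plate_origin
        c = self.chamber_size
        rects = []
        for r in range(self.n_rows):
            for col in range(self.n_cols):
                rects.append((int(round(ox + col * c)), int(round(ox + (col + 1) * c)),
                              int(round(oy + r * c)), int(round(oy + (r + 1) * c))))
        return rects


@dataclass
class PlateGroundTruth:
    """Programmed geometry and motion of a rendered stack."""

    marks: list[tuple[float, float]]
    chamber_rects: list[tuple[int, int, int, int]]
    times_h: np.ndarray
    motion: dict[int, np.ndarray]        # chamber -> programmed displacement s(t), px
    tip_rows: dict[int, np.ndarray]      # chamber -> tip row (image coords) per frame
    planted: list[int]


def _disc(img: np.ndarray, cx: float, cy: float, r: float, colour: np.ndarray) -> None:
    x0, x1 = max(0, int(cx - r) - 1), min(img.shape[1], int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(img.shape[0], int(cy + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
    img[y0:y1, x0:x1][inside] = colour


def _ellipse(img: np.ndarray, cx: float, cy: float, rx: float, ry: float,
             colour: np.ndarray) -> None:
    x0, x1 = max(0, int(cx - rx) - 1), min(img.shape[1], int(cx + rx) + 2)
    y0, y1 = max(0, int(cy - ry) - 1), min(img.shape[0], int(cy + ry) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    img[y0:y1, x0:x1][inside] = colour


def _motion_displacement(spec: SimulationSpec, times_h: np.ndarray,
                         seed: int) -> np.ndarray:
    """Programmed vertical tip displacement (px, upward positive)."""
    s = spec.amplitude * np.cos(
        2.0 * np.pi * (times_h - spec.phase_h) / spec.period_h)
    s = s + spec.trend_slope * times_h
    if spec.noise_frac > 0:
        rng = np.random.default_rng(seed)
        eta = spec.noise_frac * spec.amplitude
        s = s + rng.uniform(-eta, eta, size=len(times_h))
    return s


def render_plate_series(spec: PlateRenderSpec, out_dir: str | Path):
    """Write PNG frames and return (frame paths, ground truth).

    Frames are named ``frame_<k>.png`` so lexicographic order equals time
    order.  Identical spec -> byte-identical frames.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    times = spec.times_h
    ox, oy = spec.plate_origin
    c = spec.chamber_size
    n_chambers = spec.n_rows * spec.n_cols
    planted = [i for i in range(n_chambers) if i not in spec.empty_chambers]

    # programmed motion per planted chamber
    motion: dict[int, np.ndarray] = {}
    tip_rows: dict[int, np.ndarray] = {}
    base_tip_frac = 0.45
    for idx in planted:
        mspec = (spec.motion_by_chamber or {}).get(idx, spec.motion)
        s = _motion_displacement(mspec, times, derived_seed(spec.seed, idx))
        motion[idx] = s
        r0 = oy + (idx // spec.n_cols) * c
        tip_rows[idx] = (r0 + base_tip_frac * c) - s   # upward motion = smaller row

    # static background: white plus the four registration discs
    background = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    background[:] = BACKGROUND
    for mx, my in spec.mark_centres:
        _disc(background, mx, my, spec.mark_radius, MARK_COLOUR)

    rng = np.random.default_rng(derived_seed(spec.seed, 0xC1))
    paths = []
    for k in range(spec.n_frames):
        frame = background.copy()
        for idx in planted:
            row = idx // spec.n_cols
            col = idx % spec.n_cols
            x0, y0 = ox + col * c, oy + row * c
            ccx = x0 + c / 2.0
            tip = tip_rows[idx][k]
            # cotyledons: vertically symmetric ellipses whose outermost
            # columns sit at the programmed tip row
            rx, ry, dx = 0.12 * c, 0.07 * c, 0.15 * c
            _ellipse(frame, ccx - dx, tip, rx, ry, PLANT_COLOUR)
            _ellipse(frame, ccx + dx, tip, rx, ry, PLANT_COLOUR)
            # stem from the chamber floor up to the cotyledons
            sw = max(1, int(round(0.02 * c)))
            top = int(round(tip + ry * 0.5))
            bottom = int(round(y0 + 0.92 * c))
            frame[top:bottom, int(round(ccx - sw)):int(round(ccx + sw))] = PLANT_COLOUR
            if spec.speckle_density > 0:
                n_speck = rng.poisson(spec.speckle_density)
                for _ in range(n_speck):
                    # clutter in the outer ring of the chamber, away from the plant
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0.42, 0.47) * c
                    sx = ccx + rad * np.cos(ang)
                    sy = y0 + c / 2.0 + rad * np.sin(ang)
                    _disc(frame, sx, sy, rng.uniform(0.8, 1.6), SPECKLE_COLOUR)
        path = out_dir / f"frame_{k:04d}.png"
        iio.imwrite(path, frame)
        paths.append(path)

    truth = PlateGroundTruth(marks=spec.mark_centres,
                             chamber_rects=spec.chamber_rects,
                             times_h=times, motion=motion, tip_rows=tip_rows,
                             planted=planted)
    return paths, truth
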