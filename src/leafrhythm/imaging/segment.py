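"""Seedling segmentation by iterative luminance contrasting.

A chamber crop is downscaled to 70% linear size, converted to luminance
(Rec. 601 weights), normalised to a fixed mean level, then sheared eight
times: each pass maps the sub-mean luminance range onto the full range
(values above the mean saturate) and applies a further 10% linear contrast
expansion about mid-grey.  The result is binarised at its mean (plants are
darker than the white-paper background), and connected components are fused
into one plant mask by a metric filter scoring centroid position, area and
shape.  An empty mask encodes "no plant detected".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, transform

from ..config import Config
from .marks import red_mask

#: Rec. 601 luma weights; any fixed luma works, this one is documented.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Mean luminance level every chamber is normalised to before shearing, so
#: the filter behaves identically under lighting drift between frames.
MEAN_TARGET = 0.5


@dataclass
class SeedlingMask:
    """Binary plant mask of one chamber at the working (downscaled) resolution."""

    chamber_index: int
    mask: np.ndarray
    scale: float

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    def bbox_full_res(self) -> tuple[int, int, int, int] | None:
        """(x0, x1, y0, y1) of the mask in full-resolution chamber pixels."""
        if self.empty:
            return None
        rows, cols = np.nonzero(self.mask)
        return (int(cols.min() / self.scale), int(cols.max() / self.scale) + 1,
                int(rows.min() / self.scale), int(rows.max() / self.scale) + 1)


def _blob_scores(labels: np.ndarray, config: Config) -> list[tuple[float, object]]:
    """Plant-likeness score per blob.

    score = 1 - w_dist*(d/d_max) - w_area*(1 - a/a_max) - w_form*e with
    d the centroid distance to the chamber centre (normalised by d_max, half
    the larger chamber dimension, so that blobs hugging any border exceed
    ratio ~0.9), a the blob area (a_max the largest in the chamber) and
    e = 1 - minor/major axis ratio (0 for blobs too small to define axes).
    Seedlings sit near the chamber centre, are the largest dark structure
    and are not extremely elongated, so they score high; edge speckles and
    droplets score low.
    """
    props = measure.regionprops(labels)
    if not props:
        return []
    h, w = labels.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    d_max = max(h, w) / 2.0
    a_max = max(p.area for p in props)
    scored = []
    for p in props:
        d = float(np.hypot(*(np.asarray(p.centroid) - centre)))
        if p.axis_major_length > 0:
            e = 1.0 - p.axis_minor_length / p.axis_major_length
        else:
            e = 0.0
        score = (1.0 - config.w_dist * d / d_max
                 - config.w_area * (1.0 - p.area / a_max)
                 - config.w_form * e)
        scored.append((float(score), p))
    return scored


def unite_blobs(labels: np.ndarray, config: Config | None = None) -> np.ndarray:
    """Fuse plant fragments into one mask via the metric filter.

    The best-scoring blob seeds the union; every other blob joins if its
    score passes the acceptance threshold and its centroid lies within the
    merge radius (a fraction of the chamber diagonal) of the seed.  Split
    cotyledons are re-joined this way while distant clutter is dropped.
    """
    config = config or Config()
    out = np.zeros(labels.shape, dtype=bool)
    scored = _blob_scores(labels, config)
    if not scored:
        return out
    scored.sort(key=lambda s: s[0], reverse=True)
    seed_score, seed = scored[0]
    merge_radius = config.merge_radius_frac * float(np.hypot(*labels.shape))
    seed_centroid = np.asarray(seed.centroid)
    out[labels == seed.label] = True
    for score, blob in scored[1:]:
        dist = float(np.hypot(*(np.asarray(blob.centroid) - seed_centroid)))
        if score >= config.blob_accept and dist <= merge_radius:
            out[labels == blob.label] = True
    return out


def iterative_contrast(luma: np.ndarray, iterations: int = 8,
                       gain: float = 0.10) -> np.ndarray:
    """Shear the luminance spectrum about its mean, repeatedly.

    Each pass maps [0, mean] linearly onto [0, 1] (super-mean values
    saturate) and then stretches by ``gain`` about mid-grey.  Because most of
    a chamber is background, the mean sits just below the background level
    and the plant is driven towards black while the background saturates to
    white.
    """
    img = luma.astype(float).copy()
    for _ in range(iterations):
        m = img.mean()
        if m <= 0.0:
            break
        img = np.clip(img / m, 0.0, 1.0)
        img = np.clip((img - 0.5) * (1.0 + gain) + 0.5, 0.0, 1.0)
    return img


def segment_seedling(chamber_image: np.ndarray, chamber_index: int = 0,
                     config: Config | None = None) -> SeedlingMask:
    """Segment the seedling of one chamber crop.

    Red fiducial pixels (registration discs intruding at chamber corners)
    are replaced by background white before contrasting when
    ``config.mask_red_fiducials`` is set, so they cannot masquerade as plant
    blobs.  Returns a possibly-empty mask; emptiness means "no plant
    detected" and the frame is recorded as missing downstream.
    """
    config = config or Config()
    if chamber_image.size == 0:
        raise ValueError("chamber crop must be non-empty")
    img = np.asarray(chamber_image[..., :3], dtype=float)
    if img.max() > 1.0:
        img = img / 255.0
    if config.mask_red_fiducials:
        fid = red_mask(img, config.hue_tol_deg, config.sat_min, config.val_min)
        if fid.any():
            img = img.copy()
            img[fid] = 1.0
    h, w = img.shape[:2]
    small = transform.resize(
        img, (max(1, round(h * config.scale)), max(1, round(w * config.scale))),
        anti_aliasing=True, preserve_range=True)
    luma = small @ LUMA_WEIGHTS

    mean = luma.mean()
    if mean > 0:
        luma = np.clip(luma * (MEAN_TARGET / mean), 0.0, 1.0)
    sheared = iterative_contrast(luma, config.contrast_iterations,
                                 config.contrast_gain)
    threshold = sheared.mean()
    foreground = sheared < threshold   # plants are darker than the background
    if not foreground.any():
        return SeedlingMask(chamber_index, foreground, config.scale)
    labels = measure.label(foreground, connectivity=2)
    united = unite_blobs(labels, config)
    return SeedlingMask(chamber_index, united, config.scale)
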